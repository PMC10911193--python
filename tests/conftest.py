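import numpy as np
import pandas as pd
import pytest

from symbiotherm.synthetic import ExperimentTruth, generate_experiment


@pytest.fixture(scope="session")
def default_experiment():
    """One full synthetic experiment at default truth, shared across tests."""
    return generate_experiment(seed=1)


@pytest.fixture(scope="session")
def default_truth():
    return ExperimentTruth()


def make_series(temps, start="2022-06-01", interval_s=900, **kw):
    """Helper: TemperatureSeries from a flat array of readings."""
    from symbiotherm.thermal import TemperatureSeries

    temps = np.asarray(temps, dtype=float)
    ts = pd.date_range(start, periods=temps.size, freq=f"{interval_s}s")
    kw.setdefault("logger_id", "L1")
    kw.setdefault("treatment", "25")
    return TemperatureSeries(timestamps=ts, temps_c=temps, **kw)
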