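"""13C enrichment: delta notation, atom-percent, and pulse-validation contrasts.

A NaH13CO3 pulse-chase labels photosynthetically fixed carbon: symbionts
fix 13C during the light pulse and translocate a share to host tissue, so
a successful pulse shows symbiont fraction > symbiotic host fraction >
aposymbiotic host (which stays at natural abundance, ~1.106 atom-%).

delta13C (per-mil vs VPDB) and atom-% 13C interconvert through the VPDB
isotope ratio R = 0.0111802:

    AP = 100 * R*(d/1000 + 1) / (1 + R*(d/1000 + 1))
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats as _stats

__all__ = [
    "R_VPDB",
    "IsotopeSample",
    "EnrichmentSummary",
    "delta_to_atom_percent",
    "atom_percent_to_delta",
    "natural_abundance_ap",
    "enrichment_above_baseline",
    "pulse_validation_contrast",
    "summarize_enrichment",
    "read_isotope_csv",
]

R_VPDB = 0.0111802

FRACTIONS = ("host", "symbiont")


@dataclass(frozen=True)
class IsotopeSample:
    """13C result for one tissue fraction of one animal."""

    animal_id: str
    symbiotic: bool
    fraction: str
    delta13c_permil: float | None = None
    atom_pct_13c: float | None = None
    dry_mass_mg: float = np.nan
    treatment: str = ""

    def __post_init__(self) -> None:
        if self.fraction not in FRACTIONS:
            raise ValueError(f"fraction must be one of {FRACTIONS}")
        if self.delta13c_permil is None and self.atom_pct_13c is None:
            raise ValueError("provide delta13c_permil or atom_pct_13c")
        if self.atom_pct_13c is not None and not (0 < self.atom_pct_13c < 100):
            raise ValueError("atom_pct_13c must lie in (0, 100)")
        if self.fraction == "symbiont" and not self.symbiotic:
            raise ValueError("aposymbiotic animals have no symbiont fraction")

    @property
    def ap(self) -> float:
        """Atom-% 13C, converting from delta notation when needed."""
        if self.atom_pct_13c is not None:
            return float(self.atom_pct_13c)
        return delta_to_atom_percent(self.delta13c_permil)


def delta_to_atom_percent(delta_permil: float) -> float:
    """Convert delta13C (per-mil vs VPDB) to atom-% 13C."""
    d = np.asarray(delta_permil, dtype=float)
    if np.any(d <= -1000):
        raise ValueError("delta13C <= -1000 per-mil is non-physical")
    r = R_VPDB * (d / 1000.0 + 1.0)
    out = 100.0 * r / (1.0 + r)
    return float(out) if np.isscalar(delta_permil) else out


def atom_percent_to_delta(ap: float) -> float:
    """Inverse map: atom-% 13C to delta13C (per-mil vs VPDB)."""
    a = np.asarray(ap, dtype=float)
    if np.any((a <= 0) | (a >= 100)):
        raise ValueError("atom-% must lie in (0, 100)")
    r = a / (100.0 - a)
    out = (r / R_VPDB - 1.0) * 1000.0
    return float(out) if np.isscalar(ap) else out


def natural_abundance_ap() -> float:
    """Atom-% 13C at natural abundance (delta = 0 vs VPDB), ~1.10566."""
    return delta_to_atom_percent(0.0)


def enrichment_above_baseline(sample: IsotopeSample, baseline_ap: float) -> float:
    """Atom-% excess of a sample over a baseline (e.g. unlabeled controls)."""
    if not (0 < baseline_ap < 100):
        raise ValueError("baseline atom-% must lie in (0, 100)")
    return sample.ap - baseline_ap


@dataclass(frozen=True)
class EnrichmentSummary:
    group: str
    mean_ap: float
    se_ap: float | None
    n: int


def summarize_enrichment(samples, group_key=None) -> list[EnrichmentSummary]:
    """Mean ± SE atom-% per group (default: treatment × fraction × state)."""
    if group_key is None:
        group_key = lambda s: (
            f"{s.treatment}/{s.fraction}/{'sym' if s.symbiotic else 'apo'}"
        )
    groups: dict[str, list[float]] = {}
    for s in samples:
        groups.setdefault(group_key(s), []).append(s.ap)
    out = []
    for g, vals in sorted(groups.items()):
        arr = np.asarray(vals)
        se = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else None
        out.append(EnrichmentSummary(group=g, mean_ap=float(arr.mean()), se_ap=se, n=arr.size))
    return out


@dataclass(frozen=True)
class PulseContrastReport:
    """Ordered contrasts of atom-% among symbiont / host / aposymbiotic host."""

    group_means: dict
    contrasts: pd.DataFrame  # pair, estimate, p_adj
    pulse_successful: bool
    alpha: float
    warnings: tuple = ()


def pulse_validation_contrast(samples, alpha: float = 0.05) -> PulseContrastReport:
    """Test whether the 13C pulse worked: symbiont > host > aposymbiotic.

    Builds three groups — symbiont fraction, symbiotic host fraction, and
    aposymbiotic host fraction — and runs Tukey-adjusted pairwise contrasts
    of atom-% on a one-way linear model. Pulse success requires both the
    symbiont-vs-host and host-vs-aposymbiotic contrasts significant with
    the correct sign. Missing groups produce a partial report with a
    warning rather than an error.
    """
    def group_of(s: IsotopeSample) -> str:
        if s.fraction == "symbiont":
            return "symbiont"
        return "host_sym" if s.symbiotic else "host_apo"

    labels, values = [], []
    for s in samples:
        labels.append(group_of(s))
        values.append(s.ap)
    present = sorted(set(labels))
    if len(present) < 2:
        return PulseContrastReport(
            group_means={g: float(np.mean([v for l, v in zip(labels, values) if l == g]))
                         for g in present},
            contrasts=pd.DataFrame(columns=["pair", "estimate", "p_adj"]),
            pulse_successful=False,
            alpha=alpha,
            warnings=("fewer than 2 groups present; contrasts not estimable",),
        )
    warns = tuple(
        f"group '{g}' missing" for g in ("symbiont", "host_sym", "host_apo")
        if g not in present
    )
    table = _stats.tukey_contrasts_oneway(np.asarray(values, float), np.asarray(labels))
    means = {g: float(np.mean([v for l, v in zip(labels, values) if l == g]))
             for g in present}

    def sig_greater(a: str, b: str) -> bool:
        if a not in means or b not in means:
            return False
        row = table[table["pair"].isin([f"{a}-{b}", f"{b}-{a}"])]
        if row.empty:
            return False
        return bool(row["p_adj"].iloc[0] < alpha) and means[a] > means[b]

    success = sig_greater("symbiont", "host_sym") and sig_greater("host_sym", "host_apo")
    return PulseContrastReport(
        group_means=means,
        contrasts=table,
        pulse_successful=success,
        alpha=alpha,
        warnings=warns,
    )


def read_isotope_csv(path) -> list[IsotopeSample]:
    """Read an isotope results CSV; either delta or atom-% column suffices."""
    df = pd.read_csv(path)
    if "animal_id" not in df.columns or "fraction" not in df.columns:
        raise ValueError("isotope CSV needs columns animal_id, fraction")
    samples = []
    for r in df.to_dict("records"):
        delta = r.get("delta13c_permil")
        ap = r.get("atom_pct_13c")
        samples.append(
            IsotopeSample(
                animal_id=str(r["animal_id"]),
                symbiotic=bool(r.get("symbiotic", True)),
                fraction=str(r["fraction"]),
                delta13c_permil=None if pd.isna(delta) else float(delta),
                atom_pct_13c=None if ap is None or pd.isna(ap) else float(ap),
                dry_mass_mg=float(r.get("dry_mass_mg", np.nan)),
                treatment=str(r.get("treatment", "")),
            )
        )
    return samples
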