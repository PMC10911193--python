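"""Synthetic ramp-and-hold heat-stress experiment with known ground truth.

Emulates the full design of the anemone heat-stress study: two cohorts
(high and low symbiont density, HD/LD), four nominal temperatures (25, 27,
29, 31 °C), symbiotic and aposymbiotic states, four containers per
treatment per state with 3–4 animals each, over an 18-day calendar
(acclimation days 0–2, then a 1 °C/day ramp to target and a hold). Five
data streams are produced, each shaped like the corresponding instrument
export:

* temperature logs (per-container bath loggers + paired offset spot checks)
* O2 respirometry traces with a plate map and host protein table
* two-channel SNARF-1 cell intensity tables + calibration standards
* 13C isotope results per tissue fraction
* phenotype tables (symbiont counts in triplicate, protein, color, size)

The generating truth is explicit and serializable, so every pipeline stage
can be tested by parameter recovery. Metabolic truth uses a
hyperbolic-tangent photosynthesis–irradiance law modulated by a quadratic
thermal performance factor peaking at the true T_opt; noise is Gaussian
for temperatures and O2 (AR(1) within a trace), lognormal for counts and
isotope enrichment.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ph_imaging import _sigmoid

__all__ = [
    "ExperimentTruth",
    "SyntheticExperiment",
    "generate_temperature_logs",
    "generate_o2_traces",
    "generate_snarf_cells",
    "generate_isotopes",
    "generate_phenotypes",
    "generate_experiment",
]

LIGHT_LEVELS = (24.0, 60.0, 113.0, 165.0, 217.0, 270.0)
NATURAL_AP = 1.1056585  # atom-% 13C at delta = 0 vs VPDB


@dataclass(frozen=True)
class ExperimentTruth:
    """Ground-truth parameter bundle for one synthetic experiment."""

    treatments_c: tuple = (25.0, 27.0, 29.0, 31.0)
    cohorts: tuple = ("HD", "LD")
    baseline_cells: dict = field(
        default_factory=lambda: {"HD": 1.05e6, "LD": 2.69e5}
    )
    containers_per_group: int = 4
    animals_per_container: tuple = (3, 4)  # inclusive range
    n_days: int = 18
    acclimation_days: int = 3
    ramp_c_per_day: float = 1.0
    reading_interval_s: float = 120.0
    temp_sigma_c: float = 0.15
    container_offset_mean_c: float = 0.15
    container_offset_sd_c: float = 0.05
    offset_pair_noise_c: float = 0.05

    # metabolic truth (vial-slope scale, µmol O2 l^-1 min^-1)
    t_opt_pmax_c: float = 26.4
    t_opt_ledr_c: float = 27.2
    thermal_width_c: float = 6.0
    gross_pmax_slope: float = 1.2
    resp_slope: float = 0.4
    apo_gross_slope: float = 0.02
    apo_resp_slope: float = 0.03
    saturation_light_umol: float = 60.0
    o2_noise_umol_l: float = 0.02
    o2_noise_ar1: float = 0.3
    blank_slope_sd: float = 0.003
    n_respiro_animals: int = 8  # per state per treatment (HD cohort)
    n_blanks: int = 4
    n_below_lod_apo: int = 2  # per treatment, constructed near the blank band
    trace_duration_s: float = 660.0
    trace_interval_s: float = 15.0
    vial_volume_l: float = 0.004
    protein_sym_ug: float = 800.0
    protein_apo_ug: float = 300.0
    protein_below_lod_ug: float = 100.0

    # intracellular pH truth
    ph_at_25: dict = field(
        default_factory=lambda: {"symbiocyte": 7.35, "non_symbiocyte": 7.45}
    )
    ph_drop_per_6c: float = 0.30  # total decline from 25 to 31 °C
    cell_ph_sigma: float = 0.10
    animal_ph_sigma: float = 0.05
    channel_noise_frac: float = 0.01
    cells_symbiocyte: tuple = (9, 22)
    cells_non_symbiocyte: tuple = (7, 38)
    n_ph_animals: int = 4  # per state per treatment per cohort
    calibration_params: tuple = (2.2, 0.6, 7.2, 0.4)  # decreasing 585/640 ratio
    calibration_ph_grid: tuple = (6.0, 6.3, 6.6, 6.9, 7.2, 7.5, 7.8, 8.1, 8.4)
    standards_noise_frac: float = 0.005

    # isotope truth (atom-% 13C)
    pulse_umol_l: float = 31.22  # NaH13CO3 pulse concentration
    symbiont_excess_25: dict = field(
        default_factory=lambda: {"HD": 0.90, "LD": 0.60}
    )
    host_excess_25: dict = field(default_factory=lambda: {"HD": 0.30, "LD": 0.20})
    hd_host_excess_31_frac: float = 0.33  # HD host excess at 31 °C vs 25 °C
    isotope_lognorm_sigma: float = 0.15
    n_isotope_animals: int = 4
    n_apo_controls: int = 3

    # phenotype truth
    hd_loss_factors: dict = field(
        default_factory=lambda: {25.0: 1.0, 27.0: 0.95, 29.0: 0.75, 31.0: 0.5}
    )
    protein_cohort_ug: dict = field(
        default_factory=lambda: {"HD": 800.0, "LD": 1500.0}
    )
    apo_cells: float = 2.0e4
    count_lognorm_sigma: float = 0.2
    container_lognorm_sigma: float = 0.1
    protein_lognorm_sigma: float = 0.15

    master_seed: int = 0

    # --- truth functions ---------------------------------------------------

    def thermal_factor(self, temp_c, t_opt: float) -> np.ndarray:
        z = (np.asarray(temp_c, dtype=float) - t_opt) / self.thermal_width_c
        return np.maximum(0.0, 1.0 - z**2)

    def pi_slope(self, light_umol, temp_c: float, symbiotic: bool) -> np.ndarray:
        """True vial O2 slope (µmol l⁻¹ min⁻¹) at one light and temperature.

        Parameterized on the measurable envelopes: the net saturated
        photosynthetic rate peaks at ``t_opt_pmax_c`` and dark respiration
        magnitude peaks at ``t_opt_ledr_c`` — so the named optima are the
        optima of exactly the quantities the pipeline recovers.
        """
        light = np.asarray(light_umol, dtype=float)
        net_scale = self.gross_pmax_slope if symbiotic else self.apo_gross_slope
        resp = self.resp_slope if symbiotic else self.apo_resp_slope
        p_net = net_scale * self.thermal_factor(temp_c, self.t_opt_pmax_c)
        r = resp * self.thermal_factor(temp_c, self.t_opt_ledr_c)
        return (p_net + r) * np.tanh(light / self.saturation_light_umol) - r

    def normalized_pmax(self, temp_c: float, symbiotic: bool = True) -> float:
        """True protein-normalized P_max over the measured light range."""
        protein = self.protein_sym_ug if symbiotic else self.protein_apo_ug
        slopes = self.pi_slope(np.array(LIGHT_LEVELS), temp_c, symbiotic)
        return float(slopes.max() * self.vial_volume_l / protein)

    def normalized_ledr(self, temp_c: float, symbiotic: bool = True) -> float:
        protein = self.protein_sym_ug if symbiotic else self.protein_apo_ug
        dark = self.pi_slope(0.0, temp_c, symbiotic)
        return float(dark * self.vial_volume_l / protein)

    def ph_truth(self, treatment_c: float, cell_class: str) -> float:
        base = self.ph_at_25[cell_class]
        return base - self.ph_drop_per_6c * (treatment_c - 25.0) / 6.0

    def true_ratio(self, ph) -> np.ndarray:
        return _sigmoid(np.asarray(ph, dtype=float), *self.calibration_params)

    def loss_factor(self, cohort: str, treatment_c: float) -> float:
        if cohort == "HD":
            return self.hd_loss_factors[float(treatment_c)]
        return 1.0

    def host_excess(self, cohort: str, treatment_c: float) -> float:
        base = self.host_excess_25[cohort]
        if cohort == "LD":
            return base
        # HD host assimilation declines linearly toward the top temperature
        frac = 1.0 - (1.0 - self.hd_host_excess_31_frac) * (treatment_c - 25.0) / 6.0
        return base * frac

    def symbiont_excess(self, cohort: str, treatment_c: float) -> float:
        base = self.symbiont_excess_25[cohort]
        if cohort == "LD":
            return base
        frac = 1.0 - (1.0 - self.hd_host_excess_31_frac) * (treatment_c - 25.0) / 6.0
        return base * frac

    def bath_profile_c(self, target_c: float) -> np.ndarray:
        """Nominal daily bath temperature for an 18-day ramp-and-hold."""
        days = np.arange(self.n_days, dtype=float)
        ramp = 25.0 + self.ramp_c_per_day * np.maximum(
            0.0, days - (self.acclimation_days - 1)
        )
        return np.minimum(ramp, target_c)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, default=str, indent=2, sort_keys=True)


@dataclass
class SyntheticExperiment:
    """All synthetic data streams plus the truth that generated them."""

    temperature_logs: pd.DataFrame
    offset_pairs: pd.DataFrame
    o2_traces: pd.DataFrame
    plate_map: pd.DataFrame
    protein: pd.DataFrame
    cells: pd.DataFrame
    standards: pd.DataFrame
    isotopes: pd.DataFrame
    phenotypes: pd.DataFrame
    truth: ExperimentTruth

    def write(self, outdir) -> None:
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name in (
            "temperature_logs", "offset_pairs", "o2_traces", "plate_map",
            "protein", "cells", "standards", "isotopes", "phenotypes",
        ):
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)
        (out / "truth.json").write_text(self.truth.to_json())


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def generate_temperature_logs(
    truth: ExperimentTruth, seed=0, start: str = "2022-06-01"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-container bath logger series plus paired offset spot checks.

    Returns (logs, offset_pairs). Logs carry the bath temperature with
    Gaussian reading noise; each treatment has a constant true
    bath-vs-container offset, observable through six paired spot
    measurements per treatment (as in the offset-correction protocol).
    """
    rng = _rng(seed)
    t0 = pd.Timestamp(start)
    n_per_day = int(round(86400 / truth.reading_interval_s))
    log_rows = []
    pair_rows = []
    for cohort in truth.cohorts:
        for target in truth.treatments_c:
            offset = rng.normal(truth.container_offset_mean_c, truth.container_offset_sd_c)
            daily = truth.bath_profile_c(target)
            base = np.repeat(daily, n_per_day)
            ts = t0 + pd.to_timedelta(
                np.arange(base.size) * truth.reading_interval_s, unit="s"
            )
            for state in ("sym", "apo"):
                for c in range(truth.containers_per_group):
                    noise = rng.normal(0.0, truth.temp_sigma_c, base.size)
                    log_rows.append(
                        pd.DataFrame(
                            {
                                "timestamp": ts,
                                "temperature": base + noise,
                                "logger_id": f"{cohort}-{target:g}-{state}-c{c+1}",
                                "treatment": f"{target:g}",
                                "cohort": cohort,
                                "state": state,
                                "true_offset_c": offset,
                            }
                        )
                    )
            for day in np.linspace(2, truth.n_days - 1, 6).astype(int):
                t_bath = daily[day] + rng.normal(0, truth.offset_pair_noise_c)
                t_cont = daily[day] - offset + rng.normal(0, truth.offset_pair_noise_c)
                pair_rows.append(
                    {
                        "cohort": cohort,
                        "treatment": f"{target:g}",
                        "day": int(day),
                        "t_tank": t_bath,
                        "t_container": t_cont,
                    }
                )
    return pd.concat(log_rows, ignore_index=True), pd.DataFrame(pair_rows)


def generate_o2_traces(
    truth: ExperimentTruth, seed=0
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """O2 traces (long format), plate map, and host protein table.

    HD-cohort design: per treatment, ``n_respiro_animals`` symbiotic and
    aposymbiotic animals plus ``n_blanks`` seawater-only vials, each
    measured at six irradiances then darkness. A configured number of
    aposymbiotic animals get dark slopes inside the blank ±1 SE band to
    exercise limit-of-detection flagging.
    """
    rng = _rng(seed)
    t = np.arange(0.0, truth.trace_duration_s + 1e-9, truth.trace_interval_s)
    lights = (*LIGHT_LEVELS, 0.0)
    trace_rows = []
    map_rows = []
    protein_rows = []

    def emit_trace(vial, animal, light, temp, slope):
        ar = np.empty(t.size)
        eps = rng.normal(0.0, truth.o2_noise_umol_l, t.size)
        ar[0] = eps[0]
        for i in range(1, t.size):
            ar[i] = truth.o2_noise_ar1 * ar[i - 1] + eps[i]
        o2 = 220.0 + slope * t / 60.0 + ar
        trace_rows.append(
            pd.DataFrame(
                {
                    "vial_id": vial,
                    "timestamp_s": t,
                    "o2_umol_l": np.maximum(o2, 0.0),
                    "light_umol": light,
                    "temperature_c": temp,
                }
            )
        )

    for temp in truth.treatments_c:
        tkey = f"{temp:g}"
        for b in range(truth.n_blanks):
            vial = f"blank-{tkey}-{b+1}"
            map_rows.append({"vial_id": vial, "animal_id": "", "symbiotic": "",
                             "temperature_c": temp})
            for light in lights:
                emit_trace(vial, None, light, temp,
                           rng.normal(0.0, truth.blank_slope_sd))
        for state, symbiotic in (("sym", True), ("apo", False)):
            for a in range(truth.n_respiro_animals):
                animal = f"resp-{tkey}-{state}-{a+1}"
                vial = f"vial-{tkey}-{state}-{a+1}"
                below_lod = (not symbiotic) and a < truth.n_below_lod_apo
                protein = (
                    truth.protein_below_lod_ug if below_lod
                    else (truth.protein_sym_ug if symbiotic else truth.protein_apo_ug)
                )
                protein_rows.append(
                    {"animal_id": animal,
                     "protein_ug": protein * np.exp(rng.normal(0, 0.05))}
                )
                map_rows.append({"vial_id": vial, "animal_id": animal,
                                 "symbiotic": symbiotic, "temperature_c": temp,
                                 "below_lod_constructed": below_lod})
                for light in lights:
                    if below_lod:
                        slope = rng.normal(0.0, 0.0003)
                    else:
                        slope = truth.pi_slope(light, temp, symbiotic)
                        slope = slope + rng.normal(0.0, 0.002)
                    emit_trace(vial, animal, light, temp, slope)
    return (
        pd.concat(trace_rows, ignore_index=True),
        pd.DataFrame(map_rows),
        pd.DataFrame(protein_rows),
    )


def generate_snarf_cells(
    truth: ExperimentTruth, seed=0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell two-channel intensities plus calibration standards.

    Cell pH = treatment/class truth + animal offset + cell noise; the true
    calibration sigmoid converts pH to the 585/640 ratio, from which the
    two channel intensities are back-computed with multiplicative channel
    noise. Aposymbiotic animals contribute non-symbiocytes only.
    """
    rng = _rng(seed)
    cell_rows = []
    bg_585, bg_640 = 4.0, 5.0
    for cohort in truth.cohorts:
        for temp in truth.treatments_c:
            for state in ("sym", "apo"):
                for a in range(truth.n_ph_animals):
                    animal = f"ph-{cohort}-{temp:g}-{state}-{a+1}"
                    animal_off = rng.normal(0.0, truth.animal_ph_sigma)
                    classes = (
                        ("symbiocyte", "non_symbiocyte") if state == "sym"
                        else ("non_symbiocyte",)
                    )
                    for cls in classes:
                        lo, hi = (
                            truth.cells_symbiocyte if cls == "symbiocyte"
                            else truth.cells_non_symbiocyte
                        )
                        n_cells = int(rng.integers(lo, hi + 1))
                        ph = (
                            truth.ph_truth(temp, cls)
                            + animal_off
                            + rng.normal(0.0, truth.cell_ph_sigma, n_cells)
                        )
                        ratio = truth.true_ratio(ph)
                        sig_640 = rng.uniform(60.0, 180.0, n_cells)
                        sig_585 = ratio * sig_640
                        sig_640 = sig_640 * (
                            1 + rng.normal(0, truth.channel_noise_frac, n_cells)
                        )
                        sig_585 = sig_585 * (
                            1 + rng.normal(0, truth.channel_noise_frac, n_cells)
                        )
                        for i in range(n_cells):
                            cell_rows.append(
                                {
                                    "cell_id": f"{animal}-{cls[:3]}-{i+1}",
                                    "animal_id": animal,
                                    "cohort": cohort,
                                    "treatment": f"{temp:g}",
                                    "symbiotic": state == "sym",
                                    "cell_class": cls,
                                    "i_585": sig_585[i] + bg_585,
                                    "i_640": sig_640[i] + bg_640,
                                    "bg_585": bg_585,
                                    "bg_640": bg_640,
                                }
                            )
    ph_grid = np.asarray(truth.calibration_ph_grid)
    ratio = truth.true_ratio(ph_grid)
    span = float(ratio.max() - ratio.min())
    ratio_noisy = ratio + rng.normal(0, truth.standards_noise_frac * span, ratio.size)
    standards = pd.DataFrame({"ph": ph_grid, "ratio": ratio_noisy})
    return pd.DataFrame(cell_rows), standards


def generate_isotopes(truth: ExperimentTruth, seed=0) -> pd.DataFrame:
    """Isotope results mirroring the pulse-chase design.

    Symbiotic animals (``n_isotope_animals`` per treatment per cohort)
    yield host and symbiont fractions; aposymbiotic controls at 25 °C stay
    at natural abundance. Enrichment above baseline is multiplicative
    lognormal around the truth.
    """
    rng = _rng(seed)
    rows = []

    def ap_value(excess):
        if excess <= 0:
            return NATURAL_AP + rng.normal(0.0, 0.002)
        return NATURAL_AP + excess * np.exp(
            rng.normal(0.0, truth.isotope_lognorm_sigma)
        )

    for cohort in truth.cohorts:
        for temp in truth.treatments_c:
            for a in range(truth.n_isotope_animals):
                animal = f"iso-{cohort}-{temp:g}-sym-{a+1}"
                for fraction, excess in (
                    ("host", truth.host_excess(cohort, temp)),
                    ("symbiont", truth.symbiont_excess(cohort, temp)),
                ):
                    rows.append(
                        {
                            "animal_id": animal,
                            "cohort": cohort,
                            "treatment": f"{temp:g}",
                            "symbiotic": True,
                            "fraction": fraction,
                            "atom_pct_13c": ap_value(excess),
                            "dry_mass_mg": float(rng.uniform(0.5, 3.0)),
                        }
                    )
        for a in range(truth.n_apo_controls):
            rows.append(
                {
                    "animal_id": f"iso-{cohort}-25-apo-{a+1}",
                    "cohort": cohort,
                    "treatment": "25",
                    "symbiotic": False,
                    "fraction": "host",
                    "atom_pct_13c": ap_value(0.0),
                    "dry_mass_mg": float(rng.uniform(0.2, 1.0)),
                }
            )
    return pd.DataFrame(rows)


def generate_phenotypes(truth: ExperimentTruth, seed=0) -> pd.DataFrame:
    """Per-animal phenotype table: counts (triplicate), protein, color, size.

    HD symbiont counts decline dose-dependently to ~50% at 31 °C; LD stays
    flat; aposymbiotic counts are near zero. Containers carry lognormal
    random intercepts so mixed-model selection has signal to recover.
    """
    rng = _rng(seed)
    rows = []
    for cohort in truth.cohorts:
        for temp in truth.treatments_c:
            for state, symbiotic in (("sym", True), ("apo", False)):
                for c in range(truth.containers_per_group):
                    container = f"{cohort}-{temp:g}-{state}-c{c+1}"
                    cont_eff = np.exp(
                        rng.normal(0.0, truth.container_lognorm_sigma)
                    )
                    n_animals = int(
                        rng.integers(
                            truth.animals_per_container[0],
                            truth.animals_per_container[1] + 1,
                        )
                    )
                    for a in range(n_animals):
                        animal = f"{container}-a{a+1}"
                        if symbiotic:
                            mean_cells = (
                                truth.baseline_cells[cohort]
                                * truth.loss_factor(cohort, temp)
                                * cont_eff
                            )
                        else:
                            mean_cells = truth.apo_cells
                        cells = mean_cells * np.exp(
                            rng.normal(0.0, truth.count_lognorm_sigma)
                        )
                        reps = cells * np.exp(rng.normal(0.0, 0.05, 3))
                        protein_base = (
                            truth.protein_cohort_ug[cohort]
                            if symbiotic
                            else truth.protein_apo_ug
                        )
                        protein = protein_base * np.exp(
                            rng.normal(0.0, truth.protein_lognorm_sigma)
                        )
                        rel = cells / truth.baseline_cells["HD"]
                        roi_red = float(np.clip(200.0 * (1.0 - 0.8 * min(rel, 1.0))
                                                + rng.normal(0, 5), 0, 255))
                        disk = (1.3 if cohort == "LD" else 1.0) * np.exp(
                            rng.normal(0, 0.1)
                        )
                        rows.append(
                            {
                                "animal_id": animal,
                                "cohort": cohort,
                                "treatment": f"{temp:g}",
                                "symbiotic": symbiotic,
                                "container": container,
                                "count_rep1": reps[0],
                                "count_rep2": reps[1],
                                "count_rep3": reps[2],
                                "cells_per_animal": cells,
                                "protein_ug": protein,
                                "roi_red_intensity": roi_red,
                                "standard_red_intensity": 200.0,
                                "disk_px": disk * 300.0,
                                "ruler_px_per_cm": 300.0,
                            }
                        )
    return pd.DataFrame(rows)


def generate_experiment(truth: ExperimentTruth | None = None, seed: int | None = None) -> SyntheticExperiment:
    """Generate all five streams reproducibly from one master seed."""
    if truth is None:
        truth = ExperimentTruth()
    if seed is None:
        seed = truth.master_seed
    children = np.random.SeedSequence(seed).spawn(5)
    logs, pairs = generate_temperature_logs(truth, np.random.default_rng(children[0]))
    traces, plate_map, protein = generate_o2_traces(truth, np.random.default_rng(children[1]))
    cells, standards = generate_snarf_cells(truth, np.random.default_rng(children[2]))
    isotopes = generate_isotopes(truth, np.random.default_rng(children[3]))
    phenotypes = generate_phenotypes(truth, np.random.default_rng(children[4]))
    return SyntheticExperiment(
        temperature_logs=logs,
        offset_pairs=pairs,
        o2_traces=traces,
        plate_map=plate_map,
        protein=protein,
        cells=cells,
        standards=standards,
        isotopes=isotopes,
        phenotypes=phenotypes,
        truth=truth,
    )
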