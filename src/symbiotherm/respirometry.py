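"""Respirometry: O2 slopes, photosynthesis-irradiance fits, thermal optima.

Animals sit in 4 ml vials on an optical sensor dish; O2 concentration is
read every ~15 s for >=10 min at each of six increasing irradiances and
then in darkness. The pipeline is:

1. ``extract_rate`` — ordinary-least-squares slope over the best linear
   window (5-10 min, starting >=30 s after the light change), chosen by
   exhaustive search maximizing R^2. This replaces by-eye subsetting of the
   linear period with a reproducible rule.
2. ``blank_correct`` — subtract the mean slope of seawater-only blank vials
   at the same temperature and light, removing microbial O2 turnover.
3. ``flag_below_lod`` — animals whose uncorrected dark slope falls within
   +/-1 SE of the dark blanks are below the limit of detection and are
   excluded from metabolic summaries.
4. ``to_total_o2`` / ``normalize_to_protein`` — convert concentration
   change to total O2 per minute (x vial volume) and normalize to host
   protein.
5. ``fit_pi_curve`` — penalized-spline smooth of rate on irradiance;
   P_max is the maximum of the predicted curve over the observed light
   range; LEDR is the blank-corrected dark rate.
6. ``fit_thermal_performance`` — smooth of P_max (or LEDR) on treatment
   temperature; T_opt is where the first derivative of the smooth crosses
   zero from + to -, with a seeded bootstrap over individuals for its SE.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .smoothing import SplineSmooth, fit_penalized_spline

__all__ = [
    "O2Trace",
    "RateEstimate",
    "PICurve",
    "MetabolicSummary",
    "ThermalPerformance",
    "extract_rate",
    "blank_correct",
    "flag_below_lod",
    "to_total_o2",
    "normalize_to_protein",
    "fit_pi_curve",
    "fit_thermal_performance",
]

DEFAULT_VIAL_VOLUME_L = 0.004
PREDICTION_GRID_POINTS = 512


@dataclass(frozen=True)
class O2Trace:
    """One vial's O2 concentration time course at one light level."""

    vial_id: str
    animal_id: str | None  # None marks a seawater-only blank
    light_umol: float
    timestamps_s: np.ndarray
    o2_umol_l: np.ndarray
    temperature_c: float
    volume_l: float = DEFAULT_VIAL_VOLUME_L

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps_s, dtype=float)
        o2 = np.asarray(self.o2_umol_l, dtype=float)
        object.__setattr__(self, "timestamps_s", t)
        object.__setattr__(self, "o2_umol_l", o2)
        if t.size != o2.size:
            raise ValueError("timestamps and O2 arrays differ in length")
        if t.size > 1 and not (np.diff(t) > 0).all():
            raise ValueError("timestamps must be strictly increasing")
        if (o2 < 0).any():
            raise ValueError("O2 concentrations must be non-negative")
        if self.volume_l <= 0:
            raise ValueError("vial volume must be positive")

    @property
    def is_blank(self) -> bool:
        return self.animal_id is None

    @property
    def duration_s(self) -> float:
        return float(self.timestamps_s[-1] - self.timestamps_s[0])


@dataclass(frozen=True)
class RateEstimate:
    """OLS slope of O2 vs time over the selected linear window."""

    slope_umol_l_min: float
    window_start_s: float
    window_end_s: float
    r_squared: float
    n_points: int
    vial_id: str = ""
    animal_id: str | None = None
    light_umol: float = np.nan
    temperature_c: float = np.nan


@dataclass(frozen=True)
class PICurve:
    """Blank-corrected, protein-normalized rates across irradiances."""

    animal_id: str
    symbiotic: bool
    temperature_c: float
    points: tuple  # of (light_umol, rate_norm)

    def __post_init__(self) -> None:
        lights = [p[0] for p in self.points]
        if len(set(lights)) != len(lights):
            raise ValueError("light levels must be unique within a curve")


@dataclass(frozen=True)
class MetabolicSummary:
    animal_id: str
    temperature_c: float = np.nan
    symbiotic: bool = True
    p_max: float | None = None
    ledr: float | None = None
    edf: float | None = None
    below_lod: bool = False


@dataclass(frozen=True)
class ThermalPerformance:
    metric: str  # "p_max" or "ledr"
    t_opt_c: float
    t_opt_se_c: float
    fitted_curve: np.ndarray  # (grid, 2): temperature, predicted rate
    n_bootstrap: int
    edf: float


def _ols_slope_r2(t_min: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope (per minute) and R^2; constant y reports R^2 = 1 by convention."""
    tbar = t_min.mean()
    ybar = y.mean()
    dt = t_min - tbar
    dy = y - ybar
    sxx = float(dt @ dt)
    sxy = float(dt @ dy)
    syy = float(dy @ dy)
    slope = sxy / sxx
    if syy == 0.0:
        return 0.0, 1.0
    return slope, (sxy * sxy) / (sxx * syy)


def extract_rate(
    trace: O2Trace,
    min_window_min: float = 5.0,
    max_window_min: float = 10.0,
    skip_s: float = 30.0,
) -> RateEstimate:
    """Select the most linear admissible window and return its OLS slope.

    Admissible windows start at least ``skip_s`` after the light-level
    transition (the start of the trace, allowing light acclimation) and
    span between ``min_window_min`` and ``max_window_min`` minutes. Among
    them the window maximizing R^2 wins; ties break to the earliest start,
    then the longest window. An all-constant trace yields slope 0 with
    R^2 reported as 1 by convention.
    """
    t = trace.timestamps_s
    y = trace.o2_umol_l
    t0 = t[0]
    min_len_s = min_window_min * 60.0
    max_len_s = max_window_min * 60.0
    if trace.duration_s < skip_s + min_len_s:
        raise ValueError(
            f"trace {trace.vial_id}: duration {trace.duration_s:.0f}s too short "
            f"for skip {skip_s:.0f}s + window {min_len_s:.0f}s"
        )
    rel = t - t0
    start_candidates = np.nonzero(rel >= skip_s)[0]
    best: tuple | None = None
    for i in start_candidates:
        # admissible end indices j: window span within [min_len, max_len]
        spans = rel - rel[i]
        j_ok = np.nonzero((spans >= min_len_s) & (spans <= max_len_s))[0]
        for j in j_ok:
            if j - i + 1 < 3:
                continue
            seg_t = rel[i : j + 1] / 60.0
            seg_y = y[i : j + 1]
            slope, r2 = _ols_slope_r2(seg_t, seg_y)
            length = rel[j] - rel[i]
            key = (r2, -rel[i], length)
            if best is None or key > best[0]:
                best = (key, slope, r2, float(t[i]), float(t[j]), j - i + 1)
    if best is None:
        raise ValueError(f"trace {trace.vial_id}: no admissible window")
    _, slope, r2, ws, we, npts = best
    return RateEstimate(
        slope_umol_l_min=slope,
        window_start_s=ws,
        window_end_s=we,
        r_squared=r2,
        n_points=npts,
        vial_id=trace.vial_id,
        animal_id=trace.animal_id,
        light_umol=trace.light_umol,
        temperature_c=trace.temperature_c,
    )


def _blank_stats(blanks: Sequence[RateEstimate]):
    """Mean and SE of blank slopes grouped by (temperature, light)."""
    groups: dict[tuple, list[float]] = {}
    for b in blanks:
        groups.setdefault((b.temperature_c, b.light_umol), []).append(b.slope_umol_l_min)
    stats = {}
    for key, vals in groups.items():
        arr = np.asarray(vals)
        se = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else np.nan
        stats[key] = (float(arr.mean()), se, arr.size)
    return stats


@dataclass(frozen=True)
class CorrectedRate:
    """An animal rate after blank subtraction, with the blank stats attached."""

    rate: RateEstimate
    corrected_slope_umol_l_min: float
    blank_mean: float
    blank_se: float
    n_blanks: int


def blank_correct(
    rates: Sequence[RateEstimate], blanks: Sequence[RateEstimate]
) -> list[CorrectedRate]:
    """Subtract the mean blank slope at each (temperature, light) group."""
    stats = _blank_stats(blanks)
    out = []
    for r in rates:
        key = (r.temperature_c, r.light_umol)
        if key not in stats:
            raise KeyError(
                f"no blank vials for temperature {key[0]} °C at light {key[1]} "
                f"µmol m⁻² s⁻¹"
            )
        mean, se, n = stats[key]
        out.append(
            CorrectedRate(
                rate=r,
                corrected_slope_umol_l_min=r.slope_umol_l_min - mean,
                blank_mean=mean,
                blank_se=se,
                n_blanks=n,
            )
        )
    return out


def flag_below_lod(dark_rate: RateEstimate, blank_mean: float, blank_se: float) -> bool:
    """True when the uncorrected dark slope sits within +/-1 SE of dark blanks."""
    if not np.isfinite(blank_se):
        raise ValueError("blank SE undefined: need >=2 dark blank vials")
    return blank_mean - blank_se <= dark_rate.slope_umol_l_min <= blank_mean + blank_se


def to_total_o2(rate_umol_l_min: float, volume_l: float = DEFAULT_VIAL_VOLUME_L) -> float:
    """Concentration change (µmol l⁻¹ min⁻¹) → total O2 change (µmol min⁻¹)."""
    if volume_l <= 0:
        raise ValueError("volume must be positive")
    return rate_umol_l_min * volume_l


def normalize_to_protein(rate_umol_min: float, protein_ug: float) -> float:
    """Total O2 rate → per-µg-host-protein rate."""
    if protein_ug <= 0:
        raise ValueError("protein mass must be positive")
    return rate_umol_min / protein_ug


def fit_pi_curve(curve: PICurve) -> MetabolicSummary:
    """Smooth rate on irradiance; report P_max, LEDR and the smooth's edf.

    P_max is the maximum of the predicted curve evaluated on a dense grid
    restricted to the observed light range (no extrapolation). LEDR is the
    dark-point (0 irradiance) rate itself, not a fitted value.
    """
    pts = sorted(curve.points)
    if len(pts) < 3:
        raise ValueError("need at least 3 light levels to fit a P-I curve")
    light = np.array([p[0] for p in pts], dtype=float)
    rate = np.array([p[1] for p in pts], dtype=float)
    smooth = fit_penalized_spline(light, rate)
    grid = np.linspace(light.min(), light.max(), PREDICTION_GRID_POINTS)
    pred = smooth.predict(grid)
    ledr = None
    if light[0] == 0.0:
        ledr = float(rate[0])
    return MetabolicSummary(
        animal_id=curve.animal_id,
        temperature_c=curve.temperature_c,
        symbiotic=curve.symbiotic,
        p_max=float(pred.max()),
        ledr=ledr,
        edf=smooth.edf,
        below_lod=False,
    )


def _t_opt_from_smooth(smooth: SplineSmooth, tmin: float, tmax: float) -> float:
    """Interior + -> - derivative zero crossing, else the boundary maximum."""
    grid = np.linspace(tmin, tmax, PREDICTION_GRID_POINTS)
    pred = smooth.predict(grid)
    deriv = np.gradient(pred, grid)
    sign = np.sign(deriv)
    crossings = np.nonzero((sign[:-1] > 0) & (sign[1:] <= 0))[0]
    if crossings.size:
        # among crossings pick the one with the highest predicted value
        best = crossings[np.argmax(pred[crossings])]
        i = best
        d0, d1 = deriv[i], deriv[i + 1]
        if d0 == d1:
            return float(grid[i])
        frac = d0 / (d0 - d1)
        return float(grid[i] + frac * (grid[i + 1] - grid[i]))
    return float(grid[np.argmax(pred)])


def fit_thermal_performance(
    summaries: Sequence[MetabolicSummary],
    metric: str = "p_max",
    n_bootstrap: int = 200,
    seed: int | None = 0,
) -> ThermalPerformance:
    """Fit the thermal performance smooth of a metric and locate T_opt.

    One point per individual (temperature, metric value); T_opt is the
    temperature maximizing the smooth within the observed range, and its SE
    comes from a seeded nonparametric bootstrap resampling individuals.
    """
    if metric not in ("p_max", "ledr"):
        raise ValueError("metric must be 'p_max' or 'ledr'")
    usable = [s for s in summaries if not s.below_lod and getattr(s, metric) is not None]
    temps = np.array([s.temperature_c for s in usable], dtype=float)
    vals = np.array([float(getattr(s, metric)) for s in usable], dtype=float)
    if metric == "ledr":
        # stored as signed dark slope (negative = consumption); the thermal
        # optimum refers to maximum O2 consumption, so fit the magnitude
        vals = -vals
    if np.unique(temps).size < 3:
        raise ValueError("need >=3 distinct temperatures")
    if temps.size < 6:
        raise ValueError("need >=6 individuals")
    if np.ptp(vals) == 0:
        raise ValueError("metric values are all equal; thermal fit is degenerate")
    tmin, tmax = float(temps.min()), float(temps.max())
    smooth = fit_penalized_spline(temps, vals)
    t_opt = _t_opt_from_smooth(smooth, tmin, tmax)
    grid = np.linspace(tmin, tmax, PREDICTION_GRID_POINTS)
    fitted = np.column_stack([grid, smooth.predict(grid)])

    rng = np.random.default_rng(seed)
    boots = []
    n = temps.size
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        bt, bv = temps[idx], vals[idx]
        if np.unique(bt).size < 3 or np.ptp(bv) == 0:
            continue
        try:
            bs = fit_penalized_spline(bt, bv)
        except (ValueError, RuntimeError):
            continue
        boots.append(_t_opt_from_smooth(bs, float(bt.min()), float(bt.max())))
    se = float(np.std(boots, ddof=1)) if len(boots) > 1 else np.nan
    return ThermalPerformance(
        metric=metric,
        t_opt_c=t_opt,
        t_opt_se_c=se,
        fitted_curve=fitted,
        n_bootstrap=len(boots),
        edf=smooth.edf,
    )
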