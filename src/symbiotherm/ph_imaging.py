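"""Ratiometric SNARF-1 intracellular pH from two-channel intensities.

SNARF-1 emission is acquired in two bands (585±15 and 640±15 nm); the
background-subtracted intensity ratio I585/I640 is a monotone function of
pH over the physiological range. A calibration curve measured on the same
microscope maps ratio to pH; cells are converted individually and each
animal is summarized by the median pH of its cells, separately for
symbiont-hosting cells (symbiocytes) and cells without symbionts.

The calibration model is a four-parameter logistic in pH (lower and upper
ratio asymptotes, midpoint pH, slope) — the standard shape for a
ratiometric dye titration. With exactly three standards a straight line is
fitted instead. Conversion inverts the fitted monotone map numerically;
ratios outside the calibrated range (beyond a 1% tolerance) are excluded
rather than extrapolated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit

logger = logging.getLogger(__name__)

__all__ = [
    "CellMeasurement",
    "CalibrationCurve",
    "PhiRecord",
    "corrected_ratio",
    "fit_calibration",
    "ratio_to_ph",
    "summarize_phi",
    "read_cells_csv",
    "read_standards_csv",
]

CELL_CLASSES = ("symbiocyte", "non_symbiocyte")
RANGE_TOLERANCE = 0.01  # fractional extension of the calibrated ratio range


@dataclass(frozen=True)
class CellMeasurement:
    """Mean ROI intensities of one cell in both channels, plus background."""

    cell_id: str
    animal_id: str
    cell_class: str
    i_585: float
    i_640: float
    bg_585: float
    bg_640: float

    def __post_init__(self) -> None:
        if self.cell_class not in CELL_CLASSES:
            raise ValueError(f"cell_class must be one of {CELL_CLASSES}")
        for v in (self.i_585, self.i_640, self.bg_585, self.bg_640):
            if v < 0:
                raise ValueError("intensities must be non-negative")

    @property
    def usable(self) -> bool:
        return self.i_585 > self.bg_585 and self.i_640 > self.bg_640


def corrected_ratio(m: CellMeasurement) -> float:
    """Background-subtracted channel ratio (585/640)."""
    denom = m.i_640 - m.bg_640
    numer = m.i_585 - m.bg_585
    if denom <= 0:
        raise ValueError(
            f"cell {m.cell_id}: 640 nm signal does not exceed background"
        )
    return numer / denom


def _sigmoid(ph, r_lo, r_hi, ph_mid, slope):
    return r_lo + (r_hi - r_lo) / (1.0 + np.exp(-(ph - ph_mid) / slope))


@dataclass(frozen=True)
class CalibrationCurve:
    """Monotone map between channel ratio and pH.

    ``model`` is "sigmoid" (4-parameter logistic in pH) or "linear";
    ``params`` holds (r_lo, r_hi, ph_mid, slope) or (intercept, slope).
    """

    model: str
    params: tuple
    ph_range: tuple[float, float]
    ratio_range: tuple[float, float]
    rmse: float
    increasing: bool

    def ratio_at(self, ph) -> np.ndarray:
        ph = np.asarray(ph, dtype=float)
        if self.model == "linear":
            a, b = self.params
            return a + b * ph
        return _sigmoid(ph, *self.params)


def fit_calibration(standards: Sequence[tuple[float, float]]) -> CalibrationCurve:
    """Least-squares calibration fit to (pH, ratio) standards.

    Requires >=3 standards spanning >=1 pH unit. Fits the 4-parameter
    logistic; exactly 3 standards fall back to a straight line. Standards
    whose overall trend is not monotone produce a fit error.
    """
    pts = sorted((float(p), float(r)) for p, r in standards)
    if len(pts) < 3:
        raise ValueError("need at least 3 calibration standards")
    ph = np.array([p for p, _ in pts])
    ratio = np.array([r for _, r in pts])
    if ph[-1] - ph[0] < 1.0:
        raise ValueError("standards must span at least 1 pH unit")
    diffs = np.diff(ratio)
    if not ((diffs > 0).all() or (diffs < 0).all()):
        # allow small noise wiggles but reject trend reversals
        rho = np.corrcoef(ph, ratio)[0, 1]
        if abs(rho) < 0.9:
            raise ValueError(
                "calibration standards are not monotone in pH "
                f"(|correlation| = {abs(rho):.2f}); check standard preparation"
            )
    increasing = ratio[-1] > ratio[0]

    if len(pts) == 3:
        b, a = np.polyfit(ph, ratio, 1)[0], np.polyfit(ph, ratio, 1)[1]
        resid = ratio - (a + b * ph)
        curve = CalibrationCurve(
            model="linear",
            params=(float(a), float(b)),
            ph_range=(float(ph[0]), float(ph[-1])),
            ratio_range=(float(ratio.min()), float(ratio.max())),
            rmse=float(np.sqrt(np.mean(resid**2))),
            increasing=increasing,
        )
        return curve

    r_lo0 = float(ratio.min())
    r_hi0 = float(ratio.max())
    if not increasing:
        r_lo0, r_hi0 = r_hi0, r_lo0
    p0 = [r_lo0, r_hi0, float(np.median(ph)), 0.5 if increasing else -0.5]
    try:
        params, _ = curve_fit(_sigmoid, ph, ratio, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise ValueError(f"sigmoid calibration fit failed: {exc}") from exc
    fitted = _sigmoid(ph, *params)
    # monotonicity of the fitted curve over the standard range
    grid = np.linspace(ph[0], ph[-1], 256)
    g = _sigmoid(grid, *params)
    dg = np.diff(g)
    if not ((dg > 0).all() or (dg < 0).all()):
        raise ValueError("fitted calibration curve is not strictly monotone")
    rmin, rmax = float(min(g[0], g[-1])), float(max(g[0], g[-1]))
    return CalibrationCurve(
        model="sigmoid",
        params=tuple(float(v) for v in params),
        ph_range=(float(ph[0]), float(ph[-1])),
        ratio_range=(rmin, rmax),
        rmse=float(np.sqrt(np.mean((ratio - fitted) ** 2))),
        increasing=bool(g[-1] > g[0]),
    )


def ratio_to_ph(curve: CalibrationCurve, ratio: float) -> float:
    """Invert the calibration map for one ratio.

    The ratio must fall within the calibrated ratio range, extended by 1%
    of its width on each side; otherwise a ValueError is raised (callers
    exclude such cells and log the reason).
    """
    rmin, rmax = curve.ratio_range
    tol = RANGE_TOLERANCE * (rmax - rmin)
    if not (rmin - tol <= ratio <= rmax + tol):
        raise ValueError(
            f"ratio {ratio:.4g} outside calibrated range "
            f"[{rmin:.4g}, {rmax:.4g}] (±1%)"
        )
    lo, hi = curve.ph_range
    if curve.model == "linear":
        a, b = curve.params
        return float((ratio - a) / b)
    target = float(np.clip(ratio, curve.ratio_at(np.array([lo, hi])).min(),
                           curve.ratio_at(np.array([lo, hi])).max()))
    f = lambda p: float(curve.ratio_at(p)) - target
    flo, fhi = f(lo), f(hi)
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    return float(brentq(f, lo, hi, xtol=1e-12))


@dataclass(frozen=True)
class PhiRecord:
    """Per-animal, per-cell-class intracellular pH summary."""

    animal_id: str
    cell_class: str
    median_ph: float
    n_cells: int


def summarize_phi(
    cells: Sequence[CellMeasurement], curve: CalibrationCurve
) -> list[PhiRecord]:
    """Median converted pH per (animal, cell class).

    Cells failing background subtraction or falling outside the calibrated
    ratio range are excluded with a logged reason; a group with zero usable
    cells is omitted (logged), never reported as NaN.
    """
    converted: dict[tuple[str, str], list[float]] = {}
    for m in cells:
        key = (m.animal_id, m.cell_class)
        try:
            r = corrected_ratio(m)
            ph = ratio_to_ph(curve, r)
        except ValueError as exc:
            logger.info("excluding cell %s: %s", m.cell_id, exc)
            continue
        converted.setdefault(key, []).append(ph)
    records = []
    for (animal, cls), phs in sorted(converted.items()):
        records.append(
            PhiRecord(
                animal_id=animal,
                cell_class=cls,
                median_ph=float(np.median(phs)),
                n_cells=len(phs),
            )
        )
    return records


def read_cells_csv(path) -> list[CellMeasurement]:
    df = pd.read_csv(path)
    required = {"cell_id", "animal_id", "cell_class", "i_585", "i_640", "bg_585", "bg_640"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cell CSV missing columns: {sorted(missing)}")
    return [
        CellMeasurement(
            cell_id=str(r.cell_id),
            animal_id=str(r.animal_id),
            cell_class=str(r.cell_class),
            i_585=float(r.i_585),
            i_640=float(r.i_640),
            bg_585=float(r.bg_585),
            bg_640=float(r.bg_640),
        )
        for r in df.itertuples(index=False)
    ]


def read_standards_csv(path) -> list[tuple[float, float]]:
    df = pd.read_csv(path)
    if not {"ph", "ratio"} <= set(df.columns):
        raise ValueError("standards CSV needs columns: ph, ratio")
    return list(zip(df["ph"].astype(float), df["ratio"].astype(float)))
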