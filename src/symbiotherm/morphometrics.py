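"""Phenotype scoring: pigmentation color score, oral-disk size, symbiont density.

These are plain measurement transforms on instrument/ImageJ export tables;
all image work (ROI drawing, intensity extraction) happens upstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ColorMeasurement",
    "SizeMeasurement",
    "SymbiontDensity",
    "color_score",
    "oral_disk_cm",
    "density_normalize",
    "join_phenotypes",
]


@dataclass(frozen=True)
class ColorMeasurement:
    """Red-channel ROI intensity with an in-image red standard.

    The red standard normalizes exposure so scores compare across images;
    paler (bleached) animals reflect more red and score lower.
    """

    animal_id: str
    date: str
    roi_red_intensity: float
    standard_red_intensity: float

    def __post_init__(self) -> None:
        for v in (self.roi_red_intensity, self.standard_red_intensity):
            if not (0 <= v <= 255):
                raise ValueError("intensities must lie in [0, 255]")
        if self.standard_red_intensity <= 0:
            raise ValueError("standard intensity must be positive")


@dataclass(frozen=True)
class SizeMeasurement:
    animal_id: str
    date: str
    disk_px: float
    ruler_px_per_cm: float

    def __post_init__(self) -> None:
        if self.disk_px <= 0 or self.ruler_px_per_cm <= 0:
            raise ValueError("pixel lengths must be positive")


@dataclass(frozen=True)
class SymbiontDensity:
    animal_id: str
    cells_per_animal: float
    protein_ug: float
    cells_per_ug_protein: float


def color_score(m: ColorMeasurement) -> float:
    """Percent pigmentation score: 100 − 100·(ROI red / standard red).

    Darker, more pigmented animals score higher. An ROI brighter than the
    standard yields a negative score, which is allowed but worth a QC look.
    """
    return 100.0 - 100.0 * (m.roi_red_intensity / m.standard_red_intensity)


def oral_disk_cm(m: SizeMeasurement) -> float:
    """Oral-disk width in cm via the in-image 1 cm ruler."""
    return m.disk_px / m.ruler_px_per_cm


def density_normalize(animal_id: str, cells_per_animal: float, protein_ug: float) -> SymbiontDensity:
    """Populate per-animal and per-µg-protein symbiont densities consistently."""
    if protein_ug <= 0:
        raise ValueError("protein mass must be positive")
    if cells_per_animal < 0:
        raise ValueError("cell count cannot be negative")
    return SymbiontDensity(
        animal_id=animal_id,
        cells_per_animal=float(cells_per_animal),
        protein_ug=float(protein_ug),
        cells_per_ug_protein=float(cells_per_animal) / float(protein_ug),
    )


def join_phenotypes(
    color: pd.DataFrame | None = None,
    size: pd.DataFrame | None = None,
    counts: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Tidy per-animal phenotype table joining color, size, and density.

    Inputs are raw export tables; scores and normalizations are computed
    here. Triplicate cell counts, when present as ``count_rep1..3``,
    are averaged before normalization.
    """
    pieces = []
    if color is not None:
        c = color.copy()
        c["color_score_pct"] = 100.0 - 100.0 * (
            c["roi_red_intensity"] / c["standard_red_intensity"]
        )
        pieces.append(c[["animal_id", "color_score_pct"]])
    if size is not None:
        s = size.copy()
        s["oral_disk_cm"] = s["disk_px"] / s["ruler_px_per_cm"]
        pieces.append(s[["animal_id", "oral_disk_cm"]])
    if counts is not None:
        k = counts.copy()
        reps = [c for c in k.columns if c.startswith("count_rep")]
        if reps:
            k["cells_per_animal"] = k[reps].mean(axis=1)
        k["cells_per_ug_protein"] = k["cells_per_animal"] / k["protein_ug"]
        pieces.append(k[["animal_id", "cells_per_animal", "protein_ug", "cells_per_ug_protein"]])
    if not pieces:
        raise ValueError("no phenotype tables provided")
    out = pieces[0]
    for p in pieces[1:]:
        out = out.merge(p, on="animal_id", how="outer")
    return out.sort_values("animal_id").reset_index(drop=True)
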