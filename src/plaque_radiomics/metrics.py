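"""Conventional ("traditional") plaque measurements.

These are the quantities a neuroradiologist reads off a vessel-wall MRI
cross-section: plaque burden, luminal areas, WASID-style degree of stenosis,
intraplaque haemorrhage (IPH) by the 150%-of-muscle signal rule, and the
gadolinium enhancement ratio normalised by grey-matter signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "ConventionalMetrics",
    "plaque_burden",
    "enhancement_ratio",
    "detect_iph",
    "minimal_luminal_area",
    "stenosis_degree",
    "measure_study",
]

_EIGHT_CONN = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class ConventionalMetrics:
    """Per-patient conventional plaque metrics.

    Areas in mm^2; burden/stenosis/enhancement in percent.
    """

    stenosis_percent: float
    plaque_area: float
    plaque_burden: float
    lumen_area: float
    mla: float
    iph_present: bool
    enhancement_ratio: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.plaque_burden <= 100.0):
            raise ValueError("plaque burden outside [0, 100]")
        if self.mla < 0:
            raise ValueError("MLA must be non-negative")
        if self.stenosis_percent > 100.0:
            raise ValueError("stenosis cannot exceed 100%")


def plaque_burden(lumen_area: float, outer_area: float) -> float:
    """Plaque burden (%) = (1 - lumen area / outer wall area) x 100."""
    if outer_area <= 0:
        raise ValueError("outer wall area must be positive")
    if lumen_area < 0 or lumen_area > outer_area:
        raise ValueError("lumen area must lie in [0, outer area]")
    return (1.0 - lumen_area / outer_area) * 100.0


def enhancement_ratio(
    plaque_pre: float, gm_pre: float, plaque_post: float, gm_post: float
) -> float:
    """Contrast enhancement (%) of the plaque normalised by grey matter.

    ((plaque_post / gm_post) / (plaque_pre / gm_pre) - 1) x 100, with all
    four values ROI mean signal intensities.
    """
    for v in (plaque_pre, gm_pre, plaque_post, gm_post):
        if v <= 0:
            raise ValueError("signal intensities must be positive")
    return ((plaque_post / gm_post) / (plaque_pre / gm_pre) - 1.0) * 100.0


def detect_iph(
    t1_image: np.ndarray,
    plaque_mask: np.ndarray,
    muscle_mean: float,
    min_component_px: int = 3,
    threshold_factor: float = 1.5,
) -> bool:
    """Intraplaque haemorrhage: a hyperintense focus on pre-contrast T1.

    True iff the plaque contains an 8-connected component of at least
    ``min_component_px`` pixels whose intensities all exceed
    ``threshold_factor`` x the reference-muscle mean (default the >150% rule).
    """
    plaque_mask = np.asarray(plaque_mask, dtype=bool)
    if not plaque_mask.any():
        raise ValueError("plaque mask is empty")
    if muscle_mean <= 0:
        raise ValueError("muscle reference mean must be positive")
    hyper = plaque_mask & (np.asarray(t1_image, dtype=float) > threshold_factor * muscle_mean)
    if not hyper.any():
        return False
    comp, n_comp = ndimage.label(hyper, structure=_EIGHT_CONN)
    sizes = np.bincount(comp.ravel())[1:]
    return bool(n_comp > 0 and sizes.max() >= min_component_px)


def minimal_luminal_area(lumen_areas: Sequence[float]) -> float:
    """Minimal luminal area (mm^2) across the segmented slices."""
    areas = np.asarray(list(lumen_areas), dtype=float)
    if areas.size == 0:
        raise ValueError("no lumen areas supplied")
    if (areas < 0).any():
        raise ValueError("lumen areas must be non-negative")
    return float(areas.min())


def stenosis_degree(lumen_area_at_mla: float, reference_lumen_area: float) -> float:
    """Diameter-based (WASID-style) stenosis: (1 - d_sten/d_ref) x 100.

    Diameters are circle-equivalent, d = 2 sqrt(area / pi), so the value
    reduces to (1 - sqrt(area_sten / area_ref)) x 100.
    """
    if reference_lumen_area <= 0:
        raise ValueError("reference lumen area must be positive")
    if lumen_area_at_mla < 0:
        raise ValueError("stenotic lumen area must be non-negative")
    return (1.0 - np.sqrt(lumen_area_at_mla / reference_lumen_area)) * 100.0


def mask_area(mask: np.ndarray, pixel_spacing: float) -> float:
    """Area (mm^2) as pixel count x pixel area; matches raster segmentation."""
    return float(np.count_nonzero(mask)) * pixel_spacing**2


def measure_study(study, min_component_px: int = 3) -> ConventionalMetrics:
    """All conventional metrics for one plaque study (single analysed slice)."""
    s = study.pixel_spacing
    lumen = mask_area(study.masks["lumen"], s)
    outer = mask_area(study.masks["outer_wall"], s)
    plaque = mask_area(study.masks["plaque_roi"], s)

    t1 = study.images["T1"]
    ce = study.images["CE_T1"]
    pm = study.masks["plaque_roi"]
    gm = study.masks["grey_matter_ref"]
    muscle_mean = float(t1[study.masks["muscle_ref"]].mean())

    er = enhancement_ratio(
        float(t1[pm].mean()), float(t1[gm].mean()), float(ce[pm].mean()), float(ce[gm].mean())
    )
    mla = minimal_luminal_area([lumen])
    return ConventionalMetrics(
        stenosis_percent=stenosis_degree(mla, study.reference_lumen_area),
        plaque_area=plaque,
        plaque_burden=plaque_burden(lumen, outer),
        lumen_area=lumen,
        mla=mla,
        iph_present=detect_iph(t1, pm, muscle_mean, min_component_px),
        enhancement_ratio=er,
    )
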