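"""From-scratch 2D radiomic feature engine.

Computes the full named-feature catalogue (first-order intensity statistics,
histogram auxiliaries, shape descriptors of a one-voxel-thick slice, and
grey-level co-occurrence / run-length / size-zone texture matrices) from a
2D region of interest.

Conventions used throughout:

* grey-level indices ``i, j`` in texture formulas are 1-based bin labels of
  the discretised ROI;
* logarithms are base 2 and ``0 * log 0 == 0``;
* GLCM and GLRLM use distance 1 and the four 2D directions
  0deg, 45deg, 90deg, 135deg, with features averaged over directions;
* pixel pairs/runs crossing the mask boundary are discarded;
* GLSZM zones are 8-connected components of equal grey level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import pdist
from scipy.stats import kurtosis as _kurtosis
from scipy.stats import skew as _skew

__all__ = [
    "DiscretisedRoi",
    "FeatureExtractionError",
    "RadiomicsParams",
    "FEATURE_CATALOGUE",
    "discretise",
    "first_order_features",
    "shape_features",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "extract_all",
]

# Offsets (drow, dcol) for 0deg, 45deg, 90deg, 135deg in image coordinates.
DIRECTIONS_2D: Tuple[Tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

DEFAULT_N_BINS = 32


class FeatureExtractionError(ValueError):
    """Raised when a texture family is undefined for the given ROI."""


@dataclass(frozen=True)
class RadiomicsParams:
    """Tunable extraction settings.

    n_bins
        Number of equal-width grey-level bins used for discretisation.
    distance
        GLCM/GLRLM pixel offset distance (pixels).
    pixel_spacing
        In-plane pixel size in mm.
    slice_thickness
        Through-plane voxel size in mm.
    """

    n_bins: int = DEFAULT_N_BINS
    distance: int = 1
    pixel_spacing: float = 0.3
    slice_thickness: float = 2.0


@dataclass(frozen=True)
class DiscretisedRoi:
    """Integer grey-level labels 1..n_bins on the in-mask pixels."""

    grid: np.ndarray  # int array, 0 outside the mask
    mask: np.ndarray  # bool array
    n_bins: int
    bin_edges: np.ndarray

    @property
    def labels(self) -> np.ndarray:
        return self.grid[self.mask]


# ---------------------------------------------------------------------------
# Discretisation
# ---------------------------------------------------------------------------

def discretise(image: np.ndarray, mask: np.ndarray, n_bins: int = DEFAULT_N_BINS) -> DiscretisedRoi:
    """Equal-width discretisation of the in-mask intensities into 1..n_bins.

    Bins span the in-mask min..max; the maximum intensity is assigned to bin
    ``n_bins``.  A constant image maps every pixel to bin 1.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if not mask.any():
        raise ValueError("mask is empty")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")

    vals = image[mask]
    lo, hi = float(vals.min()), float(vals.max())
    grid = np.zeros(image.shape, dtype=np.int32)
    if hi == lo:
        grid[mask] = 1
        edges = np.array([lo, lo])
    else:
        width = (hi - lo) / n_bins
        lab = np.floor((vals - lo) / width).astype(np.int32)
        np.clip(lab, 0, n_bins - 1, out=lab)
        grid[mask] = lab + 1
        edges = lo + width * np.arange(n_bins + 1)
    return DiscretisedRoi(grid=grid, mask=mask, n_bins=int(n_bins), bin_edges=edges)


# ---------------------------------------------------------------------------
# First-order statistics
# ---------------------------------------------------------------------------

FIRSTORDER_NAMES = [
    "firstorder_Maximum",
    "firstorder_Minimum",
    "firstorder_Mean",
    "firstorder_Median",
    "firstorder_Range",
    "firstorder_StandardDeviation",
    "firstorder_Variance",
    "firstorder_MeanAbsoluteDeviation",
    "firstorder_RootMeanSquared",
    "firstorder_Energy",
    "firstorder_Skewness",
    "firstorder_Kurtosis",
    "firstorder_Uniformity",
    "firstorder_Entropy",
]

HISTOGRAM_NAMES = [
    "firstorder_Percentile10",
    "firstorder_Percentile25",
    "firstorder_Percentile75",
    "firstorder_Percentile90",
    "firstorder_InterquartileRange",
    "firstorder_RobustMeanAbsoluteDeviation",
    "firstorder_MedianAbsoluteDeviation",
    "firstorder_CoefficientOfVariation",
    "firstorder_QuartileCoefficientOfDispersion",
    "firstorder_TotalEnergy",
    "firstorder_HistogramMode",
    "firstorder_HistogramModeProbability",
    "firstorder_HistogramEntropyNormalised",
    "firstorder_HistogramMean",
    "firstorder_HistogramVariance",
    "firstorder_HistogramMedian",
    "firstorder_HistogramSkewness",
    "firstorder_HistogramKurtosis",
]


def _xlog2x(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p, dtype=float)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def _safe_skew(x: np.ndarray) -> float:
    if np.ptp(x) == 0:
        return 0.0
    return float(_skew(x))


def _safe_kurtosis(x: np.ndarray) -> float:
    # Pearson (non-excess) kurtosis; defined as 0 for a constant sample.
    if np.ptp(x) == 0:
        return 0.0
    return float(_kurtosis(x, fisher=False))


def first_order_features(
    disc: DiscretisedRoi,
    raw: np.ndarray,
    voxel_volume: float = 1.0,
) -> Dict[str, float]:
    """Intensity statistics on the raw in-mask values plus histogram features
    (uniformity, entropy and auxiliaries) on the discretised labels."""
    x = np.asarray(raw, dtype=float)[disc.mask]
    labels = disc.labels
    n = x.size

    counts = np.bincount(labels, minlength=disc.n_bins + 1)[1:].astype(float)
    p = counts / n

    mean = float(x.mean())
    sd = float(x.std())
    out: Dict[str, float] = {
        "firstorder_Maximum": float(x.max()),
        "firstorder_Minimum": float(x.min()),
        "firstorder_Mean": mean,
        "firstorder_Median": float(np.median(x)),
        "firstorder_Range": float(np.ptp(x)),
        "firstorder_StandardDeviation": sd,
        "firstorder_Variance": float(x.var()),
        "firstorder_MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "firstorder_RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "firstorder_Energy": float(np.sum(x**2)),
        "firstorder_Skewness": _safe_skew(x),
        "firstorder_Kurtosis": _safe_kurtosis(x),
        "firstorder_Uniformity": float(np.sum(p**2)),
        "firstorder_Entropy": float(-np.sum(_xlog2x(p))),
    }

    p10, p25, p75, p90 = (float(np.percentile(x, q)) for q in (10, 25, 75, 90))
    robust = x[(x >= p10) & (x <= p90)]
    med = out["firstorder_Median"]
    qsum = p75 + p25
    lab = labels.astype(float)
    mode_bin = int(np.argmax(counts)) + 1  # lowest label on ties
    out.update(
        {
            "firstorder_Percentile10": p10,
            "firstorder_Percentile25": p25,
            "firstorder_Percentile75": p75,
            "firstorder_Percentile90": p90,
            "firstorder_InterquartileRange": p75 - p25,
            "firstorder_RobustMeanAbsoluteDeviation": float(
                np.abs(robust - robust.mean()).mean()
            )
            if robust.size
            else 0.0,
            "firstorder_MedianAbsoluteDeviation": float(np.median(np.abs(x - med))),
            "firstorder_CoefficientOfVariation": sd / mean if mean != 0 else 0.0,
            "firstorder_QuartileCoefficientOfDispersion": (p75 - p25) / qsum
            if qsum != 0
            else 0.0,
            "firstorder_TotalEnergy": out["firstorder_Energy"] * voxel_volume,
            "firstorder_HistogramMode": float(mode_bin),
            "firstorder_HistogramModeProbability": float(p[mode_bin - 1]),
            "firstorder_HistogramEntropyNormalised": out["firstorder_Entropy"]
            / np.log2(disc.n_bins),
            "firstorder_HistogramMean": float(lab.mean()),
            "firstorder_HistogramVariance": float(lab.var()),
            "firstorder_HistogramMedian": float(np.median(lab)),
            "firstorder_HistogramSkewness": _safe_skew(lab),
            "firstorder_HistogramKurtosis": _safe_kurtosis(lab),
        }
    )
    return out


# ---------------------------------------------------------------------------
# Shape
# ---------------------------------------------------------------------------

SHAPE_NAMES = [
    "shape_Area",
    "shape_Perimeter",
    "shape_Volume",
    "shape_SurfaceArea",
    "shape_Maximum2DDiameterSlice",
    "shape_Maximum3DDiameter",
    "shape_Maximum2DDiameterColumn",
    "shape_Maximum2DDiameterRow",
    "shape_Sphericity",
    "shape_Elongation",
]


def shape_features(
    mask: np.ndarray,
    pixel_spacing: float = 0.3,
    slice_thickness: float = 2.0,
) -> Dict[str, float]:
    """Shape descriptors of the mask treated as a one-voxel-thick volume.

    * ``shape_Volume`` = in-plane area x slice thickness (mm^3)
    * ``shape_SurfaceArea`` = two slice faces + perimeter band (mm^2)
    * ``shape_Maximum2DDiameterSlice`` = largest in-plane pixel-centre
      distance (mm); ``shape_Maximum3DDiameter`` additionally includes the
      through-plane thickness offset
    * ``shape_Maximum2DDiameterColumn`` / ``Row`` = largest extent along the
      row / column axis respectively (mm)
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    s = float(pixel_spacing)
    t = float(slice_thickness)

    n_px = int(mask.sum())
    area = n_px * s * s

    # Exposed 4-neighbour faces -> perimeter.
    padded = np.pad(mask, 1)
    faces = 0
    for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
        faces += int(np.sum(padded & ~np.roll(np.roll(padded, dr, 0), dc, 1)))
    perimeter = faces * s

    rows, cols = np.nonzero(mask)
    coords = np.column_stack([rows, cols]).astype(float) * s
    if len(coords) > 1:
        # Pairwise distances over boundary pixels only (same maximum, cheaper).
        eroded = ndimage.binary_erosion(mask)
        brows, bcols = np.nonzero(mask & ~eroded)
        bcoords = np.column_stack([brows, bcols]).astype(float) * s
        max2d = float(pdist(bcoords).max()) if len(bcoords) > 1 else 0.0
    else:
        max2d = 0.0
    max_row_extent = float(np.ptp(rows)) * s
    max_col_extent = float(np.ptp(cols)) * s

    volume = area * t
    surface = 2.0 * area + perimeter * t
    sphericity = 2.0 * np.sqrt(np.pi * area) / perimeter if perimeter > 0 else 0.0

    centred = coords - coords.mean(axis=0)
    cov = centred.T @ centred / len(coords)
    eig = np.sort(np.linalg.eigvalsh(cov))
    elongation = float(np.sqrt(eig[0] / eig[1])) if eig[1] > 0 else 1.0

    return {
        "shape_Area": area,
        "shape_Perimeter": perimeter,
        "shape_Volume": volume,
        "shape_SurfaceArea": surface,
        "shape_Maximum2DDiameterSlice": max2d,
        "shape_Maximum3DDiameter": float(np.hypot(max2d, t)),
        "shape_Maximum2DDiameterColumn": max_row_extent,
        "shape_Maximum2DDiameterRow": max_col_extent,
        "shape_Sphericity": sphericity,
        "shape_Elongation": elongation,
    }


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

GLCM_NAMES = [
    "glcm_Autocorrelation",
    "glcm_ClusterProminence",
    "glcm_ClusterShade",
    "glcm_ClusterTendency",
    "glcm_Contrast",
    "glcm_Correlation",
    "glcm_DifferenceAverage",
    "glcm_DifferenceEntropy",
    "glcm_DifferenceVariance",
    "glcm_Dissimilarity",
    "glcm_Energy",
    "glcm_Entropy",
    "glcm_Homogeneity",
    "glcm_Imc1",
    "glcm_Imc2",
    "glcm_InverseDifferenceMoment",
    "glcm_InverseDifferenceMomentNormalised",
    "glcm_InverseDifferenceNormalised",
    "glcm_InverseVariance",
    "glcm_JointAverage",
    "glcm_MaximumProbability",
    "glcm_SumAverage",
    "glcm_SumEntropy",
    "glcm_SumOfSquares",
]


def glcm_matrix(
    disc: DiscretisedRoi, offset: Tuple[int, int], distance: int = 1
) -> np.ndarray:
    """Symmetric co-occurrence count matrix for one direction.

    Entry (i-1, j-1) counts ordered in-mask pixel pairs at the given offset
    with levels (i, j); the matrix includes both pair orientations.
    """
    dr, dc = offset[0] * distance, offset[1] * distance
    grid, mask = disc.grid, disc.mask
    nrow, ncol = grid.shape

    r0s, r0e = max(0, -dr), min(nrow, nrow - dr)
    c0s, c0e = max(0, -dc), min(ncol, ncol - dc)
    if r0s >= r0e or c0s >= c0e:
        return np.zeros((disc.n_bins, disc.n_bins), dtype=float)
    a = grid[r0s:r0e, c0s:c0e]
    b = grid[r0s + dr : r0e + dr, c0s + dc : c0e + dc]
    va = mask[r0s:r0e, c0s:c0e]
    vb = mask[r0s + dr : r0e + dr, c0s + dc : c0e + dc]
    ok = va & vb
    i = a[ok] - 1
    j = b[ok] - 1
    m = np.zeros((disc.n_bins, disc.n_bins), dtype=float)
    np.add.at(m, (i, j), 1.0)
    np.add.at(m, (j, i), 1.0)
    return m


def _glcm_features_single(p: np.ndarray, n_bins: int) -> Dict[str, float]:
    ng = n_bins
    idx = np.arange(1, ng + 1, dtype=float)
    ii = idx[:, None]
    jj = idx[None, :]

    px = p.sum(axis=1)
    mu = float(np.sum(idx * px))
    sigma2 = float(np.sum((idx - mu) ** 2 * px))
    sigma = np.sqrt(sigma2)

    diff = np.abs(ii - jj)
    # p_{|i-j|}(k), k = 0..ng-1
    pd = np.zeros(ng)
    ksum = np.zeros(2 * ng - 1)  # p_{i+j}(k), k = 2..2ng
    for k in range(ng):
        pd[k] = float(np.sum(p[diff == k]))
    srange = ii + jj
    for k in range(2, 2 * ng + 1):
        ksum[k - 2] = float(np.sum(p[srange == k]))

    kd = np.arange(ng, dtype=float)
    ks = np.arange(2, 2 * ng + 1, dtype=float)
    da = float(np.sum(kd * pd))

    entropy = float(-np.sum(_xlog2x(p)))
    hx = float(-np.sum(_xlog2x(px)))
    pxy = px[:, None] * px[None, :]
    hxy1 = float(-np.sum(p * np.where(pxy > 0, np.log2(np.maximum(pxy, 1e-300)), 0.0)))
    hxy2 = float(-np.sum(_xlog2x(pxy)))

    imc1 = (entropy - hxy1) / hx if hx > 0 else 0.0
    arg = 1.0 - np.exp(-2.0 * (hxy2 - entropy))
    imc2 = float(np.sqrt(arg)) if arg > 0 else 0.0

    corr_num = float(np.sum(ii * jj * p)) - mu * mu
    correlation = corr_num / sigma2 if sigma2 > 0 else 1.0

    off = ii + jj - 2.0 * mu
    inv_var_mask = diff > 0

    return {
        "glcm_Autocorrelation": float(np.sum(ii * jj * p)),
        "glcm_ClusterProminence": float(np.sum(off**4 * p)),
        "glcm_ClusterShade": float(np.sum(off**3 * p)),
        "glcm_ClusterTendency": float(np.sum(off**2 * p)),
        "glcm_Contrast": float(np.sum((ii - jj) ** 2 * p)),
        "glcm_Correlation": correlation,
        "glcm_DifferenceAverage": da,
        "glcm_DifferenceEntropy": float(-np.sum(_xlog2x(pd))),
        "glcm_DifferenceVariance": float(np.sum((kd - da) ** 2 * pd)),
        "glcm_Dissimilarity": float(np.sum(diff * p)),
        "glcm_Energy": float(np.sum(p**2)),
        "glcm_Entropy": entropy,
        "glcm_Homogeneity": float(np.sum(p / (1.0 + diff))),
        "glcm_Imc1": imc1,
        "glcm_Imc2": imc2,
        "glcm_InverseDifferenceMoment": float(np.sum(p / (1.0 + diff**2))),
        "glcm_InverseDifferenceMomentNormalised": float(
            np.sum(p / (1.0 + (diff / ng) ** 2))
        ),
        "glcm_InverseDifferenceNormalised": float(np.sum(p / (1.0 + diff / ng))),
        "glcm_InverseVariance": float(np.sum(p[inv_var_mask] / diff[inv_var_mask] ** 2)),
        "glcm_JointAverage": mu,
        "glcm_SumAverage": float(np.sum(ks * ksum)),
        "glcm_SumEntropy": float(-np.sum(_xlog2x(ksum))),
        "glcm_SumOfSquares": sigma2,
        "glcm_MaximumProbability": float(p.max()),
    }


def glcm_features(
    disc: DiscretisedRoi,
    distance: int = 1,
    directions: Sequence[Tuple[int, int]] = DIRECTIONS_2D,
) -> Dict[str, float]:
    """Direction-averaged GLCM features (symmetric, per-direction normalised)."""
    per_dir: List[Dict[str, float]] = []
    for off in directions:
        m = glcm_matrix(disc, off, distance)
        total = m.sum()
        if total == 0:
            continue
        per_dir.append(_glcm_features_single(m / total, disc.n_bins))
    if not per_dir:
        raise FeatureExtractionError("no valid pixel pair in any GLCM direction")
    return {k: float(np.mean([d[k] for d in per_dir])) for k in GLCM_NAMES}


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

GLRLM_NAMES = [
    "glrlm_ShortRunEmphasis",
    "glrlm_LongRunEmphasis",
    "glrlm_GreyLevelNonUniformity",
    "glrlm_GreyLevelNonUniformityNormalised",
    "glrlm_RunLengthNonUniformity",
    "glrlm_RunLengthNonUniformityNormalised",
    "glrlm_RunPercentage",
    "glrlm_GreyLevelVariance",
    "glrlm_RunVariance",
    "glrlm_RunEntropy",
    "glrlm_LowGreyLevelRunEmphasis",
    "glrlm_HighGreyLevelRunEmphasis",
    "glrlm_ShortRunLowGreyLevelEmphasis",
    "glrlm_ShortRunHighGreyLevelEmphasis",
    "glrlm_LongRunLowGreyLevelEmphasis",
    "glrlm_LongRunHighGreyLevelEmphasis",
]


def _lines_for_direction(
    grid: np.ndarray, mask: np.ndarray, offset: Tuple[int, int]
):
    """Yield (labels, validity) 1D lines traversed along the given offset."""
    dr, dc = offset
    if (dr, dc) in ((0, 1), (0, -1)):
        for r in range(grid.shape[0]):
            yield grid[r, :], mask[r, :]
    elif (dr, dc) in ((1, 0), (-1, 0)):
        for c in range(grid.shape[1]):
            yield grid[:, c], mask[:, c]
    else:
        nrow, ncol = grid.shape
        # Diagonals: main (dr*dc == 1 direction family) vs anti-diagonals.
        g = grid if dr * dc > 0 else grid[:, ::-1]
        m = mask if dr * dc > 0 else mask[:, ::-1]
        for k in range(-nrow + 1, ncol):
            yield np.diagonal(g, k), np.diagonal(m, k)


def glrlm_matrix(disc: DiscretisedRoi, offset: Tuple[int, int]) -> np.ndarray:
    """Run-length count matrix R(i, j): level i, run length j (1-based)."""
    grid, mask = disc.grid, disc.mask
    max_len = max(grid.shape)
    R = np.zeros((disc.n_bins, max_len), dtype=float)
    for labels, valid in _lines_for_direction(grid, mask, offset):
        # Sentinel-separated run-length encoding of the in-mask stretches.
        lab = np.where(valid, labels, 0)
        if not lab.any():
            continue
        boundaries = np.nonzero(np.diff(lab) != 0)[0]
        starts = np.concatenate([[0], boundaries + 1])
        ends = np.concatenate([boundaries + 1, [lab.size]])
        for s0, e0 in zip(starts, ends):
            lv = lab[s0]
            if lv > 0:
                R[lv - 1, e0 - s0 - 1] += 1.0
    return R


def _rlm_szm_features(R: np.ndarray, n_pixels: int, prefix: str, names: List[str]) -> Dict[str, float]:
    """Shared weighted-emphasis feature set for run-length and size-zone matrices."""
    nr = R.sum()
    if nr == 0:
        raise FeatureExtractionError(f"empty {prefix} matrix")
    i = np.arange(1, R.shape[0] + 1, dtype=float)[:, None]
    j = np.arange(1, R.shape[1] + 1, dtype=float)[None, :]
    p = R / nr
    gl_marginal = R.sum(axis=1)
    len_marginal = R.sum(axis=0)
    mu_i = float(np.sum(i * p))
    mu_j = float(np.sum(j * p))
    vals = {
        "ShortRunEmphasis": float(np.sum(R / j**2) / nr),
        "LongRunEmphasis": float(np.sum(R * j**2) / nr),
        "GreyLevelNonUniformity": float(np.sum(gl_marginal**2) / nr),
        "GreyLevelNonUniformityNormalised": float(np.sum(gl_marginal**2) / nr**2),
        "RunLengthNonUniformity": float(np.sum(len_marginal**2) / nr),
        "RunLengthNonUniformityNormalised": float(np.sum(len_marginal**2) / nr**2),
        "RunPercentage": float(nr / n_pixels),
        "GreyLevelVariance": float(np.sum((i - mu_i) ** 2 * p)),
        "RunVariance": float(np.sum((j - mu_j) ** 2 * p)),
        "RunEntropy": float(-np.sum(_xlog2x(p))),
        "LowGreyLevelRunEmphasis": float(np.sum(R / i**2) / nr),
        "HighGreyLevelRunEmphasis": float(np.sum(R * i**2) / nr),
        "ShortRunLowGreyLevelEmphasis": float(np.sum(R / (i**2 * j**2)) / nr),
        "ShortRunHighGreyLevelEmphasis": float(np.sum(R * i**2 / j**2) / nr),
        "LongRunLowGreyLevelEmphasis": float(np.sum(R * j**2 / i**2) / nr),
        "LongRunHighGreyLevelEmphasis": float(np.sum(R * i**2 * j**2) / nr),
    }
    # Map the generic feature order onto the family's catalogue names.
    return dict(zip(names, vals.values()))


def glrlm_features(
    disc: DiscretisedRoi, directions: Sequence[Tuple[int, int]] = DIRECTIONS_2D
) -> Dict[str, float]:
    """Direction-averaged run-length features over in-mask runs."""
    n_pixels = int(disc.mask.sum())
    per_dir = []
    for off in directions:
        R = glrlm_matrix(disc, off)
        if R.sum() == 0:
            continue
        per_dir.append(_rlm_szm_features(R, n_pixels, "glrlm", GLRLM_NAMES))
    if not per_dir:
        raise FeatureExtractionError("no valid run in any GLRLM direction")
    return {k: float(np.mean([d[k] for d in per_dir])) for k in GLRLM_NAMES}


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

GLSZM_NAMES = [
    "glszm_SmallAreaEmphasis",
    "glszm_LargeAreaEmphasis",
    "glszm_GreyLevelNonUniformity",
    "glszm_GreyLevelNonUniformityNormalised",
    "glszm_SizeZoneNonUniformity",
    "glszm_SizeZoneNonUniformityNormalised",
    "glszm_ZonePercentage",
    "glszm_GreyLevelVariance",
    "glszm_ZoneVariance",
    "glszm_ZoneEntropy",
    "glszm_LowGreyLevelZoneEmphasis",
    "glszm_HighGreyLevelZoneEmphasis",
    "glszm_SmallAreaLowGreyLevelEmphasis",
    "glszm_SmallAreaHighGreyLevelEmphasis",
    "glszm_LargeAreaLowGreyLevelEmphasis",
    "glszm_LargeAreaHighGreyLevelEmphasis",
]

_EIGHT_CONN = np.ones((3, 3), dtype=int)


def glszm_matrix(disc: DiscretisedRoi) -> np.ndarray:
    """Size-zone count matrix Z(i, s): 8-connected zones of level i, size s."""
    n_pixels = int(disc.mask.sum())
    Z = np.zeros((disc.n_bins, n_pixels), dtype=float)
    present = np.unique(disc.labels)
    for lv in present:
        comp, n_comp = ndimage.label(disc.grid == lv, structure=_EIGHT_CONN)
        if n_comp == 0:
            continue
        sizes = np.bincount(comp.ravel())[1:]
        for s in sizes:
            Z[lv - 1, s - 1] += 1.0
    return Z


def glszm_features(disc: DiscretisedRoi) -> Dict[str, float]:
    """Size-zone features; a single matrix (no direction averaging)."""
    Z = glszm_matrix(disc)
    return _rlm_szm_features(Z, int(disc.mask.sum()), "glszm", GLSZM_NAMES)


# ---------------------------------------------------------------------------
# Full catalogue
# ---------------------------------------------------------------------------

FEATURE_CATALOGUE: List[str] = (
    FIRSTORDER_NAMES + HISTOGRAM_NAMES + SHAPE_NAMES + GLCM_NAMES + GLRLM_NAMES + GLSZM_NAMES
)


def extract_features(
    image: np.ndarray,
    mask: np.ndarray,
    params: RadiomicsParams = RadiomicsParams(),
) -> Dict[str, float]:
    """All catalogue features for a single image/mask pair, in fixed order."""
    mask = np.asarray(mask, dtype=bool)
    # Crop to the mask bounding box (texture matrices are translation invariant).
    rows, cols = np.nonzero(mask)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    sub_img = np.asarray(image, dtype=float)[r0:r1, c0:c1]
    sub_mask = mask[r0:r1, c0:c1]

    disc = discretise(sub_img, sub_mask, params.n_bins)
    voxel_volume = params.pixel_spacing**2 * params.slice_thickness
    out: Dict[str, float] = {}
    out.update(first_order_features(disc, sub_img, voxel_volume))
    out.update(shape_features(sub_mask, params.pixel_spacing, params.slice_thickness))
    out.update(glcm_features(disc, params.distance))
    out.update(glrlm_features(disc))
    out.update(glszm_features(disc))
    return {name: out[name] for name in FEATURE_CATALOGUE}


def extract_all(study, params: RadiomicsParams | None = None) -> Dict[str, Dict[str, float]]:
    """Full catalogue per sequence {T1, T2, CE_T1} of a plaque study.

    Shape features depend only on the (shared) plaque mask and are computed
    once, then replicated into each sequence's vector.
    """
    if params is None:
        params = RadiomicsParams(
            pixel_spacing=study.pixel_spacing, slice_thickness=study.slice_thickness
        )
    mask = study.masks["plaque_roi"]
    result: Dict[str, Dict[str, float]] = {}
    shape_cache: Dict[str, float] | None = None
    for seq, img in study.images.items():
        try:
            feats = extract_features(img, mask, params)
        except FeatureExtractionError as exc:
            raise FeatureExtractionError(f"sequence {seq}: {exc}") from exc
        if shape_cache is None:
            shape_cache = {k: feats[k] for k in SHAPE_NAMES}
        else:
            feats.update(shape_cache)
        result[seq] = feats
    return result
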