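"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — explicit Python loops over pixel
pairs, runs, zones and rating tables — so that it shares no code path with
the vectorised implementations it checks.
"""

from __future__ import annotations

from collections import defaultdict
from math import log2, sqrt

import numpy as np

# ---------------------------------------------------------------------------
# Texture-matrix enumerators
# ---------------------------------------------------------------------------


def brute_glcm(grid, mask, offset, n_bins, distance=1):
    """Symmetric co-occurrence counts by looping over every pixel pair."""
    dr, dc = offset[0] * distance, offset[1] * distance
    nrow, ncol = grid.shape
    m = np.zeros((n_bins, n_bins))
    for r in range(nrow):
        for c in range(ncol):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < nrow and 0 <= c2 < ncol and mask[r, c] and mask[r2, c2]:
                i, j = grid[r, c] - 1, grid[r2, c2] - 1
                m[i, j] += 1
                m[j, i] += 1
    return m


def brute_glcm_features(p):
    """Hand-rolled GLCM features from a normalised matrix (base-2 logs)."""
    ng = p.shape[0]
    feats = defaultdict(float)
    px = [sum(p[i, j] for j in range(ng)) for i in range(ng)]
    mu = sum((i + 1) * px[i] for i in range(ng))
    var = sum((i + 1 - mu) ** 2 * px[i] for i in range(ng))
    for i in range(ng):
        for j in range(ng):
            v = p[i, j]
            if v == 0:
                continue
            a, b = i + 1, j + 1
            feats["Entropy"] -= v * log2(v)
            feats["Energy"] += v * v
            feats["Contrast"] += v * (a - b) ** 2
            feats["Dissimilarity"] += v * abs(a - b)
            feats["Homogeneity"] += v / (1 + abs(a - b))
            feats["InverseDifferenceMoment"] += v / (1 + (a - b) ** 2)
            feats["Autocorrelation"] += v * a * b
            feats["ClusterTendency"] += v * (a + b - 2 * mu) ** 2
            feats["ClusterShade"] += v * (a + b - 2 * mu) ** 3
            feats["ClusterProminence"] += v * (a + b - 2 * mu) ** 4
            feats["JointAverageNum"] += v * a
            feats["SumOfSquares"] += v * (a - mu) ** 2
            if a != b:
                feats["InverseVariance"] += v / (a - b) ** 2
    feats["MaximumProbability"] = float(p.max())
    feats["JointAverage"] = mu
    if var > 0:
        num = sum(
            p[i, j] * (i + 1) * (j + 1) for i in range(ng) for j in range(ng)
        ) - mu * mu
        feats["Correlation"] = num / var
    else:
        feats["Correlation"] = 1.0
    return dict(feats)


def brute_runs(grid, mask, offset):
    """All maximal same-level in-mask runs along one direction.

    Returns a dict (level, length) -> count.
    """
    dr, dc = offset
    nrow, ncol = grid.shape
    # Start positions: pixels with no predecessor along the direction.
    runs = defaultdict(int)
    for r in range(nrow):
        for c in range(ncol):
            pr, pc = r - dr, c - dc
            has_pred = (
                0 <= pr < nrow
                and 0 <= pc < ncol
                and mask[pr, pc]
                and mask[r, c]
                and grid[pr, pc] == grid[r, c]
            )
            if not mask[r, c] or has_pred:
                continue
            # Walk forward.
            length = 1
            rr, cc = r + dr, c + dc
            while (
                0 <= rr < nrow
                and 0 <= cc < ncol
                and mask[rr, cc]
                and grid[rr, cc] == grid[r, c]
            ):
                length += 1
                rr += dr
                cc += dc
            runs[(grid[r, c], length)] += 1
    return runs


def brute_zones(grid, mask):
    """8-connected equal-level zones by explicit flood fill.

    Returns a dict (level, size) -> count.
    """
    nrow, ncol = grid.shape
    seen = np.zeros_like(mask, dtype=bool)
    zones = defaultdict(int)
    for r in range(nrow):
        for c in range(ncol):
            if not mask[r, c] or seen[r, c]:
                continue
            level = grid[r, c]
            stack = [(r, c)]
            seen[r, c] = True
            size = 0
            while stack:
                rr, cc = stack.pop()
                size += 1
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        r2, c2 = rr + dr, cc + dc
                        if (
                            0 <= r2 < nrow
                            and 0 <= c2 < ncol
                            and mask[r2, c2]
                            and not seen[r2, c2]
                            and grid[r2, c2] == level
                        ):
                            seen[r2, c2] = True
                            stack.append((r2, c2))
            zones[(level, size)] += 1
    return zones


def brute_weighted_features(counts, n_pixels):
    """Naive run-length / size-zone emphasis features from (level, j) counts."""
    n = sum(counts.values())
    f = defaultdict(float)
    gl = defaultdict(float)
    ln = defaultdict(float)
    mu_i = sum(i * v for (i, _), v in counts.items()) / n
    mu_j = sum(j * v for (_, j), v in counts.items()) / n
    for (i, j), v in counts.items():
        gl[i] += v
        ln[j] += v
        f["ShortEmphasis"] += v / j**2
        f["LongEmphasis"] += v * j**2
        f["LowGreyEmphasis"] += v / i**2
        f["HighGreyEmphasis"] += v * i**2
        f["ShortLow"] += v / (i**2 * j**2)
        f["ShortHigh"] += v * i**2 / j**2
        f["LongLow"] += v * j**2 / i**2
        f["LongHigh"] += v * i**2 * j**2
        f["GreyLevelVariance"] += (v / n) * (i - mu_i) ** 2
        f["LengthVariance"] += (v / n) * (j - mu_j) ** 2
        f["Entropy"] -= (v / n) * log2(v / n)
    for k in (
        "ShortEmphasis",
        "LongEmphasis",
        "LowGreyEmphasis",
        "HighGreyEmphasis",
        "ShortLow",
        "ShortHigh",
        "LongLow",
        "LongHigh",
    ):
        f[k] /= n
    f["GreyLevelNonUniformity"] = sum(v**2 for v in gl.values()) / n
    f["GreyLevelNonUniformityNormalised"] = sum(v**2 for v in gl.values()) / n**2
    f["LengthNonUniformity"] = sum(v**2 for v in ln.values()) / n
    f["LengthNonUniformityNormalised"] = sum(v**2 for v in ln.values()) / n**2
    f["Percentage"] = n / n_pixels
    return dict(f)


# ---------------------------------------------------------------------------
# Statistics oracles
# ---------------------------------------------------------------------------


def brute_auc(scores, labels):
    """AUC as an explicit double loop over (positive, negative) pairs."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))


def anova_icc21(reader1, reader2):
    """ICC(2,1) recomputed from explicitly accumulated sums of squares."""
    data = [[float(a), float(b)] for a, b in zip(reader1, reader2)]
    n = len(data)
    k = 2
    grand = sum(sum(row) for row in data) / (n * k)
    row_means = [sum(row) / k for row in data]
    col_means = [sum(data[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((m - grand) ** 2 for m in row_means)
    ss_cols = n * sum((m - grand) ** 2 for m in col_means)
    ss_total = sum((data[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + k / n * (ms_c - ms_e))


def bootstrap_auc_variance(scores, labels, n_boot, rng):
    """Nonparametric bootstrap variance of the AUC (resampling patients)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n = len(scores)
    aucs = []
    from scipy.stats import rankdata

    while len(aucs) < n_boot:
        idx = rng.integers(0, n, size=n)
        y = labels[idx]
        if y.min() == y.max():
            continue
        s = scores[idx]
        ranks = rankdata(s)
        m = int(y.sum())
        r_pos = ranks[y == 1].sum()
        aucs.append((r_pos - m * (m + 1) / 2) / (m * (n - m)))
    return float(np.var(aucs, ddof=1))
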