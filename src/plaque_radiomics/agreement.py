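"""Inter-reader agreement statistics.

Single-measure intraclass correlation ICC(2,1) (two-way random effects,
absolute agreement), Bland-Altman bias and limits of agreement, and Cohen's
kappa for binary ratings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

__all__ = [
    "icc_two_way_random_absolute",
    "bland_altman",
    "cohens_kappa",
    "mean_icc_across_features",
    "AgreementError",
]


class AgreementError(ValueError):
    """Agreement statistic undefined for the given ratings."""


def _pair_table(reader1, reader2, min_n: int) -> Tuple[np.ndarray, np.ndarray]:
    a = np.asarray(reader1, dtype=float)
    b = np.asarray(reader2, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("readers must supply matched 1D measurement vectors")
    if a.size < min_n:
        raise ValueError(f"need at least {min_n} subjects")
    return a, b


def icc_two_way_random_absolute(reader1, reader2) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    From the two-way ANOVA mean squares with n subjects and k = 2 raters:
    (MS_R - MS_E) / (MS_R + (k-1) MS_E + k/n (MS_C - MS_E)).
    Absolute agreement penalises a systematic between-reader offset.
    """
    a, b = _pair_table(reader1, reader2, 3)
    data = np.column_stack([a, b])
    n, k = data.shape

    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)

    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols

    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))

    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    if denom <= 0 or (ms_r == 0 and ms_e == 0 and ms_c == 0):
        raise AgreementError("zero between-subject variance: ICC undefined")
    return float((ms_r - ms_e) / denom)


def bland_altman(reader1, reader2) -> Tuple[float, float, float, np.ndarray]:
    """Bland-Altman analysis of paired measurements.

    Returns (bias, lower limit, upper limit, points) where bias is the mean
    difference, the limits are bias +- 1.96 SD of the differences, and
    points are per-subject (mean, difference) pairs for plotting.
    """
    a, b = _pair_table(reader1, reader2, 2)
    diff = a - b
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    points = np.column_stack([(a + b) / 2.0, diff])
    return bias, bias - 1.96 * sd, bias + 1.96 * sd, points


def mean_icc_across_features(tables: dict) -> Tuple[float, Tuple[float, float]]:
    """Arithmetic mean (and range) of per-feature ICC(2,1) values.

    ``tables`` maps feature name -> (reader1 values, reader2 values); this is
    how a panel of re-read radiomic features is summarised into one average
    agreement figure.
    """
    if not tables:
        raise ValueError("no feature tables supplied")
    iccs = [icc_two_way_random_absolute(a, b) for a, b in tables.values()]
    return float(np.mean(iccs)), (float(np.min(iccs)), float(np.max(iccs)))


def cohens_kappa(reader1, reader2) -> float:
    """Cohen's kappa for two binary raters: (p_o - p_e) / (1 - p_e)."""
    a, b = _pair_table(reader1, reader2, 2)
    for v in np.concatenate([a, b]):
        if v not in (0.0, 1.0):
            raise ValueError("kappa requires binary (0/1) ratings")
    po = float((a == b).mean())
    p1a, p1b = a.mean(), b.mean()
    pe = p1a * p1b + (1 - p1a) * (1 - p1b)
    if pe >= 1.0:
        raise AgreementError("both raters constant: kappa undefined")
    return float((po - pe) / (1.0 - pe))
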