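"""Univariate screening, stepwise logistic regression, radiomic feature
selection, ROC/AUC machinery and the DeLong test for correlated AUCs.

The AUC is the Mann-Whitney pairwise concordance probability (ties counted
one half); the operating point maximises Youden's J with ties broken toward
higher specificity; stepwise logistic selection emulates the classic
forward-likelihood-ratio procedure (entry p < 0.10, removal p > 0.05) with
maximum-likelihood fits delegated to statsmodels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "UnivariateResult",
    "LogisticFit",
    "DiagnosticResult",
    "two_sample_ttest",
    "chi_squared_2x2",
    "auc_mann_whitney",
    "roc_points",
    "likelihood_ratios",
    "optimise_operating_point",
    "stepwise_logistic",
    "select_radiomic_features",
    "delong_auc_variance",
    "delong_test",
]


@dataclass(frozen=True)
class UnivariateResult:
    variable_name: str
    statistic: float
    p_value: float
    group_summary: Tuple
    auc: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p value outside [0, 1]")


@dataclass
class LogisticFit:
    """A fitted (possibly stepwise-selected) logistic model."""

    selected_variables: List[str]
    coefficients: Dict[str, float]
    odds_ratios: Dict[str, Tuple[float, float, float]]  # OR, CI low, CI high
    intercept: float
    converged: bool
    diagnostic: str = ""

    def linear_predictor(self, table: pd.DataFrame) -> np.ndarray:
        lp = np.full(len(table), self.intercept)
        for v in self.selected_variables:
            lp += self.coefficients[v] * table[v].to_numpy(dtype=float)
        return lp


@dataclass
class DiagnosticResult:
    """ROC summary of one scoring model at its Youden-optimal threshold."""

    roc_points: np.ndarray  # (n_thresholds, 2) of (FPR, TPR)
    auc: float
    optimal_threshold: float
    sensitivity: float
    specificity: float
    accuracy: float
    lr_plus: float
    inv_lr_minus: float

    def to_dict(self) -> Dict[str, float]:
        return {
            "auc": self.auc,
            "optimal_threshold": self.optimal_threshold,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "lr_plus": self.lr_plus,
            "inv_lr_minus": self.inv_lr_minus,
        }


# ---------------------------------------------------------------------------
# Univariate tests
# ---------------------------------------------------------------------------


def two_sample_ttest(
    x1: Sequence[float], x2: Sequence[float], name: str = "", welch: bool = False
) -> UnivariateResult:
    """Two-sided two-sample t test (Student pooled-variance by default)."""
    a = np.asarray(x1, dtype=float)
    b = np.asarray(x2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        # Degenerate: no within-group variability.
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t, p = np.inf if a.mean() > b.mean() else -np.inf, 0.0
    else:
        t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return UnivariateResult(
        variable_name=name,
        statistic=float(t),
        p_value=float(p),
        group_summary=((a.mean(), a.std(ddof=1)), (b.mean(), b.std(ddof=1))),
    )


def chi_squared_2x2(
    table: Sequence[Sequence[float]], name: str = "", correction: bool = False
) -> UnivariateResult:
    """Pearson chi-squared on a 2x2 table, df = 1.

    Continuity correction off by default (switchable).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    stat, p, _, _ = sps.chi2_contingency(t, correction=correction)
    return UnivariateResult(
        variable_name=name, statistic=float(stat), p_value=float(p), group_summary=tuple(map(tuple, t))
    )


# ---------------------------------------------------------------------------
# ROC machinery
# ---------------------------------------------------------------------------


def _split_scores(scores, labels) -> Tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pos = s[y == 1]
    neg = s[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    return pos, neg


def auc_mann_whitney(scores, labels) -> float:
    """AUC as the proportion of (positive, negative) pairs correctly ordered,
    ties counted one half (midrank formulation)."""
    pos, neg = _split_scores(scores, labels)
    all_scores = np.concatenate([pos, neg])
    ranks = sps.rankdata(all_scores)
    r_pos = ranks[: pos.size].sum()
    m, n = pos.size, neg.size
    return float((r_pos - m * (m + 1) / 2) / (m * n))


def roc_points(scores, labels) -> Tuple[np.ndarray, np.ndarray]:
    """Empirical ROC curve: thresholds (descending) and (FPR, TPR) points.

    A case is called positive when its score >= threshold.
    """
    pos, neg = _split_scores(scores, labels)
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    thresholds = np.concatenate([[np.inf], thresholds])
    fpr = np.array([(neg >= t).mean() for t in thresholds])
    tpr = np.array([(pos >= t).mean() for t in thresholds])
    return thresholds, np.column_stack([fpr, tpr])


def likelihood_ratios(sensitivity: float, specificity: float) -> Tuple[float, float]:
    """LR+ = sens / (1 - spec) and 1/LR- = spec / (1 - sens)."""
    lr_plus = sensitivity / (1.0 - specificity) if specificity < 1.0 else np.inf
    inv_lr_minus = specificity / (1.0 - sensitivity) if sensitivity < 1.0 else np.inf
    return float(lr_plus), float(inv_lr_minus)


def optimise_operating_point(scores, labels) -> DiagnosticResult:
    """Youden-optimal operating point with accuracy and likelihood ratios.

    Ties in J are broken toward the higher-specificity (higher-threshold)
    operating point.
    """
    pos, neg = _split_scores(scores, labels)
    thresholds, pts = roc_points(scores, labels)
    j = pts[:, 1] - pts[:, 0]
    # First index within floating tolerance of the maximum: ties resolve to
    # the highest threshold, i.e. the higher-specificity operating point.
    best = int(np.flatnonzero(j >= j.max() - 1e-12)[0])
    fpr, tpr = pts[best]
    sens, spec = float(tpr), float(1.0 - fpr)
    n_pos, n_neg = pos.size, neg.size
    accuracy = (sens * n_pos + spec * n_neg) / (n_pos + n_neg)
    lr_plus, inv_lr_minus = likelihood_ratios(sens, spec)
    return DiagnosticResult(
        roc_points=pts,
        auc=auc_mann_whitney(scores, labels),
        optimal_threshold=float(thresholds[best]),
        sensitivity=sens,
        specificity=spec,
        accuracy=float(accuracy),
        lr_plus=lr_plus,
        inv_lr_minus=inv_lr_minus,
    )


# ---------------------------------------------------------------------------
# Logistic regression with stepwise selection
# ---------------------------------------------------------------------------


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    import statsmodels.api as sm

    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, Xc)
        res = model.fit(disp=0, maxiter=200)
    return res


def _try_fit(y: np.ndarray, X: pd.DataFrame):
    """MLE fit, or None when the optimiser fails (separation, singularity)."""
    try:
        res = _fit_logit(y, X)
    except Exception:
        return None
    if not np.isfinite(float(res.llf)):
        return None
    return res


def stepwise_logistic(
    table: pd.DataFrame,
    labels,
    candidate_variables: Sequence[str],
    entry_p: float = 0.10,
    stay_p: float = 0.05,
) -> LogisticFit:
    """Forward-stepwise logistic regression with backward pruning.

    Entry and removal are judged by likelihood-ratio chi-squared tests (1 df)
    against the current model.  Wald 95% CIs: exp(beta +- 1.96 SE).
    Non-convergence or (quasi-)separation is flagged, never silent.
    """
    y = np.asarray(labels).astype(int)
    candidates = list(candidate_variables)
    for v in candidates:
        if table[v].nunique() < 2:
            raise ValueError(f"candidate {v!r} is constant")
    if len(y) <= len(candidates):
        raise ValueError("need more observations than candidates")

    selected: List[str] = []
    visited = set()
    diagnostic = ""
    ll_current = float(_fit_logit(y, table[[]]).llf)

    while True:
        state = tuple(sorted(selected))
        if state in visited:
            break
        visited.add(state)

        # Forward step: best candidate by LR p value.
        best_var, best_p, best_ll = None, 1.0, None
        for v in candidates:
            if v in selected:
                continue
            res = _try_fit(y, table[selected + [v]])
            if res is None:
                continue
            lr = 2.0 * (float(res.llf) - ll_current)
            p = float(sps.chi2.sf(max(lr, 0.0), df=1))
            if p < best_p or (p == best_p and best_var is None):
                best_var, best_p, best_ll = v, p, float(res.llf)
        if best_var is not None and best_p < entry_p:
            selected.append(best_var)
            ll_current = best_ll
        else:
            break

        # Backward pruning: drop any variable whose removal LR p > stay_p.
        changed = True
        while changed and len(selected) > 1:
            changed = False
            worst_var, worst_p = None, 0.0
            for v in selected:
                rest = [w for w in selected if w != v]
                res_rest = _try_fit(y, table[rest])
                if res_rest is None:
                    continue
                lr = 2.0 * (ll_current - float(res_rest.llf))
                p = float(sps.chi2.sf(max(lr, 0.0), df=1))
                if p > worst_p:
                    worst_var, worst_p = v, p
            if worst_var is not None and worst_p > stay_p:
                selected.remove(worst_var)
                res_sel = _try_fit(y, table[selected])
                if res_sel is None:
                    selected.append(worst_var)
                    break
                ll_current = float(res_sel.llf)
                changed = True

    if not selected:
        return LogisticFit([], {}, {}, intercept=float(np.log(y.mean() / (1 - y.mean()))),
                           converged=True, diagnostic="no variable entered the model")

    res = _try_fit(y, table[selected])
    if res is None:
        return LogisticFit(selected, {}, {}, intercept=0.0, converged=False,
                           diagnostic="final fit failed (separation or singular Hessian)")
    params = res.params
    bse = res.bse
    converged = bool(res.mle_retvals.get("converged", True)) and np.isfinite(bse).all()
    if not converged:
        diagnostic = "non-convergence or separation in the final fit"
    coefs = {v: float(params[v]) for v in selected}
    with np.errstate(over="ignore"):  # separation gives an infinite upper CI
        ors = {
            v: (
                float(np.exp(params[v])),
                float(np.exp(params[v] - 1.96 * bse[v])),
                float(np.exp(params[v] + 1.96 * bse[v])),
            )
            for v in selected
        }
    return LogisticFit(
        selected_variables=selected,
        coefficients=coefs,
        odds_ratios={v: (o, lo, hi) for v, (o, lo, hi) in ors.items()},
        intercept=float(params["const"]),
        converged=converged,
        diagnostic=diagnostic,
    )


# ---------------------------------------------------------------------------
# Radiomic feature selection
# ---------------------------------------------------------------------------


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p values (monotone step-up FDR)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def select_radiomic_features(
    features: pd.DataFrame,
    labels,
    p_threshold: float = 0.05,
    auc_threshold: float = 0.65,
    welch: bool = False,
    fdr_correction: bool = False,
) -> List[str]:
    """Features with a significant group difference AND discriminative AUC.

    Keeps columns with two-sided t-test p < p_threshold and symmetrised
    univariate AUC max(AUC, 1-AUC) > auc_threshold.  An empty selection is a
    legitimate outcome.  ``fdr_correction`` switches the p gate to
    Benjamini-Hochberg adjusted values (off by default: the emulated workflow
    applies no multiplicity correction).
    """
    y = np.asarray(labels).astype(int)
    cols: List[str] = []
    pvals: List[float] = []
    aucs: List[float] = []
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            continue
        res = two_sample_ttest(x[y == 1], x[y == 0], name=col, welch=welch)
        cols.append(col)
        pvals.append(res.p_value)
        aucs.append(auc_mann_whitney(x, y))
    if not cols:
        return []
    gate_p = benjamini_hochberg(pvals) if fdr_correction else np.asarray(pvals)
    return [
        c
        for c, p, a in zip(cols, gate_p, aucs)
        if p < p_threshold and max(a, 1.0 - a) > auc_threshold
    ]


# ---------------------------------------------------------------------------
# DeLong machinery
# ---------------------------------------------------------------------------


def _placements(pos: np.ndarray, neg: np.ndarray) -> Tuple[float, np.ndarray, np.ndarray]:
    """AUC plus the structural placement components V10 (per positive) and
    V01 (per negative)."""
    # psi(X, Y) = 1 if X > Y, 1/2 if X == Y, 0 otherwise; midranks give the
    # row/column means of psi without the quadratic loop.
    m, n = pos.size, neg.size
    all_scores = np.concatenate([pos, neg])
    ranks = sps.rankdata(all_scores)
    rank_pos = sps.rankdata(pos)
    rank_neg = sps.rankdata(neg)
    v10 = (ranks[:m] - rank_pos) / n
    v01 = 1.0 - (ranks[m:] - rank_neg) / m
    auc = float(v10.mean())
    return auc, v10, v01


def delong_auc_variance(scores, labels) -> Tuple[float, float]:
    """(AUC, DeLong variance of the AUC) for a single model."""
    pos, neg = _split_scores(scores, labels)
    auc, v10, v01 = _placements(pos, neg)
    s10 = v10.var(ddof=1) if pos.size > 1 else 0.0
    s01 = v01.var(ddof=1) if neg.size > 1 else 0.0
    return auc, float(s10 / pos.size + s01 / neg.size)


def delong_test(scores1, scores2, labels) -> Tuple[float, float, float, float]:
    """Paired DeLong comparison of two correlated AUCs.

    Returns (auc1, auc2, z, two-sided p).  Degenerate variance (for example
    identical scores) yields z = 0, p = 1.
    """
    s1 = np.asarray(scores1, dtype=float)
    s2 = np.asarray(scores2, dtype=float)
    y = np.asarray(labels).astype(int)
    if s1.shape != s2.shape or s1.shape[0] != y.shape[0]:
        raise ValueError("score vectors and labels must be aligned")
    pos_idx, neg_idx = y == 1, y == 0

    auc1, v10_1, v01_1 = _placements(s1[pos_idx], s1[neg_idx])
    auc2, v10_2, v01_2 = _placements(s2[pos_idx], s2[neg_idx])
    m, n = int(pos_idx.sum()), int(neg_idx.sum())

    v10 = np.vstack([v10_1, v10_2])
    v01 = np.vstack([v01_1, v01_2])
    s10 = np.cov(v10) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(v01) if n > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    if var <= 1e-15:
        return auc1, auc2, 0.0, 1.0
    z = (auc1 - auc2) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return auc1, auc2, float(z), float(p)
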