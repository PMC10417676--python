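"""Rank tests and diagnostic-accuracy statistics.

Implements the empirical ROC machinery (pairwise/rank AUC, ROC curve over
observed thresholds, Youden-J cutoff selection, DeLong and stratified
bootstrap confidence intervals), the Wilcoxon rank-sum test with an exact
enumeration mode, one-way ANOVA, and median/IQR summaries.

Conventions
-----------
* A case is test-positive iff its score >= threshold; higher scores point
  toward the positive class.
* The AUC counts tied positive/negative pairs as 1/2, so it equals the
  probability a random positive outranks a random negative and also the
  trapezoidal area under the empirical ROC curve.
* Quartiles use linear interpolation (numpy's default, "type 7").
"""

from __future__ import annotations

import math
from typing import Literal, Sequence

import numpy as np
from scipy import stats as _sps

from .types import RocPoint, ValidationError

__all__ = [
    "mann_whitney_auc",
    "roc_points",
    "trapezoid_auc",
    "youden_cutoff",
    "auc_confidence_interval",
    "wilcoxon_rank_sum",
    "one_way_anova",
    "median_iqr",
]


def _as_1d(name: str, x) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValidationError(f"{name} must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


def mann_whitney_auc(scores_pos, scores_neg) -> float:
    """Probability that a random positive scores above a random negative.

    Computed with the midrank formula; ties count half.  Agrees exactly
    with exhaustive pairwise comparison.
    """
    pos = _as_1d("scores_pos", scores_pos)
    neg = _as_1d("scores_neg", scores_neg)
    ranks = _sps.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def roc_points(scores, labels) -> list[RocPoint]:
    """Empirical ROC curve over observed thresholds.

    Thresholds are the unique observed scores in descending order, preceded
    by a sentinel above the maximum (predict-nobody-positive).  A case is
    test-positive iff score >= threshold.  The trapezoidal area over the
    curve equals :func:`mann_whitney_auc` exactly.
    """
    s = _as_1d("scores", scores)
    y = np.asarray(labels).ravel()
    if y.size != s.size:
        raise ValidationError("scores and labels must have equal length")
    y = y.astype(bool)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValidationError(
            "ROC analysis requires both classes present "
            f"(n_pos={n_pos}, n_neg={n_neg})"
        )
    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    y_sorted = y[order]
    # cumulative true/false positives after lowering the threshold past each
    # distinct score
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(~y_sorted)
    distinct = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    thresholds = s_sorted[distinct]
    tp_d = tp[distinct]
    fp_d = fp[distinct]

    points = [RocPoint(threshold=math.inf, sensitivity=0.0, specificity=1.0)]
    for t, tpi, fpi in zip(thresholds, tp_d, fp_d):
        points.append(
            RocPoint(
                threshold=float(t),
                sensitivity=float(tpi / n_pos),
                specificity=float(1.0 - fpi / n_neg),
            )
        )
    return points


def trapezoid_auc(points: Sequence[RocPoint]) -> float:
    """Trapezoidal area under an ROC point list in (FPR, TPR) space."""
    fpr = np.array([1.0 - p.specificity for p in points])
    tpr = np.array([p.sensitivity for p in points])
    order = np.argsort(fpr, kind="mergesort")
    return float(np.trapezoid(tpr[order], fpr[order]))


def youden_cutoff(points: Sequence[RocPoint]) -> tuple[float, float, float]:
    """Threshold maximizing Youden's J = sensitivity + specificity − 1.

    Ties are broken toward higher specificity, then toward the higher
    threshold.  Returns (cutoff, sensitivity, specificity).
    """
    pts = list(points)
    if len(pts) < 2:
        raise ValidationError("degenerate ROC curve: need at least two points")
    best = None
    for p in pts:
        j = p.sensitivity + p.specificity - 1.0
        key = (j, p.specificity, p.threshold)
        if best is None or key > best[0]:
            best = (key, p)
    p = best[1]
    return p.threshold, p.sensitivity, p.specificity


def _delong_interval(pos: np.ndarray, neg: np.ndarray, alpha: float):
    if pos.size < 2 or neg.size < 2:
        raise ValidationError(
            "DeLong interval requires at least two cases in each class"
        )
    # structural components: placement of each case among the other class
    greater = pos[:, None] > neg[None, :]
    equal = pos[:, None] == neg[None, :]
    psi = greater + 0.5 * equal
    v10 = psi.mean(axis=1)  # per positive
    v01 = psi.mean(axis=0)  # per negative
    auc = float(psi.mean())
    var = v10.var(ddof=1) / pos.size + v01.var(ddof=1) / neg.size
    z = _sps.norm.ppf(1.0 - alpha / 2.0)
    half = z * math.sqrt(max(var, 0.0))
    return max(0.0, auc - half), min(1.0, auc + half)


def _bootstrap_interval(
    pos: np.ndarray, neg: np.ndarray, alpha: float, n_boot: int, seed
):
    rng = np.random.default_rng(seed)
    if n_boot * pos.size * neg.size <= 50_000_000:
        # vectorized pairwise AUC across all resamples
        bp = pos[rng.integers(0, pos.size, size=(n_boot, pos.size))]
        bn = neg[rng.integers(0, neg.size, size=(n_boot, neg.size))]
        psi = (bp[:, :, None] > bn[:, None, :]) + 0.5 * (
            bp[:, :, None] == bn[:, None, :]
        )
        aucs = psi.mean(axis=(1, 2))
    else:
        aucs = np.empty(n_boot)
        for b in range(n_boot):
            bp = pos[rng.integers(0, pos.size, size=pos.size)]
            bn = neg[rng.integers(0, neg.size, size=neg.size)]
            aucs[b] = mann_whitney_auc(bp, bn)
    low, high = np.quantile(aucs, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(max(0.0, low)), float(min(1.0, high))


def auc_confidence_interval(
    scores_pos,
    scores_neg,
    alpha: float = 0.05,
    method: Literal["delong", "bootstrap"] = "delong",
    n_boot: int = 2000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Confidence interval for the AUC, clipped to [0, 1].

    ``delong`` (default) is the Wald interval from the DeLong
    structural-component variance and is deterministic; ``bootstrap`` is a
    percentile interval over ``n_boot`` class-stratified resamples and
    requires a seed for reproducibility.  At perfect separation the DeLong
    variance vanishes and the interval degenerates to a point.
    """
    pos = _as_1d("scores_pos", scores_pos)
    neg = _as_1d("scores_neg", scores_neg)
    if method == "delong":
        return _delong_interval(pos, neg, alpha)
    if method == "bootstrap":
        return _bootstrap_interval(pos, neg, alpha, n_boot, seed)
    raise ValidationError(f"unknown CI method {method!r}")


def _rank_sum_exact_p(ranks_x_sum: float, n_x: int, n: int) -> float:
    """Two-sided exact p for the rank-sum statistic without ties.

    Counts, by dynamic programming over subset sums, the number of ways to
    pick n_x of the ranks 1..n with sum at most / at least as extreme as
    observed; the null distribution is symmetric about n_x(n+1)/2.
    """
    mu2 = n_x * (n + 1)  # 2 * mean, integer
    w2 = int(round(2 * ranks_x_sum))
    d = abs(w2 - mu2)  # 2 * |W - mu|
    lo_cut2 = mu2 - d  # count P(2W <= lo_cut2) and mirror
    max_sum = sum(range(n - n_x + 1, n + 1))
    # dp[k][s] = number of k-subsets of {1..i} with sum s
    dp = np.zeros((n_x + 1, max_sum + 1), dtype=float)
    dp[0, 0] = 1.0
    for i in range(1, n + 1):
        for k in range(min(i, n_x), 0, -1):
            dp[k, i:] += dp[k - 1, : max_sum + 1 - i]
    counts = dp[n_x]
    total = counts.sum()
    sums2 = 2 * np.arange(max_sum + 1)
    lower = counts[sums2 <= lo_cut2].sum()
    upper = counts[sums2 >= mu2 + d].sum()
    return float(min(1.0, (lower + upper) / total))


def wilcoxon_rank_sum(
    x,
    y,
    mode: Literal["auto", "exact", "normal"] = "auto",
) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann–Whitney) test; returns (rank-sum of x, p).

    ``exact`` enumerates the permutation distribution of the rank sum and
    requires tie-free data; ``normal`` uses the tie-corrected Gaussian
    approximation with a 0.5 continuity correction; ``auto`` picks exact
    when there are no ties and n_x + n_y <= 20, else normal.
    """
    xa = _as_1d("x", x)
    ya = _as_1d("y", y)
    n_x, n_y = xa.size, ya.size
    n = n_x + n_y
    combined = np.concatenate([xa, ya])
    ranks = _sps.rankdata(combined)
    w = float(ranks[:n_x].sum())
    has_ties = np.unique(combined).size < n

    if mode == "auto":
        mode = "exact" if (not has_ties and n <= 20) else "normal"
    if mode == "exact":
        if has_ties:
            raise ValidationError(
                "exact mode requires tie-free data; use mode='normal'"
            )
        return w, _rank_sum_exact_p(w, n_x, n)
    if mode != "normal":
        raise ValidationError(f"unknown mode {mode!r}")

    mu = n_x * (n + 1) / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var = n_x * n_y / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return w, 1.0  # all observations identical
    z = (abs(w - mu) - 0.5) / math.sqrt(var)
    p = 2.0 * _sps.norm.sf(z)
    return w, float(min(1.0, p))


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classic one-way fixed-effects ANOVA: (F statistic, p-value).

    Requires at least two groups with at least two observations each.
    """
    if len(groups) < 2:
        raise ValidationError("one_way_anova requires at least two groups")
    arrays = [_as_1d(f"group {i}", g) for i, g in enumerate(groups)]
    for i, a in enumerate(arrays):
        if a.size < 2:
            raise ValidationError(
                f"group {i} has {a.size} observation(s); need at least two"
            )
    f, p = _sps.f_oneway(*arrays)
    if math.isnan(f):  # zero within-group variance with equal means
        return 0.0, 1.0
    return float(f), float(p)


def median_iqr(sample) -> tuple[float, float, float]:
    """(median, Q1, Q3) with linear-interpolation (type-7) quartiles."""
    arr = _as_1d("sample", sample)
    med, q1, q3 = np.quantile(arr, [0.5, 0.25, 0.75])
    return float(med), float(q1), float(q3)
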