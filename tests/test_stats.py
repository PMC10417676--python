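"""Diagnostic-accuracy statistics against independent oracles.

Brute-force oracles (pairwise enumeration for the AUC, combinatorial
enumeration for the exact rank-sum test) are defined here, independent of
the implementation, and the implementation is additionally cross-checked
against scikit-learn and scipy where they provide the same quantity.
"""

import itertools
import math

import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from nnose import (
    ValidationError,
    auc_confidence_interval,
    mann_whitney_auc,
    median_iqr,
    one_way_anova,
    roc_points,
    trapezoid_auc,
    wilcoxon_rank_sum,
    youden_cutoff,
)

# ---------------------------------------------------------------------------
# independent oracles


def pairwise_auc_oracle(pos, neg):
    """AUC by exhaustive pairwise comparison, ties counted half."""
    wins = sum(
        1.0 if p > n else (0.5 if p == n else 0.0)
        for p in pos for n in neg
    )
    return wins / (len(pos) * len(neg))


def exact_ranksum_oracle(x, y):
    """Two-sided exact rank-sum p by enumerating all rank assignments."""
    n_x, n = len(x), len(x) + len(y)
    ranks = sps.rankdata(np.concatenate([x, y]))
    w_obs = ranks[:n_x].sum()
    mu = n_x * (n + 1) / 2.0
    d = abs(w_obs - mu)
    count = 0
    total = 0
    for combo in itertools.combinations(range(1, n + 1), n_x):
        total += 1
        if abs(sum(combo) - mu) >= d - 1e-9:
            count += 1
    return count / total


# ---------------------------------------------------------------------------
# AUC and ROC


def test_auc_worked_example():
    # pairs: 3>2, 3>0, 1<2, 1>0  ->  3/4
    assert mann_whitney_auc([3, 1], [2, 0]) == pytest.approx(0.75)


def test_auc_tie_symmetry_and_separation():
    assert mann_whitney_auc([5, 5], [5, 5]) == pytest.approx(0.5)
    assert mann_whitney_auc([3, 4], [1, 2]) == pytest.approx(1.0)
    assert mann_whitney_auc([1, 2], [3, 4]) == pytest.approx(0.0)


@given(st.data())
@settings(max_examples=100, deadline=None)
def test_auc_matches_pairwise_oracle_and_sklearn(data):
    """Rank-formula AUC == exhaustive pairwise comparison == sklearn."""
    n_pos = data.draw(st.integers(1, 12))
    n_neg = data.draw(st.integers(1, 12))
    vals = st.integers(-5, 5)  # small support forces ties
    pos = data.draw(st.lists(vals, min_size=n_pos, max_size=n_pos))
    neg = data.draw(st.lists(vals, min_size=n_neg, max_size=n_neg))
    auc = mann_whitney_auc(pos, neg)
    assert auc == pytest.approx(pairwise_auc_oracle(pos, neg), abs=1e-12)
    y = [1] * n_pos + [0] * n_neg
    assert auc == pytest.approx(roc_auc_score(y, pos + neg), abs=1e-12)


@given(st.data())
@settings(max_examples=100, deadline=None)
def test_trapezoid_area_equals_pairwise_auc(data):
    """The empirical ROC curve integrates to the pairwise AUC exactly."""
    n = data.draw(st.integers(2, 50))
    scores = data.draw(
        st.lists(st.integers(-8, 8), min_size=n, max_size=n)
    )
    labels = data.draw(
        st.lists(st.booleans(), min_size=n, max_size=n).filter(
            lambda ls: any(ls) and not all(ls)
        )
    )
    pts = roc_points(scores, labels)
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    assert trapezoid_auc(pts) == pytest.approx(
        mann_whitney_auc(pos, neg), abs=1e-12
    )


@given(st.data())
@settings(max_examples=60, deadline=None)
def test_auc_invariant_under_monotone_transform(data):
    n_pos = data.draw(st.integers(2, 10))
    n_neg = data.draw(st.integers(2, 10))
    # quarter-integer scores: coarse enough that the transforms below stay
    # strictly increasing in floating point
    vals = st.integers(-40, 40).map(lambda v: v / 4.0)
    pos = np.array(data.draw(st.lists(vals, min_size=n_pos, max_size=n_pos)))
    neg = np.array(data.draw(st.lists(vals, min_size=n_neg, max_size=n_neg)))
    base = mann_whitney_auc(pos, neg)
    for f in (lambda v: 3.0 * v + 7.0, np.tanh, lambda v: np.exp(v / 10.0)):
        assert mann_whitney_auc(f(pos), f(neg)) == pytest.approx(base, abs=1e-12)


def test_roc_points_shape_and_degeneracy():
    pts = roc_points([3, 2, 1, 0], [1, 1, 0, 0])
    assert pts[0].threshold == math.inf
    assert (pts[0].sensitivity, pts[0].specificity) == (0.0, 1.0)
    assert any(p.sensitivity == 1.0 and p.specificity == 1.0 for p in pts)
    assert trapezoid_auc(pts) == pytest.approx(1.0)
    # all scores tied: two-point degenerate curve with area 1/2
    pts = roc_points([4, 4, 4, 4], [1, 1, 0, 0])
    assert len(pts) == 2
    assert trapezoid_auc(pts) == pytest.approx(0.5)
    with pytest.raises(ValidationError, match="both classes"):
        roc_points([1, 2], [1, 1])


def test_youden_cutoff_separated_and_tie_break():
    cutoff, sens, spec = youden_cutoff(roc_points([3, 4, 1, 2], [1, 1, 0, 0]))
    assert (sens, spec) == (1.0, 1.0)
    assert cutoff == 3  # smallest positive-class score
    # enumerated: J = 0.5 at thresholds 3 and 1; higher specificity wins
    cutoff, sens, spec = youden_cutoff(roc_points([3, 1, 2, 0], [1, 1, 0, 0]))
    assert (cutoff, sens, spec) == (3, 0.5, 1.0)
    # null data: J = 0 everywhere, sentinel (specificity 1) reported
    cutoff, sens, spec = youden_cutoff(roc_points([1, 1, 1, 1], [1, 1, 0, 0]))
    assert cutoff == math.inf and spec == 1.0


def test_youden_rejects_degenerate_curve():
    with pytest.raises(ValidationError, match="degenerate"):
        youden_cutoff([])


# ---------------------------------------------------------------------------
# confidence intervals


def test_delong_degenerates_at_perfect_separation():
    low, high = auc_confidence_interval([3, 4], [1, 2], method="delong")
    assert (low, high) == (1.0, 1.0)
    low, high = auc_confidence_interval([1, 2], [3, 4], method="delong")
    assert (low, high) == (0.0, 0.0)


def test_interval_bounds_clipped_into_unit_square(rng):
    pos = rng.normal(1.5, 1.0, 8)
    neg = rng.normal(0.0, 1.0, 12)
    for method in ("delong", "bootstrap"):
        low, high = auc_confidence_interval(pos, neg, method=method, seed=5)
        assert 0.0 <= low <= high <= 1.0


def test_delong_requires_two_per_class():
    with pytest.raises(ValidationError, match="at least two"):
        auc_confidence_interval([1.0], [0.0, 0.5], method="delong")


def test_bootstrap_seeded_reproducibility(rng):
    pos = rng.normal(1.0, 1.0, 7)
    neg = rng.normal(0.0, 1.0, 23)
    a = auc_confidence_interval(pos, neg, method="bootstrap", seed=42)
    b = auc_confidence_interval(pos, neg, method="bootstrap", seed=42)
    assert a == b


def test_delong_and_bootstrap_coverage():
    """Both 95% intervals track the true AUC and each other.

    Two Gaussian groups of 15 with known separation: true AUC =
    Phi(delta / sqrt(2)).  A 200-replication coverage simulation gives
    ~0.925 (DeLong) and ~0.935 (bootstrap) at this size — slightly below
    nominal, as expected of Wald/percentile intervals at n = 30 — so the
    test asserts coverage >= 0.90 for both and near-universal overlap of
    the two intervals.
    """
    delta = 0.5
    true_auc = sps.norm.cdf(delta / math.sqrt(2.0))
    rng = np.random.default_rng(20240901)
    hits = {"delong": 0, "bootstrap": 0}
    overlaps = 0
    n_rep = 200
    for _ in range(n_rep):
        pos = rng.normal(delta, 1.0, 15)
        neg = rng.normal(0.0, 1.0, 15)
        ivals = {}
        for method in hits:
            low, high = auc_confidence_interval(
                pos, neg, method=method, seed=int(rng.integers(2**31))
            )
            ivals[method] = (low, high)
            if low <= true_auc <= high:
                hits[method] += 1
        (dl, dh), (bl, bh) = ivals["delong"], ivals["bootstrap"]
        if max(dl, bl) <= min(dh, bh):
            overlaps += 1
    for method, h in hits.items():
        assert h / n_rep >= 0.90, f"{method} coverage {h / n_rep:.3f}"
    assert overlaps / n_rep >= 0.95


# ---------------------------------------------------------------------------
# rank-sum test


def test_exact_ranksum_worked_example():
    # all C(4,2)=6 rank splits; {1,2} and {3,4} are the two extremes
    stat, p = wilcoxon_rank_sum([1, 2], [3, 4], mode="exact")
    assert stat == 3.0
    assert p == pytest.approx(1 / 3, abs=1e-12)


def test_normal_mode_identical_samples_p_one():
    _, p = wilcoxon_rank_sum([5, 5, 5], [5, 5, 5], mode="normal")
    assert p == 1.0


def test_exact_mode_rejects_ties():
    with pytest.raises(ValidationError, match="tie-free"):
        wilcoxon_rank_sum([1, 2, 2], [3, 4], mode="exact")


@given(st.data())
@settings(max_examples=60, deadline=None)
def test_exact_p_matches_enumeration_oracle(data):
    """Exact two-sided p equals full C(n, n_x) enumeration (tie-free)."""
    n_x = data.draw(st.integers(2, 7))
    n_y = data.draw(st.integers(2, 7))
    vals = data.draw(
        st.lists(
            st.integers(-100, 100),
            min_size=n_x + n_y, max_size=n_x + n_y, unique=True,
        )
    )
    x, y = vals[:n_x], vals[n_x:]
    _, p = wilcoxon_rank_sum(x, y, mode="exact")
    assert p == pytest.approx(exact_ranksum_oracle(x, y), abs=1e-12)


def test_normal_mode_close_to_scipy_asymptotic(rng):
    for _ in range(20):
        x = rng.normal(0.3, 1.0, rng.integers(8, 30))
        y = rng.normal(0.0, 1.0, rng.integers(8, 30))
        _, p = wilcoxon_rank_sum(x, y, mode="normal")
        ref = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic"
        ).pvalue
        assert p == pytest.approx(ref, abs=1e-9)


def test_auto_mode_switches_on_size_and_ties():
    # small, tie-free -> matches exact
    x, y = [1, 5, 9], [2, 3, 11]
    assert wilcoxon_rank_sum(x, y, mode="auto") == wilcoxon_rank_sum(
        x, y, mode="exact"
    )
    # ties -> normal even when small
    xt, yt = [1.0, 2.0], [2.0, 3.0]
    assert wilcoxon_rank_sum(xt, yt, mode="auto") == wilcoxon_rank_sum(
        xt, yt, mode="normal"
    )


# ---------------------------------------------------------------------------
# ANOVA and quartiles


def test_anova_null_and_two_group_identity(rng):
    f, p = one_way_anova([[1.0, 2.0], [1.0, 2.0]])
    assert f == pytest.approx(0.0)
    assert p == pytest.approx(1.0)
    # two groups: F equals the square of the pooled-variance t statistic
    x = rng.normal(0.0, 1.0, 12)
    y = rng.normal(0.5, 1.0, 9)
    f, p_f = one_way_anova([x, y])
    t, p_t = sps.ttest_ind(x, y, equal_var=True)
    assert f == pytest.approx(t**2, rel=1e-10)
    assert p_f == pytest.approx(p_t, rel=1e-10)


def test_anova_three_group_hand_example():
    # groups [1,2],[3,4],[5,6]: SSB = 16 (df 2), SSW = 1.5 (df 3)
    # -> F = 8 / 0.5 = 16
    f, p = one_way_anova([[1, 2], [3, 4], [5, 6]])
    assert f == pytest.approx(16.0, rel=1e-12)
    assert p == pytest.approx(sps.f.sf(16.0, 2, 3), rel=1e-12)


def test_anova_rejects_degenerate_groups():
    with pytest.raises(ValidationError):
        one_way_anova([[1.0, 2.0]])
    with pytest.raises(ValidationError, match="at least two"):
        one_way_anova([[1.0, 2.0], [3.0]])


@pytest.mark.parametrize(
    "sample,expected",
    [
        ([1, 2, 3, 4, 5], (3.0, 2.0, 4.0)),
        ([7.5], (7.5, 7.5, 7.5)),
        ([1, 2, 3, 4], (2.5, 1.75, 3.25)),  # linear-interpolation quartiles
    ],
)
def test_median_iqr_linear_interpolation(sample, expected):
    assert median_iqr(sample) == pytest.approx(expected)


def test_empty_inputs_rejected():
    for fn in (median_iqr,):
        with pytest.raises(ValidationError, match="non-empty"):
            fn([])
    with pytest.raises(ValidationError, match="non-empty"):
        mann_whitney_auc([], [1.0])
    with pytest.raises(ValidationError, match="non-empty"):
        wilcoxon_rank_sum([1.0], [])
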