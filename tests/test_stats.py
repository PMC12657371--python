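"""Statistical layer: z-scores, group tests, partial correlation, FDR, ICC,
mediation — each against an independent oracle where one exists."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from glymphkit.stats import (
    count_percent,
    fdr_adjust,
    group_compare,
    icc_absolute_agreement,
    mediate,
    partial_correlation,
    zscore_cognition,
)


# ---------------------------------------------------------------------------
# independent oracles


def _bh_oracle(p):
    """Step-up Benjamini-Hochberg, written longhand."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p)
    q = np.empty(n)
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * n / rank)
        q[i] = prev
    return q


def _partial_r_oracle(x, y, Z):
    """Inverse-correlation-matrix definition of the partial correlation."""
    M = np.column_stack([x, y, Z])
    P = np.linalg.inv(np.corrcoef(M, rowvar=False))
    return -P[0, 1] / np.sqrt(P[0, 0] * P[1, 1])


def _icc_a1_oracle(r):
    """Two-way mean squares computed longhand with explicit loops."""
    n, k = r.shape
    grand = sum(r[i, j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(r[i, j] for j in range(k)) / k for i in range(n)]
    col = [sum(r[i, j] for i in range(n)) / n for j in range(k)]
    ssb = k * sum((rm - grand) ** 2 for rm in row)
    ssc = n * sum((cm - grand) ** 2 for cm in col)
    sst = sum((r[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    mse = (sst - ssb - ssc) / ((n - 1) * (k - 1))
    msr = ssb / (n - 1)
    msc = ssc / (k - 1)
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


# ---------------------------------------------------------------------------
# z-scoring


def test_hc_zscores_have_unit_moments(default_cohort):
    df, _ = default_cohort
    z = zscore_cognition(df)
    hc = z[df["group"] == "HC"]
    assert np.allclose(hc.mean(), 0.0, atol=1e-12)
    assert np.allclose(hc.std(ddof=1), 1.0, atol=1e-12)


def test_time_based_tests_are_inverted_after_standardization():
    """HC times mean 50 SD 10; a 70-second TMT-A gives z = 2, inverted to -2."""
    hc_times = np.array([40.0, 45, 50, 55, 60.0])
    assert hc_times.std(ddof=1) != 10  # construct exact moments instead
    hc_times = 50 + 10 * (hc_times - hc_times.mean()) / hc_times.std(ddof=1)
    df = pd.DataFrame(
        {"group": ["HC"] * 5 + ["CSVD-NCI"], "tmt_a": np.append(hc_times, 70.0)}
    )
    z = zscore_cognition(df, domain_tests={"processing_speed": "tmt_a"})
    assert z["z_processing_speed"].iloc[-1] == pytest.approx(-2.0)


def test_constant_reference_scores_rejected():
    df = pd.DataFrame({"group": ["HC"] * 4, "avlt": [30.0] * 4})
    with pytest.raises(ValueError, match="avlt"):
        zscore_cognition(df, domain_tests={"memory": "avlt"})


# ---------------------------------------------------------------------------
# group comparisons


def test_chi_square_reproduces_printed_demographics():
    """2x2 chi-square on 19/40 vs 61/120 males gives p = 0.7150; the
    hypertension split 14/40 vs 78/120 gives chi2 ~ 11.05, p < 0.001."""
    sex = np.array([1] * 19 + [0] * 21 + [1] * 61 + [0] * 59)
    grp = np.array(["HC"] * 40 + ["CSVD"] * 120)
    res = group_compare(sex, grp, kind="categorical")
    assert round(res.p, 4) == 0.7150
    htn = np.array([1] * 14 + [0] * 26 + [1] * 78 + [0] * 42)
    res = group_compare(htn, grp, kind="categorical")
    assert res.statistic == pytest.approx(11.05, abs=0.01)
    assert res.p < 0.001


def test_percent_summaries_match_printed_precision():
    assert count_percent(61, 120) == 50.83
    assert count_percent(78, 120) == 65.00
    assert count_percent(19, 40) == 47.50


def test_identical_groups_give_null_result():
    vals = np.tile([5.0], 30)
    grp = np.repeat(["a", "b", "c"], 10)
    res = group_compare(vals, grp)
    assert res.statistic == 0.0 and res.p == 1.0
    assert all(p == 1.0 for p in res.pairwise_p.values())


def test_branching_normal_vs_skewed():
    rng = np.random.default_rng(0)
    grp = np.repeat(["a", "b", "c"], 40)
    normal = rng.normal(0, 1, 120)
    assert group_compare(normal, grp).test == "anova"
    skewed = rng.exponential(1, 120) ** 3
    assert group_compare(skewed, grp).test == "kruskal"


def test_single_valued_categorical_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        group_compare(np.zeros(20), np.repeat(["a", "b"], 10), kind="categorical")


# ---------------------------------------------------------------------------
# partial correlation


def test_k0_partial_correlation_is_pearson():
    rng = np.random.default_rng(2)
    x, y = rng.normal(size=40), rng.normal(size=40)
    res = partial_correlation(x, y)
    r, p = sps.pearsonr(x, y)
    assert res.r == pytest.approx(r, abs=1e-12)
    assert res.p == pytest.approx(p, rel=1e-9)


def test_perfect_dependence_gives_r_one():
    rng = np.random.default_rng(3)
    x = rng.normal(size=30)
    Z = rng.normal(size=(30, 2))
    assert partial_correlation(x, x.copy(), Z).r == pytest.approx(1.0)


@pytest.mark.parametrize("k", [1, 2, 3, 4, 5])
def test_partial_correlation_matches_matrix_inverse_oracle(k):
    rng = np.random.default_rng(100 + k)
    for _ in range(20):
        Z = rng.normal(size=(50, k))
        x = Z @ rng.normal(size=k) + rng.normal(size=50)
        y = Z @ rng.normal(size=k) + 0.3 * x + rng.normal(size=50)
        res = partial_correlation(x, y, Z)
        assert abs(res.r - _partial_r_oracle(x, y, Z)) < 1e-12


def test_rank_deficient_covariates_rejected():
    rng = np.random.default_rng(4)
    z = rng.normal(size=30)
    Z = np.column_stack([z, 2 * z])
    with pytest.raises(ValueError, match="rank"):
        partial_correlation(rng.normal(size=30), rng.normal(size=30), Z)


# ---------------------------------------------------------------------------
# FDR


def test_bh_hand_example_and_edge_cases():
    q = fdr_adjust([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(q, 0.04)
    assert fdr_adjust([0.37])[0] == pytest.approx(0.37)
    assert np.allclose(fdr_adjust([0.2, 0.2, 0.2]), 0.2)


def test_bh_matches_longhand_oracle_on_random_vectors():
    rng = np.random.default_rng(5)
    for _ in range(50):
        p = rng.random(rng.integers(1, 40))
        assert np.allclose(fdr_adjust(p), _bh_oracle(p), atol=1e-12)


def test_fdr_families_are_independent():
    p = np.array([0.01, 0.04, 0.01, 0.04])
    fam = np.array(["a", "a", "b", "b"])
    q = fdr_adjust(p, fam)
    assert np.allclose(q[:2], _bh_oracle(p[:2]))
    assert np.allclose(q[2:], _bh_oracle(p[2:]))


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
def test_bh_q_dominates_p_and_is_bounded(pvals):
    q = fdr_adjust(pvals)
    assert np.all(q >= np.asarray(pvals) - 1e-15)
    assert np.all(q <= 1.0 + 1e-15)


def test_out_of_range_p_rejected():
    with pytest.raises(ValueError):
        fdr_adjust([0.5, 1.5])


# ---------------------------------------------------------------------------
# ICC


def test_duplicate_ratings_give_perfect_agreement():
    r = np.tile(np.arange(10.0)[:, None], (1, 2))
    res = icc_absolute_agreement(r)
    assert res.icc == pytest.approx(1.0)


def test_independent_raters_give_near_zero_icc():
    rng = np.random.default_rng(6)
    vals = [icc_absolute_agreement(rng.normal(size=(200, 2))).icc for _ in range(10)]
    assert abs(np.mean(vals)) < 0.1


def test_icc_matches_longhand_mean_squares_oracle():
    r = np.array(
        [[9.0, 2.0], [1.0, 1.0], [8.0, 4.0], [2.0, 1.0], [10.0, 5.0], [6.0, 6.0]]
    )
    res = icc_absolute_agreement(r)
    assert abs(res.icc - _icc_a1_oracle(r)) < 1e-10
    rng = np.random.default_rng(7)
    r2 = rng.normal(size=(12, 3)) + rng.normal(size=(12, 1))
    assert abs(icc_absolute_agreement(r2).icc - _icc_a1_oracle(r2)) < 1e-10


def test_icc_recovers_variance_components():
    """Data with subject variance s2 and error e2 has ICC ~ s2/(s2+e2)."""
    rng = np.random.default_rng(8)
    s2, e2 = 1.0, 0.5
    subj = rng.normal(0, np.sqrt(s2), (500, 1))
    ratings = subj + rng.normal(0, np.sqrt(e2), (500, 2))
    res = icc_absolute_agreement(ratings)
    assert res.icc == pytest.approx(s2 / (s2 + e2), abs=0.05)
    assert res.ci_low <= res.icc <= res.ci_high


def test_icc_and_partial_corr_match_pingouin():
    """Independent library route: pingouin's ICC(A,1) and partial_corr."""
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(20)
    ratings = rng.normal(size=(30, 1)) + rng.normal(0, 0.4, size=(30, 3))
    mine = icc_absolute_agreement(ratings)
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(30), 3),
            "rater": np.tile(np.arange(3), 30),
            "score": ratings.ravel(),
        }
    )
    theirs = pg.intraclass_corr(long, "subject", "rater", "score")
    icc_a1 = theirs.loc[theirs["Type"] == "ICC(A,1)", "ICC"].iloc[0]
    assert mine.icc == pytest.approx(icc_a1, abs=1e-10)

    x = rng.normal(size=60)
    Z = rng.normal(size=(60, 3))
    y = 0.4 * x + Z @ [0.2, -0.1, 0.3] + rng.normal(size=60)
    res = partial_correlation(x, y, Z)
    df = pd.DataFrame(np.column_stack([x, y, Z]), columns=["x", "y", "a", "b", "c"])
    pp = pg.partial_corr(df, "x", "y", covar=["a", "b", "c"])
    assert res.r == pytest.approx(pp["r"].iloc[0], abs=1e-10)


def test_icc_shape_requirements():
    with pytest.raises(ValueError, match="raters"):
        icc_absolute_agreement(np.ones((10, 1)))
    with pytest.raises(ValueError, match="subjects"):
        icc_absolute_agreement(np.ones((3, 2)))
    bad = np.ones((6, 2))
    bad[0, 0] = np.nan
    with pytest.raises(ValueError, match="missing"):
        icc_absolute_agreement(bad)


# ---------------------------------------------------------------------------
# mediation


def _orthogonal_mediation_frame():
    """M = 0.5X + d with d orthogonal to [1, X]: all paths identifiable and
    exact despite zero residual noise in Y."""
    x = np.tile([-1.0, 0.0, 1.0], 4)
    d = np.tile([1.0, -2.0, 1.0], 4)
    m = 0.5 * x + d
    y = 0.3 * x + 0.4 * m
    return pd.DataFrame({"x": x, "m": m, "y": y})


def test_deterministic_linear_identity():
    res = mediate(_orthogonal_mediation_frame(), "x", "m", "y", n_boot=50, seed=0)
    assert res.a == pytest.approx(0.5, abs=1e-12)
    assert res.b == pytest.approx(0.4, abs=1e-12)
    assert res.c_prime == pytest.approx(0.3, abs=1e-12)
    assert res.indirect == pytest.approx(0.2, abs=1e-12)
    assert res.c == pytest.approx(0.5, abs=1e-12)
    assert res.mediation_percent == pytest.approx(40.0, abs=1e-9)


def test_ols_identity_c_equals_cprime_plus_ab_on_random_data():
    rng = np.random.default_rng(9)
    for _ in range(10):
        n = 60
        Z = rng.normal(size=(n, 2))
        x = rng.normal(size=n)
        m = 0.4 * x + Z @ [0.2, -0.3] + rng.normal(size=n)
        y = 0.5 * m - 0.2 * x + Z @ [0.1, 0.4] + rng.normal(size=n)
        df = pd.DataFrame({"x": x, "m": m, "y": y, "z1": Z[:, 0], "z2": Z[:, 1]})
        res = mediate(df, "x", "m", "y", covariates=("z1", "z2"), n_boot=20, seed=0)
        assert abs(res.c - (res.c_prime + res.indirect)) < 1e-10


def test_bootstrap_is_seed_reproducible_and_brackets_estimate():
    rng = np.random.default_rng(10)
    n = 150
    x = rng.normal(size=n)
    m = 0.5 * x + rng.normal(size=n)
    y = 0.4 * m + 0.1 * x + rng.normal(size=n)
    df = pd.DataFrame({"x": x, "m": m, "y": y})
    r1 = mediate(df, "x", "m", "y", n_boot=500, seed=3)
    r2 = mediate(df, "x", "m", "y", n_boot=500, seed=3)
    assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)
    assert r1.ci_low <= r1.indirect <= r1.ci_high
    assert r1.significant


def test_ci_width_shrinks_with_sample_size():
    rng = np.random.default_rng(11)
    widths = []
    for n in (100, 400, 1600):
        x = rng.normal(size=n)
        m = 0.5 * x + rng.normal(size=n)
        y = 0.4 * m + 0.1 * x + rng.normal(size=n)
        df = pd.DataFrame({"x": x, "m": m, "y": y})
        r = mediate(df, "x", "m", "y", n_boot=400, seed=0)
        widths.append(r.ci_high - r.ci_low)
    assert widths[0] > widths[1] > widths[2]
    assert widths[0] / widths[2] > 2.5  # ~ sqrt(16) = 4 in expectation


def test_inconsistent_mediation_percent_is_nan():
    rng = np.random.default_rng(12)
    n = 200
    x = rng.normal(size=n)
    m = 0.8 * x + rng.normal(size=n, scale=0.5)
    y = -1.0 * m + 1.2 * x + rng.normal(size=n, scale=0.1)  # opposite signs
    df = pd.DataFrame({"x": x, "m": m, "y": y})
    res = mediate(df, "x", "m", "y", n_boot=50, seed=0)
    assert np.sign(res.indirect) != np.sign(res.c)
    assert np.isnan(res.mediation_percent)


def test_collinear_mediator_rejected():
    x = np.linspace(0, 1, 20)
    df = pd.DataFrame({"x": x, "m": 2 * x, "y": x + 1})
    with pytest.raises(ValueError, match="collinear"):
        mediate(df, "x", "m", "y", n_boot=10, seed=0)
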