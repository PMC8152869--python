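"""Tensor metrics, aggregation, permutation testing, FDR, partial correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from thalparc.micro import (
    aggregate_fixel_metric,
    aggregate_metric,
    fdr_bh,
    group_permutation_test,
    partial_correlation,
    tensor_metrics,
)


# ------------------------------------------------------------ tensor metrics


def test_tensor_metrics_isotropic():
    m = tensor_metrics(np.array([1.0, 1.0, 1.0]))
    assert m["FA"] == pytest.approx(0.0)
    assert m["MD"] == pytest.approx(1.0)
    assert m["AD"] == pytest.approx(1.0)
    assert m["RD"] == pytest.approx(1.0)


def test_tensor_metrics_stick_limit():
    m = tensor_metrics(np.array([1.0, 0.0, 0.0]))
    assert m["FA"] == pytest.approx(1.0)
    assert m["MD"] == pytest.approx(1 / 3)
    assert m["AD"] == pytest.approx(1.0)
    assert m["RD"] == pytest.approx(0.0)


def test_tensor_metrics_hand_evaluated():
    lam = np.array([1.7, 0.3, 0.3]) * 1e-3
    md = lam.mean()
    fa_expected = np.sqrt(1.5) * np.linalg.norm(lam - md) / np.linalg.norm(lam)
    m = tensor_metrics(lam)
    assert m["FA"] == pytest.approx(fa_expected, rel=1e-12)
    assert m["MD"] == pytest.approx(md)
    assert m["RD"] == pytest.approx(0.3e-3)


def test_tensor_metrics_zero_eigenvalues_fa_zero():
    m = tensor_metrics(np.zeros(3))
    assert m["FA"] == 0.0 and m["MD"] == 0.0


def test_tensor_metrics_reject_invalid():
    with pytest.raises(ValueError):
        tensor_metrics(np.array([1.0, -0.1, 0.2]))
    with pytest.raises(ValueError):
        tensor_metrics(np.array([0.1, 0.5, 0.2]))  # unsorted


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    lam=st.lists(st.floats(1e-6, 10.0), min_size=3, max_size=3),
    c=st.floats(0.01, 100.0),
)
def test_fa_scale_invariant(lam, c):
    lam = np.sort(np.asarray(lam))[::-1]
    a = tensor_metrics(lam)["FA"]
    b = tensor_metrics(c * lam)["FA"]
    assert a == pytest.approx(b, rel=1e-9, abs=1e-12)
    assert 0.0 <= a <= 1.0 + 1e-12


# -------------------------------------------------------------- aggregation


def test_aggregate_matches_brute_force(rng):
    vals = rng.normal(size=(6, 5, 4))
    region = rng.random((6, 5, 4)) < 0.3
    region[0, 0, 0] = True
    assert aggregate_metric(vals, region) == pytest.approx(vals[region].mean(), abs=1e-12)
    assert aggregate_metric(np.full((3, 3, 3), 0.3), np.ones((3, 3, 3), bool)) == pytest.approx(0.3)


def test_aggregate_two_voxels():
    vals = np.array([[[0.2]], [[0.4]]])
    assert aggregate_metric(vals, np.ones((2, 1, 1), bool)) == pytest.approx(0.3)


def test_aggregate_empty_region_warns():
    with pytest.warns(UserWarning, match="empty region"):
        out = aggregate_metric(np.ones((2, 2, 2)), np.zeros((2, 2, 2), bool))
    assert np.isnan(out)


def test_aggregate_fixel_metric_equal_weights():
    from thalparc.fixels import Fixel

    z = np.array([0.0, 0.0, 1.0])
    lists = [[Fixel(z, 1.0), Fixel(z, 3.0)], [], [Fixel(z, 2.0)], None]
    assert aggregate_fixel_metric(lists, "fd") == pytest.approx(2.0)


# --------------------------------------------------------------------- FDR


def test_fdr_bh_hand_computed_step_up():
    p = np.array([0.01, 0.02, 0.03, 0.04, 0.5])
    adj, flags = fdr_bh(p, q=0.05)
    assert flags.tolist() == [True, True, True, True, False]
    np.testing.assert_allclose(adj, [0.05, 0.05, 0.05, 0.05, 0.5])


def test_fdr_bh_all_small_and_single():
    adj, flags = fdr_bh(np.full(10, 0.001))
    assert flags.all()
    adj1, flags1 = fdr_bh(np.array([0.049]))
    assert adj1[0] == pytest.approx(0.049) and flags1[0]


def test_fdr_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        fdr_bh(np.array([0.1, 1.2]))
    with pytest.raises(ValueError):
        fdr_bh(np.array([-0.1]))


def test_fdr_bh_matches_statsmodels_fuzz(rng):
    """Exact agreement with the independent BH implementation."""
    from statsmodels.stats.multitest import multipletests

    for _ in range(300):
        m = rng.integers(1, 40)
        p = rng.random(m)
        adj, flags = fdr_bh(p, q=0.05)
        ref_flags, ref_adj, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        np.testing.assert_allclose(adj, ref_adj, rtol=0, atol=1e-12)
        assert np.array_equal(flags, ref_flags)


# --------------------------------------------------- partial correlation


def test_partial_correlation_no_covariates_is_pearson(rng):
    from scipy import stats

    x, y = rng.normal(size=(2, 15))
    r, p = partial_correlation(x, y)
    ref = stats.pearsonr(x, y)
    assert r == pytest.approx(ref.statistic, rel=1e-10)


def test_partial_correlation_perfect_dependence(rng):
    x = rng.normal(size=12)
    cov = rng.normal(size=12)
    r, p = partial_correlation(x, x.copy(), cov)
    assert r == pytest.approx(1.0)
    assert p < 1e-10


def test_partial_correlation_textbook_recursion(rng):
    """r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))."""
    from scipy import stats

    x = np.array([2.0, 4.0, 6.0, 7.0, 9.0, 10.0, 12.0, 15.0])
    z = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 7.0, 6.0, 8.0])
    y = np.array([1.0, 2.0, 4.0, 4.0, 6.0, 8.0, 9.0, 11.0])
    rxy = stats.pearsonr(x, y).statistic
    rxz = stats.pearsonr(x, z).statistic
    ryz = stats.pearsonr(y, z).statistic
    expected = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
    r, _ = partial_correlation(x, y, z)
    assert r == pytest.approx(expected, rel=1e-10)


def test_partial_correlation_matches_pingouin(rng):
    pingouin = pytest.importorskip("pingouin")
    df = pd.DataFrame(
        {
            "x": rng.normal(size=20),
            "y": rng.normal(size=20),
            "c1": rng.normal(size=20),
            "c2": rng.normal(size=20),
        }
    )
    df["y"] += 0.5 * df["x"]
    ref = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
    r, p = partial_correlation(
        df["x"].to_numpy(), df["y"].to_numpy(), df[["c1", "c2"]].to_numpy()
    )
    assert r == pytest.approx(float(ref["r"].iloc[0]), rel=1e-6)
    assert p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)


def test_partial_correlation_errors(rng):
    with pytest.raises(ValueError, match="too small"):
        partial_correlation(np.ones(3), np.ones(3), rng.normal(size=(3, 2)))
    x = rng.normal(size=10)
    with pytest.raises(ValueError, match="zero residual"):
        partial_correlation(x, np.full(10, 2.0))


# ------------------------------------------------- group permutation test


def _table(rng, n, cols=4, effect=0.0, groups=None):
    data = rng.normal(size=(n, cols))
    if groups is not None and effect:
        data[groups == "B", 0] += effect
    return pd.DataFrame(
        data, columns=[f"region{i}|FD" for i in range(cols)],
        index=[f"s{i}" for i in range(n)],
    )


def test_group_permutation_test_detects_planted_shift(rng):
    groups = np.array(["A"] * 10 + ["B"] * 10)
    tab = _table(rng, 20, effect=2.5, groups=groups)
    covs = rng.normal(size=(20, 2))
    res = group_permutation_test(tab, groups, covariates=covs, n_perm=500, seed=0)
    row0 = res.table.iloc[0]
    assert row0["p"] < 0.01 and row0["significant"]
    assert res.table.iloc[1:]["p"].min() > 0.01


def test_group_permutation_test_deterministic(rng):
    groups = np.array(["A"] * 6 + ["B"] * 6)
    tab = _table(rng, 12)
    a = group_permutation_test(tab, groups, n_perm=200, seed=5)
    b = group_permutation_test(tab, groups, n_perm=200, seed=5)
    pd.testing.assert_frame_equal(a.table, b.table)


def test_group_permutation_test_constant_column(rng):
    groups = np.array(["A"] * 5 + ["B"] * 5)
    tab = _table(rng, 10)
    tab["region0|FD"] = 1.0
    res = group_permutation_test(tab, groups, n_perm=100, seed=0)
    row = res.table[res.table.region == "region0"].iloc[0]
    assert row["p"] == 1.0 and not row["significant"]


def test_group_permutation_test_requires_two_groups(rng):
    tab = _table(rng, 6)
    with pytest.raises(ValueError):
        group_permutation_test(tab, np.array(["A"] * 6), n_perm=10)
    with pytest.raises(ValueError):
        group_permutation_test(tab, np.array(["A", "A", "B", "B", "B", "B"]), n_perm=10)


def test_residualization_idempotent(rng):
    from thalparc.micro import _residualize

    y = rng.normal(size=20)
    cov = rng.normal(size=(20, 3))
    once = _residualize(y, cov)
    twice = _residualize(once, cov)
    np.testing.assert_allclose(once, twice, atol=1e-10)


def test_group_permutation_null_calibration(rng):
    """Exchangeable groups are rejected at ~ the nominal rate."""
    alpha, hits, n_sim = 0.05, 0, 300
    groups = np.array(["A"] * 8 + ["B"] * 8)
    for i in range(n_sim):
        tab = _table(rng, 16, cols=1)
        covs = rng.normal(size=(16, 2))
        res = group_permutation_test(tab, groups, covariates=covs, n_perm=199, seed=i)
        hits += res.table["p"].iloc[0] <= alpha
    se = np.sqrt(alpha * (1 - alpha) / n_sim)
    assert abs(hits / n_sim - alpha) <= 3 * se
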