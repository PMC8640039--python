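"""Fold change, group tests, NIPALS PLS-DA VIP, classification, trends."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from sbmie import (
    FeatureTable,
    RunConfig,
    SampleMetadata,
    assign_trend_profiles,
    classify_differential,
    differential_table,
    group_test,
    log2_fold_change,
    plsda_vip,
)
from sbmie.differential import DifferentialRecord

import pandas as pd


# ---------------------------------------------------------------- log2FC


@pytest.mark.parametrize(
    "control, treatment, expected",
    [
        ([2, 2], [8, 8], 2.0),
        ([5, 5, 5], [5, 5, 5], 0.0),
        ([1, 3], [2, 6], 1.0),
    ],
)
def test_log2_fold_change_examples(control, treatment, expected):
    assert log2_fold_change(control, treatment) == pytest.approx(expected)


def test_log2fc_zero_control_needs_pseudo_mean():
    with pytest.raises(ValueError):
        log2_fold_change([0, 0], [1, 2])
    assert log2_fold_change([0, 0], [4, 4], pseudo_mean=1.0) == 2.0


@given(
    st.lists(st.floats(0.5, 100), min_size=2, max_size=8),
    st.lists(st.floats(0.5, 100), min_size=2, max_size=8),
)
def test_log2fc_antisymmetric(a, b):
    assert log2_fold_change(a, b) == pytest.approx(-log2_fold_change(b, a))


# ---------------------------------------------------------------- group tests


def test_identical_groups_p_is_one():
    assert group_test([1, 1, 1], [1, 1, 1], "welch_t") == 1.0
    assert group_test([1, 2, 3], [1, 2, 3], "wilcoxon") == 1.0


def test_welch_on_separated_groups_is_significant():
    assert group_test([1, 1, 1], [100, 100, 101], "welch_t") < 0.01


def test_wilcoxon_fully_separated_exact_p():
    # 4 vs 4 with all ranks separated: the two extreme orderings of C(8,4)=70
    p = group_test([1, 2, 3, 4], [10, 11, 12, 13], "wilcoxon")
    assert p == pytest.approx(2 / 70)


def test_zero_variance_equal_means_convention():
    assert group_test([2, 2], [2, 2], "welch_t") == 1.0


# ---------------------------------------------------------------- PLS-DA VIP


def _binary_design(n=20, p=6, seed=0, informative=0, effect=3.0):
    rng = np.random.default_rng(seed)
    y = np.r_[np.zeros(n // 2), np.ones(n - n // 2)]
    X = rng.normal(size=(n, p))
    if informative:
        X[:, :informative] += effect * y[:, None]
    return X, y


def test_single_feature_vip_is_one():
    X, y = _binary_design(p=1, informative=1)
    assert plsda_vip(X, y, n_components=1) == pytest.approx([1.0])


@pytest.mark.parametrize("seed", range(5))
def test_mean_squared_vip_is_one(seed):
    X, y = _binary_design(p=8, seed=seed, informative=2)
    vip = plsda_vip(X, y, n_components=2)
    assert np.mean(vip**2) == pytest.approx(1.0, rel=1e-9)


def test_informative_feature_outranks_noise():
    X, y = _binary_design(p=2, informative=1, effect=5.0)
    vip = plsda_vip(X, y, n_components=1)
    assert vip[0] > 1.0 > vip[1]


def _sklearn_vip(X, y, n_components):
    """Independent VIP oracle from scikit-learn's PLS implementation."""
    from sklearn.cross_decomposition import PLSRegression

    pls = PLSRegression(n_components=n_components, scale=True).fit(X, y)
    W = pls.x_weights_  # unit-norm columns
    ss = pls.y_loadings_[0] ** 2 * np.sum(pls.x_scores_**2, axis=0)
    return np.sqrt(X.shape[1] * (W**2 @ ss) / ss.sum())


@pytest.mark.parametrize("seed", range(10))
@pytest.mark.parametrize("n_components", [1, 2])
def test_vip_matches_independent_pls_oracle(seed, n_components):
    X, y = _binary_design(n=20, p=10, seed=seed, informative=3, effect=2.0)
    mine = plsda_vip(X, y, n_components=n_components)
    oracle = _sklearn_vip(X, y, n_components=n_components)
    np.testing.assert_allclose(mine, oracle, atol=1e-8)


def test_constant_feature_warned_and_vip_zero():
    X, y = _binary_design(p=4, informative=1)
    X[:, 2] = 7.0
    with pytest.warns(UserWarning, match="constant"):
        vip = plsda_vip(X, y, n_components=1)
    assert vip[2] == 0.0
    assert np.sum(vip**2) == pytest.approx(3.0)  # over the included features


def test_excess_components_reduced_with_warning():
    X, y = _binary_design(n=6, p=3, informative=1)
    with pytest.warns(UserWarning, match="reduced"):
        plsda_vip(X, y, n_components=10)


# ---------------------------------------------------------------- classify


@pytest.mark.parametrize(
    "mode, lfc, p, vip, expected",
    [
        ("deg", 1.5, 0.01, np.nan, "up"),
        ("deg", 0.5, 0.01, np.nan, "none"),
        ("deg", -1.5, 0.2, np.nan, "none"),
        ("metabolite", 0.3, 0.04, 1.2, "up"),
        ("metabolite", -0.3, 0.04, 1.2, "down"),
        ("metabolite", 0.3, 0.04, 0.8, "none"),
        ("metabolite", 0.3, 0.06, 1.2, "none"),
    ],
)
def test_classification_rules(mode, lfc, p, vip, expected):
    rec = DifferentialRecord("f", 1.0, 2.0, lfc, p, vip=vip)
    classify_differential([rec], mode=mode)
    assert rec.trend == expected
    assert rec.significant is (expected != "none")


def test_swapping_groups_flips_trend(small_table):
    table, meta = small_table
    fwd = differential_table(table, meta, "FM", "SBM40")
    rev = differential_table(table, meta, "SBM40", "FM")
    for a, b in zip(fwd, rev):
        assert a.log2fc == pytest.approx(-b.log2fc)
        assert a.p_value == pytest.approx(b.p_value)


# ---------------------------------------------------------------- trends


def _ladder_table(means, n=4, noise=0.01, seed=0):
    rng = np.random.default_rng(seed)
    groups = ["FM", "SBM20", "SBM40"]
    cols, gcol = [], []
    values = []
    for g, mu in zip(groups, means):
        for i in range(n):
            cols.append(f"{g}.content.{i}")
            gcol.append(g)
    row = np.concatenate(
        [rng.normal(mu, noise, size=n) for mu in means]
    )
    data = pd.DataFrame([row], index=["f0"], columns=cols)
    meta = pd.DataFrame(
        {"sample_id": cols, "group": gcol, "compartment": "content", "ion_mode": "positive"}
    ).set_index("sample_id")
    return FeatureTable(data), SampleMetadata(meta)


@pytest.mark.parametrize(
    "means, expected",
    [((1.0, 2.0, 3.0), "A"), ((3.0, 2.0, 1.0), "B"), ((1.0, 3.0, 2.0), "none")],
)
def test_trend_profiles(means, expected):
    table, meta = _ladder_table(means)
    [profile] = assign_trend_profiles(table, meta)
    assert profile.profile == expected


def test_trend_profile_requires_significance():
    table, meta = _ladder_table((10.0, 10.001, 10.002), noise=1.0)
    [profile] = assign_trend_profiles(table, meta)
    assert profile.profile == "none" or profile.p_value < 0.05


def test_trend_needs_three_levels():
    table, meta = _ladder_table((1.0, 2.0, 3.0))
    meta2 = SampleMetadata(
        meta.table[meta.table["group"] != "SBM20"], group_ladder=("FM", "SBM40")
    )
    with pytest.raises(ValueError):
        assign_trend_profiles(table, meta2)
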