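"""Biomarker screening: VIP ranking, mode merge, core panels, ROC, z, corr."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from sbmie import (
    correlation_matrix,
    intersect_levels,
    merge_modes,
    roc_auc,
    top_vip,
    zscore_vs_control,
)
from sbmie.differential import DifferentialRecord
from sbmie.reference_panels import PANEL_BY_LEVEL, TOP10_VIP


def _rec(fid, vip, p=0.01, sig=True):
    return DifferentialRecord(fid, 1, 2, 1.0, p, vip=vip, significant=sig)


# ---------------------------------------------------------------- top_vip


def test_top_vip_single_max():
    recs = [_rec("a", 1.1), _rec("b", 3.0), _rec("c", 2.0)]
    assert top_vip(recs, k=1) == ["b"]


def test_top_vip_tie_broken_by_smaller_p():
    recs = [_rec("a", 2.0, p=0.04), _rec("b", 2.0, p=0.01)]
    assert top_vip(recs, k=2) == ["b", "a"]


def test_top_vip_ignores_non_significant_and_warns_when_short():
    recs = [_rec("a", 5.0, sig=False), _rec("b", 1.0)]
    with pytest.warns(UserWarning, match="only 1"):
        assert top_vip(recs, k=10) == ["b"]


# ------------------------------------------------------- published worked example


def test_published_lists_merge_to_17_with_3_cross_mode_duplicates():
    """Each substitution level's positive+negative top-10 lists merge to 17
    named biomarkers with exactly 3 detected in both ion modes."""
    merged20, co20 = merge_modes(
        TOP10_VIP[("SBM20", "positive")], TOP10_VIP[("SBM20", "negative")]
    )
    assert len(merged20) == 17
    assert co20 == {"Glycitein", "Daidzein", "Glycitin"}
    merged40, co40 = merge_modes(
        TOP10_VIP[("SBM40", "positive")], TOP10_VIP[("SBM40", "negative")]
    )
    assert len(merged40) == 17 and len(co40) == 3


def test_published_panels_intersect_to_14_core_biomarkers():
    core = intersect_levels({k: set(v) for k, v in PANEL_BY_LEVEL.items()})
    assert len(core.core) == 14
    assert core.specific_per_level["SBM20"] == {
        "Byakangelicol", "3,4-dihydroxyphenylacetic acid", "Baicalin",
    }
    assert core.specific_per_level["SBM40"] == {
        "Cys-Tyr", "Indole-3-butyric acid", "3-Methoxyflavone",
    }


def test_merge_modes_disjoint_and_identical():
    merged, co = merge_modes([f"p{i}" for i in range(10)], [f"n{i}" for i in range(10)])
    assert len(merged) == 20 and co == set()
    same = [f"m{i}" for i in range(10)]
    merged, co = merge_modes(same, same)
    assert len(merged) == 10 and len(co) == 10


def test_merge_size_identity():
    pos, neg = ["a", "b", "c"], ["b", "c", "d", "e"]
    merged, co = merge_modes(pos, neg)
    assert len(merged) + len(co) == len(pos) + len(neg)


def test_intersect_identical_and_disjoint_panels():
    panel = {"m1", "m2"}
    core = intersect_levels({"L1": set(panel), "L2": set(panel)})
    assert core.core == panel
    assert all(not s for s in core.specific_per_level.values())
    core = intersect_levels({"L1": {"a"}, "L2": {"b"}})
    assert core.core == set()


# ---------------------------------------------------------------- z-scores


def test_zscore_examples():
    control = [1.0, 2.0, 3.0]  # mean 2, sd 1
    assert zscore_vs_control([2.0], control) == pytest.approx([0.0])
    assert zscore_vs_control([4.0], control) == pytest.approx([2.0])
    assert zscore_vs_control(np.arange(7.0), control).shape == (7,)


def test_zscore_zero_control_sd_errors():
    with pytest.raises(ValueError):
        zscore_vs_control([1.0], [2.0, 2.0, 2.0])


# ---------------------------------------------------------------- ROC / AUC


def test_auc_perfect_separation():
    assert roc_auc([10, 11], [1, 2]).auc == 1.0


def test_auc_all_ties():
    res = roc_auc([5, 5, 5], [5, 5, 5])
    assert res.auc == 0.5


def test_auc_hand_enumerated_example():
    res = roc_auc([3, 5], [1, 2, 4])
    assert res.auc == pytest.approx(5 / 6)
    assert res.orientation == "case_high"


def test_auc_auto_orientation():
    res = roc_auc([1, 2], [10, 11])
    assert res.auc == 1.0 and res.orientation == "case_low"


def _auc_brute_force(case, ctrl):
    wins = sum(
        1.0 if c > k else 0.5 if c == k else 0.0
        for c, k in itertools.product(case, ctrl)
    )
    return wins / (len(case) * len(ctrl))


@given(
    st.lists(st.integers(0, 6), min_size=1, max_size=8),
    st.lists(st.integers(0, 6), min_size=1, max_size=8),
)
def test_auc_equals_pairwise_enumeration(case, ctrl):
    """Rank-based AUC equals the exhaustive pairwise win-count oracle,
    including heavy ties, for all small instances."""
    expected = _auc_brute_force(case, ctrl)
    expected = max(expected, 1 - expected)  # auto-orientation
    assert roc_auc(case, ctrl).auc == pytest.approx(expected, abs=1e-12)


@given(st.lists(st.floats(0.1, 50), min_size=2, max_size=8, unique=True).map(sorted))
def test_auc_invariant_under_monotone_transform(values):
    case, ctrl = values[: len(values) // 2], values[len(values) // 2 :]
    if not case or not ctrl:
        return
    base = roc_auc(case, ctrl).auc
    logged = roc_auc(np.log(case), np.log(ctrl)).auc
    cubed = roc_auc(np.power(case, 3), np.power(ctrl, 3)).auc
    assert base == pytest.approx(logged) == pytest.approx(cubed)


def test_auc_empty_class_errors():
    with pytest.raises(ValueError):
        roc_auc([], [1.0])


# ---------------------------------------------------------------- correlation


def _panel(rows, ids=None):
    rows = np.atleast_2d(rows)
    ids = ids or [f"f{i}" for i in range(rows.shape[0])]
    return pd.DataFrame(rows, index=ids)


def test_correlation_self_is_one_unmasked():
    rng = np.random.default_rng(0)
    cm = correlation_matrix(_panel(rng.normal(size=(3, 6))))
    assert np.allclose(np.diag(cm.r), 1.0)
    assert not np.diag(cm.mask).any()


def test_perfect_anticorrelation():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    cm = correlation_matrix(_panel([x, -x]))
    assert cm.r.iloc[0, 1] == pytest.approx(-1.0)
    assert not cm.mask.iloc[0, 1]


def test_correlation_matches_brute_force_covariance():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = np.array([2.0, 4.0, 6.0, 8.1])
    cm = correlation_matrix(_panel([x, y]))
    num = np.sum((x - x.mean()) * (y - y.mean()))
    den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
    assert cm.r.iloc[0, 1] == pytest.approx(num / den, abs=1e-12)


def test_nonsignificant_pairs_masked():
    rng = np.random.default_rng(1)
    cm = correlation_matrix(_panel(rng.normal(size=(2, 5))), alpha=1e-6)
    assert cm.mask.iloc[0, 1]  # noise cannot reach p < 1e-6 with n=5


def test_constant_feature_masked_with_warning():
    with pytest.warns(UserWarning, match="constant"):
        cm = correlation_matrix(_panel([[1, 2, 3, 4], [5, 5, 5, 5]]))
    assert cm.mask.iloc[0, 1] and cm.mask.iloc[1, 0]


def test_correlation_matrix_positive_semidefinite():
    rng = np.random.default_rng(2)
    cm = correlation_matrix(_panel(rng.normal(size=(5, 30))))
    eigvals = np.linalg.eigvalsh(cm.r.to_numpy())
    assert eigvals.min() > -1e-10


def test_too_few_samples_errors():
    with pytest.raises(ValueError):
        correlation_matrix(_panel([[1.0, 2.0]]))
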