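"""Content/tissue exchange classification and representative ranking."""

import math

import pytest

from sbmie import (
    RunConfig,
    classify_differential,
    differential_table,
    exchange_classify,
    rank_representatives,
)
from sbmie.differential import DifferentialRecord
from sbmie.exchange import ExchangeRecord


def _rec(fid, lfc, p, sig=None):
    return DifferentialRecord(fid, 1.0, 2.0, lfc, p, significant=sig)


def test_docosahexaenoic_acid_row_classifies_content_up_tissue_down():
    content = [_rec("Docosahexaenoic acid", math.log2(583271866 / 430387933), 5.66e-05)]
    tissue = [_rec("Docosahexaenoic acid", math.log2(200036643 / 238785562), 0.047525)]
    records, counts = exchange_classify(content, tissue)
    assert records[0].exchange_class == "content_up_tissue_down"
    assert counts["content_up_tissue_down"] == 1


def test_cytosine_row_classifies_content_down_tissue_up():
    content = [_rec("Cytosine", math.log2(25886.01 / 74390.77), 0.002471)]
    tissue = [_rec("Cytosine", math.log2(4832.989 / 2765.373), 0.028388)]
    records, _ = exchange_classify(content, tissue)
    assert records[0].exchange_class == "content_down_tissue_up"


def test_same_sign_trends_are_not_exchanged():
    records, counts = exchange_classify([_rec("m", 1.0, 0.01)], [_rec("m", 2.0, 0.01)])
    assert records[0].exchange_class == "none"


def test_significance_required_in_both_compartments():
    records, _ = exchange_classify([_rec("m", 1.0, 0.01)], [_rec("m", -1.0, 0.2)])
    assert records[0].exchange_class == "none"


def test_upstream_significance_flag_overrides_raw_p():
    # a record may carry an upstream significance call (e.g. a published
    # trend call); the classifier honors it over the raw-P rule
    records, _ = exchange_classify(
        [_rec("m", 1.0, 0.01, sig=True)], [_rec("m", -1.0, 0.06, sig=True)]
    )
    assert records[0].exchange_class == "content_up_tissue_down"


def test_unmatched_features_are_skipped():
    records, counts = exchange_classify([_rec("a", 1.0, 0.01)], [_rec("b", -1.0, 0.01)])
    assert records == [] and sum(counts.values()) == 0


def test_swapping_compartments_mirrors_classes():
    content = [_rec("a", 1.0, 0.01), _rec("b", -2.0, 0.01), _rec("c", 1.0, 0.01)]
    tissue = [_rec("a", -1.0, 0.01), _rec("b", 0.5, 0.01), _rec("c", 2.0, 0.01)]
    fwd, fc = exchange_classify(content, tissue)
    rev, rc = exchange_classify(tissue, content)
    mirror = {
        "content_up_tissue_down": "content_down_tissue_up",
        "content_down_tissue_up": "content_up_tissue_down",
        "none": "none",
    }
    by_id = {r.feature_id: r for r in rev}
    for r in fwd:
        assert by_id[r.feature_id].exchange_class == mirror[r.exchange_class]
    assert fc["content_up_tissue_down"] == rc["content_down_tissue_up"]


def test_class_counts_sum_to_total_exchanged():
    content = [_rec(f"m{i}", (-1) ** i * 1.0, 0.01) for i in range(6)]
    tissue = [_rec(f"m{i}", (-1) ** (i + 1) * 1.0, 0.01) for i in range(6)]
    records, counts = exchange_classify(content, tissue)
    n_exchanged = sum(1 for r in records if r.exchange_class != "none")
    assert (
        counts["content_up_tissue_down"] + counts["content_down_tissue_up"]
        == n_exchanged == 6
    )


def _xrec(fid, cp, tp, clfc=1.0):
    return ExchangeRecord(fid, clfc, cp, -clfc, tp, "content_up_tissue_down")


def test_rank_by_min_p_with_lfc_tiebreak():
    a = _xrec("a", 0.001, 0.01)
    b = _xrec("b", 0.01, 0.001, clfc=2.0)
    ranked = rank_representatives([a, b], "content_up_tissue_down", k=2)
    assert [r.feature_id for r in ranked] == ["b", "a"]  # tie on min-p, |lfc| wins


def test_rank_k_larger_than_class():
    a = _xrec("a", 0.001, 0.01)
    assert rank_representatives([a], "content_up_tissue_down", k=10) == [a]
    assert rank_representatives([a], "content_down_tissue_up", k=10) == []


def test_planted_exchanged_features_recovered_exactly(planted_simulation):
    spec, res = planted_simulation
    cfg = RunConfig()

    def diff(comp):
        recs = differential_table(res.table(comp, "positive"), res.metadata, "FM", "SBM40", cfg)
        return classify_differential(recs)

    records, _ = exchange_classify(diff("content"), diff("tissue"))
    by_id = {r.feature_id: r.exchange_class for r in records}
    truth = res.truth.set_index("feature_id")["label"]
    planted_ud = truth.index[truth == "exchanged_up_down"]
    planted_du = truth.index[truth == "exchanged_down_up"]
    assert len(planted_ud) > 0 and len(planted_du) > 0
    for fid in planted_ud:
        assert by_id[fid] == "content_up_tissue_down"
    for fid in planted_du:
        assert by_id[fid] == "content_down_tissue_up"
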