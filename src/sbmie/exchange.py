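"""Inverse-correlation exchange analysis between gut contents and tissue.

A metabolite whose intensity moves significantly in opposite directions in
the intestinal contents and the intestinal tissue (up in contents while down
in tissue, or the reverse) is read as being exchanged across the gut wall.
The classifier considers only metabolites differential in BOTH compartments;
each gets one of the classes ``content_up_tissue_down``,
``content_down_tissue_up`` or ``none``.

A record counts as differential in a compartment if its ``significant`` flag
is set (an upstream classification or a published significance call);
records without a flag fall back to the raw-P rule p < alpha.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .differential import DifferentialRecord

__all__ = ["ExchangeRecord", "exchange_classify", "rank_representatives"]

CLASSES = ("content_up_tissue_down", "content_down_tissue_up", "none")


@dataclass
class ExchangeRecord:
    feature_id: str
    content_log2fc: float
    content_p: float
    tissue_log2fc: float
    tissue_p: float
    exchange_class: str


def _is_differential(record: DifferentialRecord, alpha: float) -> bool:
    if record.significant is not None:
        return bool(record.significant)
    return record.p_value < alpha


def exchange_classify(
    content_records: list[DifferentialRecord],
    tissue_records: list[DifferentialRecord],
    alpha: float = 0.05,
) -> tuple[list[ExchangeRecord], Counter]:
    """Classify co-contained metabolites by opposite content/tissue trends.

    Records are matched by feature id (the metabolite name in this pipeline);
    only metabolites present in both record sets are considered. Returns the
    records (matched metabolites only, input order of the content side) and
    the per-class counts.
    """
    tissue_by_id = {r.feature_id: r for r in tissue_records}
    out: list[ExchangeRecord] = []
    counts: Counter = Counter()
    for c in content_records:
        t = tissue_by_id.get(c.feature_id)
        if t is None:
            continue
        both_sig = _is_differential(c, alpha) and _is_differential(t, alpha)
        opposite = c.log2fc * t.log2fc < 0
        if both_sig and opposite:
            cls = (
                "content_up_tissue_down" if c.log2fc > 0 else "content_down_tissue_up"
            )
        else:
            cls = "none"
        counts[cls] += 1
        out.append(
            ExchangeRecord(
                feature_id=c.feature_id,
                content_log2fc=c.log2fc,
                content_p=c.p_value,
                tissue_log2fc=t.log2fc,
                tissue_p=t.p_value,
                exchange_class=cls,
            )
        )
    return out, counts


def rank_representatives(
    records: list[ExchangeRecord], exchange_class: str, k: int = 10
) -> list[ExchangeRecord]:
    """Top-k representatives of a class: min(content P, tissue P) ascending,
    ties by |content log2FC| descending, then feature id."""
    if exchange_class not in CLASSES:
        raise ValueError(f"unknown exchange class {exchange_class!r}")
    members = [r for r in records if r.exchange_class == exchange_class]
    members.sort(
        key=lambda r: (
            min(r.content_p, r.tissue_p),
            -abs(r.content_log2fc),
            r.feature_id,
        )
    )
    return members[:k]
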