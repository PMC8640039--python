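"""Diet-background filtration of content-differential metabolites.

Metabolites differential in the intestinal contents may simply reflect the
altered diet rather than the fish's physiological response. The filter takes
the Venn partition of diet-differential and content-differential metabolites
(matched by name) and, for each co-contained metabolite, keeps it only if its
trend reverses between diet and content (contrary log2FC signs) or the log2FC
variation range exceeds a threshold (default 2). Co-contained metabolites
with the same trend and a small variation range are removed as diet
carryover; content-only metabolites always pass.
"""

from __future__ import annotations

from dataclasses import dataclass

from .differential import DifferentialRecord

__all__ = ["VennPartition", "FilterDecision", "venn_partition", "apply_diet_filter"]


@dataclass
class VennPartition:
    content_only: set[str]
    diet_only: set[str]
    co_contained: set[str]


@dataclass
class FilterDecision:
    feature_id: str
    lfc_diet: float
    lfc_content: float
    decision: str  # keep_contrary_trend | keep_lfc_range | remove


def venn_partition(diet_diff: set[str], content_diff: set[str]) -> VennPartition:
    """Exact set partition of diet- vs content-differential metabolite names."""
    diet_diff, content_diff = set(diet_diff), set(content_diff)
    co = diet_diff & content_diff
    return VennPartition(
        content_only=content_diff - co,
        diet_only=diet_diff - co,
        co_contained=co,
    )


def apply_diet_filter(
    partition: VennPartition,
    diet_records: list[DifferentialRecord],
    content_records: list[DifferentialRecord],
    range_threshold: float = 2.0,
    range_definition: str = "difference",
) -> tuple[list[FilterDecision], set[str]]:
    """Decide keep/remove for each co-contained metabolite; return the final set.

    ``range_definition`` selects what "log2FC variation range" means:
    ``difference`` (default) is |lfc_content - lfc_diet|; ``content_abs`` is
    |lfc_content|. Trend signs come from the log2FC signs (co-contained
    features are already significant in both tables). The final
    content-differential set is content_only plus the kept co-contained ids.
    """
    diet_lfc = {r.feature_id: r.log2fc for r in diet_records}
    content_lfc = {r.feature_id: r.log2fc for r in content_records}

    decisions = []
    kept: set[str] = set()
    for fid in sorted(partition.co_contained):
        if fid not in diet_lfc:
            raise KeyError(f"co-contained feature {fid!r} missing a diet log2FC")
        if fid not in content_lfc:
            raise KeyError(f"co-contained feature {fid!r} missing a content log2FC")
        ld, lc = diet_lfc[fid], content_lfc[fid]
        if range_definition == "difference":
            rng = abs(lc - ld)
        elif range_definition == "content_abs":
            rng = abs(lc)
        else:
            raise ValueError(f"unknown range definition {range_definition!r}")
        contrary = (ld > 0) != (lc > 0)
        if contrary:
            decision = "keep_contrary_trend"
        elif rng > range_threshold:
            decision = "keep_lfc_range"
        else:
            decision = "remove"
        if decision != "remove":
            kept.add(fid)
        decisions.append(FilterDecision(fid, ld, lc, decision))

    final = set(partition.content_only) | kept
    return decisions, final
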