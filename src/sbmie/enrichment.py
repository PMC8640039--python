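"""Hypergeometric over-representation analysis (ORA) of a feature set.

Given a selected feature set (e.g. the filtered content-differential
metabolites) and a feature → pathway annotation map, each pathway is scored
by the upper-tail hypergeometric probability of drawing at least the observed
overlap when sampling the selected set from the annotated universe:

    P(X >= k),  X ~ Hypergeometric(N, K, n)

with N the annotated universe size, K the pathway size, n the annotated
selected-set size, and k the overlap. Features absent from the map are
unannotated and drop out of both N and n. Raw P values by default;
Benjamini-Hochberg correction is available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from scipy import stats

__all__ = ["EnrichmentRecord", "enrich"]


@dataclass
class EnrichmentRecord:
    pathway_id: str
    N: int
    K: int
    n: int
    k: int
    p_value: float
    significant: bool


def enrich(
    selected: set[str],
    annotation: dict[str, set[str]],
    alpha: float = 0.05,
    correction: str = "none",
) -> list[EnrichmentRecord]:
    """ORA of ``selected`` against ``annotation``; records sorted by P value.

    Only pathways with overlap k >= 1 are reported. A selected set disjoint
    from the annotated universe gives an empty result with a warning.
    """
    if not annotation:
        raise ValueError("annotation map is empty")
    universe = set(annotation)
    sel = set(selected) & universe
    if not sel:
        warnings.warn("selected set has no annotated features", stacklevel=2)
        return []

    pathways: dict[str, set[str]] = {}
    for fid, cats in annotation.items():
        for cat in cats:
            pathways.setdefault(cat, set()).add(fid)

    N, n = len(universe), len(sel)
    records = []
    for pid in sorted(pathways):
        members = pathways[pid]
        k = len(members & sel)
        if k == 0:
            continue
        K = len(members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        records.append(EnrichmentRecord(pid, N, K, n, k, p, False))

    if correction == "bh" and records:
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([r.p_value for r in records], method="fdr_bh")[1]
        for r, q in zip(records, adj):
            r.p_value = float(q)
    elif correction not in ("none", "bh"):
        raise ValueError(f"unknown correction {correction!r}")

    for r in records:
        r.significant = r.p_value < alpha
    records.sort(key=lambda r: (r.p_value, r.pathway_id))
    return records
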