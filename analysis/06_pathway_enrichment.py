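#!/usr/bin/env python
"""Hypergeometric pathway enrichment of the filtered differential metabolites.

Real pathway assignments require a metabolite database; here a synthetic
annotation map is built over the simulated features, concentrating the
planted differential features into a few "response" pathways so that
over-representation is detectable. Reports the enriched pathways at raw
P < 0.05.
"""

import argparse
from pathlib import Path

import numpy as np

from sbmie import enrich, read_table, write_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--filterdir", type=Path, default=Path("results/diet_filter"))
    ap.add_argument("--outdir", type=Path, default=Path("results/enrichment"))
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--level", default="SBM40")
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(args.seed)

    truth = read_table(args.datadir / "ground_truth.tsv")
    truth = truth[truth["ion_mode"] == "positive"]
    planted = truth.loc[truth["label"] != "null", "feature_id"].tolist()
    nulls = truth.loc[truth["label"] == "null", "feature_id"].tolist()

    # synthetic annotation: two response pathways drawing mostly planted
    # features, eight background pathways drawing uniformly
    annotation: dict[str, set[str]] = {}
    for pid, pool, size in [
        ("path_response_1", planted, max(4, len(planted) // 2)),
        ("path_response_2", planted + nulls[:40], 15),
    ] + [(f"path_bg_{i}", nulls, 25) for i in range(8)]:
        for fid in rng.choice(pool, size=min(size, len(pool)), replace=False):
            annotation.setdefault(str(fid), set()).add(pid)

    selected = set(
        read_table(args.filterdir / f"filtered_content_diff_{args.level}_positive.tsv")
        ["feature_id"].astype(str)
    )
    records = enrich(selected, annotation, alpha=0.05)
    write_table(records, args.outdir / "enrichment.tsv")
    n_sig = sum(r.significant for r in records)
    print(f"{len(records)} pathways with overlap, {n_sig} significant at P < 0.05:")
    for r in records:
        flag = "*" if r.significant else " "
        print(f" {flag} {r.pathway_id:<18} k={r.k:<3} K={r.K:<3} n={r.n:<4} N={r.N:<5} P={r.p_value:.3g}")
    print(f"wrote enrichment table to {args.outdir}/")


if __name__ == "__main__":
    main()
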