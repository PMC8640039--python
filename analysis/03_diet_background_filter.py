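#!/usr/bin/env python
"""Diet-background filtration of the content-differential metabolites.

For each substitution level and ion mode: Venn-partition the
diet-differential and content-differential sets, then keep a co-contained
metabolite only if its trend reverses between diet and content or the log2FC
variation range exceeds 2. Writes the per-metabolite decisions and the final
filtered content-differential sets.
"""

import argparse
from pathlib import Path

from sbmie import apply_diet_filter, read_table, venn_partition, write_table
from sbmie.differential import records_from_frame

MODES = ("positive", "negative")
LEVELS = ("SBM20", "SBM40")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--diffdir", type=Path, default=Path("results/differential"))
    ap.add_argument("--outdir", type=Path, default=Path("results/diet_filter"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    for level in LEVELS:
        for mode in MODES:
            diet = records_from_frame(read_table(args.diffdir / f"diet_{mode}_{level}_vs_FM.tsv"))
            content = records_from_frame(read_table(args.diffdir / f"content_{mode}_{level}_vs_FM.tsv"))
            diet_set = {r.feature_id for r in diet if r.significant}
            content_set = {r.feature_id for r in content if r.significant}
            part = venn_partition(diet_set, content_set)
            decisions, final = apply_diet_filter(part, diet, content)
            removed = sum(d.decision == "remove" for d in decisions)
            print(
                f"{level}/{mode}: {len(content_set)} content-differential, "
                f"{len(part.co_contained)} co-contained with diet, "
                f"{len(part.co_contained) - removed} kept by the filter, "
                f"{removed} removed as diet carryover -> {len(final)} final"
            )
            write_table(decisions, args.outdir / f"decisions_{level}_{mode}.tsv",
                        columns=["feature_id", "lfc_diet", "lfc_content", "decision"])
            write_table(
                [{"feature_id": fid} for fid in sorted(final)],
                args.outdir / f"filtered_content_diff_{level}_{mode}.tsv",
                columns=["feature_id"],
            )
    print(f"wrote decisions and filtered sets to {args.outdir}/")


if __name__ == "__main__":
    main()
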