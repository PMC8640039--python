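#!/usr/bin/env python
"""Inverse-correlation exchange analysis between DI contents and tissue.

Takes the SBM40 vs FM differential tables of the content and tissue
compartments (content side already diet-background-filtered), classifies
metabolites significant in both compartments with opposite trends as
exchanged, and ranks the top representatives of each direction.
"""

import argparse
from pathlib import Path

from sbmie import exchange_classify, rank_representatives, read_table, write_table
from sbmie.differential import records_from_frame

MODES = ("positive", "negative")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--diffdir", type=Path, default=Path("results/differential"))
    ap.add_argument("--filterdir", type=Path, default=Path("results/diet_filter"))
    ap.add_argument("--outdir", type=Path, default=Path("results/exchange"))
    ap.add_argument("--level", default="SBM40")
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    all_records = []
    totals = {"content_up_tissue_down": 0, "content_down_tissue_up": 0, "none": 0}
    for mode in MODES:
        content = records_from_frame(
            read_table(args.diffdir / f"content_{mode}_{args.level}_vs_FM.tsv")
        )
        kept = set(
            read_table(args.filterdir / f"filtered_content_diff_{args.level}_{mode}.tsv")
            ["feature_id"].astype(str)
        )
        # the diet filter vetoes content-side significance for carryover features
        for r in content:
            if r.significant and r.feature_id not in kept:
                r.significant = False
        tissue = records_from_frame(
            read_table(args.diffdir / f"tissue_{mode}_{args.level}_vs_FM.tsv")
        )
        records, counts = exchange_classify(content, tissue)
        all_records.extend(records)
        for k in totals:
            totals[k] += counts.get(k, 0)

    n_up = totals["content_up_tissue_down"]
    n_down = totals["content_down_tissue_up"]
    print(
        f"{args.level} vs FM: {n_up} metabolites up in contents / down in tissue, "
        f"{n_down} down in contents / up in tissue ({n_up + n_down} exchanged in total)"
    )
    write_table(all_records, args.outdir / "exchange.tsv")
    write_table(
        [{"exchange_class": k, "count": v} for k, v in totals.items()],
        args.outdir / "class_counts.tsv",
    )
    for cls in ("content_up_tissue_down", "content_down_tissue_up"):
        reps = rank_representatives(all_records, cls, k=10)
        write_table(reps, args.outdir / f"representatives_{cls}.tsv",
                    columns=["feature_id", "content_log2fc", "content_p",
                             "tissue_log2fc", "tissue_p", "exchange_class"])
        print(f"  top {cls}: {[r.feature_id for r in reps[:3]]} ...")
    print(f"wrote exchange tables to {args.outdir}/")


if __name__ == "__main__":
    main()
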