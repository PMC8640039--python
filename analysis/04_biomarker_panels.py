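#!/usr/bin/env python
"""Biomarker panels: top-10 VIP per mode, cross-mode merge, core panel,
z-scores, per-feature ROC AUC, and the significance-masked correlation map.

Ranks the diet-filtered content-differential metabolites of each substitution
level by VIP (top 10 per ion mode), merges the two ion modes by metabolite
name, intersects the levels into the conserved "core biomarker" set, and
validates each level's panel with z-scores against FM, ROC AUC (level vs FM),
and a Pearson correlation matrix masked at P > 0.05.
"""

import argparse
from pathlib import Path

import pandas as pd

from sbmie import (
    build_biomarker_panel,
    correlation_matrix,
    intersect_levels,
    read_feature_table,
    read_table,
    roc_auc,
    top_vip,
    write_table,
    zscore_vs_control,
)
from sbmie.differential import records_from_frame

MODES = ("positive", "negative")
LEVELS = ("SBM20", "SBM40")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--diffdir", type=Path, default=Path("results/differential"))
    ap.add_argument("--filterdir", type=Path, default=Path("results/diet_filter"))
    ap.add_argument("--outdir", type=Path, default=Path("results/biomarkers"))
    ap.add_argument("--k", type=int, default=10)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    panels = {}
    tables = {}
    for level in LEVELS:
        mode_lists = {}
        for mode in MODES:
            recs = records_from_frame(
                read_table(args.diffdir / f"content_{mode}_{level}_vs_FM.tsv")
            )
            kept = set(
                read_table(args.filterdir / f"filtered_content_diff_{level}_{mode}.tsv")
                ["feature_id"].astype(str)
            )
            table, meta = read_feature_table(
                args.datadir / f"content_{mode}.tsv", args.datadir / "metadata.tsv"
            )
            tables[mode] = (table, meta)
            candidates = [r for r in recs if r.feature_id in kept]
            ranked_ids = top_vip(candidates, k=args.k)
            mode_lists[mode] = [table.name_of(fid) for fid in ranked_ids]
        panel = build_biomarker_panel(level, mode_lists)
        panels[level] = panel
        print(
            f"{level}: merged panel of {len(panel.merged)} metabolites "
            f"({len(panel.co_contained_modes)} co-contained across ion modes)"
        )

        rows = []
        for mode in MODES:
            table, meta = tables[mode]
            name_to_id = {table.name_of(f): f for f in table.feature_ids}
            fm = meta.samples_where(group="FM", compartment="content", ion_mode=mode)
            trt = meta.samples_where(group=level, compartment="content", ion_mode=mode)
            for name in panel.mode_lists[mode]:
                fid = name_to_id[name]
                case = table.data.loc[fid, trt].to_numpy()
                ctrl = table.data.loc[fid, fm].to_numpy()
                roc = roc_auc(case, ctrl, feature_id=name)
                z = zscore_vs_control(case, ctrl)
                rows.append(
                    {
                        "metabolite": name,
                        "ion_mode": mode,
                        "auc": roc.auc,
                        "orientation": roc.orientation,
                        "mean_z_vs_FM": float(z.mean()),
                    }
                )
        frame = pd.DataFrame(rows)
        write_table(frame, args.outdir / f"panel_{level}.tsv")
        print(f"  min AUC {frame['auc'].min():.3f}; all >= 0.9: {bool((frame['auc'] >= 0.9).all())}")

        # correlation map across the level's panel (positive mode intensities)
        table, meta = tables["positive"]
        name_to_id = {table.name_of(f): f for f in table.feature_ids}
        ids = [name_to_id[n] for n in panel.mode_lists["positive"]]
        samples = meta.samples_where(group="FM", compartment="content", ion_mode="positive") + \
            meta.samples_where(group=level, compartment="content", ion_mode="positive")
        cm = correlation_matrix(table.data.loc[ids, samples])
        cm.r.to_csv(args.outdir / f"corr_{level}.tsv", sep="\t", float_format="%.6g")
        masked = int(cm.mask.to_numpy().sum())
        print(f"  correlation map: {masked} of {cm.mask.size} pairs masked at P > 0.05")

    core = intersect_levels({lvl: panels[lvl].merged for lvl in LEVELS})
    print(f"core biomarkers conserved across levels: {len(core.core)}")
    for lvl in LEVELS:
        print(f"  {lvl}-specific: {sorted(core.specific_per_level[lvl])}")
    write_table(
        [{"metabolite": m, "set": "core"} for m in sorted(core.core)]
        + [
            {"metabolite": m, "set": f"{lvl}_specific"}
            for lvl in LEVELS
            for m in sorted(core.specific_per_level[lvl])
        ],
        args.outdir / "core_panel.tsv",
    )
    print(f"wrote panels to {args.outdir}/")


if __name__ == "__main__":
    main()
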