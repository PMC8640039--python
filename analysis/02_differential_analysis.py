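#!/usr/bin/env python
"""Two-group differential analysis of every compartment and ion mode.

For each substitution level vs the FM control, per compartment and ion mode:
group-mean log2 fold change, Welch t on normalized log2 intensities, PLS-DA
VIP, then the metabolite significance rule (P < 0.05 and VIP >= 1) for the
content/diet/tissue tables. Writes one differential table per contrast and a
volcano-style up/down summary.
"""

import argparse
from pathlib import Path

from sbmie import RunConfig, classify_differential, differential_table, read_feature_table, write_table

COMPARTMENTS = ("diet", "content", "tissue")
MODES = ("positive", "negative")
LEVELS = ("SBM20", "SBM40")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results/differential"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)
    cfg = RunConfig()

    print(f"{'contrast':<40} {'up':>5} {'down':>5} {'tested':>7}")
    for comp in COMPARTMENTS:
        for mode in MODES:
            table, meta = read_feature_table(
                args.datadir / f"{comp}_{mode}.tsv", args.datadir / "metadata.tsv"
            )
            for level in LEVELS:
                recs = differential_table(table, meta, "FM", level, cfg)
                classify_differential(
                    recs, mode="metabolite", p_alpha=cfg.p_alpha, vip_min=cfg.vip_min
                )
                name = f"{comp}_{mode}_{level}_vs_FM"
                write_table(recs, args.outdir / f"{name}.tsv")
                up = sum(r.trend == "up" for r in recs)
                down = sum(r.trend == "down" for r in recs)
                print(f"{name:<40} {up:>5} {down:>5} {len(recs):>7}")
    print(f"wrote differential tables to {args.outdir}/")


if __name__ == "__main__":
    main()
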