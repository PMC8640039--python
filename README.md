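# sbmie — diet-corrected gut-content metabolomics for enteritis studies

Replacing fish meal with soybean meal in aquaculture feeds triggers
soybean-meal-induced enteritis (SBMIE) in the distal intestine (DI) of many
farmed fish. Untargeted LC–MS metabolomics of the DI *contents* is an
attractive non-lethal readout of this condition, but it confounds two
signals: metabolites changed by host physiology and metabolites simply
carried over from the altered diet. `sbmie` implements the downstream
pipeline that separates them and screens the result for biomarkers:

1. **Differential analysis** per feature: log2FC of group-mean ion
   intensity, Welch's t on normalized log2 intensities, and PLS-DA **VIP**
   (variable importance in projection) from a NIPALS PLS1 fit, with
   Σ VIP² = number of features so VIP = 1 is the average-importance line.
   Significance: P < 0.05 and VIP ≥ 1 (metabolites), or |log2FC| > 1 and
   P < 0.05 (DEG rule); plus monotone dose-trend profiling (profiles A/B).
2. **Diet-background filter**: a content-differential metabolite that is
   also diet-differential is kept only if its trend reverses between diet
   and content, or |log2FC_content − log2FC_diet| > 2.
3. **Biomarker screen**: top-10 VIP per ion mode → cross-mode merge by
   metabolite name → intersection across soybean-meal dose levels = the
   conserved "core biomarkers"; validated by z-scores vs control, ROC AUC
   (normalized Mann–Whitney U, ties 0.5) and a P-masked Pearson correlation
   map.
4. **Exchange analysis**: metabolites significantly changed in *both* DI
   contents and DI tissue with opposite trends, read as content↔tissue
   transfer, classified `content_up_tissue_down` / `content_down_tissue_up`.
5. Supporting modules: hypergeometric pathway over-representation, OTU
   **alpha diversity** (observed species, Shannon, Gini–Simpson, Chao1, ACE,
   Good's coverage), and a seeded synthetic-data generator that emulates the
   3-group (FM, SBM20, SBM40), 12-samples-per-group, two-ion-mode,
   three-compartment study design with planted differential, diet-derived
   and exchanged features.

See `docs/methods.md` for the model details and design choices.

## Worked example 1 — published biomarker panels

The package ships the printed top-10 VIP lists and consolidated panels of an
SBMIE feeding trial in pearl gentian grouper as a reference worked example:

```python
from sbmie import merge_modes, intersect_levels
from sbmie.reference_panels import TOP10_VIP, PANEL_BY_LEVEL

merged, co = merge_modes(TOP10_VIP[("SBM20", "positive")],
                         TOP10_VIP[("SBM20", "negative")])
print(len(merged), sorted(co))
core = intersect_levels({k: set(v) for k, v in PANEL_BY_LEVEL.items()})
print(len(core.core), sorted(core.specific_per_level["SBM40"]))
```

prints

```
17 ['Daidzein', 'Glycitein', 'Glycitin']
14 ['3-Methoxyflavone', 'Cys-Tyr', 'Indole-3-butyric acid']
```

i.e. each level's two ion-mode lists merge to 17 biomarkers with 3 detected
in both modes, and the two levels share 14 core biomarkers (mostly soy
isoflavones and saponins) plus 3 level-specific ones each.

## Worked example 2 — full synthetic pipeline

The numbered drivers under `analysis/` run the whole pipeline on a simulated
cohort at study scale and write their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py --seed 0
python analysis/02_differential_analysis.py
python analysis/03_diet_background_filter.py
python analysis/04_biomarker_panels.py
python analysis/05_exchange_analysis.py
python analysis/06_pathway_enrichment.py
python analysis/07_alpha_diversity.py
```

With seed 0 the filter stage reports, for example,

```
SBM40/positive: 199 content-differential, 29 co-contained with diet,
13 kept by the filter, 16 removed as diet carryover -> 183 final
```

(16 planted diet-carryover features removed, contrary-trend features kept),
the biomarker stage reports `min AUC 1.000; all >= 0.9: True` for the SBM40
panel, and the exchange stage finds

```
SBM40 vs FM: 17 metabolites up in contents / down in tissue,
23 down in contents / up in tissue (40 exchanged in total)
```

recovering the planted exchanged features exactly (the remainder are
strongly differential nulls and planted differential features that happened
to cross both thresholds). Ground-truth labels for every feature are in
`results/data/ground_truth.tsv`.

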