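# Methods

`sbmie` implements the downstream computational pipeline used to study
soybean-meal-induced enteritis (SBMIE) in farmed fish from untargeted
metabolomics of the distal intestine (DI): diet-background-corrected
differential analysis of gut-content metabolomes, VIP-based biomarker
screening with ROC/z-score/correlation validation, inverse-correlation
exchange analysis between gut contents and gut tissue, and the supporting
alpha-diversity and dose-trend computations. Raw spectra processing (peak
picking, identification) is upstream of this package; its inputs are
feature-intensity tables.

## Study design the pipeline assumes

Three isoproteic diets form an ordered dose ladder — a fish-meal control (FM)
and two soybean-meal substitution levels (SBM20, SBM40) — with n = 12
biological samples per group per compartment. Three compartments are
measured: the diets themselves, DI contents (luminal digesta) and DI tissue
(gut wall), each in positive and negative electrospray ionization mode
(~2,000 and ~1,100 features respectively). Feature identity across tables is
the metabolite display name, matched exactly and case-sensitively.

## Differential stage

For treatment group T vs control C, per feature:

* **log2FC** = log2(mean(T)/mean(C)) on raw intensities (group means of ion
  intensities are what published tables report). A zero control mean requires
  an explicit pseudo-mean; otherwise it is an error.
* **P value**: Welch's t by default, run on log2-transformed,
  total-intensity-normalized values (log-normal MS intensities are
  approximately normal after log). Student's t and the exact-when-feasible
  Wilcoxon rank-sum test are selectable. Two constant equal groups give
  P = 1 by convention. Raw P values are used by default, matching the
  P < 0.05 convention of the field's reporting; Benjamini–Hochberg is
  available behind `multiple_testing = "bh"`.
* **VIP** from a NIPALS PLS1 fit of the 0/1 class on the autoscaled matrix,
  with the Y-variance-weighted definition
  VIP_j = sqrt(p · Σ_a SS_a (w_ja/‖w_a‖)² / Σ_a SS_a), SS_a = q_a² t_aᵀt_a.
  This normalization gives Σ_j VIP_j² = p exactly, so VIP = 1 is the
  average-importance reference. Components default to 2; requests beyond the
  rank are truncated with a warning; constant features are excluded from
  scaling and get VIP 0. The implementation is cross-checked in the test
  suite against scikit-learn's independent PLS implementation to 1e-8.

Significance rules: *metabolite mode* — P < 0.05 and VIP ≥ 1; *DEG mode* —
|log2FC| > 1 and P < 0.05. Trend (up/down) is the log2FC sign of significant
features.

**Dose-trend profiles**: a feature is profile A if its group means strictly
increase across every step of the full ladder and the extreme-group contrast
(lowest vs highest dose) has P < 0.05; profile B is the strict mirror. The
extreme-group test was chosen as the significance criterion because it is
the simplest test that is sensitive to the monotone alternative; it is
config-exposed.

## Diet-background filter

Metabolites differential in the contents may be diet carryover rather than
host physiology. The content-differential and diet-differential name sets
are Venn-partitioned; each co-contained metabolite is kept only if

* its log2FC sign reverses between diet and content (*contrary trend*), or
* its log2FC variation range exceeds 2.

"Variation range" is interpreted as |log2FC_content − log2FC_diet| (strict
inequality); the alternative reading |log2FC_content| > 2 is selectable via
`range_definition = "content_abs"`. Trend signs come from log2FC rather than
the significance-gated trend field because co-contained metabolites are by
construction significant in both tables. Content-only metabolites always
pass; the filter is idempotent and with no diet table it is the identity.

## Biomarker screen

Per substitution level: the significant, filter-surviving content
metabolites are ranked by VIP (ties: smaller P, then id) and the top 10 per
ion mode are taken. The two mode lists are merged by metabolite name
(cross-mode duplicates counted once), and the per-level merged panels are
intersected across substitution levels into the conserved **core
biomarkers**; the remainders are level-specific. Validation:

* **z-scores** against the control group, z = (x − mean(C))/sd(C) with the
  n−1 denominator;
* **ROC AUC** computed as the normalized Mann–Whitney U (ties counted 0.5),
  auto-oriented so AUC ≥ 0.5 with the orientation recorded. This equals the
  probability that a random case sample outranks a random control sample and
  is invariant under monotone intensity transforms;
* **correlation matrix** (Pearson default, Spearman optional) across panel
  features, P from the t transform t = r√((n−2)/(1−r²)), with pairs at
  P > 0.05 masked ("blanked"); undefined correlations of constant features
  are masked with a warning. No AUC confidence interval is computed by
  default.

## Exchange analysis

Metabolites differential in BOTH the contents and the tissue with strictly
opposite log2FC signs are classified `content_up_tissue_down` or
`content_down_tissue_up`; all others are `none`. A record's differential
status is its `significant` flag when set (e.g. an upstream classification
or a published trend call); otherwise raw P < α. Carrying the flag matters
for reproducing published exchange tables, which include two representative
rows whose printed tissue P values sit marginally above 0.05 while the
source still counts them as significantly changed (see
`sbmie.reference_panels`). Representatives of each class are ranked by
min(content P, tissue P) ascending, ties by |content log2FC| descending;
this ranking convention is config-exposed because published tables do not
state theirs.

## Pathway enrichment

Over-representation of a selected feature set against a feature → pathway
map: P(X ≥ k) with X ~ Hypergeometric(N, K, n), where the universe N is the
annotated features only (unannotated features drop out of both N and n).
Pathways with zero overlap are not reported. Raw P by default, BH optional.
The test suite validates the tail against exact rational-arithmetic
enumeration for N ≤ 12.

## Alpha diversity

Per sample, from an OTU count vector: observed taxa S_obs; Shannon entropy
in **base 2** by default (consistent with published index magnitudes for
communities of a few hundred OTUs; natural log selectable); Gini–Simpson
1 − Σp²; classical Chao1 = S_obs + F1²/(2F2) with the F2 = 0 fallback
S_obs + F1(F1−1)/2; ACE with rare threshold 10 (ACE = S_obs when no rare
taxa; when the rare fraction is all singletons its sample coverage is zero
and the Chao1 value is returned since the ACE ratio is undefined); Good's
coverage 1 − F1/N. F1, F2 and N are reported alongside. No rarefaction is
applied by default. All estimators are cross-checked against scikit-bio in
the test suite.

## Synthetic data generator

`simulate()` draws log-normal intensities: log2 X = baseline_j + dose·δ_jc +
ε, with per-feature baselines ~ N(17, 2²) (log2 scale, i.e. typical ion
intensities around 10⁵), within-group noise sd derived from the intensity
coefficient of variation as σ_ln = √ln(1+CV²) (CV defaults to 30%, a
realistic within-group spread for LC–MS intensities), and planted
compartment-specific full-dose effects δ_jc on the log2 scale. Because group
effects are multiplicative, the population group-mean log2 ratio equals the
planted effect exactly. Dose response is linear along the ladder (FM 0,
SBM20 ½, SBM40 1), giving the trend-profile stage a monotone signal.

Planted classes: differential (±effect in contents), diet-derived
(same-trend: diet +e, content +0.6e, so the variation range 0.8 < 2 forces
removal by the filter; contrary: diet +e, content −e, forcing retention) and
exchanged (opposite signs in content vs tissue). Default full-dose effect is
log2FC = 2 (a 4-fold change, typical of confidently detected diet-response
metabolites). Three metabolite names are shared across ion modes to exercise
cross-mode deduplication. Labels partition the feature set and are emitted
as a ground-truth table for exact-recovery tests.

`simulate_otu()` draws multinomial counts from group-specific geometric
rank-abundance profiles p_i ∝ exp(−λ(1−g)·i) with λ = 8/n_taxa; the
dysbiosis gradient g ∈ [0,1] flattens the profile, so expected richness and
evenness rise monotonically with g — the qualitative microbiota signature of
increasing soybean-meal substitution.

What the generator does **not** emulate: chromatographic drift, batch
effects, missing-at-random dropouts, correlated metabolite modules, isotope
patterns, and compositionality of intensities. Passing recovery tests
therefore demonstrate correctness of the pipeline's logic under its own
statistical assumptions, not robustness to real-data artifacts.

## Problem sizes used in tests and the acceptance script

Simulation-based checks run at n = 12 samples per group with 400–510
features per cohort over 20 seeds (type-I calibration pools 8,000 null
features; the ROC power check plants 10 features at log2FC 2, CV 30% among
500 nulls), and the OTU gradient checks use 60–120 taxa at depths of
2,000–5,000 reads; these sizes give stable Monte-Carlo estimates while
keeping the full suite fast. The analysis drivers run at the full emulated
study scale (2,000 + 1,100 features × 3 compartments × 36 samples).

## Known limitations

* Absolute published values that depend on undeposited raw data (OTU
  diversity tables, DEG and metabolite counts, exchange totals) are not
  reproducible at the desk and are covered qualitatively by synthetic
  recovery properties instead.
* The exact univariate test, VIP cutoff and biomarker "screening index"
  behind published panels are not stated in the source reports; the defaults
  here are declared conventions, not inferences.
* PLS1 VIP is computed for two-class contrasts only; OPLS-DA and
  negative-binomial count models are out of scope.
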