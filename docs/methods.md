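# Methods

## Overview

`var3d` implements a structural characterisation pipeline for missense
variants. Each amino-acid position of a protein is described by a binary
vector over a fixed 40-feature catalog spanning seven categories:
secondary structure (DSSP 8-class), relative solvent accessibility
(five bins), physicochemical class of the reference residue,
interaction/bond participation, PTM-site identity, spatial proximity to
PTM sites, and functional-region membership. Pathogenic-vs-population
burden per feature is quantified with two-sided Fisher exact tests, the
significant features form per-context association sets, and the
per-residue **pathogenic 3D feature index**

    P3DFi = 3DF_PATH − 3DF_POP

counts how many of the residue's features belong to the pathogenic set
minus how many belong to the population set. A positive index marks a 3D
mutational hotspot. P3DFi is finally evaluated as an extra column in a
random-forest variant classifier.

## Feature catalog

The default catalog has exactly 40 features: 8 secondary-structure
states + 5 exposure bins + 6 physicochemical groups + 3 bond types +
6 PTM-site types + 6 PTM-proximity types + 6 functional-region types.
The exact identities of some entries (the split of UniProt-derived
functional annotations into six groups, the bond-type granularity) are
not fully published; this decomposition is a documented reconstruction,
versioned with the package, and the catalog is configurable wherever it
is consumed. Only three functional-region names (modular domain,
modified residue, functional/binding region) are fixed by the published
results; the other three are package defaults.

## Annotation rules

- **RSA** = ASA / MaxASA(aa), capped at 1. MaxASA uses the theoretical
  values of Tien et al. (2013); the table is configurable since the
  original analysis does not name its normalisation.
- **Exposure bins** are half-open `[lo, hi)`: core `< 5%`, buried
  `5–25%`, then `25–50` (medium-buried), `50–75` (medium-exposed),
  `≥ 75%` (exposed). The two interior edges 5% and 25% are published;
  the equal-width continuation above 25% is a package default,
  configurable.
- **PTM proximity** fires when the minimum Cα–Cα distance to a site of
  the given PTM type is strictly below 10 Å; a residue that is itself a
  PTM site has distance 0. Cα–Cα is the default convention (consistent
  with the published 6.8 Å for an i, i+4 pair); the published analysis
  does not state whether closest-atom distances were used.
- **Physicochemical groups** are a pure function of the reference amino
  acid. Special (C, G, P) and aromatic (F, W, Y) memberships are fixed;
  the default assignment of the remaining residues (aliphatic
  A/I/L/M/V, charged D/E/H/K/R, neutral S/T, polar N/Q) is an editable
  map.
- **Consolidation across structures** uses an "any mapped structure"
  rule: a structural bit is set if it fires in at least one structure
  covering the position. A position can therefore carry, e.g., two
  exposure bits if different structures resolve it differently.
  Positions with no structural coverage are flagged unresolved and
  excluded from burden analysis.
- **Bond features** (hydrogen bond, salt bridge, disulfide) are consumed
  as input flags, not recomputed from geometry, matching the original
  pipeline which took them from a curated interaction database.

## Burden statistics

For each feature × gene group (the pooled "all_genes" context plus each
protein class; multi-class genes contribute to every class they belong
to) the 2×2 table is pathogenic/population × feature present/absent.

- p: two-sided Fisher exact test, probability-ordering ("minlike")
  convention; verified against exhaustive hypergeometric enumeration for
  every testable table with n ≤ 30.
- Point estimate: the sample OR ad/bc (0 and ∞ reported exactly, as in
  the published per-class results); a conditional-MLE estimate is
  available for cross-checks.
- 95% CI: Woolf logit interval; any zero cell triggers the
  Haldane–Anscombe +0.5 correction for the interval only.
- Multiplicity: q = min(1, p·m). The study-style mode fixes m = 1,000
  (40 features × 25 groups); the default uses the number of tests
  actually run so that reusing the pipeline with another catalog cannot
  silently keep the wrong multiplier.
- RR = P(pathogenic | feature) / P(pathogenic | no feature), reported as
  a concordance check on OR. RR ≈ OR requires the *outcome* to be rare
  among both feature carriers and non-carriers (a/(a+c), b/(b+d) small),
  not the feature to be rare within each arm; the concordance test uses
  that condition.
- Variants identical in (gene, pos, ref, alt) are deduplicated before
  counting; on label conflicts pathogenic wins.

Association sets: OR > 1 and q < α → pathogenic set; OR < 1 and q < α →
population set (disjoint by construction).

## P3DFi conventions

The index is computed for the reference residue of a position; a
variant's P3DFi is the P3DFi of its reference position. One index is
computed per context (all-genes, plus one per protein class of the
gene); no automatic aggregation across contexts. Counting is uncapped:
if two exposure bits are set by multi-structure consolidation, both can
count. The sign convention is fixed by the published worked example:
positive index = hotspot. Bins are the integers −2…2 with two open
tails (< −2, > 2); the high-confidence calls use strict inequalities
(index > 2 pathogenic-like, < −2 benign-like).

The Mann–Whitney comparison between variant classes uses midrank ties;
the p value comes from exact enumeration of rank splits (dynamic
programming over the realised midranks) when n₁·n₂ ≤ 400 and from the
tie-corrected normal approximation above that. The exact path is
verified against a brute-force permutation oracle for all splits with
n₁+n₂ ≤ 10. Fitness correlation reports squared Pearson r with the
two-sided t-transform p, requiring ≥ 3 pairs and non-constant inputs.

## Ensemble

`RandomForestClassifier` with 2,000 Gini trees of depth ≤ 10, bootstrap
resampling, decision threshold strictly greater than 0.5 — the published
configuration. The pathogenicity score is the mean per-tree class
probability (a vote-fraction rule is available by flag; the original
implementation does not say which it used). Rows with any missing score
are dropped before training/evaluation with counts logged. CADD-like
scores are fed raw: trees are scale-invariant. Metrics are computed from
the confusion matrix directly; MCC with a zero denominator is reported
as 0; AUC is the rank-based probability that a random pathogenic variant
outranks a random benign one, with midranks for ties.

## Synthetic cohorts

No generative model is published for the real cohorts, so the generator
is a stand-in designed for checkability:

- Residue vectors are drawn per category: exactly one secondary
  structure state, one exposure bin and one physicochemical group per
  residue (the group realised by sampling a reference amino acid within
  it), and independent Bernoulli bits for bond/PTM/functional features.
  Features are conditionally independent given the gene's class.
- Labels follow P(pathogenic | f) = logistic(β₀ + Σ βⱼ fⱼ). With a
  single planted feature the marginal OR equals exp(β); with several,
  marginal ORs attenuate toward 1 (odds-ratio non-collapsibility), which
  is why the parameter-recovery experiment plants one feature per
  replicate.
- Defaults mirror the study scale: 1,330 genes, ~149 discovery variants
  per gene (~198k), ~17 validation variants per gene, 24 protein classes
  with multi-membership (probability 0.10 each, at least one class per
  gene). β₀ = −2.7, calibrated so the marginal pathogenic fraction is
  ~0.166 — the study-scale ratio of pathogenic to total structure-mapped
  variants. Planted log-ORs echo the published all-genes enrichments
  (disulfide ln 19.2, SUMO-proximal ln 5.8, O-GlcNAc-proximal ln 5.6,
  modular domain ln 3.4, exposed ln 0.4, ...); prevalences are
  realistic package defaults (e.g. α-helix 0.32, core 0.10, disulfide
  0.02).
- Predictor scores are label-conditional draws: SIFT-like low for
  pathogenic (Beta(2,3) vs Beta(3,2)), PolyPhen2-like the reverse,
  CADD-like Gamma(5, 4) vs Gamma(3.2, 4) — each individually of
  moderate discriminative power, leaving room for P3DFi to add signal,
  as in the published comparison.
- Fitness readouts are −α·P3DFi + Normal(0, σ²) per position, with the
  truth association sets implied by the planted signs.

What the generator does **not** model: real allele frequencies,
mutational signatures, sequence correlation of features, structure
coverage bias (the published 61% vs 33% mapping rates), or the
pathogenic-enriched composition of clinical validation sets (the
held-out set here has the same ~0.166 pathogenic fraction as discovery,
so tail-purity percentages are not comparable to the published 90%/68%).
Passing tests therefore demonstrate correctness of the statistical
machinery on planted truth, not performance on real cohorts.

## Experiment scales

- Parameter recovery: 100 replicate cohorts × 50,000 variants, single
  planted feature β = ln 4 at prevalence 0.3; the estimate must fall in
  its own 95% CI in ≥ 90% of replicates.
- Null calibration: 25 all-null cohorts × 20,000 variants (~1,000
  feature tests); 5% ± 2% of uncorrected p < 0.05 and empty q < 0.05
  association sets in ≥ 95% of cohorts.
- Ensemble ordering: 25 seeds, 200-tree forests on cohorts of 60 genes
  (~3,600 training, ~2,400 held-out variants); MCC(with P3DFi) ≥
  MCC(without) required in ≥ 80% of seeds. The analysis scripts use a
  300-gene cohort and the full 2,000-tree configuration.

## Known limitations

- The worked-example geometry ships as a synthetic stand-in (two Cα
  atoms at the published 6.8 Å); verifying the annotation module against
  the real BRCA1 BRCT structure requires the external PDB entry 2ING
  plus its DSSP output, which are not redistributed with the package.
- mmCIF input, ASA computation from raw coordinates, homology models
  and heatmap rendering are out of scope.
- The exact-enumeration Mann–Whitney path scales as O(n₁·n₂·Σranks) in
  the DP; the 400-pair default keeps it instant.
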