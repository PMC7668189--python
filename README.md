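# var3d — structural burden analysis of missense variants

Most missense variants found by clinical sequencing are of uncertain
significance. One productive way to interpret them is to ask *where they
land in the folded protein*: residues in the packed core, in β-strands,
near phosphosites or in disulfide bonds tolerate substitution very
differently from solvent-exposed loop residues. `var3d` implements that
programme as a tested pipeline for structural bioinformaticians:

1. **Annotation** — consolidate DSSP output, PDB coordinates, residue
   mappings, PTM sites and functional regions into a binary 40-feature
   vector per protein position (7 categories: secondary structure,
   exposure, physicochemical class, bonds, PTM sites, PTM proximity,
   functional regions).
2. **Burden** — for each feature and gene group (all genes pooled plus
   24 protein functional classes), a two-sided Fisher exact test on the
   2×2 table pathogenic/population × feature present/absent, with sample
   odds ratio, Woolf 95% CI, Bonferroni-style q = min(1, p·m) and
   relative risk. Features with OR > 1 and q < 0.05 form a group's
   pathogenic association set; OR < 1 and q < 0.05 the population set.
3. **P3DFi** — the pathogenic 3D feature index of a residue,
   `P3DFi = 3DF_PATH − 3DF_POP`, the number of its features in the
   pathogenic set minus the number in the population set. Positive
   values mark 3D mutational hotspots. Includes binning (< −2 … > 2),
   tail classification, Mann–Whitney comparisons and Pearson correlation
   against deep-mutational-scanning fitness.
4. **Ensemble** — a random forest (2,000 Gini trees, depth ≤ 10) over
   SIFT/PolyPhen2/CADD-like scores with or without P3DFi, with the full
   confusion-matrix panel (sensitivity, specificity, balanced accuracy,
   MCC, F1, precision, FPR, FNR) and rank-based AUC.
5. **Simulation** — synthetic cohorts with *planted* per-feature log
   odds ratios (labels drawn from a logistic model over the residue
   features), label-conditional predictor scores and P3DFi-linked
   fitness, so every stage is testable against known truth without any
   external download.

## Worked example

```python
from var3d.worked_example import f1704_p3dfi

score = f1704_p3dfi()
print(score.n_path, score.n_pop, score.index, score.hotspot)
# 6 0 6 True
```

The BRCT-domain phenylalanine F1704 of BRCA1 carries six features
(modular domain, core exposure, β-strand, aromatic, hydrogen bond,
< 10 Å from a phosphosite) that are all pathogenic-associated in
nucleic-acid-binding proteins and none population-associated, so
`P3DFi = 6 − 0 = 6`: a 3D mutational hotspot. `python
analysis/05_worked_example.py` prints the per-feature breakdown.

## Analysis scripts

Numbered drivers under `analysis/` run the full narrative on a shared
synthetic cohort (300 genes, ~45k discovery / ~5k held-out variants)
and write compact tables to `results/` (bulk data to `scratch/`):

```bash
python analysis/01_simulate_cohort.py      # cohort generation + composition
python analysis/02_burden_associations.py  # Fisher burden + association sets
python analysis/03_p3dfi_validation.py     # bin shift, tails, fitness r^2
python analysis/04_ensemble_comparison.py  # with/without-P3DFi forests (~5 min)
python analysis/05_worked_example.py       # F1704 breakdown
```

Representative output (seeded, reproducible):

```
strongest pathogenic enrichment: bond_disulfide OR=11.3 (planted conditional OR 19.2), q=8.50e-258
mean P3DFi pathogenic 2.05 vs benign 0.61 (Mann-Whitney p = 1.28e-114)
fitness correlation: r^2 = 0.61 (p = 0.00e+00, n = 106,085 positions)
with_class_p3dfi: MCC=0.562 balanced_acc=0.741 AUC=0.913
with_global_p3dfi: MCC=0.552 balanced_acc=0.733 AUC=0.912
without_p3dfi: MCC=0.508 balanced_acc=0.703 AUC=0.881
```

The disulfide odds ratio of 11.3 is the *marginal* estimate of a
conditional log-OR of ln 19.2 planted alongside eighteen other effects —
marginal ORs attenuate when several features act at once (odds-ratio
non-collapsibility); single-feature cohorts recover the planted value
exactly (see the parameter-recovery test). The model ordering —
class-context P3DFi > all-genes P3DFi > no P3DFi — is the qualitative
result the pipeline is designed to reproduce.

A thin CLI mirrors the stages (`var3d simulate|annotate|burden|score|
evaluate --help`).

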