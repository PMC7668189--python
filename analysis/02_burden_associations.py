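"""Per-feature burden analysis and association-set derivation.

Runs the two-sided Fisher burden tests for all 40 features over the
all-genes pool and each protein class (study-style fixed correction
multiplier of 1,000), derives the pathogenic/population association
sets, and compares the estimated all-genes odds ratios against the
planted truth. Full results go to scratch/, the all-genes table and the
association sets to results/.
"""

import math
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

from common import RESULTS, SCRATCH, study_cohort
from var3d.burden import ALL_GENES, BurdenConfig, derive_associations, run_burden
from var3d.experiments import burden_summary


def main() -> None:
    cohort = study_cohort()
    results = run_burden(
        cohort.discovery,
        cohort.residues,
        cohort.class_map,
        config=BurdenConfig(correction=1000),
    )
    df = burden_summary(results)
    df.to_csv(SCRATCH / "burden_results_full.tsv", sep="\t", index=False)

    allg = df[df["group"] == ALL_GENES].copy()
    truth = cohort.config.planted_log_or
    allg["OR_planted_conditional"] = [
        math.exp(truth.get(f, 0.0)) for f in allg["feature"]
    ]
    allg["in_ci"] = (allg["ci_low"] <= allg["OR_planted_conditional"]) & (
        allg["OR_planted_conditional"] <= allg["ci_high"]
    )
    allg.round(4).to_csv(RESULTS / "burden_all_genes.tsv", sep="\t", index=False)

    assoc = derive_associations(results)
    assoc.write(RESULTS / "associations.tsv")

    n_path = len(assoc.pathogenic(ALL_GENES))
    n_pop = len(assoc.population(ALL_GENES))
    print(f"all-genes associations: {n_path} pathogenic, {n_pop} population, "
          f"{40 - n_path - n_pop} unassociated")
    top = allg.sort_values("OR", ascending=False).iloc[0]
    print(f"strongest pathogenic enrichment: {top['feature']} "
          f"OR={top['OR']:.1f} (planted conditional OR "
          f"{top['OR_planted_conditional']:.1f}), q={top['q']:.2e}")
    print(f"planted conditional OR inside the marginal 95% CI for "
          f"{allg['in_ci'].mean():.0%} of all-genes features")
    print("(marginal ORs attenuate toward 1 when several features act at "
          "once — odds-ratio non-collapsibility; exact recovery holds in "
          "single-feature cohorts, see the parameter-recovery test)")
    rr_or = allg.dropna(subset=["RR"])
    rr_or = rr_or[(rr_or["OR"] > 0) & (rr_or["OR"] < math.inf)]
    corr = rr_or["RR"].corr(rr_or["OR"]) ** 2
    print(f"RR vs OR concordance across features (Pearson r^2): {corr:.2f}")


if __name__ == "__main__":
    main()
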