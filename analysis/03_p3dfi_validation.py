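"""P3DFi on held-out variants: bin shift, tail purity, fitness correlation.

Scores every residue with the association sets learned from the
discovery variants, then (1) compares the P3DFi distribution of
held-out pathogenic vs benign variants (Mann–Whitney), (2) reports the
fraction of pathogenic/benign variants per index bin and in the tails
(index > 2 / < −2), and (3) correlates the per-position index with the
simulated mutagenesis fitness readout.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import pandas as pd

from common import RESULTS, study_cohort
from var3d.burden import ALL_GENES, BurdenConfig, derive_associations, run_burden
from var3d.p3dfi import (
    BIN_LABELS,
    classify_high_confidence,
    compute_p3dfi_frame,
    correlate_fitness,
    mann_whitney_two_sided,
)


def main() -> None:
    cohort = study_cohort()
    results = run_burden(
        cohort.discovery, cohort.residues, cohort.class_map,
        config=BurdenConfig(correction=1000),
    )
    assoc = derive_associations(results)
    p3 = compute_p3dfi_frame(cohort.residues, assoc, ALL_GENES)

    val = cohort.validation.merge(
        p3[["protein", "pos", "index", "bin"]], on=["protein", "pos"], how="left"
    )
    path = val[val["label"] == "pathogenic"]
    ben = val[val["label"] == "benign"]
    test = mann_whitney_two_sided(path["index"], ben["index"])

    bins = (
        val.groupby(["bin", "label"]).size().unstack(fill_value=0)
        .reindex(list(BIN_LABELS))
        .fillna(0)
        .astype(int)
    )
    bins.to_csv(RESULTS / "p3dfi_bins.tsv", sep="\t")

    val["call"] = [classify_high_confidence(i) for i in val["index"]]
    hi = val[val["call"] == "pathogenic-like"]
    lo = val[val["call"] == "benign-like"]
    fit = correlate_fitness(p3, cohort.fitness)

    summary = pd.DataFrame(
        [
            {"quantity": "mwu_u", "value": test.u},
            {"quantity": "mwu_p", "value": test.p},
            {"quantity": "mean_index_pathogenic", "value": path["index"].mean()},
            {"quantity": "mean_index_benign", "value": ben["index"].mean()},
            {"quantity": "tail_gt2_n", "value": len(hi)},
            {"quantity": "tail_gt2_frac_pathogenic",
             "value": (hi["label"] == "pathogenic").mean()},
            {"quantity": "tail_lt-2_n", "value": len(lo)},
            {"quantity": "tail_lt-2_frac_benign",
             "value": (lo["label"] == "benign").mean()},
            {"quantity": "fitness_r2", "value": fit.r2},
            {"quantity": "fitness_p", "value": fit.p},
            {"quantity": "fitness_n", "value": fit.n},
        ]
    )
    summary.to_csv(RESULTS / "p3dfi_validation.tsv", sep="\t", index=False)

    print(f"validation variants scored: {len(val):,}")
    print(f"mean P3DFi pathogenic {path['index'].mean():.2f} vs "
          f"benign {ben['index'].mean():.2f} (Mann-Whitney p = {test.p:.2e})")
    print(f"index > 2: {len(hi)} variants, "
          f"{(hi['label'] == 'pathogenic').mean():.0%} pathogenic")
    print(f"index < -2: {len(lo)} variants, "
          f"{(lo['label'] == 'benign').mean():.0%} benign")
    print(f"fitness correlation: r^2 = {fit.r2:.2f} "
          f"(p = {fit.p:.2e}, n = {fit.n:,} positions)")


if __name__ == "__main__":
    main()
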