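"""Ensemble comparison: predictor scores with and without P3DFi.

Trains three random forests (2,000 Gini trees, depth <= 10) on the
discovery variants — with the class-context P3DFi, with the all-genes
P3DFi, and without any P3DFi — and evaluates all three on the held-out
validation variants with the full metric panel plus ROC tables.

The class-context P3DFi uses, per variant, the association sets of the
gene's first annotated protein class; the all-genes variant uses the
pooled sets.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import numpy as np
import pandas as pd

from common import RESULTS, study_cohort
from var3d.burden import ALL_GENES, BurdenConfig, derive_associations, run_burden
from var3d.ensemble import (
    SCORE_COLUMNS,
    EnsembleSpec,
    binarise_labels,
    drop_missing,
    evaluate,
    roc_table,
    train,
)
from var3d.p3dfi import compute_p3dfi_frame


def main() -> None:
    cohort = study_cohort()
    results = run_burden(
        cohort.discovery, cohort.residues, cohort.class_map,
        config=BurdenConfig(correction=1000),
    )
    assoc = derive_associations(results)

    # all-genes P3DFi per residue
    p3_global = compute_p3dfi_frame(cohort.residues, assoc, ALL_GENES)
    index_global = p3_global.set_index(["protein", "pos"])["index"]

    # class-context P3DFi: each gene scored in its first annotated class
    primary = cohort.class_map.drop_duplicates("gene").set_index("gene")["class"]
    frames = []
    for cls in sorted(primary.unique()):
        genes = primary[primary == cls].index
        res_cls = cohort.residues[cohort.residues["protein"].isin(genes)]
        if cls in assoc and len(res_cls):
            frames.append(compute_p3dfi_frame(res_cls, assoc, cls))
    p3_class = pd.concat(frames, ignore_index=True)
    index_class = p3_class.set_index(["protein", "pos"])["index"]

    scored = cohort.scores.copy()
    scored["source"] = cohort.variants["source"].to_numpy()
    keys = list(zip(scored["protein"], scored["pos"]))
    scored["p3dfi_global"] = index_global.reindex(keys).to_numpy()
    scored["p3dfi_class"] = index_class.reindex(keys).to_numpy()
    scored, n_dropped = drop_missing(
        scored, SCORE_COLUMNS + ["p3dfi_global", "p3dfi_class"]
    )
    print(f"dropped {n_dropped} variants with missing scores")

    train_df = scored[scored["source"] == "discovery"]
    test_df = scored[scored["source"] == "validation"]
    spec = EnsembleSpec(seed=0)  # 2,000 trees, gini, depth 10
    feature_sets = {
        "with_class_p3dfi": SCORE_COLUMNS + ["p3dfi_class"],
        "with_global_p3dfi": SCORE_COLUMNS + ["p3dfi_global"],
        "without_p3dfi": SCORE_COLUMNS,
    }

    rows = []
    y_test = binarise_labels(test_df["label"].tolist())
    for name, feats in feature_sets.items():
        model = train(train_df, feats, spec)
        report, scores = evaluate(model, test_df)
        rows.append({"model": name, **report.to_dict()})
        roc_table(y_test, scores).round(4).to_csv(
            RESULTS / f"roc_{name}.tsv", sep="\t", index=False
        )
        print(f"{name}: MCC={report.mcc:.3f} balanced_acc="
              f"{report.balanced_accuracy:.3f} AUC={report.auc:.3f}")

    metrics = pd.DataFrame(rows).round(4)
    metrics.to_csv(RESULTS / "ensemble_metrics.tsv", sep="\t", index=False)
    best = metrics.sort_values("mcc", ascending=False).iloc[0]
    print(f"best MCC: {best['model']} ({best['mcc']:.3f}) on "
          f"{len(test_df):,} held-out variants")


if __name__ == "__main__":
    main()
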