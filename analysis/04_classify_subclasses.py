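#!/usr/bin/env python
"""Predict PVALB vs non-PVALB identity of the cohort's postsynaptic cells.

Builds a labelled Patch-seq-style reference population, harmonizes features
across recording protocols (dropping any feature whose protocol eta²
exceeds 5%), cross-validates the robust-scaling → kNN-imputation → LDA
pipeline, calibrates PVALB probabilities on the full reference, predicts
the connectivity-assay cells, embeds everything in 2-D, and correlates the
calibrated probabilities with PPR and EPSP amplitude.

Reads results/stp_metrics.csv and cohort_truth.csv; writes
results/subclass_predictions.csv, classifier_cv.json, umap_coords.csv and
probability_correlations.json.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from stpkit import (
    IntrinsicPopulationSpec,
    cross_validate,
    embed,
    fit_classifier,
    harmonize_features,
    probability_correlations,
    simulate_intrinsic_features,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 606


def main() -> None:
    truth = pd.read_csv(RESULTS / "cohort_truth.csv").set_index("connection_id")
    metrics = pd.read_csv(RESULTS / "stp_metrics.csv")
    at50 = metrics[metrics.frequency == 50.0].set_index("connection_id")

    # reference: labelled patch-seq-style population, with the protocol shift
    # that motivates harmonization; query: one cell per cohort connection
    ref_spec = IntrinsicPopulationSpec(
        n_per_class=150, missing_rate=0.05, protocol_shift={"spike_width": 3.0}
    )
    reference = simulate_intrinsic_features(ref_spec, seed=SEED)
    query_spec = IntrinsicPopulationSpec(n_per_class=len(truth))
    pool = simulate_intrinsic_features(query_spec, seed=SEED + 1)
    pool["protocol"] = "connectivity"
    rows, taken = [], {"PVALB": 0, "non-PVALB": 0}
    for cid, regime in truth["regime"].items():
        sub = "PVALB" if regime == "depressing" else "non-PVALB"
        row = pool[pool.subclass == sub].iloc[taken[sub]].copy()
        taken[sub] += 1
        row.name = cid
        rows.append(row)
    query = pd.DataFrame(rows)

    combined = pd.concat([reference, query], ignore_index=True)
    harm = harmonize_features(combined)
    dropped = sorted(set(ref_spec.feature_names) - set(harm.retained))
    print(f"harmonization: retained {len(harm.retained)} features, "
          f"excluded {dropped} (protocol eta² > {harm.threshold:.0%})")

    cv = cross_validate(reference, harm.retained, seed=SEED)
    print(f"reference CV: accuracy {cv.accuracy:.0%}, "
          f"FPR {cv.false_positive_rate:.0%}, FNR {cv.false_negative_rate:.0%}")
    (RESULTS / "classifier_cv.json").write_text(json.dumps(
        dict(accuracy=cv.accuracy, false_positive_rate=cv.false_positive_rate,
             false_negative_rate=cv.false_negative_rate, n_folds=cv.n_folds),
        indent=2) + "\n")

    clf = fit_classifier(reference, harm.retained)
    preds = clf.predict(query)
    pred_df = pd.DataFrame(
        dict(connection_id=query.index,
             pvalb_probability=[p.pvalb_probability for p in preds],
             label=[p.label for p in preds],
             true_subclass=[("PVALB" if truth.loc[c, "regime"] == "depressing"
                             else "non-PVALB") for c in query.index]),
    )
    pred_df.to_csv(RESULTS / "subclass_predictions.csv", index=False)
    certain = pred_df[pred_df.label != "uncertain"]
    agree = (certain.label == certain.true_subclass).mean()
    print(f"query predictions: {len(certain)}/{len(pred_df)} outside the "
          f"uncertain band, {agree:.0%} agree with ground truth")

    feats = query[harm.retained].copy()
    both = pd.concat(
        [reference[harm.retained].assign(dataset="patch-seq reference"),
         feats.assign(dataset="connectivity assay")], ignore_index=True)
    xy = embed(both, harm.retained, seed=SEED)
    pd.DataFrame(dict(dataset=both.dataset, umap1=xy[:, 0], umap2=xy[:, 1])).to_csv(
        RESULTS / "umap_coords.csv", index=False)

    probs = pd.Series(pred_df.pvalb_probability.to_numpy(),
                      index=pred_df.connection_id)
    corr = probability_correlations(
        probs, at50["ppr"], at50["epsp_amplitude"])
    for name, reg in corr.items():
        print(f"PVALB probability vs {name}: slope {reg.slope:+.3f}, "
              f"R² {reg.r_squared:.3f}, p = {reg.p_value:.4g}")
    (RESULTS / "probability_correlations.json").write_text(json.dumps(
        {k: dict(slope=v.slope, r_squared=v.r_squared, p=v.p_value, n=v.n)
         for k, v in corr.items()}, indent=2) + "\n")


if __name__ == "__main__":
    sys.exit(main())
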