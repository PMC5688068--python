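#!/usr/bin/env python
"""Stability selection, univariate battery and the merged marker set.

Runs the full selection protocol on both synthetic cohorts: 300
Monte-Carlo subsamples at inclusion probability 0.70, PLS-DA VIP
threshold chosen per subsample by maximizing Q2 under 7-fold CV,
out-of-subsample prediction AUCs summarized by their median and 5th
percentile; then the per-compound univariate battery (Welch t, Storey q,
oriented AUC with DeLong CI, Youden sensitivity/specificity, post-hoc
powers) and the merge rule (union of stability-selected compounds with
those passing p<0.05, q<0.1, AUC>0.50), with the multivariate arm gated
on the permutation test from step 03.

Reads scratch/synthetic/ and results/model_summary.json; writes
results/markers_<condition>.tsv, results/stability_<condition>.tsv and
results/selection_summary.json.
"""

import json
from pathlib import Path

import voclearn as vl
from voclearn.synthetic import INTERNAL_STANDARDS, default_is_mapping

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"
SEED = 20172


def main() -> None:
    model_summary = json.loads((OUT / "model_summary.json").read_text())
    truth = json.loads((OUT / "synthetic_cohorts.json").read_text())
    summary = {}
    for condition in ("alkaline", "acid"):
        table = vl.FeatureTable.read_tsv(
            ROOT / "scratch" / "synthetic" / condition / "cohort.tsv",
            internal_standards=INTERNAL_STANDARDS,
            condition=condition,
        )
        pm = vl.preprocess_pipeline(table, default_is_mapping(table.feature_ids))

        stab = vl.stability_select(
            pm, None, vl.StabilitySpec(n_subsamples=300, seed=SEED)
        )
        stab.selection_frequency.rename("selection_frequency").to_csv(
            OUT / f"stability_{condition}.tsv", sep="\t"
        )

        uni = vl.univariate_battery(pm.X_log, pm.y.to_numpy())
        model_valid = model_summary[condition]["model_valid"]
        stab_for_merge = stab if model_valid else (
            vl.StabilitySelectionResult(
                selection_frequency=stab.selection_frequency,
                auc_distribution=stab.auc_distribution,
                auc_median=stab.auc_median, auc_p5=stab.auc_p5,
                selected=set(), spec=stab.spec,
            )
        )
        markers = vl.merge_selections(stab_for_merge, uni)
        rows = uni.loc[sorted(markers.members)].round(4).reset_index()
        rows["from_multivariate"] = rows.feature_id.isin(markers.from_multivariate)
        rows["from_univariate"] = rows.feature_id.isin(markers.from_univariate)
        rows.to_csv(OUT / f"markers_{condition}.tsv", sep="\t", index=False)

        planted = set(truth[condition]["truth"])
        summary[condition] = {
            "stability_auc_median": round(stab.auc_median, 3),
            "stability_auc_p5": round(stab.auc_p5, 3),
            "n_stability_selected": len(stab.selected),
            "n_univariate_pass": len(markers.from_univariate),
            "n_markers": len(markers.members),
            "n_planted": len(planted),
            "n_planted_recovered": len(planted & markers.members),
        }
        s = summary[condition]
        print(f"{condition}: stability AUC median={s['stability_auc_median']} "
              f"p5={s['stability_auc_p5']}; markers={s['n_markers']} "
              f"(recovered {s['n_planted_recovered']}/{s['n_planted']} planted)")
    (OUT / "selection_summary.json").write_text(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
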