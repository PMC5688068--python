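#!/usr/bin/env python
"""Multivariate modeling of the two synthetic cohorts.

For each condition: preprocess (internal-standard ratio, triplicate
median, half-minimum imputation, log, autoscale), screen outliers by
Hotelling T2 / DModX at the 95% level, fit a 2-component PLS-DA model,
post-transform it to one predictive + one orthogonal component, and
validate by 7-fold cross-validation (Q2, held-out AUC) and a
199-permutation test on the class labels. The alkaline cohort carries
planted signal and should validate; the acid cohort should fail the
permutation test — the study's negative acid-condition result.

Reads scratch/synthetic/ (run 02 first); writes results/model_summary.json
and results/plsda_scores_<condition>.tsv.
"""

import json
from pathlib import Path

import pandas as pd

import voclearn as vl
from voclearn.synthetic import INTERNAL_STANDARDS, default_is_mapping

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"
SEED = 20171


def main() -> None:
    summary = {}
    for condition in ("alkaline", "acid"):
        table = vl.FeatureTable.read_tsv(
            ROOT / "scratch" / "synthetic" / condition / "cohort.tsv",
            internal_standards=INTERNAL_STANDARDS,
            condition=condition,
        )
        pm = vl.preprocess_pipeline(
            table, default_is_mapping(table.feature_ids)
        )
        X, y = pm.values(), pm.y_signed()

        screen = vl.outlier_screen(vl.fit_pca(X, 2), level=0.95)
        model = vl.fit_plsda(X, y, A=2)
        q2, cv_auc = vl.cross_validate(X, y, A=2, k=7, seed=SEED)
        perm = vl.permutation_test(X, y, A=2, n_perm=199, k=7, seed=SEED + 1)
        pt = vl.post_transform(model)

        scores = pd.DataFrame(
            {"group": pm.y, "t_pred": pt.T_pred[:, 0], "t_orth": pt.T_orth[:, 0]}
        )
        scores.to_csv(OUT / f"plsda_scores_{condition}.tsv", sep="\t", index=False)

        summary[condition] = {
            "n_subjects": int(len(y)),
            "n_features": int(X.shape[1]),
            "n_outliers_flagged": len(screen.flagged),
            "A": model.A,
            "R2Y": round(model.R2Y, 3),
            "Q2": round(q2, 3),
            "cv_auc": round(cv_auc, 3),
            "permutation_p": round(perm.p_value, 4),
            "model_valid": bool(perm.p_value < 0.05),
        }
        s = summary[condition]
        print(f"{condition}: A={s['A']} R2Y={s['R2Y']} Q2={s['Q2']} "
              f"cv AUC={s['cv_auc']} permutation p={s['permutation_p']} "
              f"-> {'validated' if s['model_valid'] else 'NOT validated'}")
    (OUT / "model_summary.json").write_text(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
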