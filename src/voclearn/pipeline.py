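"""End-to-end analysis pipeline.

Stage order: simulate/ingest -> preprocess (IS ratio, replicate median,
log, autoscale) -> PCA outlier screen -> PLS-DA with post-transformation,
cross-validation and class-permutation test -> Monte-Carlo stability
selection + univariate battery -> marker merge -> report.

The multivariate arm of the merge is gated on the permutation test: the
stability-selected features are claimed as markers only when the PLS-DA
model is significant against label permutation (as in the study, where
the acid-condition model failed the permutation test and no markers were
reported from it). The full stability frequency table is written either
way.

A run on the same config and seed is bit-reproducible: every stochastic
stage draws its seed deterministically from the run seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .multivariate import (
    choose_n_components,
    cross_validate,
    fit_pca,
    fit_plsda,
    outlier_screen,
    permutation_test,
    post_transform,
)
from .preprocess import FeatureTable, ProcessedMatrix, preprocess_pipeline
from .selection import (
    StabilitySpec,
    merge_selections,
    stability_select,
    univariate_battery,
)
from .synthetic import CohortSpec, default_is_mapping, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline run needs; loadable from YAML."""

    input_path: str | None = None          # tidy TSV; mutually exclusive with cohort
    cohort: CohortSpec | None = None       # synthetic cohort spec
    condition: str = "alkaline"
    missing_policy: str = "half_min"
    normalize_internal_standards: bool = True
    components: int | str = 2              # or "auto"
    cv_folds: int = 7
    n_permutations: int = 199
    permutation_alpha: float = 0.05
    stability: StabilitySpec = field(default_factory=StabilitySpec)
    p_max: float = 0.05
    q_max: float = 0.1
    auc_min: float = 0.50
    outlier_level: float = 0.95
    exclude_outliers: bool = False
    out_dir: str = "out"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.cohort is None):
            raise ValueError("exactly one of input_path or cohort must be given")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cohort = raw.pop("cohort", None)
        stability = raw.pop("stability", None)
        cfg = cls(
            cohort=CohortSpec(**cohort) if cohort else None,
            stability=StabilitySpec(**stability) if stability else StabilitySpec(),
            **raw,
        )
        return cfg


def _stage_seed(base: int, stage: int) -> int:
    return int(np.random.SeedSequence([base, stage]).generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the pipeline; returns the summary dict and writes outputs.

    Outputs under ``config.out_dir``: summary.json, markers.tsv,
    stability.tsv, auc_distribution.tsv, outliers.tsv, scores.tsv,
    manifest.json and log.txt. On stage failure a FAILED marker file
    names the stage and the exception is re-raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "log.txt", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("voclearn")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    stage = "setup"
    try:
        stage = "ingest"
        if config.cohort is not None:
            spec = dataclasses.replace(config.cohort, seed=_stage_seed(config.seed, 0))
            cohort = generate_cohort(spec)
            table = cohort.table
            truth = sorted(cohort.truth)
        else:
            table = FeatureTable.read_tsv(config.input_path, condition=config.condition)
            truth = None
        logger.info("ingested %d injections x %d features",
                    *table.abundances.shape)

        stage = "preprocess"
        mapping = (
            default_is_mapping(table.feature_ids)
            if config.normalize_internal_standards
            and table.is_internal_standard.any()
            else None
        )
        pm = preprocess_pipeline(table, mapping, config.missing_policy)
        X, y = pm.values(), pm.y_signed()

        stage = "outlier_screen"
        n_pca = min(2, min(X.shape[0] - 1, X.shape[1]))
        report = outlier_screen(fit_pca(X, n_pca), level=config.outlier_level)
        outliers = pd.DataFrame(
            {
                "subject": np.arange(len(report.dmodx)),
                "hotelling_t2": report.hotelling_t2,
                "dmodx": report.dmodx,
                "flagged": [i in report.flagged for i in range(len(report.dmodx))],
            }
        )
        outliers.to_csv(out / "outliers.tsv", sep="\t", index=False)
        if config.exclude_outliers and report.flagged:
            keep = np.array([i not in report.flagged for i in range(len(y))])
            logger.info("excluding %d flagged subjects", (~keep).sum())
            pm = ProcessedMatrix(
                X=pm.X.iloc[keep].reset_index(drop=True),
                y=pm.y.iloc[keep].reset_index(drop=True),
                feature_ids=pm.feature_ids,
                column_means=pm.column_means,
                column_sds=pm.column_sds,
                X_log=pm.X_log.iloc[keep].reset_index(drop=True),
            )
            X, y = pm.values(), pm.y_signed()

        stage = "plsda"
        if config.components == "auto":
            A = choose_n_components(X, y, k=config.cv_folds,
                                    seed=_stage_seed(config.seed, 1))
        else:
            A = int(config.components)
        model = fit_plsda(X, y, A=A)
        q2, cv_auc = cross_validate(X, y, A=A, k=config.cv_folds,
                                    seed=_stage_seed(config.seed, 2))
        model.Q2, model.cv_auc = q2, cv_auc
        pt = post_transform(model) if model.A >= 2 else model
        perm = permutation_test(
            X, y, A=A, n_perm=config.n_permutations, k=config.cv_folds,
            seed=_stage_seed(config.seed, 3),
        )
        scores = pd.DataFrame(
            pt.T, columns=[f"t{a + 1}" for a in range(pt.T.shape[1])]
        )
        scores.insert(0, "group", pm.y.to_numpy())
        scores.to_csv(out / "scores.tsv", sep="\t", index=False)

        stage = "stability_selection"
        stab_spec = dataclasses.replace(
            config.stability, seed=_stage_seed(config.seed, 4),
            cv_folds=config.cv_folds,
        )
        stab = stability_select(X, y, stab_spec, feature_ids=pm.feature_ids)
        pd.DataFrame(
            {"feature_id": stab.selection_frequency.index,
             "selection_frequency": stab.selection_frequency.to_numpy()}
        ).to_csv(out / "stability.tsv", sep="\t", index=False)
        pd.DataFrame({"auc": stab.auc_distribution}).to_csv(
            out / "auc_distribution.tsv", sep="\t", index=False
        )

        stage = "univariate"
        uni = univariate_battery(pm.X_log, pm.y.to_numpy())

        stage = "merge"
        model_valid = perm.p_value < config.permutation_alpha
        if not model_valid:
            logger.info(
                "PLS-DA failed the permutation test (p=%.3f); "
                "multivariate arm contributes no markers", perm.p_value,
            )
            stab_for_merge = dataclasses.replace(stab, selected=set())
        else:
            stab_for_merge = stab
        markers = merge_selections(
            stab_for_merge, uni, config.p_max, config.q_max, config.auc_min
        )
        marker_rows = uni.loc[sorted(markers.members)].reset_index()
        marker_rows["from_multivariate"] = marker_rows["feature_id"].isin(
            markers.from_multivariate
        )
        marker_rows["from_univariate"] = marker_rows["feature_id"].isin(
            markers.from_univariate
        )
        marker_rows.to_csv(out / "markers.tsv", sep="\t", index=False)

        stage = "report"
        summary = {
            "condition": table.condition,
            "n_subjects": int(len(y)),
            "n_features": int(X.shape[1]),
            "n_components": int(model.A),
            "R2Y": round(float(model.R2Y), 4),
            "Q2": round(float(q2), 4),
            "cv_auc": round(float(cv_auc), 4),
            "permutation_p": round(float(perm.p_value), 5),
            "permutation_statistic": perm.statistic,
            "model_valid": bool(model_valid),
            "n_outliers_flagged": int(len(report.flagged)),
            "stability_auc_median": round(float(stab.auc_median), 4),
            "stability_auc_p5": round(float(stab.auc_p5), 4),
            "n_markers": int(len(markers.members)),
            "markers": sorted(markers.members),
            "markers_from_multivariate": sorted(markers.from_multivariate),
            "markers_from_univariate": sorted(markers.from_univariate),
            "truth": truth,
            "seed": config.seed,
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))

        manifest = {
            "stage_order": [
                "ingest", "preprocess", "outlier_screen", "plsda",
                "stability_selection", "univariate", "merge", "report",
            ],
            "seed": config.seed,
            "version": __version__,
            "input_sha256": hashlib.sha256(
                np.ascontiguousarray(X).tobytes()
            ).hexdigest(),
            "summary_sha256": hashlib.sha256(
                json.dumps(summary, sort_keys=True).encode()
            ).hexdigest(),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return summary
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
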