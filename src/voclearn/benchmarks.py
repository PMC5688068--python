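"""Reference computations on synthetic study conditions.

Each function re-runs one headline check of the pipeline from scratch —
worked examples on the packaged tables, calibration of the permutation
test and the outlier screen on null cohorts, and recovery of planted
markers — and returns plain numbers. They are shared by the test suite
and by ``scripts/acceptance.py``.

Study conditions for the simulations: two groups of 28 and 21 subjects
(the cohort sizes), 50 features with 5 informative at a planted log-scale
effect of 2 SD for recovery runs, triplicate replicates with 15%
technical CV, all features fully present. Stability selection uses 100
Monte-Carlo subsamples here (the protocol's 300 scaled down; frequencies
are already stable at 100).
"""

from __future__ import annotations

import tempfile

import numpy as np
import pandas as pd

from .multivariate import fit_pca, outlier_screen, permutation_test
from .pipeline import RunConfig, run_pipeline
from .preprocess import GroupSummary, preprocess_pipeline, welch_t_from_summary
from .selection import StabilitySpec, stability_select
from .synthetic import CohortSpec, default_is_mapping, generate_cohort, generate_null
from .voc_tables import load_cohort_characteristics, load_marker_table, load_voc_table

RECOVERY_SPEC = dict(n_features=50, n_informative=5, effect_size=2.0)
NULL_SPEC = dict(n_features=50, n_informative=0)


def _seed(base: int, *path: int) -> int:
    return int(np.random.SeedSequence([base, *path]).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# worked examples on the packaged tables
# ---------------------------------------------------------------------------

def cohort_table_welch_pvalues() -> dict[str, float]:
    """Recompute the two-group Welch p-values from the printed summaries."""
    t1 = load_cohort_characteristics().set_index("variable")
    out = {}
    for var in ("Age (years)", "HOMA-IR"):
        r = t1.loc[var]
        g = GroupSummary(r.nw_mean, r.nw_sd, int(r.nw_n),
                         r.ow_mean, r.ow_sd, int(r.ow_n))
        out[var] = welch_t_from_summary(g)[2]
    return out


def fixture_compound_counts() -> dict[str, int]:
    return {
        "acid": len(load_voc_table("acid")),
        "alkaline": len(load_voc_table("alkaline")),
    }


def marker_gate_pass_count() -> int:
    """Rows of the printed 14-marker table passing the univariate gate
    (p < 0.05, q < 0.1, AUC > 0.50); the oriented point AUC exceeds 0.5
    for every row, so p and q decide."""
    t4 = load_marker_table()
    ok = (t4.t_p_value < 0.05) & (t4.q_value < 0.1)
    return int(ok.sum())


# ---------------------------------------------------------------------------
# calibration on null data
# ---------------------------------------------------------------------------

def _preprocessed(spec: CohortSpec):
    cohort = generate_cohort(spec)
    pm = preprocess_pipeline(
        cohort.table, default_is_mapping(cohort.table.feature_ids)
    )
    return cohort, pm


def permutation_type1_rate(
    n_cohorts: int = 200, n_perm: int = 99, base_seed: int = 0, alpha: float = 0.05
) -> float:
    """Fraction of null cohorts where the class-permutation test rejects."""
    rejections = 0
    for i in range(n_cohorts):
        spec = CohortSpec(**NULL_SPEC, seed=_seed(base_seed, 1, i))
        _, pm = _preprocessed(spec)
        res = permutation_test(
            pm.values(), pm.y_signed(), A=2, n_perm=n_perm,
            seed=_seed(base_seed, 2, i),
        )
        rejections += res.p_value <= alpha
    return rejections / n_cohorts


def outlier_flag_rate(
    n_subjects: int = 500, n_features: int = 20, n_components: int = 2,
    seed: int = 0, level: float = 0.95,
) -> float:
    """Flagged fraction of the combined T2/DModX screen on null data."""
    X = np.random.default_rng(seed).standard_normal((n_subjects, n_features))
    report = outlier_screen(fit_pca(X, n_components), level=level)
    return len(report.flagged) / n_subjects


def null_stability_auc(n_seeds: int = 10, base_seed: int = 0,
                       n_subsamples: int = 100) -> float:
    """Median out-of-subsample AUC on null cohorts (across seeds)."""
    medians = []
    for i in range(n_seeds):
        spec = CohortSpec(**NULL_SPEC, seed=_seed(base_seed, 3, i))
        _, pm = _preprocessed(spec)
        res = stability_select(
            pm, None, StabilitySpec(n_subsamples=n_subsamples,
                                    seed=_seed(base_seed, 4, i))
        )
        medians.append(res.auc_median)
    return float(np.median(medians))


# ---------------------------------------------------------------------------
# recovery of planted markers
# ---------------------------------------------------------------------------

def stability_top10_recovery(
    n_seeds: int = 50, base_seed: int = 0, n_subsamples: int = 100
) -> float:
    """Fraction of seeds where all 5 planted features rank in the top 10
    by stability-selection frequency."""
    hits = 0
    for i in range(n_seeds):
        spec = CohortSpec(**RECOVERY_SPEC, seed=_seed(base_seed, 5, i))
        cohort, pm = _preprocessed(spec)
        res = stability_select(
            pm, None, StabilitySpec(n_subsamples=n_subsamples,
                                    seed=_seed(base_seed, 6, i))
        )
        top10 = set(
            res.selection_frequency.sort_values(ascending=False).index[:10]
        )
        hits += cohort.truth <= top10
    return hits / n_seeds


def _run_once(cohort_kwargs: dict, seed: int, n_subsamples: int = 100) -> dict:
    with tempfile.TemporaryDirectory() as tmp:
        cfg = RunConfig(
            cohort=CohortSpec(**cohort_kwargs),
            components=2,
            n_permutations=99,
            stability=StabilitySpec(n_subsamples=n_subsamples),
            out_dir=tmp,
            seed=seed,
        )
        return run_pipeline(cfg)


def pipeline_marker_recovery(n_seeds: int = 50, base_seed: int = 0) -> float:
    """Fraction of seeds where the merged marker set contains all 5
    planted features."""
    hits = 0
    for i in range(n_seeds):
        summary = _run_once(RECOVERY_SPEC, _seed(base_seed, 7, i))
        hits += set(summary["truth"]) <= set(summary["markers"])
    return hits / n_seeds


def null_pipeline_empty_rate(n_seeds: int = 50, base_seed: int = 0) -> float:
    """Fraction of null-cohort runs ending with an empty marker set."""
    empty = 0
    for i in range(n_seeds):
        summary = _run_once(NULL_SPEC, _seed(base_seed, 8, i))
        empty += summary["n_markers"] == 0
    return empty / n_seeds
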