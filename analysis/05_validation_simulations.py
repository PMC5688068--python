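#!/usr/bin/env python
"""Calibration and recovery simulations for the whole pipeline.

Checks, on freshly generated cohorts (28 vs 21 subjects, 50 compounds):

* type-I error of the class-permutation test on null cohorts;
* the flag rate of the combined T2/DModX outlier screen on 500 null
  subjects at the 95% level;
* the out-of-subsample stability AUC on null cohorts (should sit near
  chance, the acid-condition analogue);
* recovery of 5 planted compounds (effect 2 log-SD) by stability
  selection (all 5 in the frequency top 10) and by the full pipeline's
  merged marker set;
* how often a null cohort ends with a non-empty marker set (the
  irreducible leak of the q<0.1 FDR gate plus the 5% permutation gate).

Problem sizes here are trimmed for a quick desk run; scripts/acceptance.py
runs the full versions. Writes results/validation_summary.json.
"""

import json
from pathlib import Path

from voclearn import benchmarks

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20173


def main() -> None:
    out = {
        "permutation_type1_rate": benchmarks.permutation_type1_rate(
            n_cohorts=100, n_perm=99, base_seed=SEED
        ),
        "outlier_flag_rate": benchmarks.outlier_flag_rate(
            n_subjects=500, seed=SEED
        ),
        "null_stability_auc_median": benchmarks.null_stability_auc(
            n_seeds=10, base_seed=SEED
        ),
        "stability_top10_recovery_rate": benchmarks.stability_top10_recovery(
            n_seeds=25, base_seed=SEED
        ),
        "pipeline_marker_recovery_rate": benchmarks.pipeline_marker_recovery(
            n_seeds=25, base_seed=SEED
        ),
        "null_pipeline_empty_rate": benchmarks.null_pipeline_empty_rate(
            n_seeds=25, base_seed=SEED
        ),
    }
    for k, v in out.items():
        print(f"{k}: {v}")
    (OUT / "validation_summary.json").write_text(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
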