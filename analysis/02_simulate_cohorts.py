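#!/usr/bin/env python
"""Generate the two synthetic study cohorts.

Emulates the study design with the generator: an alkaline-condition
cohort (83 compounds, occurrence frequencies from the identification
table, 14 planted discriminating compounds — the size of the reported
marker set — at a demonstration effect of 1.5 log-SD) and an
acid-condition cohort with no planted signal (the condition in which the
study found no group difference). Both have 28 NW and 21 OW/Ob subjects
analysed in triplicate.

Cohort tables are large and go to scratch/synthetic/ (not a deliverable);
results/synthetic_cohorts.json records their shape and truth.
"""

import json
from pathlib import Path

import voclearn as vl

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "synthetic"
OUT = ROOT / "results"
OUT.mkdir(exist_ok=True)

SEED = 20170

def main() -> None:
    info = {}
    specs = {
        "alkaline": vl.CohortSpec.from_study_tables(
            "alkaline", seed=SEED, n_informative=14, effect_size=1.5
        ),
        "acid": vl.CohortSpec.from_study_tables("acid", seed=SEED + 1),
    }
    for condition, spec in specs.items():
        cohort = (vl.generate_cohort if spec.n_informative else vl.generate_null)(spec)
        cohort.write(SCRATCH / condition)
        info[condition] = {
            "n_injections": len(cohort.table.abundances),
            "n_features": len(cohort.table.feature_ids),
            "n_informative": spec.n_informative,
            "truth": sorted(cohort.truth),
            "seed": spec.seed,
        }
        print(f"{condition}: {info[condition]['n_injections']} injections x "
              f"{info[condition]['n_features']} features "
              f"({spec.n_informative} informative) -> scratch/synthetic/{condition}/")
    (OUT / "synthetic_cohorts.json").write_text(json.dumps(info, indent=2))


if __name__ == "__main__":
    main()
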