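"""Synthetic two-group VOC cohorts.

The study's raw data are not public, so this module generates cohorts
with the statistical structure the downstream analysis assumes: two
groups of children (normal-weight vs overweight/obese), log-normal
peak-area abundances with feature-specific spread, a planted subset of
discriminating compounds whose group log-means differ, per-subject
presence/absence following per-compound occurrence frequencies,
triplicate technical replicates with multiplicative noise, and six
spiked internal-standard peaks with no group effect.

The planted group difference is applied on the log scale, before
replicate noise, so that it survives the median-of-triplicates step;
absence is encoded as a true missing mark (NaN), not zero, so the
imputation policy downstream is exercised explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocess import GROUP_NW, GROUP_OW, FeatureTable
from .voc_tables import occurrence_probabilities

#: Names of the six spiked internal standards.
INTERNAL_STANDARDS = [
    "IS_2-beta-pinene",
    "IS_2-octanone",
    "IS_4-hexen-ol",
    "IS_ethyl-nonanoate",
    "IS_trans-2-decenal",
    "IS_aniline",
]

# feature log-SD range: right-skewed GC-MS peak-area ratios typically span
# a ~1.3-2.7x geometric CV; drawn once per feature from this range.
_LOG_SD_RANGE = (0.3, 1.0)
_LOG_MEAN_RANGE = (-1.0, 2.0)
_IS_LOG_SD = 0.1


@dataclass
class CohortSpec:
    """Parameters of a synthetic two-group cohort.

    ``effect_size`` is the group log-mean shift of informative features in
    units of the feature's own log-SD (a standardized mean difference on
    the log scale). ``occurrence_probs`` may be a scalar applied to all
    features or a vector with one probability per feature.
    ``replicate_cv`` is the coefficient of variation of the multiplicative
    technical-replicate noise.
    """

    n_group1: int = 28
    n_group2: int = 21
    n_features: int = 83
    n_informative: int = 0
    effect_size: float = 0.0
    occurrence_probs: float | np.ndarray = 1.0
    n_replicates: int = 3
    replicate_cv: float = 0.15
    seed: int = 0
    condition: str = "alkaline"

    def __post_init__(self) -> None:
        for name in ("n_group1", "n_group2"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if not 0 <= self.n_informative <= self.n_features:
            raise ValueError("n_informative must lie in [0, n_features]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.replicate_cv < 0:
            raise ValueError("replicate_cv must be nonnegative")
        occ = np.atleast_1d(np.asarray(self.occurrence_probs, dtype=float))
        if occ.size == 1:
            occ = np.full(self.n_features, occ[0])
        if occ.size != self.n_features:
            raise ValueError("occurrence_probs must be scalar or length n_features")
        if np.any(occ <= 0) or np.any(occ > 1):
            raise ValueError("occurrence_probs must lie in (0, 1]")
        object.__setattr__(self, "occurrence_probs", occ)

    @classmethod
    def from_study_tables(
        cls, condition: str = "alkaline", seed: int = 0, **overrides
    ) -> "CohortSpec":
        """Cohort emulating the study conditions: n=28 NW vs 21 OW/Ob,
        110 (acid) or 83 (alkaline) compounds with occurrence frequencies
        taken from the packaged identification tables (mean of the two
        group columns, floored at one detectable subject)."""
        nw = occurrence_probabilities(condition, "NW")
        ow = occurrence_probabilities(condition, "OW/Ob")
        occ = np.clip((nw.to_numpy() + ow.to_numpy()) / 2.0, 1.0 / 25, 1.0)
        kw = dict(
            n_group1=28,
            n_group2=21,
            n_features=len(occ),
            occurrence_probs=occ,
            condition=condition,
            seed=seed,
        )
        kw.update(overrides)
        return cls(**kw)


@dataclass
class SyntheticCohort:
    """A generated cohort plus its ground truth."""

    table: FeatureTable
    truth: set[str]
    spec: CohortSpec
    effect_directions: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.truth) != self.spec.n_informative:
            raise ValueError("truth size must equal n_informative")
        if not self.truth <= set(self.table.feature_ids):
            raise ValueError("truth features must exist in the table")

    def write(self, directory) -> None:
        """Tidy TSV plus a truth sidecar (feature_id, is_informative)."""
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.table.write_tsv(d / "cohort.tsv")
        feats = [f for f in self.table.feature_ids]
        pd.DataFrame(
            {"feature_id": feats, "is_informative": [f in self.truth for f in feats]}
        ).to_csv(d / "truth.tsv", sep="\t", index=False)


def _feature_ids(n: int) -> list[str]:
    return [f"V{j + 1:03d}" for j in range(n)]


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw one cohort from the generative model; same seed, same bytes."""
    rng = np.random.default_rng(spec.seed)
    n1, n2, p = spec.n_group1, spec.n_group2, spec.n_features
    n = n1 + n2
    r = spec.n_replicates

    sigma = rng.uniform(*_LOG_SD_RANGE, size=p)
    mu = rng.uniform(*_LOG_MEAN_RANGE, size=p)
    informative = np.sort(rng.choice(p, size=spec.n_informative, replace=False))
    signs = rng.choice([-1, 1], size=spec.n_informative)

    # subject-level biological log abundances
    level = mu + sigma * rng.standard_normal((n, p))
    group2 = np.zeros(n, dtype=bool)
    group2[n1:] = True
    shift = np.zeros(p)
    shift[informative] = signs * spec.effect_size * sigma[informative]
    level[group2] += shift

    present = rng.random((n, p)) < spec.occurrence_probs

    sd_rep = np.sqrt(np.log1p(spec.replicate_cv**2))
    noise = sd_rep * rng.standard_normal((n, r, p))
    areas = np.exp(level[:, None, :] + noise)
    areas[~present[:, None, :].repeat(r, axis=1)] = np.nan

    mu_is = rng.uniform(3.0, 5.0, size=len(INTERNAL_STANDARDS))
    is_areas = np.exp(
        mu_is + _IS_LOG_SD * rng.standard_normal((n, r, len(INTERNAL_STANDARDS)))
    )

    feats = _feature_ids(p)
    cols = feats + INTERNAL_STANDARDS
    flat = np.concatenate([areas, is_areas], axis=2).reshape(n * r, len(cols))

    subjects = [f"NW{i + 1:02d}" for i in range(n1)] + [
        f"OW{i + 1:02d}" for i in range(n2)
    ]
    subject_col = np.repeat(subjects, r)
    group_col = np.repeat([GROUP_NW] * n1 + [GROUP_OW] * n2, r)
    repl_col = np.tile(np.arange(1, r + 1), n)

    table = FeatureTable(
        abundances=pd.DataFrame(flat, columns=cols),
        subject_ids=pd.Series(subject_col),
        groups=pd.Series(group_col),
        replicate_index=pd.Series(repl_col),
        is_internal_standard=pd.Series(
            [c in INTERNAL_STANDARDS for c in cols], index=cols
        ),
        condition=spec.condition,
    )
    truth = {feats[j] for j in informative}
    directions = {feats[j]: int(s) for j, s in zip(informative, signs)}
    return SyntheticCohort(table=table, truth=truth, spec=spec, effect_directions=directions)


def generate_null(spec: CohortSpec) -> SyntheticCohort:
    """As :func:`generate_cohort` with no informative features (empty truth)."""
    return generate_cohort(replace(spec, n_informative=0, effect_size=0.0))


def default_is_mapping(feature_ids: list[str]) -> dict[str, str]:
    """Round-robin assignment of metabolites to the six internal standards.

    The study normalizes each metabolite to "the related internal
    standard" without stating the mapping; any fixed assignment exercises
    the ratio step, and the standards carry no group signal.
    """
    metabolites = [f for f in feature_ids if f not in INTERNAL_STANDARDS]
    return {
        f: INTERNAL_STANDARDS[i % len(INTERNAL_STANDARDS)]
        for i, f in enumerate(metabolites)
    }
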