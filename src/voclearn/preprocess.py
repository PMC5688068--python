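"""Preprocessing of SPME GC-MS peak-area tables.

The analysis-ready matrix is produced by a fixed chain:

    internal-standard ratio -> median of technical replicates
        -> missing-value imputation -> natural log -> autoscaling

Also provides small clinical/chromatographic utilities used around the
feature table: Kovats retention indices, the HOMA-IR insulin-resistance
index, and a Welch t-test computed from printed summary statistics
(mean +/- SD and n per group), as needed to recompute two-group p-values
from a cohort characteristics table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Canonical group labels: normal-weight and overweight/obese children.
GROUP_NW = "NW"
GROUP_OW = "OW/Ob"

_META_COLS = ["subject_id", "group", "replicate"]


class NormalizationError(ValueError):
    """Raised when an internal-standard peak is missing or nonpositive."""


@dataclass
class FeatureTable:
    """Injection-level VOC peak areas with replicate and group structure.

    Parameters
    ----------
    abundances
        DataFrame of shape (injections, features); NaN marks an absent
        peak (the compound was not detected in that injection), never a
        numeric zero.
    subject_ids, groups, replicate_index
        Per-injection metadata, aligned with ``abundances`` rows.
    is_internal_standard
        Boolean Series indexed by feature id; True for spiked standards.
    condition
        Sample-preparation pH condition, ``"acid"`` or ``"alkaline"``.
    """

    abundances: pd.DataFrame
    subject_ids: pd.Series
    groups: pd.Series
    replicate_index: pd.Series
    is_internal_standard: pd.Series
    condition: str = "alkaline"

    def __post_init__(self) -> None:
        n = len(self.abundances)
        for name in ("subject_ids", "groups", "replicate_index"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match abundances")
        vals = self.abundances.to_numpy(dtype=float)
        if np.nanmin(vals, initial=np.inf) < 0:
            raise ValueError("abundances must be nonnegative")
        levels = pd.unique(self.groups)
        if len(levels) != 2:
            raise ValueError(f"expected exactly two group levels, got {list(levels)}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.abundances.columns)

    def to_tidy(self) -> pd.DataFrame:
        """Tidy TSV layout: subject_id, group, replicate, then features."""
        meta = pd.DataFrame(
            {
                "subject_id": self.subject_ids.to_numpy(),
                "group": self.groups.to_numpy(),
                "replicate": self.replicate_index.to_numpy(),
            }
        )
        return pd.concat([meta, self.abundances.reset_index(drop=True)], axis=1)

    def write_tsv(self, path) -> None:
        self.to_tidy().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tidy(
        cls,
        df: pd.DataFrame,
        internal_standards: list[str] | None = None,
        condition: str = "alkaline",
    ) -> "FeatureTable":
        missing = [c for c in _META_COLS if c not in df.columns]
        if missing:
            raise ValueError(f"tidy table lacks metadata columns {missing}")
        feats = [c for c in df.columns if c not in _META_COLS]
        is_std = pd.Series(
            [f in set(internal_standards or []) for f in feats], index=feats
        )
        return cls(
            abundances=df[feats].astype(float).reset_index(drop=True),
            subject_ids=df["subject_id"].reset_index(drop=True),
            groups=df["group"].reset_index(drop=True),
            replicate_index=df["replicate"].reset_index(drop=True),
            is_internal_standard=is_std,
            condition=condition,
        )

    @classmethod
    def read_tsv(cls, path, internal_standards=None, condition="alkaline"):
        return cls.from_tidy(
            pd.read_csv(path, sep="\t"), internal_standards, condition
        )


@dataclass
class ProcessedMatrix:
    """Subject-level autoscaled log matrix ready for PCA / PLS-DA.

    ``X`` holds autoscaled natural-log abundances; ``X_log`` keeps the
    log-transformed but unscaled values, which the univariate t-test
    battery uses (the t statistic is invariant to the scaling anyway,
    but log-scale values are interpretable).
    """

    X: pd.DataFrame
    y: pd.Series
    feature_ids: list[str]
    column_means: np.ndarray
    column_sds: np.ndarray
    X_log: pd.DataFrame | None = None
    dropped_features: list[str] = field(default_factory=list)

    def values(self) -> np.ndarray:
        return self.X.to_numpy(dtype=float)

    def y_signed(self, positive: str = GROUP_OW) -> np.ndarray:
        """Class response encoded +1 for ``positive``, -1 otherwise."""
        return np.where(self.y.to_numpy() == positive, 1.0, -1.0)


@dataclass
class GroupSummary:
    """Two-group summary statistics as printed in cohort tables (M +/- SD)."""

    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int

    def __post_init__(self) -> None:
        if self.sd1 < 0 or self.sd2 < 0:
            raise ValueError("standard deviations must be nonnegative")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("each group needs n >= 2")


# ---------------------------------------------------------------------------
# preprocessing chain
# ---------------------------------------------------------------------------

def normalize_to_internal_standard(
    table: FeatureTable, mapping: dict[str, str]
) -> FeatureTable:
    """Divide each metabolite peak by its internal standard within injection.

    ``mapping`` sends every non-standard feature id to one of the spiked
    internal standards. Standard columns are dropped from the result.
    Missing metabolite peaks stay missing; a missing or nonpositive
    standard peak is an error naming the injection and the standard.
    """
    std_ids = [f for f in table.feature_ids if table.is_internal_standard.get(f, False)]
    metabolites = [f for f in table.feature_ids if f not in std_ids]
    unmapped = [f for f in metabolites if f not in mapping]
    if unmapped:
        raise NormalizationError(f"features without an internal-standard mapping: {unmapped[:5]}")
    bad_targets = sorted({mapping[f] for f in metabolites} - set(std_ids))
    if bad_targets:
        raise NormalizationError(f"mapping targets are not internal standards: {bad_targets}")

    for s in std_ids:
        col = table.abundances[s].to_numpy(dtype=float)
        bad = np.where(~(col > 0))[0]
        if bad.size:
            raise NormalizationError(
                f"internal standard {s!r} missing or nonpositive in injection {bad[0]}"
            )

    ratios = {}
    for f in metabolites:
        ratios[f] = table.abundances[f] / table.abundances[mapping[f]]
    out = pd.DataFrame(ratios, columns=metabolites)
    return replace(
        table,
        abundances=out,
        is_internal_standard=pd.Series(False, index=metabolites),
    )


def collapse_replicates(table: FeatureTable) -> FeatureTable:
    """Median over technical replicates; one row per subject.

    A cell is missing in the output iff all of the subject's replicate
    values are missing. Idempotent: collapsing a collapsed table is the
    identity. Subject order follows first appearance.
    """
    subj = table.subject_ids.to_numpy()
    order = pd.unique(subj)
    tidy = table.abundances.copy()
    tidy["_subject"] = subj
    med = tidy.groupby("_subject", sort=False).median()
    med = med.loc[order]

    group_of = dict(zip(subj, table.groups.to_numpy()))
    return replace(
        table,
        abundances=med.reset_index(drop=True),
        subject_ids=pd.Series(order),
        groups=pd.Series([group_of[s] for s in order]),
        replicate_index=pd.Series(np.ones(len(order), dtype=int)),
    )


def log_autoscale(
    table: FeatureTable, missing_policy: str = "half_min"
) -> ProcessedMatrix:
    """Impute, natural-log transform and autoscale a subject-level table.

    missing_policy:
      * ``half_min`` — impute missing cells with half the feature's
        minimum observed value (the usual GC-MS detection-floor
        convention for absent peaks);
      * ``drop_feature`` — drop any feature with missing cells.

    Features missing in every subject, and features with zero variance
    after the log transform, are dropped with a logged warning.
    Autoscaling uses the sample SD (n-1 denominator).
    """
    if missing_policy not in ("half_min", "drop_feature"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    if table.subject_ids.duplicated().any():
        raise ValueError("collapse replicates before log_autoscale (duplicate subjects)")

    A = table.abundances.copy()
    dropped: list[str] = []

    all_missing = [f for f in A.columns if A[f].isna().all()]
    if all_missing:
        logger.warning("dropping features missing in all subjects: %s", all_missing)
        dropped += all_missing
        A = A.drop(columns=all_missing)

    if missing_policy == "drop_feature":
        some_missing = [f for f in A.columns if A[f].isna().any()]
        if some_missing:
            logger.warning("drop_feature policy removing %d features", len(some_missing))
            dropped += some_missing
            A = A.drop(columns=some_missing)
    else:
        for f in A.columns:
            col = A[f]
            if col.isna().any():
                A[f] = col.fillna(col.min() / 2.0)

    if (A.to_numpy() <= 0).any():
        raise ValueError("log transform requires strictly positive abundances")
    L = np.log(A)

    sds = L.std(axis=0, ddof=1)
    constant = list(L.columns[(sds == 0) | sds.isna()])
    if constant:
        logger.warning("dropping zero-variance features: %s", constant)
        dropped += constant
        L = L.drop(columns=constant)
        sds = sds.drop(constant)

    means = L.mean(axis=0)
    Z = (L - means) / sds
    return ProcessedMatrix(
        X=Z,
        y=table.groups.copy().reset_index(drop=True),
        feature_ids=list(Z.columns),
        column_means=means.to_numpy(),
        column_sds=sds.to_numpy(),
        X_log=L,
        dropped_features=dropped,
    )


def preprocess_pipeline(
    table: FeatureTable,
    mapping: dict[str, str] | None = None,
    missing_policy: str = "half_min",
) -> ProcessedMatrix:
    """Full chain: IS ratio (if a mapping is given) -> median -> log/autoscale."""
    if mapping is not None:
        table = normalize_to_internal_standard(table, mapping)
    table = collapse_replicates(table)
    return log_autoscale(table, missing_policy=missing_policy)


# ---------------------------------------------------------------------------
# chromatographic / clinical utilities
# ---------------------------------------------------------------------------

def kovats_index(
    rt: float, alkane_rts: dict[int, float], mode: str = "linear"
) -> float:
    """Retention index of a peak against a C8-C20 n-alkane ladder.

    ``linear`` is the van den Dool & Kratz form for temperature-programmed
    runs; ``logarithmic`` is the original isothermal Kovats form (log
    retention times). Both return 100*n at an alkane's own retention time.
    """
    if mode not in ("linear", "logarithmic"):
        raise ValueError(f"unknown mode {mode!r}")
    carbons = sorted(alkane_rts)
    if carbons[0] < 8 or carbons[-1] > 20 or carbons != list(range(carbons[0], carbons[-1] + 1)):
        raise ValueError("alkane carbon numbers must be contiguous within 8..20")
    rts = np.array([alkane_rts[c] for c in carbons], dtype=float)
    if not np.all(np.diff(rts) > 0):
        raise ValueError("alkane retention times must be strictly increasing")
    if not (rts[0] <= rt <= rts[-1]):
        raise ValueError(f"retention time {rt} outside alkane window [{rts[0]}, {rts[-1]}]")

    i = int(np.searchsorted(rts, rt, side="right") - 1)
    i = min(i, len(carbons) - 2)
    n, rt_n, rt_n1 = carbons[i], rts[i], rts[i + 1]
    if mode == "linear":
        frac = (rt - rt_n) / (rt_n1 - rt_n)
    else:
        frac = (np.log(rt) - np.log(rt_n)) / (np.log(rt_n1) - np.log(rt_n))
    return 100.0 * (n + frac)


def homa_ir(insulin_mU_L: float, glucose_mmol_L: float) -> float:
    """HOMA-IR = insulin (mU/L) x glucose (mmol/L) / 22.5."""
    if insulin_mU_L <= 0 or glucose_mmol_L <= 0:
        raise ValueError("insulin and glucose must be positive")
    return insulin_mU_L * glucose_mmol_L / 22.5


def welch_t_from_summary(g: GroupSummary) -> tuple[float, float, float]:
    """Welch two-sample t-test from group means, SDs and sizes.

    Returns (t, Welch-Satterthwaite df, two-sided p).
    """
    v1, v2 = g.sd1**2 / g.n1, g.sd2**2 / g.n2
    se = np.sqrt(v1 + v2)
    if se == 0:
        raise ValueError("both group SDs are zero")
    t = (g.mean1 - g.mean2) / se
    df = (v1 + v2) ** 2 / (v1**2 / (g.n1 - 1) + v2**2 / (g.n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)
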