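"""Variable selection: Monte-Carlo stability selection around PLS-DA VIP,
and the univariate t / FDR / ROC battery with post-hoc power.

Stability selection repeatedly (default 300 times) draws a random
subsample of subjects (each included independently with probability
0.70), fits a PLS-DA model on the subsample, picks the VIP threshold
that maximizes Q2 under 7-fold cross-validation restricted to the
surviving features, records which features survive, and scores the
excluded subjects with the reduced model to accumulate an
out-of-subsample prediction AUC per subsample. Features are ranked by
selection frequency; the AUC distribution (median, 5th percentile)
estimates predictive power.

The univariate battery computes, per compound on log-scale values:
Welch t-test p, Storey q-value, oriented Mann-Whitney AUC with DeLong
95% CI, sensitivity/specificity at the Youden-optimal cutpoint, and
post-hoc powers for the t-test and the ROC test. The marker set is the
union of the stability-selected compounds and those passing the
univariate gate (p < 0.05, q < 0.1, AUC > 0.50).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate, stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.power import TTestIndPower

from .multivariate import (
    _auc_from_scores,
    _encode_y,
    _pls1,
    cross_validate,
    fit_plsda,
)
from .preprocess import GROUP_NW, GROUP_OW, GroupSummary, ProcessedMatrix

logger = logging.getLogger(__name__)

DEFAULT_VIP_GRID = (0.8, 0.9, 1.0, 1.1, 1.2, 1.5)


# ---------------------------------------------------------------------------
# stability selection
# ---------------------------------------------------------------------------

@dataclass
class StabilitySpec:
    """Monte-Carlo stability-selection parameters.

    ``inclusion_prob`` is the prior probability with which each subject
    enters a subsample; the study protocol uses 300 subsamples at 0.70
    with the VIP threshold chosen by Q2 maximization under 7-fold CV.
    ``frequency_cutoff`` converts frequencies into a selected set; the
    full frequency vector is always reported alongside.
    """

    n_subsamples: int = 300
    inclusion_prob: float = 0.70
    vip_threshold_grid: tuple = DEFAULT_VIP_GRID
    cv_folds: int = 7
    frequency_cutoff: float = 0.5
    n_components: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.inclusion_prob < 1:
            if not (self.inclusion_prob == 1.0 and self.n_subsamples == 1):
                raise ValueError("inclusion_prob must lie in (0, 1)")
        if self.n_subsamples < 1:
            raise ValueError("n_subsamples must be >= 1")
        if self.n_subsamples < 10 and self.n_subsamples != 1:
            warnings.warn("fewer than 10 subsamples gives unstable frequencies")
        if len(self.vip_threshold_grid) == 0:
            raise ValueError("vip_threshold_grid must be nonempty")


@dataclass
class StabilitySelectionResult:
    selection_frequency: pd.Series       # per feature, in [0, 1]
    auc_distribution: np.ndarray         # one out-of-subsample AUC per usable draw
    auc_median: float
    auc_p5: float
    selected: set
    spec: StabilitySpec
    n_skipped_auc: int = 0


def stability_select(
    X, y, spec: StabilitySpec, feature_ids: list[str] | None = None
) -> StabilitySelectionResult:
    """Run Monte-Carlo stability selection on an autoscaled matrix."""
    if isinstance(X, ProcessedMatrix):
        feature_ids = X.feature_ids
        y = X.y_signed()
        X = X.values()
    X = np.asarray(X, dtype=float)
    yv = _encode_y(y)
    n, p = X.shape
    if feature_ids is None:
        feature_ids = [f"f{j}" for j in range(p)]
    grid = np.asarray(spec.vip_threshold_grid, dtype=float)
    rng = np.random.default_rng(spec.seed)

    counts = np.zeros(p)
    aucs: list[float] = []
    n_skipped = 0
    for b in range(spec.n_subsamples):
        include = _draw_subsample(yv, spec.inclusion_prob, rng)
        Xb, yb = X[include], yv[include]
        selected_b = _select_by_vip_q2(
            Xb, yb, grid, spec.n_components, spec.cv_folds, rng
        )
        counts[selected_b] += 1

        exclude = ~include
        if exclude.any() and len(np.unique(yv[exclude])) == 2:
            scores = _fit_predict(Xb[:, selected_b], yb, X[exclude][:, selected_b],
                                  spec.n_components)
            aucs.append(_auc_from_scores(scores, yv[exclude] > 0))
        else:
            n_skipped += 1
            if exclude.any():
                logger.info("subsample %d: excluded set lacks a class, no AUC", b)
            else:
                logger.info("subsample %d: no excluded subjects, no AUC", b)

    freq = pd.Series(counts / spec.n_subsamples, index=feature_ids)
    auc_arr = np.asarray(aucs)
    if auc_arr.size == 0:
        warnings.warn("no out-of-subsample AUC could be computed")
        med = p5 = float("nan")
    else:
        med = float(np.median(auc_arr))
        p5 = float(np.percentile(auc_arr, 5))
    selected = set(freq.index[freq >= spec.frequency_cutoff])
    return StabilitySelectionResult(
        selection_frequency=freq,
        auc_distribution=auc_arr,
        auc_median=med,
        auc_p5=p5,
        selected=selected,
        spec=spec,
        n_skipped_auc=n_skipped,
    )


def _draw_subsample(y: np.ndarray, prob: float, rng) -> np.ndarray:
    """Bernoulli subject inclusion; redrawn (logged) until both classes
    appear at least twice among the included subjects."""
    for attempt in range(1000):
        include = rng.random(len(y)) < prob
        if include.sum() >= 4 and min(
            np.sum(y[include] > 0), np.sum(y[include] < 0)
        ) >= 2:
            if attempt:
                logger.info("subsample redrawn %d time(s)", attempt)
            return include
    raise RuntimeError("could not draw a subsample containing both classes")


def _select_by_vip_q2(Xb, yb, grid, A, k, rng) -> np.ndarray:
    """Feature mask from the VIP threshold maximizing Q2 under k-fold CV.

    Ties prefer the larger threshold (fewer features). Thresholds keeping
    no feature score -inf; if every threshold does, the full model's
    top-VIP feature is kept as a fallback.
    """
    mu = Xb.mean(axis=0)
    sd = Xb.std(axis=0, ddof=1)
    sd[sd < 1e-12] = 1.0
    Xs = (Xb - mu) / sd
    model = fit_plsda(Xs, yb, A=A)
    vip = model.vip
    kk = min(k, len(yb))
    best_q2 = -np.inf
    best_mask = None
    for thr in sorted(grid, reverse=True):
        mask = vip >= thr
        if not mask.any():
            continue
        q2 = cross_validate(Xb[:, mask], yb, A=A, k=kk,
                            seed=np.random.default_rng(rng.integers(2**31)))[0]
        if q2 > best_q2:
            best_q2, best_mask = q2, mask
    if best_mask is None:
        best_mask = vip >= vip.max()
    return np.where(best_mask)[0]


def _fit_predict(Xtr, ytr, Xte, A) -> np.ndarray:
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0, ddof=1)
    sd[sd < 1e-12] = 1.0
    ym = ytr.mean()
    W, P, T, c, ssy, a_eff = _pls1((Xtr - mu) / sd, ytr - ym, A)
    if a_eff == 0:
        return np.full(len(Xte), ym)
    B = W @ np.linalg.solve(P.T @ W, c)
    return ((Xte - mu) / sd) @ B + ym


# ---------------------------------------------------------------------------
# univariate battery
# ---------------------------------------------------------------------------

def feature_auc(values: np.ndarray, labels, positive: str | float = GROUP_OW):
    """Oriented Mann-Whitney AUC of a single feature.

    Returns ``(auc, direction)`` with ``auc >= 0.5`` and ``direction``
    naming which class has the higher values (ties counted 1/2). Missing
    values are excluded pairwise (the label is dropped with the value).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    keep = ~np.isnan(values)
    values, labels = values[keep], labels[keep]
    pos = labels == positive
    if pos.all() or not pos.any():
        raise ValueError("both classes must be present")
    auc = _auc_from_scores(values, pos)
    neg_label = labels[~pos][0]
    if auc >= 0.5:
        return auc, f"{positive}>{neg_label}"
    return 1.0 - auc, f"{neg_label}>{positive}"


def auc_ci(
    values,
    labels,
    positive: str | float = GROUP_OW,
    level: float = 0.95,
    method: str = "delong",
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Confidence interval for the oriented AUC.

    ``delong`` (default) uses the DeLong placement-value variance with a
    normal interval, clipped to [0, 1]; ``bootstrap`` is a seeded
    percentile bootstrap over subjects. A degenerate DeLong variance
    (e.g. complete separation) falls back to the bootstrap with a warning.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    keep = ~np.isnan(values)
    values, labels = values[keep], labels[keep]
    pos = labels == positive
    if pos.sum() < 3 or (~pos).sum() < 3:
        raise ValueError("need at least 3 subjects per class")
    raw = _auc_from_scores(values, pos)
    auc = raw if raw >= 0.5 else 1.0 - raw
    oriented = values if raw >= 0.5 else -values

    if method == "delong":
        var = _delong_variance(oriented[pos], oriented[~pos])
        if var > 0:
            z = stats.norm.ppf(0.5 + level / 2)
            half = z * np.sqrt(var)
            return max(0.0, auc - half), min(1.0, auc + half)
        warnings.warn("degenerate DeLong variance; falling back to bootstrap")
        method = "bootstrap"
    if method != "bootstrap":
        raise ValueError(f"unknown method {method!r}")

    rng = np.random.default_rng(seed)
    ip, ineg = np.where(pos)[0], np.where(~pos)[0]
    boots = np.empty(n_boot)
    for b in range(n_boot):
        sp = rng.choice(ip, size=len(ip), replace=True)
        sn = rng.choice(ineg, size=len(ineg), replace=True)
        r = stats.rankdata(np.concatenate([oriented[sp], oriented[sn]]))
        n1 = len(sp)
        boots[b] = (r[:n1].sum() - n1 * (n1 + 1) / 2) / (n1 * len(sn))
    lo, hi = np.percentile(boots, [(1 - level) / 2 * 100, (1 + level) / 2 * 100])
    return float(max(0.0, lo)), float(min(1.0, hi))


def _delong_variance(pos_vals: np.ndarray, neg_vals: np.ndarray) -> float:
    """DeLong AUC variance via midrank placement values."""
    m, n = len(pos_vals), len(neg_vals)
    allv = np.concatenate([pos_vals, neg_vals])
    r_all = stats.rankdata(allv)
    r_pos = stats.rankdata(pos_vals)
    r_neg = stats.rankdata(neg_vals)
    v10 = (r_all[:m] - r_pos) / n            # placements of positives
    v01 = 1.0 - (r_all[m:] - r_neg) / m      # placements of negatives
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def sens_spec_at_youden(values, labels, positive: str | float = GROUP_OW):
    """Sensitivity/specificity at the cutpoint maximizing Youden's J.

    Values are oriented so the positive class tends higher; candidate
    cutpoints are the observed values plus one above the maximum
    (predict positive iff oriented value >= cutpoint). Ties in J break
    toward higher specificity. Returns (sens, spec, cutpoint) with the
    cutpoint on the oriented scale.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    keep = ~np.isnan(values)
    values, labels = values[keep], labels[keep]
    pos = labels == positive
    if not pos.any() or pos.all():
        raise ValueError("both classes must be present")
    raw = _auc_from_scores(values, pos)
    oriented = values if raw >= 0.5 else -values

    cuts = np.unique(oriented)
    cuts = np.append(cuts, cuts[-1] + 1.0)
    best = (-np.inf, -np.inf, np.nan, np.nan, np.nan)  # (J, spec, sens, spec, cut)
    n_pos, n_neg = pos.sum(), (~pos).sum()
    for cut in cuts:
        pred_pos = oriented >= cut
        sens = np.sum(pred_pos & pos) / n_pos
        spec = np.sum(~pred_pos & ~pos) / n_neg
        j = sens + spec - 1.0
        if (j, spec) > (best[0], best[1]):
            best = (j, spec, sens, spec, cut)
    return float(best[2]), float(best[3]), float(best[4])


def q_values(p: np.ndarray, method: str = "storey") -> np.ndarray:
    """False-discovery-rate q-values.

    ``storey``: Storey's estimator with the smoother pi0 estimate (cubic
    smoothing spline of pi0(lambda) over lambda = 0.05..0.95, evaluated
    at the largest lambda, clipped to (0, 1]); ``bh``: Benjamini-Hochberg
    adjusted p-values. Both are monotone non-decreasing in p.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    if method != "storey":
        raise ValueError(f"unknown method {method!r}")

    lam = np.arange(0.05, 0.96, 0.05)
    pi0_lam = np.array([np.mean(p > l) / (1.0 - l) for l in lam])
    if np.all(pi0_lam == 0):
        pi0 = 1.0 / m
    else:
        spline = interpolate.UnivariateSpline(lam, pi0_lam, k=3)
        pi0 = float(spline(lam[-1]))
        pi0 = min(1.0, max(pi0, 1.0 / m))

    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q_ord = pi0 * ranked * m / np.arange(1, m + 1)
    q_ord = np.minimum.accumulate(q_ord[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_ord, 1.0)
    return q


def power_t(g: GroupSummary, alpha: float = 0.05) -> float:
    """Post-hoc power of the two-sample t-test at the observed effect.

    Uses the pooled standardized difference d and the noncentral-t
    formulation (via statsmodels); at d = 0 the power equals alpha.
    """
    sp2 = ((g.n1 - 1) * g.sd1**2 + (g.n2 - 1) * g.sd2**2) / (g.n1 + g.n2 - 2)
    if sp2 <= 0:
        raise ValueError("zero pooled standard deviation")
    d = abs(g.mean1 - g.mean2) / np.sqrt(sp2)
    if d == 0:
        return alpha
    return float(
        TTestIndPower().power(
            effect_size=d, nobs1=g.n1, ratio=g.n2 / g.n1, alpha=alpha,
            alternative="two-sided",
        )
    )


def power_roc(auc: float, n1: int, n2: int, alpha: float = 0.05) -> float:
    """Power of the two-sided test of H0: AUC = 0.5 at the observed AUC.

    Normal approximation with the Mann-Whitney null variance
    (n1+n2+1)/(12 n1 n2) and the Hanley-McNeil variance at the
    alternative. Monotone increasing in AUC and in min(n1, n2).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per class")
    if auc <= 0.5:
        warnings.warn("AUC <= 0.5: power equals the significance level")
        return alpha
    if auc > 1:
        raise ValueError("AUC cannot exceed 1")
    v0 = (n1 + n2 + 1) / (12.0 * n1 * n2)
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    va = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n2 - 1) * (q2 - auc**2)) / (
        n1 * n2
    )
    va = max(va, 1e-12)
    za = stats.norm.ppf(1 - alpha / 2)
    delta = auc - 0.5
    upper = stats.norm.sf((za * np.sqrt(v0) - delta) / np.sqrt(va))
    lower = stats.norm.cdf((-za * np.sqrt(v0) - delta) / np.sqrt(va))
    return float(upper + lower)


def univariate_battery(
    X_log: pd.DataFrame,
    y,
    positive: str = GROUP_OW,
    q_method: str = "storey",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-feature t / q / ROC statistics on log-scale subject values.

    The Welch t-test runs on log-transformed (pre-autoscaling) values;
    the t statistic is invariant to the global autoscaling, so this only
    fixes the interpretable scale. Returns one row per feature with
    columns direction, auc, auc_ci_low/high, power_roc, specificity,
    sensitivity, t_p_value, power_t, q_value.
    """
    y = np.asarray(y)
    pos = y == positive
    if not pos.any() or pos.all():
        raise ValueError(f"positive class {positive!r} must be one of two levels")
    n1, n2 = int(pos.sum()), int((~pos).sum())
    rows = []
    for f in X_log.columns:
        v = X_log[f].to_numpy(dtype=float)
        auc, direction = feature_auc(v, y, positive)
        lo, hi = auc_ci(v, y, positive)
        sens, spec, _ = sens_spec_at_youden(v, y, positive)
        t, pval = stats.ttest_ind(v[pos], v[~pos], equal_var=False, nan_policy="omit")
        g = GroupSummary(
            mean1=np.nanmean(v[pos]), sd1=np.nanstd(v[pos], ddof=1), n1=n1,
            mean2=np.nanmean(v[~pos]), sd2=np.nanstd(v[~pos], ddof=1), n2=n2,
        )
        rows.append(
            dict(
                feature_id=f, direction=direction, auc=auc,
                auc_ci_low=lo, auc_ci_high=hi,
                power_roc=power_roc(auc, n1, n2, alpha) if auc > 0.5 else alpha,
                specificity=spec, sensitivity=sens,
                t_p_value=float(pval), power_t=power_t(g, alpha),
            )
        )
    out = pd.DataFrame(rows).set_index("feature_id")
    out["q_value"] = q_values(out["t_p_value"].to_numpy(), method=q_method)
    return out


# ---------------------------------------------------------------------------
# merge rule
# ---------------------------------------------------------------------------

@dataclass
class MarkerSet:
    """Putative markers: union of the multivariate and univariate arms."""

    members: set
    from_multivariate: set
    from_univariate: set
    directions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.members == self.from_multivariate | self.from_univariate


def univariate_pass(
    uni: pd.DataFrame,
    p_max: float = 0.05,
    q_max: float = 0.1,
    auc_min: float = 0.50,
) -> set:
    """Features passing the significance gate: p < p_max, q < q_max, AUC > auc_min."""
    ok = (
        (uni["t_p_value"] < p_max)
        & (uni["q_value"] < q_max)
        & (uni["auc"] > auc_min)
    )
    return set(uni.index[ok])


def merge_selections(
    stab: StabilitySelectionResult,
    uni: pd.DataFrame,
    p_max: float = 0.05,
    q_max: float = 0.1,
    auc_min: float = 0.50,
) -> MarkerSet:
    """Union of stability-selected features and the univariate gate."""
    stab_features = set(stab.selection_frequency.index)
    if stab_features != set(uni.index):
        raise ValueError("stability and univariate results cover different features")
    from_uni = univariate_pass(uni, p_max, q_max, auc_min)
    from_multi = set(stab.selected)
    members = from_multi | from_uni
    directions = {f: uni.loc[f, "direction"] for f in members}
    return MarkerSet(
        members=members,
        from_multivariate=from_multi,
        from_univariate=from_uni,
        directions=directions,
    )
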