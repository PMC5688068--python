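"""PCA outlier screening and post-transformed PLS-DA with VIP.

The discriminant model is single-response PLS (PLS1) on a centered
class response encoded +1/-1, fitted by NIPALS with X-block deflation.
Model quality is summarized by R2Y (explained class variance), Q2
(R2Y on pooled 7-fold cross-validated predictions) and the AUC of the
held-out continuous predictions; significance is assessed by a
permutation test on the class labels with the full cross-validation
pipeline re-run inside every permutation.

Post-transformation rotates the fitted score/weight space so that one
component carries all covariance with the class response and the
remaining components are class-orthogonal; fitted values and the
regression vector are unchanged. This mirrors the predictive/orthogonal
decomposition used in the chemometrics literature (Stocchero-Paris
post-transformation of PLS models).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

_TOL = 1e-12


# ---------------------------------------------------------------------------
# PCA and outlier screening
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    loadings: np.ndarray          # (features, components), orthonormal
    scores: np.ndarray            # (subjects, components)
    eigenvalues: np.ndarray       # score variances, non-increasing
    n_components: int
    residual_matrix: np.ndarray   # X - T P'
    mean_: np.ndarray
    n_samples: int
    n_features: int


@dataclass
class OutlierReport:
    hotelling_t2: np.ndarray
    t2_limit: float
    dmodx: np.ndarray
    dmodx_limit: float
    flagged: set
    level: float


def fit_pca(X: np.ndarray, n_components: int) -> PCAModel:
    """PCA by SVD of the column-centered matrix.

    Scores are ``X_c @ loadings``; eigenvalues are score variances
    (singular values squared over n-1). A request beyond the matrix rank
    is truncated with a warning.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size else 0
    if n_components > rank:
        warnings.warn(
            f"requested {n_components} components exceeds rank {rank}; truncating"
        )
        n_components = rank
    L = Vt[:n_components].T
    T = Xc @ L
    eig = s[:n_components] ** 2 / (n - 1)
    return PCAModel(
        loadings=L,
        scores=T,
        eigenvalues=eig,
        n_components=n_components,
        residual_matrix=Xc - T @ L.T,
        mean_=mean,
        n_samples=n,
        n_features=p,
    )


def outlier_screen(model: PCAModel, level: float = 0.95) -> OutlierReport:
    """Hotelling T2 (within-model) and DModX (residual) outlier tests.

    ``level`` is the family confidence level of the combined screen; the
    two statistics are tested at the Sidak-split level
    ``1 - sqrt(1 - alpha)`` each so that on null data the union of the
    two tests flags ~``1 - level`` of observations.

    Formulas (documented here because the exact convention is
    software-lineage-dependent):

    * ``T2_i = sum_a t_ia^2 / lambda_a`` with limit
      ``A (n-1)(n+1) / (n (n-A)) * F_{1-a'}(A, n-A)``;
    * ``DModX_i = s_i / s0`` with ``s_i^2 = sum_j e_ij^2 / (p-A)``,
      ``s0^2 = sum_ij e_ij^2 / ((n-A-1)(p-A))`` and limit
      ``sqrt(F_{1-a'}(p-A, (n-A-1)(p-A)))``.
    """
    n, p, A = model.n_samples, model.n_features, model.n_components
    if n < 3:
        raise ValueError("outlier screening needs at least 3 subjects")
    alpha = 1.0 - level
    alpha_each = 1.0 - np.sqrt(1.0 - alpha)

    t2 = np.sum(model.scores**2 / model.eigenvalues, axis=1)
    t2_limit = (
        A * (n - 1) * (n + 1) / (n * (n - A)) * stats.f.ppf(1 - alpha_each, A, n - A)
    )

    E = model.residual_matrix
    dof_i = p - A
    dof_pool = (n - A - 1) * dof_i
    s_i = np.sqrt(np.sum(E**2, axis=1) / dof_i)
    s0 = np.sqrt(np.sum(E**2) / dof_pool)
    dmodx = s_i / s0 if s0 > 0 else np.zeros(n)
    dmodx_limit = np.sqrt(stats.f.ppf(1 - alpha_each, dof_i, dof_pool))

    flagged = set(np.where((t2 > t2_limit) | (dmodx > dmodx_limit))[0])
    return OutlierReport(
        hotelling_t2=t2,
        t2_limit=float(t2_limit),
        dmodx=dmodx,
        dmodx_limit=float(dmodx_limit),
        flagged=flagged,
        level=level,
    )


# ---------------------------------------------------------------------------
# PLS-DA (PLS1, NIPALS)
# ---------------------------------------------------------------------------

@dataclass
class PLSDAModel:
    W: np.ndarray                 # x-weights (features, A), unit columns
    P: np.ndarray                 # x-loadings (features, A)
    T: np.ndarray                 # x-scores (subjects, A)
    c: np.ndarray                 # y-loadings (A,)
    A: int
    ssy: np.ndarray               # y-variance explained per component
    R2Y: float
    B: np.ndarray                 # regression vector W (P'W)^-1 c
    x_mean: np.ndarray
    y_mean: float
    Q2: float | None = None
    cv_auc: float | None = None
    vip: np.ndarray | None = None
    post_transformed: bool = False
    T_pred: np.ndarray | None = None
    T_orth: np.ndarray | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Continuous class prediction (training-data encoding scale)."""
        return (np.asarray(X, dtype=float) - self.x_mean) @ self.B + self.y_mean


def _pls1(Xc: np.ndarray, yc: np.ndarray, A: int):
    """NIPALS PLS1 on centered data; returns (W, P, T, c, ssy, A_eff).

    For a single response the NIPALS weight iteration converges in one
    step: w_a = X'y / ||X'y||, with X deflated by t p' per component.
    """
    n, p = Xc.shape
    A = min(A, p, max(n - 1, 1))
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    T = np.zeros((n, A))
    c = np.zeros(A)
    ssy = np.zeros(A)
    Xd = Xc.copy()
    yd = yc.copy()
    a_eff = 0
    for a in range(A):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw < _TOL:
            break
        w /= nw
        t = Xd @ w
        tt = t @ t
        if tt < _TOL:
            break
        ca = (t @ yd) / tt
        pa = (Xd.T @ t) / tt
        Xd -= np.outer(t, pa)
        yd = yd - ca * t
        W[:, a], P[:, a], T[:, a], c[a] = w, pa, t, ca
        ssy[a] = ca * ca * tt
        a_eff += 1
    return W[:, :a_eff], P[:, :a_eff], T[:, :a_eff], c[:a_eff], ssy[:a_eff], a_eff


def fit_plsda(X: np.ndarray, y: np.ndarray, A: int = 2) -> PLSDAModel:
    """Fit a PLS-DA model on a (typically autoscaled) matrix.

    ``y`` may be +1/-1 floats or two string labels (the lexicographically
    larger label becomes +1). X and y are centered internally; if A
    exceeds the usable rank the model is truncated with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = _encode_y(y)
    if A < 1:
        raise ValueError("A must be >= 1")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, T, c, ssy, a_eff = _pls1(X - x_mean, y - y_mean, A)
    if a_eff == 0:
        raise ValueError("no usable PLS component (X'y vanishes)")
    if a_eff < A:
        warnings.warn(f"PLS truncated to {a_eff} components (rank limit)")
    B = W @ np.linalg.solve(P.T @ W, c)
    yc = y - y_mean
    resid = yc - (X - x_mean) @ B
    tss = float(yc @ yc)
    r2y = 1.0 - float(resid @ resid) / tss if tss > 0 else 0.0
    model = PLSDAModel(
        W=W, P=P, T=T, c=c, A=a_eff, ssy=ssy, R2Y=r2y, B=B,
        x_mean=x_mean, y_mean=y_mean,
    )
    model.vip = vip_scores(model)
    return model


def _encode_y(y) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype.kind in "OUS":
        levels = sorted(set(y.tolist()))
        if len(levels) != 2:
            raise ValueError(f"y must have exactly two levels, got {levels}")
        return np.where(y == levels[1], 1.0, -1.0)
    y = y.astype(float)
    if len(np.unique(y)) != 2:
        raise ValueError("y must have exactly two levels")
    return y


def vip_scores(model: PLSDAModel) -> np.ndarray:
    """Variable Influence on Projection (Wold VIP).

    VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a ),
    where SSY_a is the y-variance explained by component a. Squared VIPs
    average to 1 over features.
    """
    ssy_tot = model.ssy.sum()
    if ssy_tot <= 0:
        raise ValueError("model explains no class variance; VIP undefined")
    p = model.W.shape[0]
    wnorm2 = np.sum(model.W**2, axis=0)
    contrib = (model.W**2 / wnorm2) @ model.ssy
    return np.sqrt(p * contrib / ssy_tot)


def post_transform(model: PLSDAModel, y: np.ndarray | None = None) -> PLSDAModel:
    """Rotate the model so one score component is predictive, the rest orthogonal.

    The rotation R is orthogonal with first column proportional to T'y;
    rotated scores T R then satisfy (T R)' y = (||T'y||, 0, ..., 0), i.e.
    only the first (predictive) component covaries with the response.
    Weights and loadings rotate with R, y-loadings rotate contravariantly,
    so fitted values and the regression vector are unchanged.

    With A = 1 the model is already in predictive form and is returned
    unchanged (with a log note).
    """
    if model.A == 1:
        logger.info("post_transform: single-component model returned unchanged")
        out = _copy_model(model)
        out.post_transformed = True
        out.T_pred = model.T.copy()
        out.T_orth = np.zeros((model.T.shape[0], 0))
        return out
    if y is None:
        # reconstruct the centered response from the fitted scores
        yc_fit = model.T @ model.c
    else:
        yc_fit = _encode_y(y) - model.y_mean
    v = model.T.T @ yc_fit
    nv = np.linalg.norm(v)
    if nv < _TOL:
        raise ValueError("scores carry no covariance with y; cannot post-transform")
    # orthonormal basis with first vector along v (Householder completion)
    R = _rotation_with_first_column(v / nv)
    out = _copy_model(model)
    out.W = model.W @ R
    out.P = model.P @ R
    out.T = model.T @ R
    out.c = R.T @ model.c
    out.post_transformed = True
    out.T_pred = out.T[:, :1]
    out.T_orth = out.T[:, 1:]
    out.vip = model.vip
    return out


def _rotation_with_first_column(u: np.ndarray) -> np.ndarray:
    A = len(u)
    M = np.eye(A)
    M[:, 0] = u
    Q, _ = np.linalg.qr(M)
    # QR may flip the sign of the first column; align with u
    if Q[:, 0] @ u < 0:
        Q[:, 0] *= -1
    return Q


def _copy_model(model: PLSDAModel) -> PLSDAModel:
    return PLSDAModel(
        W=model.W.copy(), P=model.P.copy(), T=model.T.copy(), c=model.c.copy(),
        A=model.A, ssy=model.ssy.copy(), R2Y=model.R2Y, B=model.B.copy(),
        x_mean=model.x_mean.copy(), y_mean=model.y_mean, Q2=model.Q2,
        cv_auc=model.cv_auc, vip=None if model.vip is None else model.vip.copy(),
    )


# ---------------------------------------------------------------------------
# cross-validation and permutation testing
# ---------------------------------------------------------------------------

def _auc_from_scores(scores: np.ndarray, positive: np.ndarray) -> float:
    """Mann-Whitney concordance of continuous scores vs a boolean mask,
    ties counted 1/2."""
    r = stats.rankdata(scores)
    n1 = int(positive.sum())
    n2 = len(scores) - n1
    if n1 == 0 or n2 == 0:
        raise ValueError("both classes required for AUC")
    return float((r[positive].sum() - n1 * (n1 + 1) / 2) / (n1 * n2))


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator):
    """Class-balanced fold labels: shuffle within class, deal round-robin."""
    fold = np.empty(len(y), dtype=int)
    start = 0
    for cls in np.unique(y):
        idx = np.where(y == cls)[0]
        rng.shuffle(idx)
        fold[idx] = (np.arange(len(idx)) + start) % k
        start += len(idx)  # stagger so folds get even totals
    return fold


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    A: int = 2,
    k: int = 7,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Q2 and held-out AUC under stratified k-fold cross-validation.

    Q2 is SIMCA-style: one pooled PRESS over the concatenated held-out
    predictions, 1 - PRESS/TSS (TSS about the overall mean). Each
    training fold is re-centered and re-scaled to unit variance before
    fitting, and the fold assignment is seeded.
    """
    X = np.asarray(X, dtype=float)
    y = _encode_y(y)
    n = len(y)
    if k > n:
        raise ValueError("more folds than samples")
    counts = [np.sum(y == c) for c in np.unique(y)]
    if min(counts) < 2:
        raise ValueError("each class needs at least 2 members")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fold = _stratified_folds(y, k, rng)
    preds = np.empty(n)
    for f in range(k):
        te = fold == f
        tr = ~te
        if not te.any():
            continue
        ytr = y[tr]
        if len(np.unique(ytr)) < 2:
            raise ValueError("a training fold lost a class; use fewer folds")
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0, ddof=1)
        sd[sd < _TOL] = 1.0
        Xtr = (X[tr] - mu) / sd
        Xte = (X[te] - mu) / sd
        ym = ytr.mean()
        W, P, T, c, ssy, a_eff = _pls1(Xtr, ytr - ym, A)
        if a_eff == 0:
            preds[te] = ym
            continue
        B = W @ np.linalg.solve(P.T @ W, c)
        preds[te] = Xte @ B + ym
    press = float(np.sum((y - preds) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    q2 = 1.0 - press / tss
    auc = _auc_from_scores(preds, y > 0)
    return q2, auc


def choose_n_components(
    X: np.ndarray, y: np.ndarray, max_A: int = 5, k: int = 7, seed: int = 0
) -> int:
    """Smallest component count maximizing Q2 over A = 1..max_A."""
    q2s = []
    for A in range(1, max_A + 1):
        rng = np.random.default_rng(seed)  # same folds for every A
        q2s.append(cross_validate(X, y, A=A, k=k, seed=rng)[0])
    return int(np.argmax(q2s)) + 1


@dataclass
class PermutationResult:
    observed_stat: float
    null_stats: np.ndarray
    n_permutations: int
    p_value: float
    statistic: str = "cv_auc"


def permutation_test(
    X: np.ndarray,
    y: np.ndarray,
    A: int = 2,
    n_perm: int = 1000,
    stat: str = "cv_auc",
    k: int = 7,
    seed: int = 0,
) -> PermutationResult:
    """Class-permutation test with the full CV pipeline inside each draw.

    p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    if stat not in ("cv_auc", "Q2"):
        raise ValueError(f"unknown statistic {stat!r}")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    y = _encode_y(y)
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate class response")
    rng = np.random.default_rng(seed)
    pick = (lambda qa: qa[1]) if stat == "cv_auc" else (lambda qa: qa[0])
    observed = pick(cross_validate(X, y, A=A, k=k, seed=rng))
    null = np.empty(n_perm)
    for b in range(n_perm):
        yp = rng.permutation(y)
        null[b] = pick(cross_validate(X, yp, A=A, k=k, seed=rng))
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    return PermutationResult(
        observed_stat=float(observed),
        null_stats=null,
        n_permutations=n_perm,
        p_value=float(p),
        statistic=stat,
    )
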