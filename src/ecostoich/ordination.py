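"""Redundancy analysis (RDA), permutation envfit and the limitation regression.

RDA is the constrained ordination used to relate the enzyme/stoichiometry
responses to the environmental predictors: regress the (centered, by
default unit-variance) response matrix Y on the standardized predictor
matrix X by least squares, then take the principal axes of the fitted
values. Each constrained eigenvalue, as a share of the total variance of
Y, is the percentage of response variation that axis explains.

envfit projects a single environmental variable onto the first two site
axes: r^2 is the squared multiple correlation from regressing the variable
on the two axis scores, significance comes from permuting the variable
across sites, and the arrow direction is the normalized pair of
regression coefficients.

(The detrended-correspondence-analysis gradient-length diagnostic some
workflows run before choosing RDA is intentionally not implemented; a log
message notes the omission.)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import qr

logger = logging.getLogger(__name__)


@dataclass
class OrdinationResult:
    eigenvalues: np.ndarray          # per constrained axis, non-increasing
    proportion_explained: np.ndarray  # % of total response variance
    site_scores: pd.DataFrame        # samples x axes
    response_scores: pd.DataFrame    # response variables x axes
    n_constrained_axes: int
    predictors: list[str]


@dataclass
class EnvfitResult:
    variable: str
    axis1: float    # direction cosine on axis 1
    axis2: float
    r2: float
    p: float

    @property
    def stars(self) -> str:
        for thr, s in ((0.001, "***"), (0.01, "**"), (0.05, "*")):
            if self.p < thr:
                return s
        return ""


def _standardize(A: np.ndarray) -> np.ndarray:
    sd = A.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (A - A.mean(axis=0)) / sd


def rda_fit(Y: pd.DataFrame, X: pd.DataFrame, standardize_y: bool = True) -> OrdinationResult:
    """Constrained ordination of responses Y on predictors X.

    Y columns are centered (and, by default, scaled to unit variance since
    the responses mix units); X columns are standardized. Collinear
    predictor columns are dropped with a warning. Requires n > rank(X).
    """
    if len(Y) != len(X):
        raise ValueError("Y and X must have aligned rows")
    if Y.isna().any().any() or X.isna().any().any():
        raise ValueError("missing values not allowed")
    logger.info("DCA gradient-length pre-check not performed (diagnostic only)")
    n = len(Y)
    raw_rank = np.linalg.matrix_rank(X.to_numpy(dtype=float))
    if n <= raw_rank:
        raise ValueError(f"need n > rank(X) ({n} <= {raw_rank})")
    Ym = Y.to_numpy(dtype=float)
    Yc = _standardize(Ym) if standardize_y else Ym - Ym.mean(axis=0)
    Xs = _standardize(X.to_numpy(dtype=float))
    # rank-revealing QR to drop collinear predictors
    _, R, piv = qr(Xs, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(Xs.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    keep = sorted(piv[:rank])
    kept_names = [X.columns[i] for i in keep]
    dropped = [c for c in X.columns if c not in kept_names]
    if dropped:
        logger.warning("dropping collinear predictor column(s): %s", dropped)
    Xs = Xs[:, keep]
    if n <= rank:
        raise ValueError(f"need n > rank(X) ({n} <= {rank})")
    B, *_ = np.linalg.lstsq(Xs, Yc, rcond=None)
    Yhat = Xs @ B
    U, s, Vt = np.linalg.svd(Yhat, full_matrices=False)
    n_axes = min(rank, Y.shape[1], int((s > s[0] * 1e-12).sum()) if s.size else 0)
    s = s[:n_axes]
    eig = s**2 / (n - 1)
    total_var = (Yc**2).sum() / (n - 1)
    prop = eig / total_var * 100.0
    axes = [f"RDA{i + 1}" for i in range(n_axes)]
    site = pd.DataFrame(U[:, :n_axes] * s, columns=axes, index=Y.index)
    resp = pd.DataFrame(Vt[:n_axes].T, columns=axes, index=Y.columns)
    return OrdinationResult(
        eigenvalues=eig, proportion_explained=prop, site_scores=site,
        response_scores=resp, n_constrained_axes=n_axes, predictors=kept_names,
    )


def envfit(
    ordination: OrdinationResult,
    env,
    n_perm: int = 999,
    seed: int | None = None,
    name: str = "env",
) -> EnvfitResult:
    """Fit one environmental vector onto the first two ordination axes.

    p = (1 + #{permuted r^2 >= observed r^2}) / (1 + n_perm) — the add-one
    permutation estimator, never exactly zero.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    e = np.asarray(env, dtype=float)
    S = ordination.site_scores.to_numpy()[:, :2]
    if len(e) != len(S):
        raise ValueError("env vector not aligned with site scores")
    if np.std(e) == 0:
        raise ValueError("zero variance environmental vector")
    Sc = S - S.mean(axis=0)
    Q, _ = np.linalg.qr(Sc)

    def r2_of(cols: np.ndarray) -> np.ndarray:
        ec = cols - cols.mean(axis=0)
        fit = Q.T @ ec
        return (fit**2).sum(axis=0) / (ec**2).sum(axis=0)

    r2 = float(r2_of(e[:, None])[0])
    rng = np.random.default_rng(seed)
    perms = np.column_stack([rng.permutation(e) for _ in range(n_perm)])
    r2_perm = r2_of(perms)
    p = (1 + int((r2_perm >= r2 - 1e-12).sum())) / (1 + n_perm)
    coef, *_ = np.linalg.lstsq(Sc, e - e.mean(), rcond=None)
    norm = np.linalg.norm(coef)
    d = coef / norm if norm > 0 else coef
    return EnvfitResult(variable=name, axis1=float(d[0]), axis2=float(d[1]),
                        r2=r2, p=float(p))


def envfit_table(
    ordination: OrdinationResult,
    env: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """envfit for every column of ``env``; per-variable derived seeds."""
    rng = np.random.default_rng(seed)
    rows = []
    for col in env.columns:
        sub = int(rng.integers(0, 2**31 - 1))
        r = envfit(ordination, env[col], n_perm=n_perm, seed=sub, name=col)
        rows.append({"variable": r.variable, "axis1": r.axis1, "axis2": r.axis2,
                     "r2": r.r2, "p": r.p, "significance": r.stars})
    return pd.DataFrame(rows)


def limitation_regression(vector_lengths, vector_angles) -> dict:
    """OLS of C limitation (vector length) on N/P limitation (vector angle).

    Returns slope, intercept, Pearson r and its t-test p-value.
    """
    x = np.asarray(vector_angles, dtype=float)
    y = np.asarray(vector_lengths, dtype=float)
    if len(x) != len(y):
        raise ValueError("length/angle vectors must align")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite observations")
    if np.std(x) == 0:
        raise ValueError("zero variance in vector angle")
    res = stats.linregress(x, y)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "r": float(res.rvalue), "p": float(res.pvalue)}
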