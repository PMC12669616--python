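"""Partial-least-squares path modeling (composite SEM) with bootstrap effects.

Latent constructs (e.g. "soil nutrients", "enzyme activity") are measured
reflectively by blocks of observed indicators. Estimation follows the
classical PLS algorithm with the path weighting scheme: all indicators are
z-scored; latent scores are standardized weighted composites of their
block's indicators; inner proxies combine predecessor latents via their
regression coefficients and successor latents via correlations; mode-A
outer weights are the correlations of indicators with the inner proxy.
Iteration stops when the largest outer-weight change falls below ``tol``.

Structural (path) coefficients are then OLS coefficients of each
endogenous latent on its predecessors. The total effect of one construct
on another is the sum over all directed paths of the products of path
coefficients (the Neumann closure of the coefficient matrix — finite for
a DAG). Significance is assessed by resampling rows with replacement,
refitting, and referring estimate / bootstrap-SE to the standard normal
(two-sided); percentile intervals are also reported. Model fit is
summarized by SRMR, the root-mean-square difference between observed and
model-implied indicator correlations, with implied correlations
reconstructed from loadings and latent correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class PathModelError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    pass


@dataclass
class PathModelSpec:
    """Blocks (construct -> reflective indicator list) and directed paths."""

    blocks: dict[str, list[str]]
    paths: list[tuple[str, str]]

    def validate(self, columns=None) -> None:
        names = list(self.blocks)
        for src, tgt in self.paths:
            for b in (src, tgt):
                if b not in names:
                    raise PathModelError(f"path references unknown block {b!r}")
        in_paths = {b for edge in self.paths for b in edge}
        orphan = [b for b in names if b not in in_paths]
        if orphan:
            raise PathModelError(f"block(s) not on any path: {orphan}")
        if columns is not None:
            for b, inds in self.blocks.items():
                missing = [i for i in inds if i not in columns]
                if missing:
                    raise PathModelError(f"block {b!r} indicators missing: {missing}")
        self.topological_order()

    def predecessors(self, block: str) -> list[str]:
        return [s for s, t in self.paths if t == block]

    def successors(self, block: str) -> list[str]:
        return [t for s, t in self.paths if s == block]

    def endogenous(self) -> list[str]:
        return [b for b in self.blocks if self.predecessors(b)]

    def topological_order(self) -> list[str]:
        # Kahn's algorithm; raises on cycles.
        indeg = {b: len(self.predecessors(b)) for b in self.blocks}
        order, ready = [], [b for b in self.blocks if indeg[b] == 0]
        while ready:
            b = ready.pop(0)
            order.append(b)
            for t in self.successors(b):
                indeg[t] -= 1
                if indeg[t] == 0:
                    ready.append(t)
        if len(order) != len(self.blocks):
            raise PathModelError("path graph contains a cycle")
        return order


@dataclass
class PathModelResult:
    spec: PathModelSpec
    outer_weights: dict[str, np.ndarray]
    loadings: dict[str, np.ndarray]
    scores: pd.DataFrame
    path_coefficients: pd.DataFrame   # blocks x blocks, [source, target]
    r2: dict[str, float]
    total: pd.DataFrame = None
    n_iter: int = 0
    srmr_value: float = None

    @property
    def total_effects_matrix(self) -> pd.DataFrame:
        if self.total is None:
            self.total = total_effects(self.path_coefficients)
        return self.total


def _zscore(A: np.ndarray) -> np.ndarray:
    sd = A.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise PathModelError("constant indicator (zero variance)")
    return (A - A.mean(axis=0)) / sd


def fit_pls(
    data: pd.DataFrame,
    spec: PathModelSpec,
    tol: float = 1e-7,
    max_iter: int = 300,
) -> PathModelResult:
    """Fit the PLS path model on complete cases of ``data``."""
    spec.validate(columns=data.columns)
    indicators = [i for b in spec.blocks.values() for i in b]
    df = data[indicators]
    n_dropped = int(df.isna().any(axis=1).sum())
    if n_dropped:
        logger.warning("dropping %d incomplete case(s)", n_dropped)
        df = df.dropna()
    n = len(df)
    blocks = list(spec.blocks)
    for b in spec.endogenous():
        if n <= len(spec.predecessors(b)):
            raise PathModelError(f"too few cases for block {b!r}")
    Z = {b: _zscore(df[spec.blocks[b]].to_numpy(dtype=float)) for b in blocks}
    for b in blocks:
        if Z[b].shape[1] > 1:
            C = np.corrcoef(Z[b], rowvar=False)
            if np.any(np.abs(C - np.eye(len(C))) > 1 - 1e-10):
                raise PathModelError(
                    f"perfectly collinear indicators in block {b!r}"
                )

    def make_scores(w):
        out = {}
        for b in blocks:
            s = Z[b] @ w[b]
            sd = s.std(ddof=1)
            out[b] = (s - s.mean()) / sd if sd > 0 else s - s.mean()
        return out

    w = {b: np.ones(len(spec.blocks[b])) / np.sqrt(len(spec.blocks[b]))
         for b in blocks}
    single = {b for b in blocks if len(spec.blocks[b]) == 1}
    for b in single:
        w[b] = np.ones(1)
    scores = make_scores(w)
    n_iter = 0
    delta = 0.0
    for n_iter in range(1, max_iter + 1):
        # inner estimation, path weighting scheme
        inner = {}
        for b in blocks:
            proxy = np.zeros(n)
            preds = spec.predecessors(b)
            if preds:
                Xp = np.column_stack([scores[p] for p in preds])
                coef, *_ = np.linalg.lstsq(Xp, scores[b], rcond=None)
                proxy = proxy + Xp @ coef
            for t in spec.successors(b):
                r = np.corrcoef(scores[b], scores[t])[0, 1]
                proxy = proxy + r * scores[t]
            sd = proxy.std()
            inner[b] = proxy / sd if sd > 0 else scores[b]
        # outer estimation, mode A
        w_new = {}
        for b in blocks:
            if b in single:
                w_new[b] = np.ones(1)
                continue
            wv = Z[b].T @ inner[b] / n
            w_new[b] = wv / np.linalg.norm(wv)
        delta = max(np.max(np.abs(w_new[b] - w[b])) for b in blocks)
        w = w_new
        scores = make_scores(w)
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            f"outer weights did not converge in {max_iter} iterations "
            f"(last delta {delta:.3e})"
        )
    # orient each latent to correlate positively with its first indicator
    for b in blocks:
        r = np.corrcoef(scores[b], Z[b][:, 0])[0, 1]
        if r < 0:
            w[b] = -w[b]
            scores[b] = -scores[b]
    loadings = {
        b: np.array([np.corrcoef(Z[b][:, j], scores[b])[0, 1]
                     for j in range(Z[b].shape[1])])
        for b in blocks
    }
    P = pd.DataFrame(0.0, index=blocks, columns=blocks)
    r2 = {}
    for b in spec.endogenous():
        preds = spec.predecessors(b)
        Xp = np.column_stack([scores[p] for p in preds])
        coef, *_ = np.linalg.lstsq(Xp, scores[b], rcond=None)
        fitted = Xp @ coef
        r2[b] = float(1 - ((scores[b] - fitted) ** 2).sum()
                      / (scores[b] ** 2).sum())
        for p, c in zip(preds, coef):
            P.loc[p, b] = float(c)
    score_df = pd.DataFrame({b: scores[b] for b in blocks}, index=df.index)
    res = PathModelResult(
        spec=spec, outer_weights=w, loadings=loadings, scores=score_df,
        path_coefficients=P, r2=r2, n_iter=n_iter,
    )
    res.total = total_effects(P)
    return res


def total_effects(path_coefficients: pd.DataFrame) -> pd.DataFrame:
    """Total (direct + all indirect) effects via the Neumann closure.

    For an acyclic coefficient matrix B (B[source, target]), the total
    effect matrix is sum_{k>=1} B^k = (I - B)^{-1} - I.
    """
    B = path_coefficients.to_numpy(dtype=float)
    k = len(B)
    # cycle check on the adjacency structure
    A = (B != 0).astype(int)
    M = A.copy()
    for _ in range(k):
        if np.trace(M) > 0:
            raise PathModelError("path graph contains a cycle")
        M = M @ A
    T = np.linalg.inv(np.eye(k) - B) - np.eye(k)
    return pd.DataFrame(T, index=path_coefficients.index,
                        columns=path_coefficients.columns)


def bootstrap_paths(
    data: pd.DataFrame,
    spec: PathModelSpec,
    n_boot: int = 5000,
    seed: int | None = None,
    tol: float = 1e-7,
    max_iter: int = 300,
) -> dict:
    """Bootstrap p-values (normal-reference t) and percentile CIs.

    Returns {"paths": DataFrame, "total_effects": DataFrame, "n_failed": int}.
    Each frame has source, target, estimate, se, t, p, ci_low, ci_high.
    Deterministic given seed; failed resamples are skipped (error if more
    than 10% fail).
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    base = fit_pls(data, spec, tol=tol, max_iter=max_iter)
    blocks = list(spec.blocks)
    rng = np.random.default_rng(seed)
    indicators = [i for b in spec.blocks.values() for i in b]
    df = data[indicators].dropna().reset_index(drop=True)
    n = len(df)
    path_draws, tot_draws = [], []
    n_failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            r = fit_pls(df.iloc[idx], spec, tol=tol, max_iter=max_iter)
        except (PathModelError, ConvergenceError):
            n_failed += 1
            continue
        path_draws.append(r.path_coefficients.to_numpy())
        tot_draws.append(r.total.to_numpy())
    if n_failed > 0:
        logger.warning("%d bootstrap resample(s) failed and were skipped", n_failed)
    if n_failed > 0.10 * n_boot:
        raise RuntimeError(f"too many bootstrap failures: {n_failed}/{n_boot}")

    def table(est: pd.DataFrame, draws: list, pairs) -> pd.DataFrame:
        D = np.stack(draws)
        rows = []
        for s, t in pairs:
            i, j = blocks.index(s), blocks.index(t)
            samp = D[:, i, j]
            se = float(samp.std(ddof=1))
            e = float(est.iloc[i, j])
            tt = e / se if se > 0 else np.inf * np.sign(e)
            rows.append({
                "source": s, "target": t, "estimate": e, "se": se,
                "t": float(tt),
                "p": float(2 * stats.norm.sf(abs(tt))),
                "ci_low": float(np.percentile(samp, 2.5)),
                "ci_high": float(np.percentile(samp, 97.5)),
            })
        return pd.DataFrame(rows)

    tot = base.total
    tot_pairs = [(s, t) for s in blocks for t in blocks
                 if abs(tot.loc[s, t]) > 0 or (s, t) in spec.paths]
    return {
        "paths": table(base.path_coefficients, path_draws, spec.paths),
        "total_effects": table(tot, tot_draws, tot_pairs),
        "n_failed": n_failed,
    }


def _one_factor_loadings(R: np.ndarray) -> np.ndarray:
    """Principal-axis one-factor loadings of a block correlation matrix.

    A two-indicator block is exactly decomposed (lambda_i = sqrt(|r|));
    larger blocks use iterated principal-axis factoring on the
    reduced correlation matrix.
    """
    p = R.shape[0]
    if p == 1:
        return np.ones(1)
    if p == 2:
        r = R[0, 1]
        lam = np.sqrt(abs(r))
        return np.array([lam, np.copysign(lam, r) if r != 0 else 0.0])
    # start from squared multiple correlations
    try:
        h = 1.0 - 1.0 / np.diag(np.linalg.inv(R))
    except np.linalg.LinAlgError:
        h = np.full(p, 0.5)
    lam = np.zeros(p)
    for _ in range(200):
        Rh = R.copy()
        np.fill_diagonal(Rh, h)
        vals, vecs = np.linalg.eigh(Rh)
        lam_new = np.sqrt(max(vals[-1], 0.0)) * vecs[:, -1]
        if lam_new.sum() < 0:
            lam_new = -lam_new
        if np.max(np.abs(lam_new - lam)) < 1e-10:
            lam = lam_new
            break
        lam = lam_new
        h = np.clip(lam**2, 0.0, 0.995)
    return lam


def srmr(result: PathModelResult, data: pd.DataFrame) -> float:
    """Standardized root mean square residual of indicator correlations.

    Implied correlations come from the factor-model reading of the fitted
    composites: within a block, r_ij = lambda_i lambda_j with one-factor
    loadings fitted to the block's observed correlations; between blocks,
    r_ij = lambda_i phi*_ab lambda_j, where phi*_ab is the composite-score
    correlation disattenuated by each composite's correlation with its
    block factor (w' lambda). A block whose correlations are exactly
    rank-one is therefore reproduced without residual.
    """
    if result is None or result.scores is None:
        raise PathModelError("model not fitted")
    spec = result.spec
    indicators = [i for b in spec.blocks.values() for i in b]
    df = data[indicators].dropna()
    obs = np.corrcoef(df.to_numpy(dtype=float), rowvar=False)
    blocks = list(spec.blocks)
    phi = np.corrcoef(
        np.column_stack([result.scores[b] for b in blocks]), rowvar=False
    )
    if phi.ndim == 0:
        phi = np.array([[1.0]])
    # factor loadings and composite-factor correlations per block
    lam: dict[str, float] = {}
    attn: dict[str, float] = {}
    pos = {i: k for k, i in enumerate(indicators)}
    for b in blocks:
        inds = spec.blocks[b]
        idx = [pos[i] for i in inds]
        Rb = obs[np.ix_(idx, idx)]
        lam_b = _one_factor_loadings(Rb)
        for i, l in zip(inds, lam_b):
            lam[i] = float(l)
        Zb = _zscore(df[inds].to_numpy(dtype=float))
        s = Zb @ result.outer_weights[b]
        w_eff = result.outer_weights[b] / s.std(ddof=1)
        attn[b] = float(np.clip(w_eff @ lam_b, 0.3, 1.0))
    block_of = {i: b for b, inds in spec.blocks.items() for i in inds}
    k = len(indicators)
    impl = np.eye(k)
    for a in range(k):
        for b_ in range(a + 1, k):
            ia, ib = indicators[a], indicators[b_]
            ba, bb = block_of[ia], block_of[ib]
            if ba == bb:
                r = lam[ia] * lam[ib]
            else:
                pa, pb = blocks.index(ba), blocks.index(bb)
                phi_star = np.clip(
                    phi[pa, pb] / (attn[ba] * attn[bb]), -1.0, 1.0)
                r = lam[ia] * phi_star * lam[ib]
            impl[a, b_] = impl[b_, a] = r
    iu = np.triu_indices(k, 1)
    resid = obs[iu] - impl[iu]
    value = float(np.sqrt(np.mean(resid**2)))
    result.srmr_value = value
    return value


def study_path_spec(target: str = "C") -> PathModelSpec:
    """Default driver model for the mine-drainage study layout.

    Exogenous single-indicator blocks for mining distance and soil depth;
    composite blocks for soil nutrients (AP, NO3-N), microbial biomass
    (MBC, MBN), enzyme activity (BG, LAP, ALP) and ecoenzymatic
    stoichiometry (E_C:N, E_C:P, E_N:P); the endpoint is microbial C
    limitation (vector length) or P limitation (vector angle).
    """
    if target not in ("C", "P"):
        raise ValueError("target must be 'C' or 'P'")
    endpoint = "C_limitation" if target == "C" else "P_limitation"
    indicator = "vector_length" if target == "C" else "vector_angle"
    blocks = {
        "mining_distance": ["mining_distance"],
        "soil_depth": ["depth_cm"],
        "soil_nutrients": ["AP", "NO3_N"],
        "microbial_biomass": ["MBC", "MBN"],
        "enzyme_activity": ["BG", "LAP", "ALP"],
        "ecoenzymatic_stoichiometry": ["ECN", "ECP", "ENP"],
        endpoint: [indicator],
    }
    paths = [
        ("mining_distance", "soil_nutrients"),
        ("mining_distance", "enzyme_activity"),
        ("soil_depth", "soil_nutrients"),
        ("soil_depth", "microbial_biomass"),
        ("soil_depth", "enzyme_activity"),
        ("soil_depth", "ecoenzymatic_stoichiometry"),
        ("soil_nutrients", "microbial_biomass"),
        ("soil_nutrients", "ecoenzymatic_stoichiometry"),
        ("soil_nutrients", endpoint),
        ("microbial_biomass", "ecoenzymatic_stoichiometry"),
        ("microbial_biomass", endpoint),
        ("enzyme_activity", "ecoenzymatic_stoichiometry"),
        ("enzyme_activity", endpoint),
        ("ecoenzymatic_stoichiometry", endpoint),
    ]
    return PathModelSpec(blocks=blocks, paths=paths)
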