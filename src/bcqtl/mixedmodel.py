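"""Henderson III F-tests and Bayesian estimation of the full genetic model.

The scan stage tests fixed QTL-effect blocks with the extra-sum-of-squares
F-statistic

    F = [SSR(b_Q | b_B) / (r_W - r_WB)] / [SSE / (n - r_W)]

computed from ordinary least-squares projections with tolerance-based ranks.
The estimation stage fits the full model (fixed additive/dominance/epistatic
effects, random environment and QTL-by-environment blocks with identity
correlation) by block Gibbs sampling, with a deterministic EM point-estimate
fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cholesky, solve_triangular, svd

__all__ = [
    "TestableModel",
    "HendersonTest",
    "FixedBlock",
    "RandomBlock",
    "FullModel",
    "EffectPosterior",
    "orth_basis",
    "henderson_f",
    "block_f_tests",
    "fit_gibbs",
    "fit_em",
]

RANK_RTOL = 1e-10
VARIANCE_FLOOR = 1e-10


def orth_basis(X: np.ndarray, rtol: float = RANK_RTOL) -> np.ndarray:
    """Orthonormal basis of the column space, with relative rank tolerance."""
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        return np.zeros((X.shape[0], 0))
    U, s, _ = svd(X, full_matrices=False)
    if s.size == 0 or s[0] == 0.0:
        return np.zeros((X.shape[0], 0))
    rank = int(np.sum(s > rtol * s[0]))
    return U[:, :rank]


@dataclass
class TestableModel:
    """Response, tested fixed block and background block for one F-test."""

    __test__ = False  # not a pytest class despite the name

    y: np.ndarray
    W_Q: np.ndarray
    W_B: np.ndarray


@dataclass
class HendersonTest:
    F: float
    df1: int
    df2: int
    p_value: float
    ssr: float
    sse: float
    status: str = "ok"  # "ok" | "inestimable"


def henderson_f(model: TestableModel) -> HendersonTest:
    """Extra-sum-of-squares F-test of the W_Q block given W_B."""
    y = np.asarray(model.y, dtype=float)
    n = y.shape[0]
    QB = orth_basis(model.W_B)
    r_wb = QB.shape[1]
    ry = y - QB @ (QB.T @ y)
    sse_reduced = float(ry @ ry)
    WQt = model.W_Q - QB @ (QB.T @ model.W_Q)
    # rank relative to the combined design, not the residualized block alone
    scale = np.linalg.norm(model.W_Q) if model.W_Q.size else 0.0
    U, s, _ = svd(WQt, full_matrices=False) if WQt.size else (np.zeros((n, 0)), np.zeros(0), None)
    k = int(np.sum(s > RANK_RTOL * max(scale, s[0] if s.size else 0.0))) if s.size else 0
    if k == 0:
        return HendersonTest(np.nan, 0, n - r_wb, np.nan, 0.0, sse_reduced, "inestimable")
    U = U[:, :k]
    t = U.T @ ry
    ssr = float(t @ t)
    sse = sse_reduced - ssr
    df2 = n - (r_wb + k)
    if df2 <= 0:
        return HendersonTest(np.nan, k, df2, np.nan, ssr, sse, "inestimable")
    F = (ssr / k) / (sse / df2) if sse > 0 else np.inf
    p = float(stats.f.sf(F, k, df2))
    return HendersonTest(float(F), k, df2, p, ssr, sse, "ok")


def block_f_tests(Y: np.ndarray, W_B: np.ndarray, blocks: list):
    """F-tests of several W_Q blocks against one background, for one or many
    response columns at once.

    Parameters
    ----------
    Y : (n,) or (n, m) response(s)
    W_B : background design
    blocks : list of (n, q_i) tested blocks

    Returns (F, df1, df2) with F of shape (len(blocks), m).
    """
    Y = np.asarray(Y, dtype=float)
    one = Y.ndim == 1
    if one:
        Y = Y[:, None]
    n, m = Y.shape
    QB = orth_basis(W_B)
    r_wb = QB.shape[1]
    RY = Y - QB @ (QB.T @ Y)
    sse_red = np.einsum("ij,ij->j", RY, RY)
    F = np.full((len(blocks), m), np.nan)
    df1 = np.zeros(len(blocks), dtype=int)
    df2 = np.zeros(len(blocks), dtype=int)
    for b, W_Q in enumerate(blocks):
        WQt = W_Q - QB @ (QB.T @ W_Q)
        scale = np.linalg.norm(W_Q) if W_Q.size else 0.0
        if WQt.size == 0:
            continue
        U, s, _ = svd(WQt, full_matrices=False)
        k = int(np.sum(s > RANK_RTOL * max(scale, s[0] if s.size else 0.0)))
        if k == 0 or n - r_wb - k <= 0:
            continue
        T = U[:, :k].T @ RY
        ssr = np.einsum("ij,ij->j", T, T)
        sse = sse_red - ssr
        df1[b], df2[b] = k, n - r_wb - k
        with np.errstate(divide="ignore", invalid="ignore"):
            F[b] = (ssr / k) / (sse / df2[b])
    return (F[:, 0] if one else F), df1, df2


# ---------------------------------------------------------------------------
# full-model estimation
# ---------------------------------------------------------------------------

@dataclass
class FixedBlock:
    """Fixed-effect columns: one term such as "a", "d" or "aa"."""

    term: str
    labels: list
    X: np.ndarray


@dataclass
class RandomBlock:
    """Random-effect columns sharing one variance component (R_u = I)."""

    term: str
    labels: list
    Z: np.ndarray


@dataclass
class FullModel:
    y: np.ndarray
    fixed: list
    random: list = field(default_factory=list)


@dataclass
class EffectPosterior:
    """Posterior summaries: one row per fixed effect / random-effect level."""

    effects: pd.DataFrame  # columns: term, level, kind, mean, sd, ess
    variance_components: dict
    method: str = "gibbs"
    diagnostics: dict = field(default_factory=dict)

    def get(self, term: str, level: str) -> float:
        df = self.effects
        row = df[(df["term"] == term) & (df["level"] == level)]
        return float(row["mean"].iloc[0]) if len(row) else np.nan


def _ess(draws: np.ndarray) -> np.ndarray:
    """Effective sample size per column (initial positive sequence)."""
    n, k = draws.shape
    out = np.empty(k)
    x = draws - draws.mean(axis=0)
    for j in range(k):
        v = x[:, j]
        var = v @ v / n
        if var == 0:
            out[j] = n
            continue
        nfft = 1 << (2 * n - 1).bit_length()
        f = np.fft.rfft(v, nfft)
        acf = np.fft.irfft(f * np.conjugate(f), nfft)[:n].real / (n * var)
        # Geyer initial positive sequence on pair sums
        pair = acf[1:-1:2] + acf[2::2]
        tau = 1.0
        for ps in pair:
            if ps < 0:
                break
            tau += 2.0 * ps
        out[j] = min(n, n / max(tau, 1e-12))
    return out


def _assemble(model: FullModel):
    """Stack blocks, drop aliased fixed columns, precompute cross-products."""
    y = np.asarray(model.y, dtype=float)
    n = y.shape[0]
    X = np.column_stack([b.X for b in model.fixed]) if model.fixed else np.zeros((n, 0))
    fixed_meta = [(b.term, lab) for b in model.fixed for lab in b.labels]
    # drop aliased fixed columns, keeping earlier-declared terms (mu, a, d,
    # aa in declaration order) so the flagged term is the semantically
    # redundant one
    keep = np.arange(X.shape[1])
    if X.shape[1]:
        _, s, _ = svd(X, full_matrices=False)
        rank = int(np.sum(s > RANK_RTOL * s[0])) if s.size else 0
        if rank < X.shape[1]:
            kept: list = []
            Q = np.zeros((n, 0))
            for j in range(X.shape[1]):
                col = X[:, j]
                resid = col - Q @ (Q.T @ col)
                if np.linalg.norm(resid) > RANK_RTOL * max(np.linalg.norm(col), s[0]):
                    kept.append(j)
                    Q = np.column_stack([Q, resid / np.linalg.norm(resid)])
            keep = np.array(kept, dtype=int)
    dropped = [fixed_meta[j] for j in range(X.shape[1]) if j not in set(keep.tolist())]
    X = X[:, keep]
    fixed_meta = [fixed_meta[j] for j in keep]
    mats = [X] + [b.Z for b in model.random]
    C = np.column_stack(mats) if mats else np.zeros((n, 0))
    slices = []
    start = X.shape[1]
    for b in model.random:
        q = b.Z.shape[1]
        slices.append(slice(start, start + q))
        start += q
    return y, C, X.shape[1], fixed_meta, slices, dropped


def fit_gibbs(
    model: FullModel,
    n_burn: int = 2000,
    n_iter: int = 10000,
    seed=0,
    thin: int = 1,
) -> EffectPosterior:
    """Block Gibbs sampler for the full mixed model.

    Fixed effects get a flat prior; each random block u_j ~ N(0, sigma2_j I)
    with a limiting vague scaled-inverse-chi-square prior on sigma2_j
    (positivity floor 1e-10); residual variance likewise.
    """
    rng = np.random.default_rng(seed)
    y, C, n_fixed, fixed_meta, rslices, dropped = _assemble(model)
    n, q = C.shape
    if q == 0:
        raise ValueError("model has no effects")
    M = C.T @ C
    cy = C.T @ y
    yty = float(y @ y)
    vy = float(np.var(y)) if n > 1 else 1.0

    theta = np.zeros(q)
    sigma2 = np.array([max(vy / 10.0, VARIANCE_FLOOR) for _ in rslices])
    sigma2_e = max(vy, VARIANCE_FLOOR)

    # a small ridge keeps the fixed-block precision invertible when fixed
    # columns are collinear with random ones (rank within tolerance)
    fixed_ridge = 1e-12

    kept = []
    kept_var = []
    n_total = n_burn + n_iter
    diverged = False
    for it in range(n_total):
        # all coefficients jointly | variances (avoids the slow mixing of the
        # nearly aliased fixed-main / random-QE split)
        prior_prec = np.full(q, fixed_ridge)
        for j, s in enumerate(rslices):
            prior_prec[s] = 1.0 / sigma2[j]
        P = M / sigma2_e + np.diag(prior_prec)
        rhs = cy / sigma2_e
        for jitter in (0.0, 1e-10, 1e-8):
            try:
                L = cholesky(P + jitter * np.eye(q), lower=True)
                break
            except np.linalg.LinAlgError:
                L = None
        if L is None:
            raise np.linalg.LinAlgError("conditional covariance not positive definite")
        mean = solve_triangular(L.T, solve_triangular(L, rhs, lower=True), lower=False)
        z = rng.standard_normal(q)
        theta = mean + solve_triangular(L.T, z, lower=False)
        # variance components
        for j, s in enumerate(rslices):
            u = theta[s]
            qj = s.stop - s.start
            sigma2[j] = max(
                (u @ u) / rng.chisquare(qj) if qj > 0 else VARIANCE_FLOOR,
                VARIANCE_FLOOR,
            )
        sse = yty - 2.0 * theta @ cy + theta @ M @ theta
        sigma2_e = max(sse / rng.chisquare(n), VARIANCE_FLOOR)
        if sigma2_e > 1e6 * max(vy, 1e-300) or np.any(sigma2 > 1e6 * max(vy, 1e-300)):
            diverged = True
        if it >= n_burn and (it - n_burn) % thin == 0:
            kept.append(theta.copy())
            kept_var.append(np.concatenate([sigma2, [sigma2_e]]))

    draws = np.asarray(kept)
    vdraws = np.asarray(kept_var)
    ess = _ess(draws)
    rows = []
    for j, (term, label) in enumerate(fixed_meta):
        rows.append(
            dict(term=term, level=label, kind="fixed",
                 mean=draws[:, j].mean(), sd=draws[:, j].std(ddof=1), ess=ess[j])
        )
    for b, s in zip(model.random, rslices):
        for k, label in enumerate(b.labels):
            j = s.start + k
            rows.append(
                dict(term=b.term, level=label, kind="random",
                     mean=draws[:, j].mean(), sd=draws[:, j].std(ddof=1), ess=ess[j])
            )
    for term, label in dropped:
        rows.append(dict(term=term, level=label, kind="fixed",
                         mean=np.nan, sd=np.nan, ess=np.nan))
    vc = {b.term: float(vdraws[:, j].mean()) for j, b in enumerate(model.random)}
    vc["residual"] = float(vdraws[:, -1].mean())
    return EffectPosterior(
        effects=pd.DataFrame(rows),
        variance_components=vc,
        method="gibbs",
        diagnostics={"diverged": diverged, "n_kept": draws.shape[0],
                     "dropped_aliased": dropped},
    )


def fit_em(model: FullModel, max_iter: int = 200, tol: float = 1e-8) -> EffectPosterior:
    """Deterministic EM point estimation (fallback for fast tests).

    Iterates EM updates of the variance components on the mixed-model
    equations and returns the final BLUE/BLUP solution; SDs are the
    square roots of the diagonal of the inverse coefficient matrix.
    """
    y, C, n_fixed, fixed_meta, rslices, dropped = _assemble(model)
    n, q = C.shape
    M = C.T @ C
    cy = C.T @ y
    yty = float(y @ y)
    vy = float(np.var(y)) if n > 1 else 1.0
    sigma2 = np.full(len(rslices), max(vy / 10.0, VARIANCE_FLOOR))
    sigma2_e = max(vy / 2.0, VARIANCE_FLOOR)
    theta = np.zeros(q)
    for _ in range(max_iter):
        D = np.zeros(q)
        for j, s in enumerate(rslices):
            D[s] = 1.0 / sigma2[j]
        A = M / sigma2_e + np.diag(D)
        Ainv = np.linalg.inv(A + 1e-12 * np.eye(q))
        theta = Ainv @ (cy / sigma2_e)
        new_s2 = sigma2.copy()
        for j, s in enumerate(rslices):
            u = theta[s]
            qj = s.stop - s.start
            tr = np.trace(Ainv[s, s])
            new_s2[j] = max((u @ u + tr) / max(qj, 1), VARIANCE_FLOOR)
        sse = yty - 2.0 * theta @ cy + theta @ M @ theta
        new_e = max((sse + np.trace(M @ Ainv)) / n, VARIANCE_FLOOR)
        moved = abs(new_e - sigma2_e) + float(np.abs(new_s2 - sigma2).sum())
        sigma2, sigma2_e = new_s2, new_e
        if moved < tol * vy:
            break
    D = np.zeros(q)
    for j, s in enumerate(rslices):
        D[s] = 1.0 / sigma2[j]
    A = M / sigma2_e + np.diag(D)
    Ainv = np.linalg.inv(A + 1e-12 * np.eye(q))
    theta = Ainv @ (cy / sigma2_e)
    sd = np.sqrt(np.maximum(np.diag(Ainv), 0.0))
    rows = []
    for j, (term, label) in enumerate(fixed_meta):
        rows.append(dict(term=term, level=label, kind="fixed",
                         mean=theta[j], sd=sd[j], ess=np.nan))
    for b, s in zip(model.random, rslices):
        for k, label in enumerate(b.labels):
            j = s.start + k
            rows.append(dict(term=b.term, level=label, kind="random",
                             mean=theta[j], sd=sd[j], ess=np.nan))
    for term, label in dropped:
        rows.append(dict(term=term, level=label, kind="fixed",
                         mean=np.nan, sd=np.nan, ess=np.nan))
    vc = {b.term: float(sigma2[j]) for j, b in enumerate(model.random)}
    vc["residual"] = float(sigma2_e)
    return EffectPosterior(
        effects=pd.DataFrame(rows), variance_components=vc, method="em",
        diagnostics={"dropped_aliased": dropped},
    )
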