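"""Composite interval mapping workflow for double backcross populations.

Stages: marker-pair cofactor pre-selection (forward stepwise over marker
intervals), permutation-calibrated genome-wide thresholds, 1D scan for main
effect QTLs, 2D scan for additive-by-additive epistasis, peak calling, and
backward-elimination model selection followed by full-model estimation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig
from .mixedmodel import (
    FixedBlock,
    FullModel,
    RandomBlock,
    fit_em,
    fit_gibbs,
    orth_basis,
)
from .probability import locus_effect_coefficients
from .simulate import ProgenyData

__all__ = [
    "ScanContext",
    "ScanProfile",
    "MappingResult",
    "select_cofactors_mps",
    "select_cofactor_pairs",
    "scan_1d",
    "scan_2d",
    "permutation_threshold",
    "call_peaks",
    "call_peaks_2d",
    "select_final_model",
    "map_qtls",
]

log = logging.getLogger(__name__)

RANK_RTOL = 1e-10


class _FEngine:
    """Extra-sum-of-squares F-tests of many small blocks against one
    background, for one or many response columns simultaneously."""

    def __init__(self, W_B: np.ndarray, Y: np.ndarray):
        Y = np.asarray(Y, dtype=float)
        self.one = Y.ndim == 1
        if self.one:
            Y = Y[:, None]
        self.n = Y.shape[0]
        self.QB = orth_basis(W_B)
        self.r_wb = self.QB.shape[1]
        self.RY = Y - self.QB @ (self.QB.T @ Y)
        self.sse_red = np.einsum("ij,ij->j", self.RY, self.RY)

    def test(self, W_Q: np.ndarray):
        """Returns (F, df1, df2, p) — F and p are per response column."""
        WQt = W_Q - self.QB @ (self.QB.T @ W_Q)
        scale = np.linalg.norm(W_Q) if W_Q.size else 0.0
        if WQt.size == 0:
            return None
        U, s, _ = np.linalg.svd(WQt, full_matrices=False)
        k = int(np.sum(s > RANK_RTOL * max(scale, s[0] if s.size else 0.0)))
        df2 = self.n - self.r_wb - k
        if k == 0 or df2 <= 0:
            return None
        T = U[:, :k].T @ self.RY
        ssr = np.einsum("ij,ij->j", T, T)
        sse = np.maximum(self.sse_red - ssr, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (ssr / k) / (sse / df2)
        p = stats.f.sf(F, k, df2)
        if self.one:
            return float(F[0]), k, df2, float(p[0])
        return F, k, df2, p

    def test_many(self, blocks: list, chunk: int = 400):
        """Batched F-tests of many equal-width blocks.

        Returns (F, df1, df2) with F of shape (len(blocks), m); inestimable
        blocks get NaN.
        """
        if not blocks:
            return (np.zeros((0, self.RY.shape[1])), np.zeros(0, int), np.zeros(0, int))
        k = blocks[0].shape[1]
        m = self.RY.shape[1]
        F = np.full((len(blocks), m), np.nan)
        df1 = np.zeros(len(blocks), dtype=int)
        df2 = np.zeros(len(blocks), dtype=int)
        tol2 = RANK_RTOL**2
        for lo in range(0, len(blocks), chunk):
            sub = blocks[lo:lo + chunk]
            W = np.concatenate(sub, axis=1)  # (n, b*k)
            scale2 = np.array([float(np.einsum("ij,ij->", b, b)) for b in sub])
            RW = W - self.QB @ (self.QB.T @ W)
            RW = RW.reshape(self.n, len(sub), k).transpose(1, 0, 2)
            G = np.einsum("bnk,bnl->bkl", RW, RW)
            B = np.einsum("bnk,nm->bkm", RW, self.RY)
            s, V = np.linalg.eigh(G)  # ascending eigenvalues (= squared svals)
            smax = s[:, -1].clip(min=0.0)
            thr = tol2 * np.maximum(scale2, smax)
            keep = s > thr[:, None]
            T = np.einsum("bkl,bkm->blm", V, B)  # projections on eigvecs
            with np.errstate(divide="ignore", invalid="ignore"):
                contrib = np.where(keep[:, :, None], T**2 / s[:, :, None], 0.0)
            ssr = contrib.sum(axis=1)  # (b, m)
            kb = keep.sum(axis=1)
            d2 = self.n - self.r_wb - kb
            ok = (kb > 0) & (d2 > 0)
            sse = np.maximum(self.sse_red[None, :] - ssr, 0.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                f = (ssr / kb[:, None]) / (sse / d2[:, None])
            f[~ok] = np.nan
            F[lo:lo + len(sub)] = f
            df1[lo:lo + len(sub)] = kb
            df2[lo:lo + len(sub)] = d2
        return F, df1, df2


class ScanContext:
    """Per-dataset precomputations shared by all scan stages."""

    def __init__(self, data: ProgenyData, window_cm: float = 10.0):
        self.data = data
        self.lmap = data.lmap
        self.window = float(window_cm)
        y, env, ind = data.response()
        self.y, self.env, self.ind = y, env, ind
        self.n_obs = len(y)
        self.n_env = int(env.max()) + 1
        self.n_ind = data.n_individuals
        self._env_mask = (env[:, None] == np.arange(self.n_env)[None, :]).astype(float)

        g = data.genotypes.astype(float)
        g[data.genotypes < 0] = np.nan
        self.xi = g - 1.0
        self.zeta = np.where(g == 1.0, 0.5, -0.5)
        self.zeta[np.isnan(g)] = np.nan
        # mean-impute missing cofactor scores (rare; flanking-marker QTL
        # coefficients handle missingness properly via enlarged intervals)
        for m in (self.xi, self.zeta):
            if np.isnan(m).any():
                log.warning("missing marker genotypes: cofactor scores mean-imputed")
                mu = np.nanmean(m, axis=0)
                idx = np.where(np.isnan(m))
                m[idx] = np.take(mu, idx[1])

        # interval table: one row per marker interval, global id
        rows = []
        for c, pos in enumerate(self.lmap.positions):
            off = self.lmap.offset(c)
            for j in range(len(pos) - 1):
                rows.append((c, off + j, off + j + 1, pos[j], pos[j + 1]))
        self.intervals = pd.DataFrame(
            rows, columns=["chrom", "left_gidx", "right_gidx", "left_cm", "right_cm"]
        )
        self._iv_chrom = self.intervals["chrom"].to_numpy()
        self._iv_lg = self.intervals["left_gidx"].to_numpy()
        self._iv_rg = self.intervals["right_gidx"].to_numpy()
        self._iv_lcm = self.intervals["left_cm"].to_numpy()
        self._iv_rcm = self.intervals["right_cm"].to_numpy()
        self._coeff_cache: dict = {}
        self._marker_block_cache: dict = {}

    # ---- design-column helpers -------------------------------------------

    def env_expand(self, cols: np.ndarray) -> np.ndarray:
        """(n_ind, k) per-individual columns -> (n_obs, k * n_env)."""
        per_obs = np.atleast_2d(np.asarray(cols, dtype=float).T).T[self.ind]
        out = per_obs[:, :, None] * self._env_mask[:, None, :]
        return out.reshape(self.n_obs, -1)

    def intercepts(self) -> np.ndarray:
        return self._env_mask

    def marker_block(self, interval_id: int) -> np.ndarray:
        """xi/zeta cofactor columns (both flanking markers, per environment)."""
        blk = self._marker_block_cache.get(interval_id)
        if blk is None:
            li, ri = int(self._iv_lg[interval_id]), int(self._iv_rg[interval_id])
            cols = np.column_stack(
                [self.xi[:, li], self.zeta[:, li], self.xi[:, ri], self.zeta[:, ri]]
            )
            blk = self.env_expand(cols)
            self._marker_block_cache[interval_id] = blk
        return blk

    def pair_block(self, gi: int, gj: int) -> np.ndarray:
        """xi*xi interaction columns of two intervals' flanking marker pairs."""
        al, ar = int(self._iv_lg[gi]), int(self._iv_rg[gi])
        bl, br = int(self._iv_lg[gj]), int(self._iv_rg[gj])
        cols = np.column_stack(
            [self.xi[:, al] * self.xi[:, bl], self.xi[:, ar] * self.xi[:, br]]
        )
        return self.env_expand(cols)

    def locus_coeffs(self, chrom: int, pos: float):
        """Per-individual (x_A, x_D) at a position on chromosome ``chrom``."""
        key = (chrom, round(float(pos), 6))
        got = self._coeff_cache.get(key)
        if got is None:
            off = self.lmap.offset(chrom)
            geno = self.data.genotypes[:, off:off + len(self.lmap.positions[chrom])]
            x_a, x_d = locus_effect_coefficients(
                geno, self.data.origin, self.data.line_type,
                self.lmap.positions[chrom], float(pos),
            )
            got = (x_a, x_d)
            self._coeff_cache[key] = got
        return got

    def qtl_block(self, chrom: int, pos: float) -> np.ndarray:
        """Per-environment additive+dominance columns at a tested position."""
        x_a, x_d = self.locus_coeffs(chrom, pos)
        cols = np.column_stack([np.nan_to_num(x_a), np.nan_to_num(x_d)])
        return self.env_expand(cols)

    def epi_block(self, ci: int, pi: float, cj: int, pj: float) -> np.ndarray:
        """Per-environment additive-by-additive column for a position pair."""
        xa_i, _ = self.locus_coeffs(ci, pi)
        xa_j, _ = self.locus_coeffs(cj, pj)
        return self.env_expand(np.nan_to_num(xa_i * xa_j)[:, None])

    # ---- geometry helpers -------------------------------------------------

    def interval_of(self, chrom: int, pos: float) -> int:
        hit = np.where(
            (self._iv_chrom == chrom)
            & (self._iv_lcm <= pos + 1e-9)
            & (self._iv_rcm >= pos - 1e-9)
        )[0]
        if hit.size == 0:
            raise ValueError(f"position {pos} outside chromosome {chrom} map")
        return int(hit[0])

    def interval_distance(self, gi: int, gj: int) -> float:
        if self._iv_chrom[gi] != self._iv_chrom[gj]:
            return np.inf
        return max(
            0.0,
            max(self._iv_lcm[gi], self._iv_lcm[gj])
            - min(self._iv_rcm[gi], self._iv_rcm[gj]),
        )

    def grid_1d(self, step: float) -> list:
        """(chrom, pos) scan grid covering every chromosome at ``step`` cM."""
        out = []
        for c, pos in enumerate(self.lmap.positions):
            grid = np.arange(pos[0], pos[-1] + 1e-9, step)
            if grid[-1] < pos[-1] - 1e-9:
                grid = np.append(grid, pos[-1])
            out.extend((c, float(p)) for p in grid)
        return out

    def allowed_interval_pair(self, gi: int, gj: int) -> bool:
        """Distinct intervals: different chromosomes or >= 1 interval apart."""
        if self._iv_chrom[gi] != self._iv_chrom[gj]:
            return True
        return abs(gi - gj) >= 2


@dataclass
class ScanProfile:
    """F-statistic profile over tested positions or position pairs."""

    table: pd.DataFrame
    kind: str  # "1d" | "2d"
    threshold: float | None = None


@dataclass
class MappingResult:
    """Final declared QTL set with posterior effect estimates."""

    qtls: list
    pairs: list
    posterior: object = None
    thresholds: dict = field(default_factory=dict)
    cofactors: list = field(default_factory=list)
    cofactor_pairs: list = field(default_factory=list)
    audit: list = field(default_factory=list)
    config: dict = field(default_factory=dict)
    profiles: dict = field(default_factory=dict)

    def main_effects_table(self, n_env: int = 3) -> pd.DataFrame:
        rows = []
        for q in self.qtls:
            row = {
                "chromosome": q["chromosome"],
                "position_cM": q["position_cM"],
                "F": q.get("F", np.nan),
            }
            if self.posterior is not None:
                lab = q["label"]
                row["a"] = self.posterior.get("a", lab)
                row["d"] = self.posterior.get("d", lab)
                for h in range(n_env):
                    row[f"ae{h + 1}"] = self.posterior.get(f"ae:{lab}", f"E{h + 1}")
                    row[f"de{h + 1}"] = self.posterior.get(f"de:{lab}", f"E{h + 1}")
            rows.append(row)
        return pd.DataFrame(rows)

    def epistasis_table(self, n_env: int = 3) -> pd.DataFrame:
        rows = []
        for e in self.pairs:
            row = {
                "chromosome_i": e["chromosome_i"],
                "position_i_cM": e["position_i_cM"],
                "chromosome_j": e["chromosome_j"],
                "position_j_cM": e["position_j_cM"],
                "F": e.get("F", np.nan),
            }
            if self.posterior is not None:
                lab = e["label"]
                row["aa"] = self.posterior.get("aa", lab)
                for h in range(n_env):
                    row[f"aae{h + 1}"] = self.posterior.get(f"aae:{lab}", f"E{h + 1}")
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cofactor pre-selection (MPS)
# ---------------------------------------------------------------------------

def _forward_select(ctx, base_blocks, candidates, blocks_of, alpha_in, max_terms):
    """Forward stepwise selection of term blocks by Henderson F."""
    selected = []
    remaining = list(candidates)
    cand_blocks = {c: blocks_of(c) for c in candidates}
    while remaining and len(selected) < max_terms:
        W_B = np.column_stack(base_blocks + [cand_blocks[s] for s in selected])
        eng = _FEngine(W_B, ctx.y)
        F, df1, df2 = eng.test_many([cand_blocks[c] for c in remaining])
        with np.errstate(invalid="ignore"):
            p = stats.f.sf(F[:, 0], np.maximum(df1, 1), np.maximum(df2, 1))
        p[~np.isfinite(F[:, 0])] = np.inf
        if not len(p) or np.all(~np.isfinite(p)):
            break
        best = int(np.lexsort((-F[:, 0], p))[0])
        if not np.isfinite(p[best]) or p[best] >= alpha_in:
            break
        selected.append(remaining.pop(best))
    return selected


def select_cofactors_mps(
    ctx: ScanContext, alpha_in: float = 0.01, max_cofactors: int = 10
) -> list:
    """Forward stepwise selection of marker intervals as scan cofactors."""
    if not 0.0 < alpha_in < 1.0:
        raise ValueError("alpha_in must be in (0, 1)")
    if max_cofactors <= 0:
        return []
    return _forward_select(
        ctx, [ctx.intercepts()], list(ctx.intervals.index),
        ctx.marker_block, alpha_in, max_cofactors,
    )


def select_cofactor_pairs(
    ctx: ScanContext,
    declared: list,
    alpha_in: float = 0.01,
    max_pairs: int = 5,
) -> list:
    """Forward stepwise selection of marker-interval pairs (xi*xi products)
    as cofactors for the 2D scan, conditional on declared QTL terms."""
    if max_pairs <= 0:
        return []
    base = [ctx.intercepts()] + [
        ctx.qtl_block(q["chromosome_idx"], q["position_cM"]) for q in declared
    ]
    cands = [
        (gi, gj)
        for gi in ctx.intervals.index
        for gj in ctx.intervals.index
        if gi < gj and ctx.allowed_interval_pair(gi, gj)
    ]
    return _forward_select(
        ctx, base, cands, lambda p: ctx.pair_block(*p), alpha_in, max_pairs
    )


# ---------------------------------------------------------------------------
# genome scans
# ---------------------------------------------------------------------------

def _scan_1d_F(ctx: ScanContext, cofactors, step, Y):
    """F values at every 1D grid position for each response column."""
    Y = np.asarray(Y, dtype=float)
    m = 1 if Y.ndim == 1 else Y.shape[1]
    grid = ctx.grid_1d(step)
    F = np.full((len(grid), m), np.nan)
    meta = []
    by_interval: dict = {}
    for gidx, (c, pos) in enumerate(grid):
        by_interval.setdefault(ctx.interval_of(c, pos), []).append(gidx)
    for iv, gidxs in by_interval.items():
        included = [
            cf for cf in cofactors if ctx.interval_distance(cf, iv) > ctx.window
        ]
        W_B = np.column_stack(
            [ctx.intercepts()] + [ctx.marker_block(cf) for cf in included]
        )
        eng = _FEngine(W_B, Y)
        blocks = [ctx.qtl_block(*grid[g]) for g in gidxs]
        Fg, df1, df2 = eng.test_many(blocks)
        for j, gidx in enumerate(gidxs):
            F[gidx] = Fg[j]
            meta.append((gidx, df1[j] if df1[j] > 0 else np.nan,
                         df2[j] if df1[j] > 0 else np.nan))
    return grid, F, dict((g, (a, b)) for g, a, b in meta)


def scan_1d(
    ctx: ScanContext, cofactors: list, step: float = 1.0
) -> ScanProfile:
    """1D genome scan testing per-environment additive+dominance blocks."""
    if step <= 0:
        raise ValueError("step must be positive")
    grid, F, dfs = _scan_1d_F(ctx, cofactors, step, ctx.y)
    rows = []
    for gidx, (c, pos) in enumerate(grid):
        f = F[gidx, 0]
        df1, df2 = dfs.get(gidx, (np.nan, np.nan))
        p = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else np.nan
        rows.append(
            {
                "chromosome": ctx.lmap.chrom_names[c],
                "chromosome_idx": c,
                "position_cM": pos,
                "F": f,
                "df1": df1,
                "df2": df2,
                "p": p,
            }
        )
    return ScanProfile(pd.DataFrame(rows), kind="1d")


def _pair_grid(
    ctx: ScanContext,
    step: float,
    anchors: list | None = None,
    interval_subset: set | None = None,
) -> list:
    """Tested position pairs ((ci, pi, iv_i), (cj, pj, iv_j)) at the 2D step.

    ``anchors`` are extra exact positions (declared QTLs) added to the grid so
    candidate pairs are tested at the declared loci, not only at grid points.
    ``interval_subset`` restricts the tested pairs to candidate intervals.
    """
    pergrid = {}
    points = ctx.grid_1d(step)
    for c, pos in anchors or []:
        if not any(ci == c and abs(p - pos) < 1e-9 for ci, p in points):
            points.append((c, float(pos)))
    for c, pos in points:
        pergrid.setdefault(ctx.interval_of(c, pos), []).append((c, pos))
    if interval_subset is not None:
        pergrid = {iv: pts for iv, pts in pergrid.items() if iv in interval_subset}
    pairs = []
    ivs = sorted(pergrid)
    for ii, gi in enumerate(ivs):
        for gj in ivs[ii:]:
            if gi == gj or not ctx.allowed_interval_pair(gi, gj):
                continue
            for (ci, pi) in pergrid[gi]:
                for (cj, pj) in pergrid[gj]:
                    pairs.append(((ci, pi, gi), (cj, pj, gj)))
    return pairs


def _scan_2d_F(ctx: ScanContext, declared, pair_cofactors, Y, pos_pairs):
    """F values for explicit position pairs, grouped by background design.

    Each epistasis test is conditional on the *tested* loci's own
    per-environment additive/dominance terms (in addition to the declared
    QTLs and pair cofactors): x_AA contains -x_D/2 of each member exactly,
    so an unconditioned test would read marginal dominance as interaction.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    m = Y.shape[1]
    declared_blocks = [
        ctx.qtl_block(q["chromosome_idx"], q["position_cM"]) for q in declared
    ]
    F = np.full((len(pos_pairs), m), np.nan)
    dfs = {}
    # group by the set of pair cofactors excluded near the tested intervals
    groups: dict = {}
    for idx, ((ci, pi, gi), (cj, pj, gj)) in enumerate(pos_pairs):
        excl = []
        for k, (ca, cb) in enumerate(pair_cofactors):
            near_ab = (
                ctx.interval_distance(ca, gi) <= ctx.window
                and ctx.interval_distance(cb, gj) <= ctx.window
            )
            near_ba = (
                ctx.interval_distance(ca, gj) <= ctx.window
                and ctx.interval_distance(cb, gi) <= ctx.window
            )
            if near_ab or near_ba:
                excl.append(k)
        groups.setdefault(tuple(excl), []).append(idx)
    n = ctx.n_obs
    for excl, idxs in groups.items():
        bg = [ctx.intercepts()] + declared_blocks + [
            ctx.pair_block(*pc)
            for k, pc in enumerate(pair_cofactors)
            if k not in excl
        ]
        eng = _FEngine(np.column_stack(bg), Y)
        QB, RY, sse_red = eng.QB, eng.RY, eng.sse_red
        for idx in idxs:
            (ci, pi, _), (cj, pj, _) = pos_pairs[idx]
            # main-effect terms of the tested loci join the null model
            Z = np.column_stack(
                [ctx.qtl_block(ci, pi), ctx.qtl_block(cj, pj)]
            )
            UZ = orth_basis(Z - QB @ (QB.T @ Z))
            W = ctx.epi_block(ci, pi, cj, pj)
            Wt = W - QB @ (QB.T @ W)
            Wt -= UZ @ (UZ.T @ Wt)
            scale = np.linalg.norm(W)
            U, s, _ = np.linalg.svd(Wt, full_matrices=False)
            k = int(np.sum(s > RANK_RTOL * max(scale, s[0] if s.size else 0.0)))
            df2 = n - eng.r_wb - UZ.shape[1] - k
            if k == 0 or df2 <= 0:
                continue
            TZ = UZ.T @ RY
            TW = U[:, :k].T @ RY
            sse_base = sse_red - np.einsum("ij,ij->j", TZ, TZ)
            ssr = np.einsum("ij,ij->j", TW, TW)
            sse = np.maximum(sse_base - ssr, 0.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                F[idx] = (ssr / k) / (sse / df2)
            dfs[idx] = (k, df2)
    return F, dfs


def scan_2d(
    ctx: ScanContext,
    declared: list,
    pair_cofactors: list,
    step: float = 5.0,
    interval_subset: set | None = None,
) -> ScanProfile:
    """2D scan testing per-environment epistatic (x_A x_A) blocks.

    With ``interval_subset`` the scan covers pairs of candidate intervals
    only; otherwise the whole genome."""
    if step <= 0:
        raise ValueError("step must be positive")
    anchors = [(q["chromosome_idx"], q["position_cM"]) for q in declared]
    pos_pairs = _pair_grid(ctx, step, anchors, interval_subset)
    F, dfs = _scan_2d_F(ctx, declared, pair_cofactors, ctx.y, pos_pairs)
    rows = []
    for idx, ((ci, pi, gi), (cj, pj, gj)) in enumerate(pos_pairs):
        f = F[idx, 0]
        df1, df2 = dfs.get(idx, (np.nan, np.nan))
        rows.append(
            {
                "chromosome_i": ctx.lmap.chrom_names[ci],
                "chromosome_i_idx": ci,
                "position_i_cM": pi,
                "chromosome_j": ctx.lmap.chrom_names[cj],
                "chromosome_j_idx": cj,
                "position_j_cM": pj,
                "F": f,
                "df1": df1,
                "df2": df2,
                "p": float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else np.nan,
            }
        )
    cols = [
        "chromosome_i", "chromosome_i_idx", "position_i_cM",
        "chromosome_j", "chromosome_j_idx", "position_j_cM",
        "F", "df1", "df2", "p",
    ]
    return ScanProfile(pd.DataFrame(rows, columns=cols), kind="2d")


# ---------------------------------------------------------------------------
# permutation thresholds
# ---------------------------------------------------------------------------

def _permuted_responses(ctx: ScanContext, n_perm: int, rng) -> np.ndarray:
    """Phenotypes permuted within environment x backcross-origin strata."""
    Y = np.empty((ctx.n_obs, n_perm))
    strata = []
    origin_obs = ctx.data.origin[ctx.ind]
    for h in range(ctx.n_env):
        for o in (0, 1):
            idx = np.where((ctx.env == h) & (origin_obs == o))[0]
            if idx.size:
                strata.append(idx)
    for j in range(n_perm):
        col = ctx.y.copy()
        for idx in strata:
            col[idx] = ctx.y[idx][rng.permutation(idx.size)]
        Y[:, j] = col
    return Y


def permutation_threshold(
    ctx: ScanContext,
    kind: str,
    n_perm: int,
    alpha: float,
    seed,
    cofactors: list | None = None,
    declared: list | None = None,
    pair_cofactors: list | None = None,
    step: float | None = None,
    interval_subset: set | None = None,
) -> float:
    """Genome-wide (1 - alpha) empirical quantile of the max-F statistic."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if alpha < 1.0 / n_perm:
        raise ValueError(f"alpha={alpha} unresolvable with n_perm={n_perm}")
    rng = np.random.default_rng(seed)
    Y = _permuted_responses(ctx, n_perm, rng)
    if kind == "1d":
        _, F, _ = _scan_1d_F(ctx, cofactors or [], step or 1.0, Y)
    elif kind == "2d":
        anchors = [(q["chromosome_idx"], q["position_cM"]) for q in declared or []]
        pos_pairs = _pair_grid(ctx, step or 5.0, anchors, interval_subset)
        F, _ = _scan_2d_F(ctx, declared or [], pair_cofactors or [], Y, pos_pairs)
    else:
        raise ValueError("kind must be '1d' or '2d'")
    if F.shape[0] == 0:
        return float("inf")  # nothing to test: threshold can never be crossed
    with np.errstate(all="ignore"):
        max_f = np.nanmax(np.nan_to_num(F, nan=-np.inf), axis=0)
    max_f = np.sort(max_f)
    k = math.ceil((1.0 - alpha) * n_perm)
    return float(max_f[k - 1])


# ---------------------------------------------------------------------------
# peak calling
# ---------------------------------------------------------------------------

def call_peaks(
    profile: ScanProfile, threshold: float, min_separation_cm: float = 20.0
) -> list:
    """Local maxima above threshold, merged within the separation window."""
    df = profile.table
    cands = []
    for c, grp in df.groupby("chromosome_idx", sort=True):
        grp = grp.sort_values("position_cM").reset_index(drop=True)
        F = grp["F"].to_numpy()
        pos = grp["position_cM"].to_numpy()
        for i in range(len(grp)):
            f = F[i]
            if not np.isfinite(f) or f <= threshold:
                continue
            left = F[i - 1] if i > 0 else -np.inf
            right = F[i + 1] if i < len(grp) - 1 else -np.inf
            if f > left and f >= right:  # plateau resolved to leftmost point
                cands.append(
                    {
                        "chromosome": grp["chromosome"].iloc[i],
                        "chromosome_idx": int(c),
                        "position_cM": float(pos[i]),
                        "F": float(f),
                    }
                )
    cands.sort(key=lambda d: (-d["F"], d["chromosome_idx"], d["position_cM"]))
    kept = []
    for cand in cands:
        clash = any(
            k["chromosome_idx"] == cand["chromosome_idx"]
            and abs(k["position_cM"] - cand["position_cM"]) < min_separation_cm
            for k in kept
        )
        if not clash:
            kept.append(cand)
    kept.sort(key=lambda d: (d["chromosome_idx"], d["position_cM"]))
    for q in kept:
        q["label"] = f"{q['chromosome']}@{q['position_cM']:.2f}"
    return kept


def _nms_pairs(cands: list, min_separation_cm: float) -> list:
    """Greedy non-maximum suppression of pair candidates (largest F first)."""
    cands = sorted(
        cands,
        key=lambda d: (
            -d["F"], d["chromosome_i_idx"], d["position_i_cM"],
            d["chromosome_j_idx"], d["position_j_cM"],
        ),
    )
    kept = []
    for c in cands:
        clash = any(
            k["chromosome_i_idx"] == c["chromosome_i_idx"]
            and k["chromosome_j_idx"] == c["chromosome_j_idx"]
            and abs(k["position_i_cM"] - c["position_i_cM"]) < min_separation_cm
            and abs(k["position_j_cM"] - c["position_j_cM"]) < min_separation_cm
            for k in kept
        )
        if not clash:
            kept.append(c)
    return kept


def call_peaks_2d(
    profile: ScanProfile, threshold: float, min_separation_cm: float = 20.0
) -> list:
    """Above-threshold pair maxima with non-maximum suppression."""
    df = profile.table
    if df.empty:
        return []
    F = pd.to_numeric(df["F"], errors="coerce")
    df = df[np.isfinite(F) & (F > threshold)]
    cands = [
        {
            "chromosome_i": row.chromosome_i,
            "chromosome_i_idx": int(row.chromosome_i_idx),
            "position_i_cM": float(row.position_i_cM),
            "chromosome_j": row.chromosome_j,
            "chromosome_j_idx": int(row.chromosome_j_idx),
            "position_j_cM": float(row.position_j_cM),
            "F": float(row.F),
        }
        for row in df.itertuples()
    ]
    return _nms_pairs(cands, min_separation_cm)


def _refine_pair(ctx, declared, pair_cofactors, peak, span_cm, step=1.0):
    """1 cM refinement of a 2D peak within +/- span of each member.

    A member within the exclusion window of a declared main-effect QTL is
    pinned to that QTL's (1D-estimated) position; only free members slide.
    """
    def local_grid(c, p0):
        for q in declared:
            if q["chromosome_idx"] == c and abs(q["position_cM"] - p0) <= ctx.window:
                return [float(q["position_cM"])]
        pos = ctx.lmap.positions[c]
        lo, hi = max(pos[0], p0 - span_cm), min(pos[-1], p0 + span_cm)
        return [float(x) for x in np.arange(lo, hi + 1e-9, step)]

    ci, cj = peak["chromosome_i_idx"], peak["chromosome_j_idx"]
    combos = []
    for pi in local_grid(ci, peak["position_i_cM"]):
        for pj in local_grid(cj, peak["position_j_cM"]):
            gi = ctx.interval_of(ci, pi)
            gj = ctx.interval_of(cj, pj)
            if gi == gj or not ctx.allowed_interval_pair(gi, gj):
                continue
            combos.append(((ci, pi, gi), (cj, pj, gj)))
    if not combos:
        return peak
    F, _ = _scan_2d_F(ctx, declared, pair_cofactors, ctx.y, combos)
    best = int(np.nanargmax(F[:, 0]))
    (ci, pi, _), (cj, pj, _) = combos[best]
    out = dict(peak)
    out.update(position_i_cM=pi, position_j_cM=pj, F=float(F[best, 0]))
    return out


# ---------------------------------------------------------------------------
# final model selection and estimation
# ---------------------------------------------------------------------------

def _pair_label(e) -> str:
    return (
        f"{e['chromosome_i']}@{e['position_i_cM']:.2f}"
        f"x{e['chromosome_j']}@{e['position_j_cM']:.2f}"
    )


def select_final_model(
    ctx: ScanContext,
    main_candidates: list,
    pair_candidates: list,
    config: RunConfig | None = None,
    seed=None,
) -> MappingResult:
    """Backward elimination over candidate term blocks, then full-model fit."""
    cfg = config or RunConfig()
    audit = []
    mains = [dict(q) for q in main_candidates]
    pairs = [dict(e) for e in pair_candidates]
    for q in mains:
        q.setdefault("label", f"{q['chromosome']}@{q['position_cM']:.2f}")
    for e in pairs:
        e.setdefault("label", _pair_label(e))

    def block_of(item, is_pair):
        if is_pair:
            return ctx.epi_block(
                item["chromosome_i_idx"], item["position_i_cM"],
                item["chromosome_j_idx"], item["position_j_cM"],
            )
        return ctx.qtl_block(item["chromosome_idx"], item["position_cM"])

    while mains or pairs:
        items = [(q, False) for q in mains] + [(e, True) for e in pairs]
        blocks = [block_of(it, isp) for it, isp in items]
        worst, worst_p = None, -np.inf
        for i, (it, isp) in enumerate(items):
            W_B = np.column_stack(
                [ctx.intercepts()] + [b for j, b in enumerate(blocks) if j != i]
            )
            res = _FEngine(W_B, ctx.y).test(blocks[i])
            p = 1.0 if res is None else res[3]
            if p > worst_p:
                worst, worst_p = i, p
        if worst is None or worst_p <= cfg.select_alpha:
            break
        it, isp = items[worst]
        audit.append(
            f"dropped {'pair' if isp else 'qtl'} {it['label']} (p={worst_p:.4g})"
        )
        (pairs if isp else mains).remove(it)

    result = MappingResult(
        qtls=mains, pairs=pairs, audit=audit, config=cfg.to_dict()
    )
    p = ctx.n_env
    env_labels = [f"E{h + 1}" for h in range(p)]
    fixed = [FixedBlock("mu", ["mu"], np.ones((ctx.n_obs, 1)))]
    random = [RandomBlock("env", env_labels, ctx.intercepts())]
    for q in mains:
        x_a, x_d = ctx.locus_coeffs(q["chromosome_idx"], q["position_cM"])
        x_a, x_d = np.nan_to_num(x_a), np.nan_to_num(x_d)
        fixed.append(FixedBlock("a", [q["label"]], x_a[ctx.ind][:, None]))
        fixed.append(FixedBlock("d", [q["label"]], x_d[ctx.ind][:, None]))
        random.append(
            RandomBlock(f"ae:{q['label']}", env_labels, ctx.env_expand(x_a[:, None]))
        )
        random.append(
            RandomBlock(f"de:{q['label']}", env_labels, ctx.env_expand(x_d[:, None]))
        )
    for e in pairs:
        xa_i, _ = ctx.locus_coeffs(e["chromosome_i_idx"], e["position_i_cM"])
        xa_j, _ = ctx.locus_coeffs(e["chromosome_j_idx"], e["position_j_cM"])
        x_aa = np.nan_to_num(xa_i * xa_j)
        fixed.append(FixedBlock("aa", [e["label"]], x_aa[ctx.ind][:, None]))
        random.append(
            RandomBlock(f"aae:{e['label']}", env_labels, ctx.env_expand(x_aa[:, None]))
        )
    model = FullModel(y=ctx.y, fixed=fixed, random=random)
    if cfg.estimation == "gibbs":
        result.posterior = fit_gibbs(
            model, n_burn=cfg.gibbs_burn, n_iter=cfg.gibbs_iter,
            seed=seed if seed is not None else cfg.seed,
        )
    else:
        result.posterior = fit_em(model)
    return result


# ---------------------------------------------------------------------------
# end-to-end orchestration
# ---------------------------------------------------------------------------

def map_qtls(
    data: ProgenyData,
    config: RunConfig | None = None,
    thresholds: dict | None = None,
) -> MappingResult:
    """Full mapping workflow: MPS -> thresholds -> 1D/2D scans -> peak
    calling -> model selection -> effect estimation."""
    cfg = config or RunConfig()
    ctx = ScanContext(data, window_cm=cfg.window_cm)
    ss = np.random.SeedSequence(cfg.seed)
    perm_seed_1d, perm_seed_2d, gibbs_seed = ss.spawn(3)
    audit = []

    cof = select_cofactors_mps(ctx, cfg.mps_alpha, cfg.max_cofactors)
    audit.append(f"MPS selected intervals: {cof}")

    thresholds = dict(thresholds or {})
    if "1d" not in thresholds:
        thresholds["1d"] = permutation_threshold(
            ctx, "1d", cfg.n_perm, cfg.alpha, perm_seed_1d,
            cofactors=cof, step=cfg.step_1d,
        )
    prof1 = scan_1d(ctx, cof, cfg.step_1d)
    prof1.threshold = thresholds["1d"]
    mains = call_peaks(prof1, thresholds["1d"], cfg.min_separation_cm)
    audit.append(f"1D peaks: {[q['label'] for q in mains]}")

    pair_peaks: list = []
    pair_cof: list = []
    if cfg.include_epistasis:
        pair_cof = select_cofactor_pairs(
            ctx, mains, cfg.mps_pair_alpha, cfg.max_cofactor_pairs
        )
        audit.append(f"MPS selected interval pairs: {pair_cof}")
        subset = None
        if cfg.scan_2d_scope == "candidates":
            # candidate intervals: declared QTLs and 1D cofactor intervals
            # (purely epistatic loci surface there through their
            # side-dependent marginal signal) plus members of the strictly
            # pre-selected interval pairs
            subset = {ctx.interval_of(q["chromosome_idx"], q["position_cM"])
                      for q in mains}
            subset.update(cof)
            subset.update(iv for pc in pair_cof for iv in pc)
            audit.append(f"2D candidate intervals: {sorted(subset)}")
        if subset is not None and len(subset) < 2:
            audit.append("2D stage skipped: fewer than two candidate intervals")
            thresholds.setdefault("2d", float("inf"))
            prof2 = None
            result = select_final_model(ctx, mains, [], cfg, seed=gibbs_seed)
            result.thresholds = thresholds
            result.cofactors = cof
            result.cofactor_pairs = pair_cof
            result.audit = audit + result.audit
            result.profiles = {"1d": prof1}
            return result
        if "2d" not in thresholds:
            thresholds["2d"] = permutation_threshold(
                ctx, "2d", cfg.n_perm, cfg.alpha, perm_seed_2d,
                declared=mains, pair_cofactors=pair_cof, step=cfg.step_2d,
                interval_subset=subset,
            )
        prof2 = scan_2d(ctx, mains, pair_cof, cfg.step_2d, interval_subset=subset)
        prof2.threshold = thresholds["2d"]
        raw_peaks = call_peaks_2d(prof2, thresholds["2d"], cfg.min_separation_cm)
        pair_peaks = _nms_pairs(
            [
                _refine_pair(ctx, mains, pair_cof, pk, cfg.refine_span_cm)
                for pk in raw_peaks
            ],
            cfg.min_separation_cm,
        )
        audit.append(f"2D peaks: {[_pair_label(e) for e in pair_peaks]}")
    else:
        prof2 = None

    result = select_final_model(
        ctx, mains, pair_peaks, cfg, seed=gibbs_seed
    )
    result.thresholds = thresholds
    result.cofactors = cof
    result.cofactor_pairs = pair_cof
    result.audit = audit + result.audit
    result.profiles = {"1d": prof1}
    if prof2 is not None:
        result.profiles["2d"] = prof2
    return result
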