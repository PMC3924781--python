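"""Simulation of DH/RI line panels, double backcross progeny and phenotypes.

The generative model for the phenotype of individual k in environment h is

    y_hk = mu + sum_i a_i xA_ki + sum_i d_i xD_ki + sum_ij aa_ij xAA_kij
         + e_h + sum_i ae_hi xA_ki + sum_i de_hi xD_ki + sum_ij aae_hij xAA_kij
         + eps_hk

where the QTL coefficients are the known-genotype codes at the simulated QTL
loci, environment-interaction effects are fixed per-environment constants of
the scenario, e_h ~ N(0, sigma2_env) and eps ~ N(0, sigma2_eps) with
sigma2_eps calibrated so the trait reaches the scenario's heritability.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .probability import recomb_fraction

__all__ = [
    "LinkageMap",
    "QtlEffect",
    "EpistasisEffect",
    "QtlScenario",
    "ProgenyData",
    "build_standard_map",
    "seven_qtl_scenario",
    "simulate_lines",
    "simulate_double_backcross",
    "calibrate_residual_variance",
    "genetic_values",
    "simulate_phenotypes",
    "simulate_dataset",
]


@dataclass
class LinkageMap:
    """Ordered markers with cM positions, grouped by chromosome."""

    chrom_names: list
    marker_names: list  # list of lists, parallel to chrom_names
    positions: list     # list of float arrays, strictly increasing

    def __post_init__(self):
        if len({len(self.chrom_names), len(self.marker_names), len(self.positions)}) != 1:
            raise ValueError("chromosome, name and position lists must align")
        self.positions = [np.asarray(p, dtype=float) for p in self.positions]
        seen = set()
        for c, names, pos in zip(self.chrom_names, self.marker_names, self.positions):
            if len(names) != len(pos):
                raise ValueError(f"chromosome {c}: names/positions length mismatch")
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"chromosome {c}: positions must strictly increase")
            for nm in names:
                if nm in seen:
                    raise ValueError(f"duplicate marker name {nm!r}")
                seen.add(nm)

    @property
    def n_chrom(self) -> int:
        return len(self.chrom_names)

    @property
    def n_markers(self) -> int:
        return sum(len(p) for p in self.positions)

    def chrom_index(self, chrom) -> int:
        return self.chrom_names.index(chrom)

    def offset(self, c: int) -> int:
        """Global column offset of chromosome ``c`` in the genotype matrix."""
        return sum(len(p) for p in self.positions[:c])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c, names, pos in zip(self.chrom_names, self.marker_names, self.positions):
            rows.extend({"chromosome": c, "marker": m, "position_cM": p}
                        for m, p in zip(names, pos))
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LinkageMap":
        chroms, names, pos = [], [], []
        for c, grp in df.groupby("chromosome", sort=False):
            chroms.append(c)
            names.append(list(grp["marker"]))
            pos.append(np.asarray(grp["position_cM"], dtype=float))
        return cls(chroms, names, pos)


def build_standard_map(n_chrom: int = 5, n_markers: int = 11, spacing_cm: float = 10.0) -> LinkageMap:
    """Evenly spaced map: default 5 chromosomes x 11 markers at 10 cM."""
    chroms = [f"C{i + 1}" for i in range(n_chrom)]
    names = [[f"M{i + 1}_{j + 1}" for j in range(n_markers)] for i in range(n_chrom)]
    pos = [np.arange(n_markers) * spacing_cm for _ in range(n_chrom)]
    return LinkageMap(chroms, names, pos)


@dataclass
class QtlEffect:
    """One QTL: position, main effects and fixed per-environment deviations."""

    name: str
    chromosome: str
    position_cm: float
    a: float = 0.0
    d: float = 0.0
    ae: tuple = ()
    de: tuple = ()


@dataclass
class EpistasisEffect:
    name: str
    qtl_i: str
    qtl_j: str
    aa: float = 0.0
    aae: tuple = ()


@dataclass
class QtlScenario:
    """True QTL architecture used by the phenotype generator."""

    qtls: list
    epistasis: list
    n_env: int
    heritability: float
    mu: float = 0.0
    sigma2_env: float = 0.0

    def __post_init__(self):
        if not 0.0 < self.heritability <= 1.0:
            raise ValueError("heritability must be in (0, 1]")
        names = [q.name for q in self.qtls]
        if len(set(names)) != len(names):
            raise ValueError("duplicate QTL names")
        for q in self.qtls:
            q.ae = tuple(q.ae) if len(q.ae) else (0.0,) * self.n_env
            q.de = tuple(q.de) if len(q.de) else (0.0,) * self.n_env
            if len(q.ae) != self.n_env or len(q.de) != self.n_env:
                raise ValueError(f"{q.name}: ae/de must have length n_env")
        for e in self.epistasis:
            if e.qtl_i not in names or e.qtl_j not in names:
                raise ValueError(f"{e.name}: references undeclared QTL")
            e.aae = tuple(e.aae) if len(e.aae) else (0.0,) * self.n_env
            if len(e.aae) != self.n_env:
                raise ValueError(f"{e.name}: aae must have length n_env")

    def qtl(self, name: str) -> QtlEffect:
        return next(q for q in self.qtls if q.name == name)

    def qtl_positions(self) -> list:
        return [(q.chromosome, q.position_cm) for q in self.qtls]

    def main_effect_qtls(self) -> list:
        """QTLs with any nonzero main or QE effect of their own."""
        return [
            q for q in self.qtls
            if q.a != 0 or q.d != 0 or any(q.ae) or any(q.de)
        ]

    def without_epistasis(self) -> "QtlScenario":
        """Same scenario with every epistatic effect removed."""
        out = dataclasses.replace(self)
        out.qtls = [dataclasses.replace(q) for q in self.qtls]
        out.epistasis = []
        return out


def seven_qtl_scenario() -> QtlScenario:
    """The built-in 7-QTL / 3-pair / 3-environment benchmark scenario.

    Five QTLs carry main effects, two are purely epistatic; total trait
    heritability is 60%.
    """
    qtls = [
        QtlEffect("Q1", "C1", 44.0, a=-2.78, d=-3.08),
        QtlEffect("Q2", "C2", 75.0, a=0.00, d=2.50, ae=(-2.00, -0.70, 2.70)),
        QtlEffect("Q3", "C3", 50.0, a=2.90, d=3.50, ae=(2.60, -1.30, -1.30)),
        QtlEffect("Q4", "C4", 73.0, a=-3.30, d=-1.90, de=(-2.10, 2.50, -0.40)),
        QtlEffect("Q5", "C5", 15.0, a=1.90, d=0.00),
        QtlEffect("Q6", "C4", 24.0),
        QtlEffect("Q7", "C5", 79.0),
    ]
    epi = [
        EpistasisEffect("EQ1", "Q1", "Q6", aa=-3.09, aae=(2.52, -0.16, -2.36)),
        EpistasisEffect("EQ2", "Q3", "Q5", aa=2.10, aae=(-2.10, 0.20, 1.90)),
        EpistasisEffect("EQ3", "Q6", "Q7", aa=-2.60),
    ]
    return QtlScenario(qtls=qtls, epistasis=epi, n_env=3, heritability=0.60)


@dataclass
class ProgenyData:
    """Genotyped double-backcross progeny with multi-environment phenotypes.

    ``genotypes`` uses absolute codes (2 = P1/P1, 1 = het, 0 = P2/P2,
    -1 = missing); ``origin`` is 0 for BC_P1 and 1 for BC_P2 progeny.
    """

    lmap: LinkageMap
    genotypes: np.ndarray
    origin: np.ndarray
    line_type: str = "DH"
    phenotypes: pd.DataFrame | None = None
    qtl_positions: list = field(default_factory=list)   # true loci (simulated data)
    qtl_codes: np.ndarray | None = None                 # (n, K) genotype codes there
    sim_info: dict = field(default_factory=dict)

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.origin = np.asarray(self.origin, dtype=np.int8)
        if self.genotypes.shape[1] != self.lmap.n_markers:
            raise ValueError("genotype matrix does not match the linkage map")
        if self.genotypes.shape[0] != self.origin.shape[0]:
            raise ValueError("origin labels do not match the genotype matrix")
        bad_p1 = (self.origin == 0)[:, None] & (self.genotypes == 0)
        bad_p2 = (self.origin == 1)[:, None] & (self.genotypes == 2)
        if bad_p1.any() or bad_p2.any():
            raise ValueError(
                "genotype codes inconsistent with backcross origin "
                "(wrong-parent homozygote found)"
            )

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    def chrom_genotypes(self, c: int) -> np.ndarray:
        off = self.lmap.offset(c)
        return self.genotypes[:, off:off + len(self.lmap.positions[c])]

    def response(self):
        """(y, env_index, individual_index) from the phenotype table."""
        if self.phenotypes is None:
            raise ValueError("no phenotypes attached")
        ph = self.phenotypes.sort_values(["environment", "individual"])
        y = ph["value"].to_numpy(dtype=float)
        env = ph["environment"].to_numpy(dtype=int) - 1
        ind = ph["individual"].to_numpy(dtype=int) - 1
        return y, env, ind


def _simulate_haplotypes(positions: np.ndarray, n: int, rng, line_type: str) -> np.ndarray:
    """Markov chain of parental origins (0 = P1, 1 = P2) along one chromosome."""
    m = len(positions)
    out = np.empty((n, m), dtype=np.uint8)
    out[:, 0] = rng.random(n) < 0.5
    r = recomb_fraction(np.diff(positions))
    if line_type == "RI":
        # expanded recombination after repeated selfing (Haldane-Waddington)
        r = 2.0 * r / (1.0 + 2.0 * r)
    switch = rng.random((n, m - 1)) < r[None, :]
    for j in range(1, m):
        out[:, j] = out[:, j - 1] ^ switch[:, j - 1]
    return out


def simulate_lines(
    lmap: LinkageMap,
    n: int,
    rng,
    line_type: str = "DH",
    extra_positions: list | None = None,
):
    """Simulate ``n`` homozygous lines (DH or selfed RI).

    Each line is represented by its haplotype of parental origins (0 = P1
    allele, 1 = P2 allele) at every marker, plus optionally at extra loci
    (the true QTL positions).

    Returns ``(marker_alleles, extra_alleles)`` with shapes (n, n_markers)
    and (n, len(extra_positions)).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng)
    extra_positions = extra_positions or []
    marker_alleles = np.empty((n, lmap.n_markers), dtype=np.uint8)
    extra_alleles = np.empty((n, len(extra_positions)), dtype=np.uint8)
    for c, chrom in enumerate(lmap.chrom_names):
        mpos = lmap.positions[c]
        extras = [(k, p) for k, (ch, p) in enumerate(extra_positions) if ch == chrom]
        aug = np.concatenate([mpos, [p for _, p in extras]])
        order = np.argsort(aug, kind="stable")
        hap = _simulate_haplotypes(aug[order], n, rng, line_type)
        inv = np.empty_like(order)
        inv[order] = np.arange(len(order))
        off = lmap.offset(c)
        marker_alleles[:, off:off + len(mpos)] = hap[:, inv[:len(mpos)]]
        for slot, (k, _) in enumerate(extras):
            extra_alleles[:, k] = hap[:, inv[len(mpos) + slot]]
    return marker_alleles, extra_alleles


def simulate_double_backcross(
    lmap: LinkageMap,
    marker_alleles: np.ndarray,
    n1: int,
    n2: int,
    rng,
    line_type: str = "DH",
    extra_alleles: np.ndarray | None = None,
    qtl_positions: list | None = None,
) -> ProgenyData:
    """Cross lines to P1 (n1 progeny) and to P2 (n2 progeny).

    A progeny's genotype at a locus is the line's gamete allele plus the
    fixed parental allele. Lines are taken in order when enough exist,
    otherwise sampled with replacement.
    """
    if n1 < 0 or n2 < 0:
        raise ValueError("progeny counts must be non-negative")
    rng = np.random.default_rng(rng)
    n_lines = marker_alleles.shape[0]
    total = n1 + n2
    if total <= n_lines:
        pick = np.arange(total)
    else:
        pick = rng.integers(0, n_lines, size=total)
    origin = np.concatenate([np.zeros(n1, np.int8), np.ones(n2, np.int8)])
    la = marker_alleles[pick]

    def codes(alleles):
        # BC_P1: P1 allele (0) -> P1/P1 hom (2); P2 allele -> het (1)
        # BC_P2: P2 allele (1) -> P2/P2 hom (0); P1 allele -> het (1)
        c = np.empty(alleles.shape, dtype=np.int8)
        p1 = origin == 0
        c[p1] = np.where(alleles[p1] == 0, 2, 1)
        c[~p1] = np.where(alleles[~p1] == 1, 0, 1)
        return c

    qtl_codes = None
    if extra_alleles is not None and qtl_positions:
        qtl_codes = codes(extra_alleles[pick])
    return ProgenyData(
        lmap=lmap,
        genotypes=codes(la),
        origin=origin,
        line_type=line_type,
        qtl_positions=list(qtl_positions or []),
        qtl_codes=qtl_codes,
    )


def _true_coefficients(progeny: ProgenyData, scenario: QtlScenario):
    """Known-genotype xA, xD at the true QTLs and xAA per epistatic pair."""
    if progeny.qtl_codes is None:
        raise ValueError("progeny lacks simulated QTL genotypes")
    pos_index = {f"{c}:{p}": k for k, (c, p) in enumerate(progeny.qtl_positions)}
    cols = [pos_index[f"{q.chromosome}:{q.position_cm}"] for q in scenario.qtls]
    code = progeny.qtl_codes[:, cols].astype(float)
    x_a = code - 1.0
    x_d = np.where(code == 1, 0.5, -0.5)
    name_col = {q.name: j for j, q in enumerate(scenario.qtls)}
    x_aa = np.column_stack(
        [x_a[:, name_col[e.qtl_i]] * x_a[:, name_col[e.qtl_j]] for e in scenario.epistasis]
    ) if scenario.epistasis else np.zeros((progeny.n_individuals, 0))
    return x_a, x_d, x_aa


def genetic_values(progeny: ProgenyData, scenario: QtlScenario) -> np.ndarray:
    """Summed genetic contribution per (environment, individual): (p, n)."""
    x_a, x_d, x_aa = _true_coefficients(progeny, scenario)
    a = np.array([q.a for q in scenario.qtls])
    d = np.array([q.d for q in scenario.qtls])
    aa = np.array([e.aa for e in scenario.epistasis])
    base = x_a @ a + x_d @ d + (x_aa @ aa if len(aa) else 0.0)
    G = np.tile(base, (scenario.n_env, 1))
    for h in range(scenario.n_env):
        ae = np.array([q.ae[h] for q in scenario.qtls])
        de = np.array([q.de[h] for q in scenario.qtls])
        aae = np.array([e.aae[h] for e in scenario.epistasis])
        G[h] += x_a @ ae + x_d @ de + (x_aa @ aae if len(aae) else 0.0)
    return G


def calibrate_residual_variance(scenario: QtlScenario, progeny: ProgenyData) -> float:
    """Residual variance giving the scenario's heritability on this sample.

    sigma2_eps = V_G (1 - h2) / h2 with V_G the empirical variance of the
    summed genetic contributions over individuals and environments.
    """
    h2 = scenario.heritability
    if h2 <= 0:
        raise ValueError("heritability must be positive")
    v_g = float(np.var(genetic_values(progeny, scenario)))
    if h2 == 1.0:
        return 0.0
    if v_g == 0.0:
        raise ValueError("no genetic variance: cannot calibrate residual")
    return v_g * (1.0 - h2) / h2


def simulate_phenotypes(progeny: ProgenyData, scenario: QtlScenario, rng) -> pd.DataFrame:
    """Attach a simulated multi-environment phenotype table to ``progeny``."""
    rng = np.random.default_rng(rng)
    G = genetic_values(progeny, scenario)
    p, n = G.shape
    sigma2_eps = calibrate_residual_variance(scenario, progeny)
    e_h = rng.normal(0.0, np.sqrt(scenario.sigma2_env), size=p) if scenario.sigma2_env > 0 else np.zeros(p)
    eps = rng.normal(0.0, np.sqrt(sigma2_eps), size=(p, n)) if sigma2_eps > 0 else np.zeros((p, n))
    Y = scenario.mu + G + e_h[:, None] + eps
    table = pd.DataFrame(
        {
            "environment": np.repeat(np.arange(1, p + 1), n),
            "individual": np.tile(np.arange(1, n + 1), p),
            "value": Y.ravel(),
        }
    )
    progeny.phenotypes = table
    progeny.sim_info = {
        "sigma2_eps": sigma2_eps,
        "genetic_values": G,
        "realized_h2": float(np.var(G) / np.var(Y)) if np.var(Y) > 0 else np.nan,
    }
    return table


def simulate_dataset(
    scenario: QtlScenario,
    n1: int,
    n2: int,
    seed,
    lmap: LinkageMap | None = None,
    line_type: str = "DH",
) -> ProgenyData:
    """One fully simulated dataset: lines -> double backcross -> phenotypes."""
    rng = np.random.default_rng(seed)
    lmap = lmap or build_standard_map()
    qtl_pos = scenario.qtl_positions()
    marker_alleles, extra = simulate_lines(
        lmap, max(n1 + n2, 1), rng, line_type=line_type, extra_positions=qtl_pos
    )
    progeny = simulate_double_backcross(
        lmap, marker_alleles, n1, n2, rng,
        line_type=line_type, extra_alleles=extra, qtl_positions=qtl_pos,
    )
    simulate_phenotypes(progeny, scenario, rng)
    return progeny
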