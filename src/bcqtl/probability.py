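"""Recombination arithmetic and conditional QTL-genotype probabilities.

Converts flanking-marker genotypes of double-backcross progeny (DH or RI
lines crossed to either homozygous parent) into conditional probabilities of
the three QTL genotypes at any scanned position, and from those into the
additive/dominance/epistatic effect coefficients used by the scan models.

Genotype codes used throughout the package are absolute:
``2`` = P1/P1 homozygote, ``1`` = heterozygote, ``0`` = P2/P2 homozygote,
``-1`` = missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeInconsistencyError",
    "IntervalGeometry",
    "QtlConditionalProbs",
    "EffectCoefficients",
    "recomb_fraction",
    "map_distance",
    "split_interval",
    "conditional_probs",
    "effect_coefficients",
    "epistasis_coefficient",
    "marker_cofactor_coefficients",
    "coefficient_lookup",
    "locus_effect_coefficients",
    "probability_table",
]

#: recombination fractions below this are treated as exactly zero
R_EPS = 1e-8

SIDES = ("P1", "P2")
LINE_TYPES = ("DH", "RI")
#: the four flank classes as (left_is_het, right_is_het)
FLANK_CLASSES = (
    ("hom", "hom"),
    ("hom", "het"),
    ("het", "hom"),
    ("het", "het"),
)


class GenotypeInconsistencyError(ValueError):
    """A probability-zero marker observation given the interval geometry."""


def recomb_fraction(distance_cm):
    """Haldane map function: cM distance -> recombination fraction.

    Accepts scalars or arrays; raises on negative distances.
    """
    d = np.asarray(distance_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("genetic distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return r if r.ndim else float(r)


def map_distance(r):
    """Inverse Haldane: recombination fraction -> cM distance."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = -50.0 * np.log(1.0 - 2.0 * r)
    return d if d.ndim else float(d)


@dataclass(frozen=True)
class IntervalGeometry:
    """Recombination bookkeeping for a marker interval with a tested locus.

    ``r1`` is the recombination fraction between the left flanking marker and
    the locus, ``r2`` between the locus and the right marker, ``r`` across the
    whole interval (no interference: ``r = r1 + r2 - 2 r1 r2``), and the
    ``s`` values are the complements.
    """

    r1: float
    r2: float

    def __post_init__(self):
        for name in ("r1", "r2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 0.5:
                raise ValueError(f"{name}={v} outside [0, 0.5]")

    @property
    def r(self) -> float:
        return self.r1 + self.r2 - 2.0 * self.r1 * self.r2

    @property
    def s(self) -> float:
        return 1.0 - self.r

    @property
    def s1(self) -> float:
        return 1.0 - self.r1

    @property
    def s2(self) -> float:
        return 1.0 - self.r2


def split_interval(left_dist_cm: float, right_dist_cm: float) -> IntervalGeometry:
    """Geometry of a locus splitting an interval into two cM sub-distances."""
    return IntervalGeometry(
        r1=recomb_fraction(left_dist_cm), r2=recomb_fraction(right_dist_cm)
    )


@dataclass(frozen=True)
class QtlConditionalProbs:
    """P(QQ), P(Qq), P(qq) at the tested locus given the flank class."""

    p1: float
    p2: float
    p3: float

    def as_tuple(self):
        return (self.p1, self.p2, self.p3)


@dataclass(frozen=True)
class EffectCoefficients:
    """Additive/dominance coefficients implied by QTL genotype probabilities."""

    x_a: float
    x_d: float


def _near_far(line_type: str, left_het: bool, right_het: bool, g: IntervalGeometry):
    """Probability that the line gamete carries the recurrent-parent allele
    at the locus ("near") vs the opposite allele ("far"), given flank states.

    "het" flanks mark where the line haplotype carries the non-recurrent
    parent's allele.
    """
    r1, r2, r = g.r1, g.r2, g.r
    s1, s2, s = g.s1, g.s2, g.s
    recombinant = left_het != right_het
    if line_type == "DH":
        if recombinant:
            if r < R_EPS:
                raise GenotypeInconsistencyError(
                    "recombinant flanking genotypes in a zero-length interval"
                )
            return (s1 * r2 / r, r1 * s2 / r) if not left_het else (r1 * s2 / r, s1 * r2 / r)
        if not left_het:
            return s1 * s2 / s, r1 * r2 / s
        return r1 * r2 / s, s1 * s2 / s
    if line_type == "RI":
        if recombinant:
            if r1 + r2 < R_EPS:
                raise GenotypeInconsistencyError(
                    "recombinant flanking genotypes in a zero-length interval"
                )
            return (r2 / (r1 + r2), r1 / (r1 + r2)) if not left_het else (
                r1 / (r1 + r2),
                r2 / (r1 + r2),
            )
        w = 4.0 * r1 * r2
        if not left_het:
            return 1.0 / (1.0 + w), w / (1.0 + w)
        return w / (1.0 + w), 1.0 / (1.0 + w)
    raise ValueError(f"unknown line type {line_type!r}")


def conditional_probs(
    flank: tuple[str, str],
    side: str,
    line_type: str,
    geom: IntervalGeometry,
) -> QtlConditionalProbs:
    """Conditional QTL genotype probabilities given the flanking-marker class.

    Parameters
    ----------
    flank
        ``(left_state, right_state)`` with states ``"hom"``/``"het"``. On the
        DH(RI) x P1 side "hom" means P1/P1; on the x P2 side it means P2/P2.
    side
        ``"P1"`` or ``"P2"`` — which parent the lines were backcrossed to.
    line_type
        ``"DH"`` or ``"RI"`` (selfed RI).
    """
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}")
    if flank not in FLANK_CLASSES:
        raise ValueError(f"flank class must be one of {FLANK_CLASSES}")
    left_het = flank[0] == "het"
    right_het = flank[1] == "het"
    near, far = _near_far(line_type, left_het, right_het, geom)
    if side == "P1":
        return QtlConditionalProbs(near, far, 0.0)
    return QtlConditionalProbs(0.0, far, near)


def effect_coefficients(probs: QtlConditionalProbs) -> EffectCoefficients:
    """x_A = p1 - p3 and x_D = (p2 - p1 - p3)/2."""
    return EffectCoefficients(
        x_a=probs.p1 - probs.p3,
        x_d=(probs.p2 - probs.p1 - probs.p3) / 2.0,
    )


def epistasis_coefficient(xa_i: float, xa_j: float) -> float:
    """Additive-by-additive coefficient: the product of the two x_A values."""
    return xa_i * xa_j


_MARKER_CODES = {"MM": (1.0, -0.5), "Mm": (0.0, 0.5), "mm": (-1.0, -0.5)}


def marker_cofactor_coefficients(marker_genotype) -> tuple[float, float]:
    """(xi, zeta) cofactor codes for a marker genotype.

    Accepts the symbolic codes ``"MM"/"Mm"/"mm"`` or the numeric codes
    ``2/1/0``. xi is 1/0/-1 and zeta is -0.5/0.5/-0.5 respectively.
    """
    if isinstance(marker_genotype, str):
        try:
            return _MARKER_CODES[marker_genotype]
        except KeyError:
            raise ValueError(f"unknown marker genotype {marker_genotype!r}") from None
    code = int(marker_genotype)
    if code not in (0, 1, 2):
        raise ValueError(f"unknown marker genotype code {code!r}")
    return (float(code - 1), 0.5 if code == 1 else -0.5)


# ---------------------------------------------------------------------------
# vectorized lookup used by the simulator and the genome scan
# ---------------------------------------------------------------------------

def coefficient_lookup(geom: IntervalGeometry, line_type: str = "DH"):
    """(x_A, x_D) lookup tables indexed by [side, left_code, right_code].

    ``side`` is 0 for BC_P1 and 1 for BC_P2; marker codes are the absolute
    0/1/2 codes. Entries for combinations impossible on a side (e.g. a P2/P2
    homozygote in a BC_P1 progeny) are NaN.
    """
    A = np.full((2, 3, 3), np.nan)
    D = np.full((2, 3, 3), np.nan)
    for si, side in enumerate(SIDES):
        hom_code = 2 if side == "P1" else 0
        for lstate, lcode in (("hom", hom_code), ("het", 1)):
            for rstate, rcode in (("hom", hom_code), ("het", 1)):
                try:
                    p = conditional_probs((lstate, rstate), side, line_type, geom)
                except GenotypeInconsistencyError:
                    continue
                c = effect_coefficients(p)
                A[si, lcode, rcode] = c.x_a
                D[si, lcode, rcode] = c.x_d
    return A, D


def _single_flank_coeffs(genotype_codes, origin, line_type, dist_cm):
    """Coefficients when only one informative flanking marker exists."""
    if line_type == "DH":
        r = recomb_fraction(dist_cm)
        near, far = 1.0 - r, r
    else:
        # expanded recombination on an RI (selfed) map
        r = recomb_fraction(dist_cm)
        R = 2.0 * r / (1.0 + 2.0 * r)
        near, far = 1.0 - R, R
    x_a = np.full(genotype_codes.shape, np.nan)
    x_d = np.full(genotype_codes.shape, np.nan)
    p1_side = origin == 0
    hom = genotype_codes == np.where(p1_side, 2, 0)
    het = genotype_codes == 1
    # P1 side: (p1, p2) = (near, far) if hom flank else (far, near)
    p_rec = np.where(hom, near, np.where(het, far, np.nan))
    p_het = np.where(hom, far, np.where(het, near, np.nan))
    x_a = np.where(p1_side, p_rec, -p_rec)
    x_d = (p_het - p_rec) / 2.0
    return x_a, x_d


def locus_effect_coefficients(
    genotypes: np.ndarray,
    origin: np.ndarray,
    line_type: str,
    marker_pos: np.ndarray,
    position: float,
):
    """Per-individual (x_A, x_D) at an arbitrary chromosome position.

    Parameters
    ----------
    genotypes
        ``(n, m)`` absolute genotype codes for the chromosome's ``m`` markers
        (``-1`` = missing).
    origin
        length-``n`` backcross origin labels, 0 = BC_P1, 1 = BC_P2.
    marker_pos
        increasing cM positions of the chromosome's markers.
    position
        tested position in cM (within the map span).

    Individuals with missing flanks fall back to the nearest non-missing
    markers (enlarged interval); with no informative marker at all the
    coefficients are NaN.
    """
    genotypes = np.asarray(genotypes)
    origin = np.asarray(origin)
    marker_pos = np.asarray(marker_pos, dtype=float)
    n, m = genotypes.shape
    x_a = np.full(n, np.nan)
    x_d = np.full(n, np.nan)

    observed = genotypes >= 0
    left_ok = observed & (marker_pos[None, :] <= position + 1e-9)
    right_ok = observed & (marker_pos[None, :] >= position - 1e-9)
    # nearest informative flank indices; -1 where none exists
    li = np.where(
        left_ok.any(axis=1), m - 1 - np.argmax(left_ok[:, ::-1], axis=1), -1
    )
    ri = np.where(right_ok.any(axis=1), np.argmax(right_ok, axis=1), -1)

    keys = (li + 1) * (m + 2) + (ri + 1)
    for key in np.unique(keys):
        sel = keys == key
        l, r = int(key // (m + 2)) - 1, int(key % (m + 2)) - 1
        if l < 0 and r < 0:
            continue  # no informative marker: stays NaN
        if l < 0 or r < 0:
            idx = l if l >= 0 else r
            xa, xd = _single_flank_coeffs(
                genotypes[sel, idx], origin[sel], line_type,
                abs(position - marker_pos[idx]),
            )
            x_a[sel], x_d[sel] = xa, xd
            continue
        if l == r or marker_pos[r] - marker_pos[l] < 1e-9:
            # position sits on a non-missing marker: genotype is known
            code = genotypes[sel, l]
            x_a[sel] = code - 1.0
            x_d[sel] = np.where(code == 1, 0.5, -0.5)
            continue
        geom = split_interval(position - marker_pos[l], marker_pos[r] - position)
        A, D = coefficient_lookup(geom, line_type)
        x_a[sel] = A[origin[sel], genotypes[sel, l], genotypes[sel, r]]
        x_d[sel] = D[origin[sel], genotypes[sel, l], genotypes[sel, r]]
    return x_a, x_d


def probability_table(r1_values, r2_values, line_types=LINE_TYPES) -> pd.DataFrame:
    """Audit table of conditional probabilities on an (r1, r2) grid.

    Columns: side, line_type, flank_class, r1, r2, p1, p2, p3.
    """
    rows = []
    for line_type in line_types:
        for side in SIDES:
            for flank in FLANK_CLASSES:
                for r1 in np.atleast_1d(r1_values):
                    for r2 in np.atleast_1d(r2_values):
                        geom = IntervalGeometry(float(r1), float(r2))
                        try:
                            p = conditional_probs(flank, side, line_type, geom)
                        except GenotypeInconsistencyError:
                            continue
                        rows.append(
                            {
                                "side": side,
                                "line_type": line_type,
                                "flank_class": "/".join(flank),
                                "r1": float(r1),
                                "r2": float(r2),
                                "p1": p.p1,
                                "p2": p.p2,
                                "p3": p.p3,
                            }
                        )
    return pd.DataFrame(rows)
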