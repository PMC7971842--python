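"""Log-linear case-parent-trio likelihood with a parent-of-origin parameter.

The sampling unit is a case family: an affected child plus (some of) its
parents, genotyped at one biallelic SNP.  Writing m, f, c for the
mother/father/child minor-allele dosages, the expected count of each
Mendelian-consistent trio configuration is modelled as

    E[n(m, f, c, origin)] = mu_j * t * R_c * S_m * W^{[origin = paternal]}

where

* ``mu_j`` — six nuisance strata, one per unordered parental genotype
  pair (mating type), absorbing population structure; ordered pairs within
  a stratum share the same ``mu`` (parental mating symmetry).  The last
  stratum {0,0} is the gauge, fixed at 1 when fitting.
* ``t`` — the Mendelian transmission probability of the child outcome
  given the ordered parental pair (1, 1/2 or 1/4).
* ``R_c`` — relative risk for a child carrying c copies of the minor
  allele (R_0 = 1).
* ``S_m`` — relative risk for a mother carrying m copies (S_0 = 1),
  capturing prenatal maternal-genotype effects.
* ``W`` — the imprinting (parent-of-origin) relative risk: the risk
  multiplier when a heterozygous child's single minor allele is paternally
  rather than maternally derived.  Homozygous children carry one allele
  from each parent, so W applies only to heterozygotes.

Conditioning the Poisson log-linear counts on their total gives a
multinomial over the 16 cells (15 observable trio categories; the
het-het-het category is split into maternal- and paternal-origin cells
because only there the origin is latent).  Families with missing parents
contribute the sum of cell probabilities compatible with their observed
members — the observed-data likelihood used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .pedio import MISSING, TrioGenotype

__all__ = [
    "PoeParams",
    "CellTable",
    "build_cell_table",
    "cell_probs",
    "loglik_complete",
    "loglik_observed",
    "OBSERVABLE_CATEGORIES",
    "STRATA_PAIRS",
]

# Mating strata: unordered parental genotype pairs, conventional order.
STRATA_PAIRS: tuple[tuple[int, int], ...] = (
    (2, 2), (2, 1), (2, 0), (1, 1), (1, 0), (0, 0),
)
_STRATUM_INDEX = {pair: j for j, pair in enumerate(STRATA_PAIRS)}

ORIGIN_NONE = "none"       # child not heterozygous
ORIGIN_MATERNAL = "maternal"
ORIGIN_PATERNAL = "paternal"


def stratum_index(m: int, f: int) -> int:
    """0-based mating-type stratum of an (unordered) parental pair."""
    return _STRATUM_INDEX[tuple(sorted((m, f), reverse=True))]


@dataclass(frozen=True)
class PoeParams:
    """Model parameters; all strictly positive.

    ``mu`` holds the six mating-stratum weights in :data:`STRATA_PAIRS`
    order; the identifiability gauge fixes ``mu[5]`` (the {0,0} stratum)
    at 1 during fitting, but arbitrary positive values are accepted here.
    """

    mu: tuple[float, ...] = (1.0,) * 6
    R1: float = 1.0
    R2: float = 1.0
    S1: float = 1.0
    S2: float = 1.0
    W: float = 1.0

    def __post_init__(self) -> None:
        if len(self.mu) != 6:
            raise ValueError("mu must have six strata")
        for v in (*self.mu, self.R1, self.R2, self.S1, self.S2, self.W):
            if not (v > 0 and np.isfinite(v)):
                raise ValueError(f"parameters must be positive and finite, got {v}")

    @classmethod
    def null(cls) -> "PoeParams":
        return cls()

    def r(self, c: int) -> float:
        return (1.0, self.R1, self.R2)[c]

    def s(self, m: int) -> float:
        return (1.0, self.S1, self.S2)[m]


@dataclass(frozen=True)
class Cell:
    """One complete-trio configuration with (latent) parental origin."""

    m: int
    f: int
    c: int
    stratum: int          # 0..5 into STRATA_PAIRS
    t: float              # Mendelian transmission factor
    origin: str           # maternal / paternal / none

    def multiplier(self, params: PoeParams) -> float:
        w = params.W if self.origin == ORIGIN_PATERNAL else 1.0
        return params.r(self.c) * params.s(self.m) * w


@dataclass
class CellTable:
    """The enumerated support of the complete-trio model.

    16 cells: the 15 Mendelian-consistent (m, f, c) categories, with the
    ambiguous (1, 1, 1) category appearing twice (maternal- and
    paternal-origin, transmission factor 1/4 each).  Within every ordered
    parental pair the transmission factors sum to 1 over child outcomes.
    """

    cells: list[Cell]
    # Derived arrays for vectorized likelihood work.
    m: np.ndarray = field(init=False)
    f: np.ndarray = field(init=False)
    c: np.ndarray = field(init=False)
    stratum: np.ndarray = field(init=False)
    t: np.ndarray = field(init=False)
    paternal: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.m = np.array([cell.m for cell in self.cells], dtype=np.int8)
        self.f = np.array([cell.f for cell in self.cells], dtype=np.int8)
        self.c = np.array([cell.c for cell in self.cells], dtype=np.int8)
        self.stratum = np.array([cell.stratum for cell in self.cells], dtype=np.int8)
        self.t = np.array([cell.t for cell in self.cells])
        self.paternal = np.array(
            [cell.origin == ORIGIN_PATERNAL for cell in self.cells]
        )

    def __len__(self) -> int:
        return len(self.cells)

    def weights(self, params: PoeParams) -> np.ndarray:
        """Unnormalized cell weights mu_j * t * R_c * S_m * W^[paternal]."""
        mu = np.asarray(params.mu)
        r = np.array([1.0, params.R1, params.R2])
        s = np.array([1.0, params.S1, params.S2])
        w = np.where(self.paternal, params.W, 1.0)
        return mu[self.stratum] * self.t * r[self.c] * s[self.m] * w

    def compatibility_mask(
        self, m: int | None, f: int | None, c: int | None
    ) -> np.ndarray:
        """Boolean mask over cells consistent with observed dosages
        (``None`` or ``MISSING`` means unobserved)."""
        mask = np.ones(len(self.cells), dtype=bool)
        for observed, col in ((m, self.m), (f, self.f), (c, self.c)):
            if observed is not None and observed != MISSING:
                mask &= col == observed
        return mask


def build_cell_table() -> CellTable:
    """Enumerate the complete-trio cells by explicit allele transmission.

    Each parent transmits one allele (heterozygotes transmit each with
    probability 1/2); outcomes with identical (m, f, c, origin) are
    merged, which collapses nothing except bookkeeping — the only category
    with two distinct origins is (1, 1, 1).
    """
    merged: dict[tuple[int, int, int, str], float] = {}
    for m in (0, 1, 2):
        for f in (0, 1, 2):
            m_alleles = {0: (0,), 1: (0, 1), 2: (1,)}[m]
            f_alleles = {0: (0,), 1: (0, 1), 2: (1,)}[f]
            for am in m_alleles:
                for af in f_alleles:
                    c = am + af
                    t = 1.0 / (len(m_alleles) * len(f_alleles))
                    if c == 1:
                        origin = ORIGIN_MATERNAL if am == 1 else ORIGIN_PATERNAL
                    else:
                        origin = ORIGIN_NONE
                    key = (m, f, c, origin)
                    merged[key] = merged.get(key, 0.0) + t
    cells = [
        Cell(m=m, f=f, c=c, stratum=stratum_index(m, f), t=t, origin=origin)
        for (m, f, c, origin), t in sorted(merged.items())
    ]
    return CellTable(cells)


_TABLE = build_cell_table()

#: The 15 observable (m, f, c) trio categories, in cell-table order.
OBSERVABLE_CATEGORIES: tuple[tuple[int, int, int], ...] = tuple(
    sorted({(cell.m, cell.f, cell.c) for cell in _TABLE.cells})
)
_CATEGORY_INDEX = {cat: i for i, cat in enumerate(OBSERVABLE_CATEGORIES)}

# Map each of the 16 cells onto its observable category.
_CELL_TO_CATEGORY = np.array(
    [_CATEGORY_INDEX[(cell.m, cell.f, cell.c)] for cell in _TABLE.cells]
)


def cell_probs(params: PoeParams, table: CellTable | None = None) -> np.ndarray:
    """Multinomial cell probabilities: weights normalized to sum 1."""
    table = table or _TABLE
    w = table.weights(params)
    return w / w.sum()


def observable_probs(params: PoeParams) -> np.ndarray:
    """Probabilities of the 15 observable categories; the (1,1,1) category
    sums its maternal- and paternal-origin cells (origin is latent)."""
    p = cell_probs(params)
    out = np.zeros(len(OBSERVABLE_CATEGORIES))
    np.add.at(out, _CELL_TO_CATEGORY, p)
    return out


def category_index(m: int, f: int, c: int) -> int:
    """Index of a Mendelian-consistent trio category; raises otherwise."""
    try:
        return _CATEGORY_INDEX[(m, f, c)]
    except KeyError:
        raise ValueError(
            f"trio category (m={m}, f={f}, c={c}) is Mendelian-inconsistent"
        ) from None


def loglik_complete(counts: Sequence[float], params: PoeParams) -> float:
    """Multinomial log-likelihood of complete-trio counts.

    ``counts`` has length 16 (per cell, in cell-table order — the two
    origin counts of the (1,1,1) category are summed internally since
    origin is unobservable) or 15 (per observable category, in
    :data:`OBSERVABLE_CATEGORIES` order).  Counts may be non-integer
    (expected counts are valid input).
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("negative counts")
    if counts.shape == (len(_TABLE),):
        obs = np.zeros(len(OBSERVABLE_CATEGORIES))
        np.add.at(obs, _CELL_TO_CATEGORY, counts)
    elif counts.shape == (len(OBSERVABLE_CATEGORIES),):
        obs = counts
    else:
        raise ValueError(
            f"counts must have length {len(_TABLE)} (cells) or "
            f"{len(OBSERVABLE_CATEGORIES)} (observable categories)"
        )
    pi = observable_probs(params)
    nz = obs > 0
    return float(np.sum(obs[nz] * np.log(pi[nz])))


def _pattern(trio: TrioGenotype) -> tuple[int, int, int]:
    return (trio.m, trio.f, trio.c)


def loglik_observed(
    trios: Iterable[TrioGenotype], params: PoeParams
) -> float:
    """Observed-data log-likelihood with missing-parent marginalization.

    Each family contributes the log of the summed probabilities of all
    complete-trio cells compatible with its observed members (a missing
    parent is integrated out under the same mating-stratum parameters —
    no external allele-frequency model).  Equals
    :func:`loglik_complete` when no parent is missing.  A complete trio in
    a Mendelian-inconsistent category raises (QC should have removed it).
    """
    counts: dict[tuple[int, int, int], int] = {}
    for trio in trios:
        if trio.c == MISSING:
            raise ValueError(
                f"family {trio.family_id}: case child genotype is missing"
            )
        key = _pattern(trio)
        counts[key] = counts.get(key, 0) + 1

    p = cell_probs(params)
    total = 0.0
    for (m, f, c), n in counts.items():
        if m != MISSING and f != MISSING:
            category_index(m, f, c)  # raises on inconsistent complete trios
        prob = float(p[_TABLE.compatibility_mask(m, f, c)].sum())
        if prob <= 0:
            raise ValueError(
                f"observed pattern (m={m}, f={f}, c={c}) has zero probability"
            )
        total += n * np.log(prob)
    return total


def aggregate_patterns(
    trios: Iterable[TrioGenotype],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Group families by observed pattern for fast repeated likelihoods.

    Returns ``(masks, counts, patterns)`` where ``masks`` is a boolean
    (n_patterns, n_cells) compatibility matrix, ``counts`` the family
    count per pattern, and ``patterns`` the (m, f, c) observed dosages
    (with ``MISSING``) per pattern row.
    """
    counts: dict[tuple[int, int, int], int] = {}
    for trio in trios:
        if trio.c == MISSING:
            raise ValueError(
                f"family {trio.family_id}: case child genotype is missing"
            )
        m, f, c = _pattern(trio)
        if m != MISSING and f != MISSING:
            category_index(m, f, c)
        counts[(m, f, c)] = counts.get((m, f, c), 0) + 1
    patterns = sorted(counts)
    masks = np.stack(
        [_TABLE.compatibility_mask(*pat) for pat in patterns]
    )
    n = np.array([counts[pat] for pat in patterns], dtype=float)
    return masks, n, np.array(patterns, dtype=int)


def get_table() -> CellTable:
    """The module-level cell table (immutable by convention)."""
    return _TABLE
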