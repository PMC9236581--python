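"""Core genomic types shared by every other module.

A SNP genotype database is an individuals x loci table of minor-allele
counts.  Each entry is 0, 1 or 2 and is carried on the wire as a 2-bit
pattern ('00', '01', '10'); the pattern '11' (value 3) is not a valid
genotype and may only exist transiently inside fingerprint insertion.

The module also provides the Mendelian trio-consistency predicate and the
similarity functions (inner product, cosine) used by the kinship-based
attack and mitigation machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GenotypeMatrix",
    "FamilySet",
    "Trio",
    "KnowledgeS",
    "KnowledgeJ",
    "encode_genotype",
    "decode_genotype",
    "mendel_consistent",
    "MENDEL_TABLE",
    "inner_similarity",
    "cosine_similarity",
    "empirical_marginal",
]

VALID_GENOTYPES = (0, 1, 2)


class GenotypeDomainError(ValueError):
    """A genotype code outside its documented domain."""


class DimensionError(ValueError):
    """Vector or matrix shapes do not line up."""


# ---------------------------------------------------------------------------
# genotype matrix
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Individuals x loci table of minor-allele counts.

    Parameters
    ----------
    row_ids
        Unique individual identifiers, one per row.  The identifier string
        is the primary key concatenated into every keyed selection call,
        so it must be stable across row reordering.
    values
        M x N integer array with entries in {0, 1, 2}.
    locus_ids
        SNP / attribute labels, one per column.
    """

    row_ids: list[str]
    values: np.ndarray
    locus_ids: list[str]
    _row_index: dict[str, int] = field(init=False, repr=False)
    _locus_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        self.row_ids = [str(r) for r in self.row_ids]
        self.locus_ids = [str(c) for c in self.locus_ids]
        if self.values.ndim != 2:
            raise DimensionError("values must be a 2-D table")
        m, n = self.values.shape
        if m != len(self.row_ids) or n != len(self.locus_ids):
            raise DimensionError(
                f"shape {self.values.shape} does not match "
                f"{len(self.row_ids)} row ids / {len(self.locus_ids)} locus ids"
            )
        if len(set(self.row_ids)) != m or m == 0:
            raise ValueError("row_ids must be unique and non-empty")
        if len(set(self.locus_ids)) != n:
            raise ValueError("locus_ids must be unique")
        self._row_index = {r: i for i, r in enumerate(self.row_ids)}
        self._locus_index = {c: j for j, c in enumerate(self.locus_ids)}

    # -- views ----------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_loci(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row_index(self, row_id: str) -> int:
        return self._row_index[row_id]

    def locus_index(self, locus_id: str) -> int:
        return self._locus_index[locus_id]

    def row(self, row_id: str) -> np.ndarray:
        return self.values[self._row_index[row_id]]

    def column(self, locus_id: str) -> np.ndarray:
        return self.values[:, self._locus_index[locus_id]]

    # -- validity -------------------------------------------------------
    def validate(self) -> None:
        """Raise if any stored value is outside {0,1,2}."""
        bad = (self.values < 0) | (self.values > 2)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeDomainError(
                f"invalid genotype {int(self.values[i, j])} at row "
                f"'{self.row_ids[i]}', locus '{self.locus_ids[j]}'"
            )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.row_ids), self.values.copy(), list(self.locus_ids)
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.row_ids == other.row_ids
            and self.locus_ids == other.locus_ids
            and np.array_equal(self.values, other.values)
        )


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Trio:
    mother: str
    father: str
    child: str

    def __iter__(self):
        return iter((self.mother, self.father, self.child))


@dataclass
class FamilySet:
    """Mother-father-child trios referencing rows of a genotype matrix."""

    trios: list[Trio]

    def __post_init__(self) -> None:
        self.trios = [t if isinstance(t, Trio) else Trio(*t) for t in self.trios]
        for t in self.trios:
            if len({t.mother, t.father, t.child}) != 3:
                raise ValueError(f"trio members must be distinct: {t}")

    def __len__(self) -> int:
        return len(self.trios)

    def __iter__(self):
        return iter(self.trios)

    def validate_against(self, db: GenotypeMatrix) -> None:
        known = set(db.row_ids)
        for t in self.trios:
            for member in t:
                if member not in known:
                    raise ValueError(f"pedigree id '{member}' not in the matrix")

    def first_degree_pairs(self) -> list[tuple[str, str, str]]:
        """(parent_id, child_id, kind) for every mother-child and
        father-child pair, kind in {"mother", "father"}."""
        pairs = []
        for t in self.trios:
            pairs.append((t.mother, t.child, "mother"))
            pairs.append((t.father, t.child, "father"))
        return pairs


# ---------------------------------------------------------------------------
# public prior knowledge
# ---------------------------------------------------------------------------

@dataclass
class KnowledgeS:
    """Kinship similarity values: ordered (parent_id, child_id) -> <r_i, r_j>.

    The similarity between two individuals is the inner product of their
    genotype vectors, so every value is a non-negative integer-like real.
    """

    similarities: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        for pair, v in self.similarities.items():
            if v < 0:
                raise ValueError(f"negative similarity for pair {pair}")

    def get(self, id_a: str, id_b: str) -> float | None:
        return self.similarities.get((id_a, id_b))

    def validate_against(self, families: FamilySet) -> None:
        allowed = {(p, c) for p, c, _ in families.first_degree_pairs()}
        for pair in self.similarities:
            if pair not in allowed:
                raise ValueError(f"similarity pair {pair} is not a first-degree "
                                 "pair of any trio")


@dataclass
class KnowledgeJ:
    """Pairwise SNP joint distributions: (locus_p, locus_q) -> 3x3 matrix.

    J[p,q][a,b] = Pr(value at p is a, value at q is b).  Marginalizing over
    the second locus yields the public marginal Pr(C_p); the construction
    guarantees that the marginal of p is the same whichever partner locus
    is used.
    """

    joints: dict[tuple[str, str], np.ndarray]

    def __post_init__(self) -> None:
        clean = {}
        for pair, j in self.joints.items():
            j = np.asarray(j, dtype=float)
            if j.shape != (3, 3):
                raise DimensionError(f"joint for {pair} is not 3x3")
            if (j < 0).any() or abs(j.sum() - 1.0) > 1e-9:
                raise ValueError(f"joint for {pair} is not a probability table")
            clean[pair] = j
        self.joints = clean

    def loci(self) -> list[str]:
        out: list[str] = []
        for p, q in self.joints:
            if p not in out:
                out.append(p)
            if q not in out:
                out.append(q)
        return out

    def marginal(self, locus: str) -> np.ndarray:
        """Public marginal Pr(C_p) from any joint involving ``locus``."""
        for (p, q), j in self.joints.items():
            if p == locus:
                return j.sum(axis=1)
            if q == locus:
                return j.sum(axis=0)
        raise KeyError(f"locus '{locus}' absent from the joint set")

    def check_marginal_consistency(self, atol: float = 1e-6) -> None:
        """All joints containing a locus must imply the same marginal."""
        seen: dict[str, np.ndarray] = {}
        for (p, q), j in self.joints.items():
            for locus, marg in ((p, j.sum(axis=1)), (q, j.sum(axis=0))):
                if locus in seen:
                    if np.abs(seen[locus] - marg).max() > atol:
                        raise ValueError(
                            f"inconsistent marginals for locus '{locus}'")
                else:
                    seen[locus] = marg


# ---------------------------------------------------------------------------
# scalar operations
# ---------------------------------------------------------------------------

def encode_genotype(v: int) -> tuple[int, int]:
    """2-bit encoding (high bit, low bit) of a genotype code.

    0 -> (0,0), 1 -> (0,1), 2 -> (1,0).  Code 3 -> (1,1) is representable
    because insertion may create it transiently, but it is never a valid
    stored genotype.
    """
    if v not in (0, 1, 2, 3):
        raise GenotypeDomainError(f"genotype code {v!r} outside {{0,1,2,3}}")
    return (v >> 1) & 1, v & 1


def decode_genotype(high: int, low: int) -> int:
    if high not in (0, 1) or low not in (0, 1):
        raise GenotypeDomainError("bits must be 0 or 1")
    return (high << 1) | low


def _transmissible_alleles(g: int) -> tuple[int, ...]:
    # a parent with 0/1/2 minor alleles can transmit these allele counts
    return {0: (0,), 1: (0, 1), 2: (1,)}[g]


def _build_mendel_table() -> np.ndarray:
    tbl = np.zeros((3, 3, 3), dtype=bool)
    for mo in VALID_GENOTYPES:
        for fa in VALID_GENOTYPES:
            for ch in VALID_GENOTYPES:
                tbl[mo, fa, ch] = any(
                    a + b == ch
                    for a in _transmissible_alleles(mo)
                    for b in _transmissible_alleles(fa)
                )
    return tbl


#: MENDEL_TABLE[mother, father, child] — vectorized trio consistency lookup
MENDEL_TABLE = _build_mendel_table()
MENDEL_TABLE.setflags(write=False)


def mendel_consistent(mother: int, father: int, child: int) -> bool:
    """Can the child's minor-allele count arise from one allele per parent?

    Strict check: a de-novo mutation is counted as a violation.
    """
    for g in (mother, father, child):
        if g not in VALID_GENOTYPES:
            raise GenotypeDomainError(
                f"genotype code {g!r} outside {{0,1,2}}; sanitize before the "
                "Mendel check")
    return bool(MENDEL_TABLE[mother, father, child])


def inner_similarity(a: Sequence[int], b: Sequence[int]) -> float:
    """Inner product <a, b> of two genotype vectors."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise DimensionError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.dot(a.astype(np.int64), b.astype(np.int64)))


def cosine_similarity(a: Sequence[int], b: Sequence[int]) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise DimensionError(f"length mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(a, b) / (na * nb))


def empirical_marginal(db: GenotypeMatrix, locus: str | int) -> np.ndarray:
    """Empirical distribution over {0,1,2} of one column.

    Transient code-3 cells are excluded from the count (there should be
    none in a released database).
    """
    col = db.column(locus) if isinstance(locus, str) else db.values[:, locus]
    col = col[col != 3]
    if col.size == 0:
        raise ValueError("empty column: marginal undefined")
    counts = np.bincount(col, minlength=3)[:3]
    return counts / counts.sum()


def tv_distance(p: np.ndarray, q: np.ndarray) -> float:
    """Total-variation distance between two categorical distributions."""
    return 0.5 * float(np.abs(np.asarray(p, float) - np.asarray(q, float)).sum())
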