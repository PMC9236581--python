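"""Vanilla fingerprint insertion, blind extraction and suspect matching.

Insertion walks the database row by row.  A row is selected when
U1(K|row_id) mod floor(1/gamma_r) = 0, and within a selected row a cell
at locus p is selected when U2(K|row_id|p) mod floor(1/gamma_l) = 0.
For a selected cell the scheme draws a mask bit x, a fingerprint index l,
and a bit position t (counted from the last bit of the 2-bit genotype
encoding), then overwrites that bit with the mark m = x XOR f[l].

Because every choice is a keyed function of the row and locus labels
alone, extraction can re-derive the exact set of marked cells from the
suspect copy, read the embedded bits back, and reconstruct the
fingerprint by majority voting with confidence threshold tau.

Writing a bit can transiently produce the invalid pattern '11' (genotype
3).  The scheme then clears the *other* bit, so the released value stays
in {0,1,2} while the bit that extraction reads is preserved exactly.
"""

from __future__ import annotations

import hmac
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .datamodel import GenotypeMatrix
from .keystream import FINGERPRINT_BITS, FingerprintString, OwnerKey

__all__ = [
    "FingerprintMask",
    "FingerprintTemplate",
    "MarkCell",
    "MatchResult",
    "UNDET",
    "insert_fingerprint",
    "extract_fingerprint",
    "template_from_votes",
    "match_suspect",
]

#: template symbol for a fingerprint bit the owner cannot determine
UNDET = -1


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class MarkCell:
    """One marked cell: where the mark went and how it was derived."""

    row_id: str
    locus_id: str
    t: int     # bit position, counted from the last bit (1 = low, 2 = high)
    x: int     # mask bit
    l: int     # fingerprint index, 0-based
    m: int     # mark bit actually written


@dataclass
class FingerprintMask:
    """The set of cells touched by insertion under one (K, gamma_r, gamma_l).

    Storage is a cache: the same set is recomputable from the key and the
    row/locus labels, which is exactly what extraction does.
    """

    cells: list[MarkCell]
    _by_cell: set[tuple[str, str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_cell = {(c.row_id, c.locus_id) for c in self.cells}

    def __len__(self) -> int:
        return len(self.cells)

    def __contains__(self, cell: tuple[str, str]) -> bool:
        return cell in self._by_cell

    def masked_pairs(self) -> set[tuple[str, str]]:
        return set(self._by_cell)

    def boolean_mask(self, db: GenotypeMatrix) -> np.ndarray:
        """M x N boolean array, True where a cell carries a mark."""
        out = np.zeros(db.shape, dtype=bool)
        for c in self.cells:
            out[db.row_index(c.row_id), db.locus_index(c.locus_id)] = True
        return out

    def to_records(self) -> list[dict]:
        return [
            {"row": c.row_id, "locus": c.locus_id, "t": c.t,
             "x": c.x, "l": c.l, "m": c.m}
            for c in self.cells
        ]


@dataclass
class FingerprintTemplate:
    """Voting result of extraction: one symbol in {0, 1, UNDET} per index."""

    symbols: np.ndarray          # length L, values in {0, 1, UNDET}
    c0: np.ndarray               # votes for 0 per index
    c1: np.ndarray               # votes for 1 per index
    tau: float

    @property
    def L(self) -> int:
        return len(self.symbols)

    @property
    def n_undetermined(self) -> int:
        return int(np.sum(self.symbols == UNDET))

    def determined(self) -> np.ndarray:
        return self.symbols != UNDET


def _floor_inv(gamma: float, name: str) -> int:
    if not (0.0 < gamma < 1.0):
        raise ParameterError(f"{name} must lie in (0, 1), got {gamma}")
    return int(np.floor(1.0 / gamma))


def _iter_marks(
    key: OwnerKey,
    row_ids: Sequence[str],
    locus_ids: Sequence[str],
    gamma_r: float,
    gamma_l: float,
    L: int,
) -> Iterator[tuple[int, int, int, int, int]]:
    """Yield (row_index, locus_index, x, l, t) for every selected cell.

    This single generator backs both insertion and extraction, which is
    what guarantees they derive identical cell sets and mark metadata.
    """
    mod_r = _floor_inv(gamma_r, "gamma_r")
    mod_l = _floor_inv(gamma_l, "gamma_l")
    secret = key.secret
    sep = b"|"
    loc_bytes = [str(c).encode("utf-8") for c in locus_ids]
    for i, rid in enumerate(row_ids):
        rb = str(rid).encode("utf-8")
        u1 = int.from_bytes(hmac.digest(secret, b"U1|" + rb, "sha256"), "big")
        if u1 % mod_r != 0:
            continue
        for j, cb in enumerate(loc_bytes):
            tail = rb + sep + cb
            u2 = int.from_bytes(
                hmac.digest(secret, b"U2|" + tail, "sha256"), "big")
            if u2 % mod_l != 0:
                continue
            u3 = int.from_bytes(
                hmac.digest(secret, b"U3|" + tail, "sha256"), "big")
            u4 = int.from_bytes(
                hmac.digest(secret, b"U4|" + tail, "sha256"), "big")
            u5 = int.from_bytes(
                hmac.digest(secret, b"U5|" + tail, "sha256"), "big")
            yield i, j, u3 % 2, u4 % L, (u5 % 2) + 1


def _write_bit(value: int, t: int, m: int) -> int:
    """Set the t-th-to-last bit of the 2-bit encoding to m; resolve '11'."""
    if t == 1:
        new = (value & 0b10) | m
    else:
        new = (value & 0b01) | (m << 1)
    if new == 0b11:
        # invalid genotype: clear the other bit, keeping bit t equal to m
        new = m if t == 1 else (m << 1)
    return new


def _read_bit(value: int, t: int) -> int:
    return (value >> (t - 1)) & 1


def insert_fingerprint(
    db: GenotypeMatrix,
    key: OwnerKey,
    sp_id,
    gamma_r: float,
    gamma_l: float,
) -> tuple[GenotypeMatrix, FingerprintMask]:
    """Embed the recipient's fingerprint into a copy of ``db``.

    Returns the fingerprinted database and the mask of marked cells.
    Expected mark density is gamma_r * gamma_l (up to the floor in
    1/gamma); a marked cell keeps its value whenever the mark bit equals
    the bit already stored there.
    """
    from .keystream import generate_fingerprint

    db.validate()
    fp = generate_fingerprint(key, sp_id)
    out = db.copy()
    vals = out.values
    cells: list[MarkCell] = []
    for i, j, x, l, t in _iter_marks(
        key, db.row_ids, db.locus_ids, gamma_r, gamma_l, fp.L
    ):
        m = x ^ fp.bits[l]
        vals[i, j] = _write_bit(int(vals[i, j]), t, m)
        cells.append(
            MarkCell(db.row_ids[i], db.locus_ids[j], t=t, x=x, l=l, m=m))
    out.validate()
    return out, FingerprintMask(cells)


def extract_fingerprint(
    db_suspect: GenotypeMatrix,
    key: OwnerKey,
    gamma_r: float,
    gamma_l: float,
    tau: float = 0.7,
    L: int = FINGERPRINT_BITS,
) -> FingerprintTemplate:
    """Blindly extract a fingerprint template from a suspect copy.

    Re-derives every marked position from the key and the labels, reads
    the embedded bits, and thresholds the per-index votes at confidence
    tau (default 0.7).  An index whose winning vote fraction stays below
    tau — or that receives no votes at all — is left undetermined.
    """
    if not (0.5 < tau <= 1.0):
        raise ParameterError(f"tau must lie in (0.5, 1], got {tau}")
    c0 = np.zeros(L, dtype=np.int64)
    c1 = np.zeros(L, dtype=np.int64)
    vals = db_suspect.values
    for i, j, x, l, t in _iter_marks(
        key, db_suspect.row_ids, db_suspect.locus_ids, gamma_r, gamma_l, L
    ):
        m = _read_bit(int(vals[i, j]), t)
        if m ^ x:
            c1[l] += 1
        else:
            c0[l] += 1
    return template_from_votes(c0, c1, tau)


def template_from_votes(
    c0: np.ndarray, c1: np.ndarray, tau: float
) -> FingerprintTemplate:
    """Threshold per-index vote counts into {0, 1, UNDET} symbols.

    Index l resolves to 1 when c1/(c0+c1) >= tau, to 0 when
    c0/(c0+c1) >= tau, and stays undetermined otherwise — including when
    it received no votes at all.
    """
    c0 = np.asarray(c0, dtype=np.int64)
    c1 = np.asarray(c1, dtype=np.int64)
    total = c0 + c1
    symbols = np.full(c0.shape, UNDET, dtype=np.int8)
    voted = total > 0
    r1 = np.where(voted, c1 / np.maximum(total, 1), 0.0)
    r0 = np.where(voted, c0 / np.maximum(total, 1), 0.0)
    symbols[voted & (r1 >= tau)] = 1
    symbols[voted & (r0 >= tau)] = 0
    return FingerprintTemplate(symbols=symbols, c0=c0, c1=c1, tau=tau)


@dataclass
class MatchResult:
    """Ranking of candidate recipients against an extracted template."""

    ranking: list[tuple[str, float]]   # (sp_id, agreement), best first
    inconclusive: bool                 # True when no bit was determined

    @property
    def best(self) -> tuple[str, float]:
        return self.ranking[0]


def match_suspect(
    template: FingerprintTemplate,
    candidates: Sequence[FingerprintString],
) -> MatchResult:
    """Rank candidate fingerprints by agreement over the determined bits.

    Agreement is matches / number of determined bits; ties keep the
    candidate input order.  An all-undetermined template yields an
    inconclusive result (agreement 0 for everyone) rather than an error.
    """
    if not candidates:
        raise ValueError("need at least one candidate fingerprint")
    det = template.determined()
    n_det = int(det.sum())
    scored: list[tuple[str, float]] = []
    for cand in candidates:
        if cand.L != template.L:
            raise ValueError("candidate length differs from template")
        if n_det == 0:
            scored.append((cand.sp_id, 0.0))
        else:
            agree = int(np.sum(template.symbols[det] == cand.as_array()[det]))
            scored.append((cand.sp_id, agree / n_det))
    order = sorted(range(len(scored)), key=lambda k: (-scored[k][1], k))
    return MatchResult(
        ranking=[scored[k] for k in order], inconclusive=(n_det == 0))
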