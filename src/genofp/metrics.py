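"""Robustness and utility metrics for fingerprinted genotype databases.

Robustness is the fraction of fingerprint bits an extraction fails to
recover (Percmp).  Utility is measured as cell-level accuracy against a
reference copy and as the stability of GWAS-style SNP-phenotype
association: per-locus odds-ratio P-values under a random case/control
split, and the overlap of the top-k lowest-P loci before and after a
transformation.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.stats import norm

from .datamodel import DimensionError, GenotypeMatrix
from .keystream import FingerprintString
from .vanilla import UNDET, FingerprintTemplate

__all__ = [
    "AssociationCounts",
    "accuracy",
    "perc_changed",
    "perc_compromised",
    "snp_p_value",
    "case_control_split",
    "locus_p_values",
    "topk_consistency",
]


def accuracy(reference: GenotypeMatrix, other: GenotypeMatrix) -> float:
    """Fraction of cells equal between two same-shape databases (Acc)."""
    if reference.row_ids != other.row_ids or \
            reference.locus_ids != other.locus_ids:
        raise DimensionError("databases must share row and locus ids")
    m, n = reference.shape
    matched = int(np.sum(reference.values == other.values))
    return float(Fraction(matched, m * n))


def perc_changed(reference: GenotypeMatrix, other: GenotypeMatrix) -> float:
    """Perchg = 1 - Acc."""
    return 1.0 - accuracy(reference, other)


def perc_compromised(
    template: FingerprintTemplate,
    original: FingerprintString,
    undet_policy: str = "mismatch",
) -> float:
    """Fraction of fingerprint positions the owner fails to recover (Percmp).

    Under the default policy an undetermined symbol counts as a
    compromised bit — the owner cannot confirm it.  With
    ``undet_policy="ignore"`` only determined-but-wrong bits count
    (denominator stays L).
    """
    if template.L != original.L:
        raise DimensionError("template and fingerprint lengths differ")
    if undet_policy not in ("mismatch", "ignore"):
        raise ValueError(f"unknown undet policy {undet_policy!r}")
    sym = template.symbols
    bits = original.as_array()
    wrong = int(np.sum((sym != UNDET) & (sym != bits)))
    if undet_policy == "mismatch":
        wrong += template.n_undetermined
    return float(Fraction(wrong, template.L))


# ---------------------------------------------------------------------------
# SNP-phenotype association
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssociationCounts:
    """Genotype counts at one locus for disjoint case and control groups."""

    S0: int
    S1: int
    S2: int
    C0: int
    C1: int
    C2: int

    def __post_init__(self) -> None:
        if min(self.S0, self.S1, self.S2, self.C0, self.C1, self.C2) < 0:
            raise ValueError("counts must be non-negative")


def snp_p_value(counts: AssociationCounts) -> float:
    """Two-sided odds-ratio P-value for one locus.

    The genotype table is collapsed to carrier (1 or 2 minor alleles)
    versus non-carrier: OR = C0 (S1+S2) / (S0 (C1+C2)), z = ln(OR) over
    its standard error, p = Psi(-|z|) + 1 - Psi(|z|) with Psi the
    standard normal CDF.  A zero in any collapsed cell triggers the
    Haldane-Anscombe correction (0.5 added to all four cells).
    """
    s_car = counts.S1 + counts.S2
    c_car = counts.C1 + counts.C2
    if counts.S0 + s_car == 0 or counts.C0 + c_car == 0:
        raise ValueError("a group is structurally empty: association undefined")
    a, b, c, d = float(counts.S0), float(s_car), float(counts.C0), float(c_car)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds_ratio = (c * b) / (a * d)
    std_err = np.sqrt(1 / b + 1 / a + 1 / d + 1 / c)
    z = np.log(odds_ratio) / std_err
    return float(norm.cdf(-abs(z)) + 1 - norm.cdf(abs(z)))


def case_control_split(
    row_ids: list[str], seed: int
) -> tuple[list[str], list[str]]:
    """Uniform random, non-overlapping 50/50 case/control partition."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(row_ids))
    half = len(row_ids) // 2
    case = [row_ids[i] for i in order[:half]]
    control = [row_ids[i] for i in order[half:]]
    return case, control


def locus_p_values(
    db: GenotypeMatrix, case_ids: list[str], control_ids: list[str]
) -> np.ndarray:
    """Per-locus association P-values under a fixed case/control split."""
    if set(case_ids) & set(control_ids):
        raise ValueError("case and control groups must be disjoint")
    case_rows = [db.row_index(r) for r in case_ids]
    ctrl_rows = [db.row_index(r) for r in control_ids]
    s_counts = np.stack([
        (db.values[case_rows] == g).sum(axis=0) for g in (0, 1, 2)])
    c_counts = np.stack([
        (db.values[ctrl_rows] == g).sum(axis=0) for g in (0, 1, 2)])
    out = np.empty(db.n_loci)
    for j in range(db.n_loci):
        out[j] = snp_p_value(AssociationCounts(
            int(s_counts[0, j]), int(s_counts[1, j]), int(s_counts[2, j]),
            int(c_counts[0, j]), int(c_counts[1, j]), int(c_counts[2, j])))
    return out


def _top_k(p_values: np.ndarray, locus_ids: list[str], k: int) -> set[str]:
    order = sorted(range(len(locus_ids)), key=lambda j: (p_values[j],
                                                         locus_ids[j]))
    return {locus_ids[j] for j in order[:k]}


def topk_consistency(
    reference: GenotypeMatrix,
    modified: GenotypeMatrix,
    case_ids: list[str],
    control_ids: list[str],
    k: int = 50,
) -> float:
    """Overlap fraction of the k most-associated loci before/after change.

    Both databases are scored under the identical case/control split;
    P-value ties break on the locus label.
    """
    if reference.locus_ids != modified.locus_ids:
        raise DimensionError("databases must share locus ids")
    if k > reference.n_loci:
        raise ValueError("k exceeds the number of loci")
    top_ref = _top_k(locus_p_values(reference, case_ids, control_ids),
                     reference.locus_ids, k)
    top_mod = _top_k(locus_p_values(modified, case_ids, control_ids),
                     modified.locus_ids, k)
    return len(top_ref & top_mod) / k
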