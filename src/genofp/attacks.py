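"""Adversary models against a fingerprinted genotype database.

Three attackers, all trying to distort embedded fingerprint bits while
changing as few cells as possible:

* ``flip_attack`` — blind baseline: random cells are reassigned to a
  uniformly chosen different valid genotype.
* ``row_attack`` — kinship-aware: first flips trio loci that violate
  Mendelian inheritance (mark embedding is the most likely cause), then
  pushes empirical parent-child similarities back toward their public
  values S, on the theory that cells driving the discrepancy are marks.
* ``col_attack`` — LD-aware: restores each column's empirical genotype
  marginal toward the public marginal implied by the pairwise joint
  distributions J, using the same Sinkhorn transport machinery as the
  defense but without mask knowledge, so marks and clean cells are hit
  alike.

``combined_correlation_attack`` runs the row attack followed by the
column attack under one shared cell-change budget.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datamodel import (
    MENDEL_TABLE,
    FamilySet,
    GenotypeMatrix,
    KnowledgeJ,
    KnowledgeS,
    empirical_marginal,
    tv_distance,
)
from .mitigation import (
    _PAIR_MOVES,
    _trio_rows,
    sinkhorn_plan,
    transport_cell_moves,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AttackBudget",
    "flip_attack",
    "row_attack",
    "col_attack",
    "combined_correlation_attack",
]


@dataclass
class AttackBudget:
    """Upper bound on the fraction of cells the attacker will change."""

    max_change_fraction: float
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_change_fraction <= 1.0):
            raise ValueError("max_change_fraction must lie in [0, 1]")

    def cell_limit(self, db: GenotypeMatrix) -> int:
        m, n = db.shape
        return int(round(self.max_change_fraction * m * n))


def flip_attack(
    db: GenotypeMatrix, fraction: float, seed: int = 0
) -> GenotypeMatrix:
    """Replace a random ``fraction`` of cells with a different valid value.

    Exactly round(fraction * M * N) distinct cells change; each gets one
    of the other two genotype codes uniformly at random, so the realized
    change fraction equals the request.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = db.copy()
    m, n = out.shape
    k = int(round(fraction * m * n))
    if k == 0:
        return out
    flat = rng.choice(m * n, size=k, replace=False)
    offsets = rng.integers(1, 3, size=k)  # +1 or +2 mod 3: the other values
    vals = out.values.reshape(-1)
    vals[flat] = (vals[flat] + offsets) % 3
    return out


# ---------------------------------------------------------------------------
# row-wise correlation attack
# ---------------------------------------------------------------------------

def _nearest_consistent(
    mo: int, fa: int, ch: int, member: int
) -> int | None:
    """Nearest replacement for one trio member restoring consistency.

    member: 0 = mother, 1 = father, 2 = child.  Ties prefer the lower
    value; None when no single-member fix exists.
    """
    trio = [mo, fa, ch]
    best = None
    for v in (0, 1, 2):
        trial = list(trio)
        trial[member] = v
        if not MENDEL_TABLE[trial[0], trial[1], trial[2]]:
            continue
        key = (abs(v - trio[member]), v)
        if best is None or key < best[0]:
            best = (key, v)
    return None if best is None else best[1]


def row_attack(
    db: GenotypeMatrix,
    families: FamilySet,
    S: KnowledgeS,
    budget: AttackBudget,
    sim_tol: float = 1.0,
) -> tuple[GenotypeMatrix, dict]:
    """Kinship-structure restoration attack Atk_row(S).

    Phase A flips one uniformly chosen member of every Mendel-violating
    trio locus to its nearest consistent value.  Phase B ranks
    parent-child pairs by the discrepancy |S' - S| between empirical and
    public similarity and applies trio-tuple moves toward S until each
    pair is within ``sim_tol`` or the cell budget runs out.
    """
    rng = np.random.default_rng(budget.rng_seed)
    out = db.copy()
    vals = out.values
    limit = budget.cell_limit(db)
    changed = 0

    # --- phase A: Mendelian repair (attacker's version: any member) ----
    phase_a = 0
    for trio in families:
        if changed >= limit:
            break
        im, if_, ic = _trio_rows(db, trio)
        viol = np.flatnonzero(~MENDEL_TABLE[vals[im], vals[if_], vals[ic]])
        rows = (im, if_, ic)
        for j in viol:
            if changed >= limit:
                break
            mo, fa, ch = int(vals[im, j]), int(vals[if_, j]), int(vals[ic, j])
            # uniform guess among members admitting a single-value fix
            fixable = [
                (k, fix) for k, fix in
                ((k, _nearest_consistent(mo, fa, ch, k)) for k in range(3))
                if fix is not None
            ]
            member, fix = fixable[rng.integers(len(fixable))]
            vals[rows[member], j] = fix
            changed += 1
            phase_a += 1

    # --- phase B: similarity discrepancy reduction ---------------------
    phase_b = 0
    trio_of_child = {t.child: t for t in families}
    pairs = []
    for parent, child, kind in families.first_degree_pairs():
        s_pub = S.get(parent, child)
        if s_pub is None:
            logger.warning("no public similarity for (%s, %s); pair skipped",
                           parent, child)
            continue
        pairs.append((parent, child, kind, float(s_pub)))

    def discrepancy(parent: str, child: str, s_pub: float) -> float:
        emp = float(
            np.dot(vals[db.row_index(parent)].astype(np.int64),
                   vals[db.row_index(child)].astype(np.int64)))
        return emp - s_pub

    ranked = sorted(
        pairs,
        key=lambda pr: -abs(discrepancy(pr[0], pr[1], pr[3])),
    )
    for parent, child, kind, s_pub in ranked:
        if changed >= limit:
            break
        trio = trio_of_child[child]
        rows = _trio_rows(db, trio)
        gap = -discrepancy(parent, child, s_pub)  # public minus empirical
        while abs(gap) > sim_tol and changed + 2 <= limit:
            direction = "up" if gap > 0 else "down"
            pattern, replacement = _PAIR_MOVES[kind][direction]
            im, if_, ic = rows
            match = np.flatnonzero(
                (vals[im] == pattern[0])
                & (vals[if_] == pattern[1])
                & (vals[ic] == pattern[2])
            )
            if match.size == 0:
                break
            j = int(rng.choice(match))
            for row, new in zip(rows, replacement):
                if vals[row, j] != new:
                    vals[row, j] = new
                    changed += 1
                    phase_b += 1
            gap += -1 if gap > 0 else 1
    report = {
        "cells_changed": changed,
        "phase_a_cells": phase_a,
        "phase_b_cells": phase_b,
    }
    return out, report


def col_attack(
    db: GenotypeMatrix,
    J: KnowledgeJ,
    budget: AttackBudget,
    tv_threshold: float = 0.005,
    lam: float = 50.0,
) -> tuple[GenotypeMatrix, dict]:
    """LD-marginal restoration attack Atk_col(J).

    Columns are visited in decreasing total-variation distance between
    their empirical marginal and the public J-implied one.  Each column
    above ``tv_threshold`` is pushed toward the public marginal by a
    Sinkhorn transport plan executed on uniformly random cells (the
    attacker cannot tell marked cells apart), until the budget runs out.
    """
    rng = np.random.default_rng(budget.rng_seed + 1)
    out = db.copy()
    vals = out.values
    limit = budget.cell_limit(db)
    changed = 0
    known = set(J.loci())
    scored = []
    for locus in db.locus_ids:
        if locus not in known:
            logger.warning("locus '%s' absent from J; skipped", locus)
            continue
        tv = tv_distance(empirical_marginal(db, locus), J.marginal(locus))
        scored.append((tv, locus))
    scored.sort(key=lambda s: -s[0])
    for tv, locus in scored:
        if tv <= tv_threshold or changed >= limit:
            continue
        j = db.locus_index(locus)
        source = empirical_marginal(out, locus)
        target = J.marginal(locus)
        if tv_distance(source, target) <= tv_threshold:
            continue
        plan = sinkhorn_plan(source, target, lam=lam)
        eligible = np.ones(vals.shape[0], dtype=bool)  # attacker has no mask
        moves = transport_cell_moves(vals[:, j], eligible, plan.plan, rng)
        for row, b in moves:
            if changed >= limit:
                break
            if vals[row, j] != b:
                vals[row, j] = b
                changed += 1
    return out, {"cells_changed": changed}


def combined_correlation_attack(
    db: GenotypeMatrix,
    families: FamilySet,
    S: KnowledgeS,
    J: KnowledgeJ,
    budget: AttackBudget,
    tv_threshold: float = 0.005,
    lam: float = 50.0,
) -> tuple[GenotypeMatrix, dict]:
    """Atk_row(S) followed by Atk_col(J) under one shared budget."""
    m, n = db.shape
    after_row, rep_row = row_attack(db, families, S, budget)
    remaining = budget.max_change_fraction - rep_row["cells_changed"] / (m * n)
    col_budget = AttackBudget(max(remaining, 0.0), budget.rng_seed)
    after_col, rep_col = col_attack(
        after_row, J, col_budget, tv_threshold=tv_threshold, lam=lam)
    total = rep_row["cells_changed"] + rep_col["cells_changed"]
    report = {
        "row_attack": rep_row,
        "col_attack": rep_col,
        "cells_changed": total,
        "perchg": total / (m * n),
    }
    return after_col, report
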