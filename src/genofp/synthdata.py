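"""Synthetic SNP populations with trio structure and adjacent-locus LD.

The generator emulates the shape of a family-based genotyping panel: a
set of mother-father-child trios plus unrelated individuals, typed at N
biallelic SNPs coded as minor-allele counts.  Founder haplotypes follow
a first-order Markov chain along the genome whose stationary per-locus
allele frequency is the requested MAF and whose adjacent-locus allele
correlation is ``ld_r`` — enough LD structure to make the column-wise
attack and mitigation non-trivial.  Children receive, independently at
every locus, one uniformly chosen allele from each parent's two
haplotypes, so with ``mutation_rate`` 0 every trio is exactly Mendel
consistent.

``derive_knowledge`` measures the public prior knowledge (kinship
similarities S, pairwise joint distributions J) directly from a
generated matrix, giving exact ground truth for attack and mitigation
experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import (
    FamilySet,
    GenotypeMatrix,
    KnowledgeJ,
    KnowledgeS,
    Trio,
    inner_similarity,
)

__all__ = ["PopulationSpec", "generate_population", "derive_knowledge"]


@dataclass
class PopulationSpec:
    """Parameters of a synthetic trio population.

    maf may be a scalar (shared by all loci) or a length-n_snps array;
    values must lie in (0, 0.5].  ld_r is the adjacent-locus haplotype
    allele correlation in [0, 1).  mutation_rate is the per-transmission
    allele flip probability (default 0: strict Mendelian inheritance).
    """

    n_families: int
    n_unrelated: int
    n_snps: int
    maf: float | np.ndarray = 0.25
    ld_r: float = 0.0
    mutation_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 0 or self.n_unrelated < 0 or self.n_snps <= 0:
            raise ValueError("population sizes must be non-negative, snps > 0")
        if self.n_families + self.n_unrelated == 0:
            raise ValueError("population is empty")
        maf = np.broadcast_to(
            np.asarray(self.maf, dtype=float), (self.n_snps,)).copy()
        if ((maf <= 0) | (maf > 0.5)).any():
            raise ValueError("maf values must lie in (0, 0.5]")
        self.maf = maf
        if not (0.0 <= self.ld_r < 1.0):
            raise ValueError("ld_r must lie in [0, 1)")
        if not (0.0 <= self.mutation_rate <= 1.0):
            raise ValueError("mutation_rate must lie in [0, 1]")

    @property
    def n_individuals(self) -> int:
        return 3 * self.n_families + self.n_unrelated


def _markov_haplotypes(
    n_hap: int, maf: np.ndarray, r: float, rng: np.random.Generator
) -> np.ndarray:
    """n_hap haplotypes whose locus-p allele is Bernoulli(maf[p]) with
    lag-1 correlation r along the chain."""
    n = maf.size
    hap = np.empty((n_hap, n), dtype=np.int8)
    hap[:, 0] = rng.random(n_hap) < maf[0]
    for p in range(1, n):
        m_prev, m_cur = maf[p - 1], maf[p]
        slope = r * np.sqrt(m_cur * (1 - m_cur) / (m_prev * (1 - m_prev)))
        p1 = np.clip(m_cur + slope * (hap[:, p - 1] - m_prev), 0.0, 1.0)
        hap[:, p] = rng.random(n_hap) < p1
    return hap


def _transmit(
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    mutation_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete per parent: a per-locus uniform pick between the
    parent's two haplotypes (no recombination blocks), optionally hit by
    per-locus mutation flips."""
    pick = rng.integers(0, 2, size=hap_a.shape, dtype=np.int8)
    gamete = np.where(pick == 0, hap_a, hap_b)
    if mutation_rate > 0:
        flip = rng.random(hap_a.shape) < mutation_rate
        gamete = np.where(flip, 1 - gamete, gamete)
    return gamete.astype(np.int8)


def generate_population(
    spec: PopulationSpec,
) -> tuple[GenotypeMatrix, FamilySet]:
    """Simulate a genotype matrix and its trio pedigree.

    Deterministic in ``spec.seed``.  Row order: family blocks
    (mother, father, child) first, then unrelated individuals.
    """
    rng = np.random.default_rng(spec.seed)
    n_founders = 2 * spec.n_families + spec.n_unrelated
    hap = _markov_haplotypes(2 * n_founders, spec.maf, spec.ld_r, rng)
    hap1, hap2 = hap[:n_founders], hap[n_founders:]
    genotypes = []
    row_ids = []
    trios = []
    for i in range(spec.n_families):
        mo, fa = 2 * i, 2 * i + 1
        mid, fid, cid = f"fam{i:04d}_m", f"fam{i:04d}_f", f"fam{i:04d}_c"
        child = (
            _transmit(hap1[mo], hap2[mo], spec.mutation_rate, rng)
            + _transmit(hap1[fa], hap2[fa], spec.mutation_rate, rng)
        )
        genotypes += [hap1[mo] + hap2[mo], hap1[fa] + hap2[fa], child]
        row_ids += [mid, fid, cid]
        trios.append(Trio(mother=mid, father=fid, child=cid))
    for u in range(spec.n_unrelated):
        f = 2 * spec.n_families + u
        genotypes.append(hap1[f] + hap2[f])
        row_ids.append(f"ind{u:05d}")
    locus_ids = [f"rs{p:04d}" for p in range(spec.n_snps)]
    db = GenotypeMatrix(row_ids, np.vstack(genotypes), locus_ids)
    return db, FamilySet(trios)


def derive_knowledge(
    db: GenotypeMatrix,
    families: FamilySet,
    extra_pairs: int = 0,
    seed: int = 0,
) -> tuple[KnowledgeS, KnowledgeJ]:
    """Measure public prior knowledge from a genotype matrix.

    S holds the inner-product similarity of every mother-child and
    father-child pair.  J holds the empirical 3x3 joint distribution of
    every adjacent locus pair, plus ``extra_pairs`` random non-adjacent
    pairs.  Because all joints come from one matrix, their implied
    per-locus marginals are exactly consistent.
    """
    families.validate_against(db)
    sims: dict[tuple[str, str], float] = {}
    for parent, child, _kind in families.first_degree_pairs():
        sims[(parent, child)] = inner_similarity(db.row(parent), db.row(child))

    pairs = [(j, j + 1) for j in range(db.n_loci - 1)]
    if extra_pairs > 0:
        rng = np.random.default_rng(seed)
        existing = set(pairs)
        while len(pairs) - (db.n_loci - 1) < extra_pairs:
            a, b = sorted(rng.choice(db.n_loci, size=2, replace=False))
            if (a, b) not in existing:
                pairs.append((int(a), int(b)))
                existing.add((int(a), int(b)))
    joints: dict[tuple[str, str], np.ndarray] = {}
    m = db.n_individuals
    for a, b in pairs:
        combo = 3 * db.values[:, a].astype(np.int64) + db.values[:, b]
        table = np.bincount(combo, minlength=9).reshape(3, 3) / m
        joints[(db.locus_ids[a], db.locus_ids[b])] = table
    return KnowledgeS(sims), KnowledgeJ(joints)
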