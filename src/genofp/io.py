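"""Readers and writers for the on-disk formats.

* genotype matrix — TSV, first column the individual id, header row the
  locus labels, cells in {0,1,2};
* pedigree — PED/FAM-style whitespace text (family_id, individual_id,
  father_id, mother_id, ...), "0" marking a founder parent;
* prior knowledge — JSON: S keyed "id_a|id_b", J keyed "locusP|locusQ"
  with row-major 3x3 probability arrays;
* fingerprint mask — diagnostic JSON (the mask is recomputable from the
  key, so the file is a cache, never a source of truth);
* optional VCF import of biallelic SNP records.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    FamilySet,
    GenotypeMatrix,
    KnowledgeJ,
    KnowledgeS,
    Trio,
)
from .keystream import OwnerKey
from .vanilla import FingerprintMask, MarkCell

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "IntegrityError",
    "read_matrix",
    "write_matrix",
    "read_pedigree",
    "write_pedigree",
    "read_knowledge_s",
    "write_knowledge_s",
    "read_knowledge_j",
    "write_knowledge_j",
    "read_mask",
    "write_mask",
    "read_key_file",
    "read_vcf",
]


class ParseError(ValueError):
    """Malformed input file."""


class IntegrityError(ValueError):
    """Cross-file referential integrity violation."""


# ---------------------------------------------------------------------------
# genotype matrix
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path) -> GenotypeMatrix:
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file is not a genotype matrix") from exc
    if frame.shape[0] == 0 or frame.shape[1] == 0:
        raise ParseError(f"{path}: no data rows or columns")
    arr = frame.to_numpy(dtype=object)
    valid = np.isin(arr, ("0", "1", "2"))
    if not valid.all():
        i, j = np.argwhere(~valid)[0]
        raise ParseError(
            f"{path}: invalid genotype {arr[i, j]!r} at row "
            f"'{frame.index[i]}', locus '{frame.columns[j]}'")
    values = arr.astype(np.int8)
    return GenotypeMatrix(
        [str(r) for r in frame.index], values, [str(c) for c in frame.columns])


def write_matrix(db: GenotypeMatrix, path: str | Path) -> None:
    frame = pd.DataFrame(db.values, index=db.row_ids, columns=db.locus_ids)
    frame.to_csv(path, sep="\t", index_label="individual")


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def read_pedigree(
    path: str | Path, db: GenotypeMatrix | None = None
) -> FamilySet:
    """Parse trios from PED/FAM-style text.

    A line whose father and mother fields are both non-"0" defines the
    trio (mother, father, child); founder lines only introduce ids.
    When a matrix is supplied, referential integrity is checked and a
    dangling id is fatal.
    """
    path = Path(path)
    trios: list[Trio] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 4:
            raise ParseError(
                f"{path}:{lineno}: expected at least 4 whitespace-separated "
                f"columns, got {len(fields)}")
        _family, individual, father, mother = fields[:4]
        if father != "0" and mother != "0":
            trios.append(Trio(mother=mother, father=father, child=individual))
    families = FamilySet(trios)
    if db is not None:
        try:
            families.validate_against(db)
        except ValueError as exc:
            raise IntegrityError(str(exc)) from exc
    return families


def write_pedigree(families: FamilySet, path: str | Path) -> None:
    lines = []
    for i, trio in enumerate(families):
        fam = f"FAM{i:04d}"
        lines.append(f"{fam}\t{trio.mother}\t0\t0")
        lines.append(f"{fam}\t{trio.father}\t0\t0")
        lines.append(f"{fam}\t{trio.child}\t{trio.father}\t{trio.mother}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# prior knowledge
# ---------------------------------------------------------------------------

def read_knowledge_s(
    path: str | Path, families: FamilySet | None = None
) -> KnowledgeS:
    raw = json.loads(Path(path).read_text())
    sims: dict[tuple[str, str], float] = {}
    for key, value in raw.items():
        parts = key.split("|")
        if len(parts) != 2:
            raise ParseError(f"{path}: S key {key!r} is not 'id_a|id_b'")
        sims[(parts[0], parts[1])] = float(value)
    knowledge = KnowledgeS(sims)
    if families is not None:
        try:
            knowledge.validate_against(families)
        except ValueError as exc:
            raise IntegrityError(str(exc)) from exc
    return knowledge


def write_knowledge_s(S: KnowledgeS, path: str | Path) -> None:
    raw = {f"{a}|{b}": v for (a, b), v in S.similarities.items()}
    Path(path).write_text(json.dumps(raw, indent=1, sort_keys=True))


def read_knowledge_j(path: str | Path) -> KnowledgeJ:
    raw = json.loads(Path(path).read_text())
    joints: dict[tuple[str, str], np.ndarray] = {}
    for key, rows in raw.items():
        parts = key.split("|")
        if len(parts) != 2:
            raise ParseError(f"{path}: J key {key!r} is not 'locusP|locusQ'")
        joints[(parts[0], parts[1])] = np.asarray(rows, dtype=float)
    try:
        return KnowledgeJ(joints)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_knowledge_j(J: KnowledgeJ, path: str | Path) -> None:
    raw = {f"{p}|{q}": j.tolist() for (p, q), j in J.joints.items()}
    Path(path).write_text(json.dumps(raw, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# mask (diagnostic cache)
# ---------------------------------------------------------------------------

def write_mask(mask: FingerprintMask, path: str | Path) -> None:
    Path(path).write_text(json.dumps(mask.to_records(), indent=1))


def read_mask(path: str | Path) -> FingerprintMask:
    raw = json.loads(Path(path).read_text())
    cells = [
        MarkCell(rec["row"], rec["locus"], t=int(rec["t"]),
                 x=int(rec["x"]), l=int(rec["l"]), m=int(rec["m"]))
        for rec in raw
    ]
    return FingerprintMask(cells)


def read_key_file(path: str | Path) -> OwnerKey:
    data = Path(path).read_bytes().rstrip(b"\r\n")
    return OwnerKey(data)


# ---------------------------------------------------------------------------
# optional VCF import
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Import biallelic SNP records from a VCF as minor-allele counts.

    The ALT allele is treated as the minor allele.  Multi-allelic records
    and records with any missing genotype call are rejected (counted and
    logged, not fatal).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    columns: list[np.ndarray] = []
    locus_ids: list[str] = []
    rejected = 0
    for record in vcf:
        if len(record.ALT) != 1 or not record.is_snp:
            rejected += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gts = record.gt_types
        if (gts == 2).any():
            rejected += 1
            continue
        counts = np.where(gts == 3, 2, gts).astype(np.int8)
        columns.append(counts)
        locus_ids.append(record.ID or f"{record.CHROM}:{record.POS}")
    if rejected:
        logger.info("read_vcf: rejected %d records "
                    "(multi-allelic, non-SNP or missing GT)", rejected)
    if not columns:
        raise ParseError(f"{path}: no usable biallelic SNP records")
    return GenotypeMatrix(samples, np.column_stack(columns), locus_ids)
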