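"""Pre-orthology filtering of proteins and homology-family assignments.

Three filters are applied before tree-based orthology inference: a strict
minimum protein length (>100 aa by default), an e-value cutoff on
profile-search family assignments (1e-10 by default), and a universality
requirement keeping only families represented in every taxon of the study.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    taxon: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FamilyAssignment:
    protein_id: str
    family_id: str
    e_value: float


def filter_by_length(
    proteins: Iterable[ProteinRecord], min_length: int = 100
) -> list[ProteinRecord]:
    """Keep proteins strictly longer than ``min_length`` residues."""
    return [p for p in proteins if p.length > min_length]


def filter_assignments(
    assignments: Iterable[FamilyAssignment], e_threshold: float = 1e-10
) -> list[FamilyAssignment]:
    """Keep assignments with e-value <= threshold; malformed rows are dropped."""
    kept = []
    for a in assignments:
        try:
            e = float(a.e_value)
        except (TypeError, ValueError):
            logger.warning("dropping assignment with malformed e-value: %r", a)
            continue
        if e < 0:
            logger.warning("dropping assignment with negative e-value: %r", a)
            continue
        if e <= e_threshold:
            kept.append(a)
    return kept


def retain_universal_families(
    assignments: Iterable[FamilyAssignment],
    proteins: Iterable[ProteinRecord],
    required_taxa: Sequence[str],
) -> list[str]:
    """Families whose assigned proteins cover every required taxon.

    Raises ``KeyError`` naming any assignment protein id that cannot be
    resolved to a taxon.
    """
    taxon_of = {p.id: p.taxon for p in proteins}
    coverage: dict[str, set[str]] = {}
    for a in assignments:
        if a.protein_id not in taxon_of:
            raise KeyError(f"unknown protein id in assignments: {a.protein_id!r}")
        coverage.setdefault(a.family_id, set()).add(taxon_of[a.protein_id])
    required = set(required_taxa)
    return sorted(f for f, taxa in coverage.items() if taxa >= required)


def read_proteins(path: str | Path, sep: str = "|") -> list[ProteinRecord]:
    """FASTA with ``taxon|gene`` headers."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        taxon = rec.id.split(sep)[0]
        records.append(ProteinRecord(id=rec.id, taxon=taxon, sequence=str(rec.seq)))
    return records


def read_assignments(path: str | Path) -> list[FamilyAssignment]:
    """3-column tab-separated: protein_id, family_id, e_value."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            protein_id, family_id, e_value = line.split("\t")[:3]
            try:
                e = float(e_value)
            except ValueError:
                logger.warning("skipping malformed assignment row: %r", line)
                continue
            out.append(FamilyAssignment(protein_id, family_id, e))
    return out
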