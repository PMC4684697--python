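"""Alignment trimming, concatenation, and partitioned supermatrix output.

Per-ortholog alignments are occupancy-trimmed, concatenated per taxon in a
fixed order, and the resulting supermatrix is written with RAxML-style
partition blocks (1-based inclusive coordinates) and a gap percentage over
the full taxa x sites grid.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

#: characters counted as gaps in the gap-fraction denominator;
#: 'X' is a residue, not a gap
GAP_CHARS = frozenset("-?")


@dataclass
class Alignment:
    """Equal-length sequence rows keyed by taxon."""

    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"unequal row lengths: {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def taxa(self) -> set[str]:
        return set(self.rows)


@dataclass(frozen=True)
class PartitionBlock:
    name: str
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad block coordinates {self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Supermatrix:
    rows: dict[str, str]
    blocks: list[PartitionBlock]

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def gap_fraction(self) -> float:
        """Gap percentage: 100 * gap characters / (taxa * length)."""
        cells = len(self.rows) * self.length
        if cells == 0:
            return 0.0
        gaps = sum(
            1 for seq in self.rows.values() for c in seq if c in GAP_CHARS
        )
        return 100.0 * gaps / cells


def trim_columns(aln: Alignment, min_occupancy: float = 0.5) -> Alignment:
    """Keep columns whose non-gap fraction is >= ``min_occupancy``.

    A light occupancy criterion standing in for block-based alignment
    trimmers.  Raises ``ValueError`` if no column survives.
    """
    if not 0 < min_occupancy <= 1:
        raise ValueError("min_occupancy must be in (0, 1]")
    taxa = list(aln.rows)
    n = len(taxa)
    keep = [
        i
        for i in range(aln.length)
        if sum(aln.rows[t][i] not in GAP_CHARS for t in taxa) / n >= min_occupancy
    ]
    if not keep:
        raise ValueError("no column satisfies the occupancy threshold")
    return Alignment(
        rows={t: "".join(aln.rows[t][i] for i in keep) for t in taxa}
    )


def concatenate(
    alignments: Sequence[tuple[str, Alignment]], taxa: Sequence[str]
) -> Supermatrix:
    """Concatenate named alignments per taxon, recording partition blocks.

    Every alignment must contain exactly one row per taxon; a missing
    taxon raises ``ValueError`` naming both.
    """
    parts: dict[str, list[str]] = {t: [] for t in taxa}
    blocks: list[PartitionBlock] = []
    cursor = 1
    for name, aln in alignments:
        for t in taxa:
            if t not in aln.rows:
                raise ValueError(f"alignment {name!r} is missing taxon {t!r}")
            parts[t].append(aln.rows[t])
        blocks.append(
            PartitionBlock(name=name, start=cursor, end=cursor + aln.length - 1)
        )
        cursor += aln.length
    return Supermatrix(
        rows={t: "".join(parts[t]) for t in taxa}, blocks=blocks
    )


def write_partitions(
    sm: Supermatrix, model_label: str, path: str | Path | None = None
) -> list[str]:
    """RAxML-style partition lines ``LABEL, name = start-end``."""
    if not sm.blocks:
        raise ValueError("supermatrix has no partition blocks")
    lines = [
        f"{model_label}, {b.name} = {b.start}-{b.end}" for b in sm.blocks
    ]
    if path is not None:
        Path(path).write_text("\n".join(lines) + "\n")
    return lines


_PARTITION_RE = re.compile(
    r"^\s*\S+\s*,\s*(?P<name>\S+)\s*=\s*(?P<start>\d+)\s*-\s*(?P<end>\d+)\s*$"
)


def parse_partitions(lines: Iterable[str]) -> list[PartitionBlock]:
    """Inverse of ``write_partitions`` (round-trips the block list)."""
    blocks = []
    for line in lines:
        if not line.strip():
            continue
        m = _PARTITION_RE.match(line)
        if m is None:
            raise ValueError(f"unparseable partition line: {line!r}")
        blocks.append(
            PartitionBlock(
                name=m["name"], start=int(m["start"]), end=int(m["end"])
            )
        )
    return blocks


def write_fasta(rows: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for taxon, seq in rows.items():
            fh.write(f">{taxon}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def read_fasta_alignment(path: str | Path) -> Alignment:
    from Bio import SeqIO

    return Alignment(
        rows={rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    )


def write_phylip(rows: dict[str, str], path: str | Path) -> None:
    """Relaxed PHYLIP: full names, two-space separator."""
    if not rows:
        raise ValueError("empty matrix")
    length = len(next(iter(rows.values())))
    width = max(len(t) for t in rows)
    with open(path, "w") as fh:
        fh.write(f"{len(rows)} {length}\n")
        for taxon, seq in rows.items():
            fh.write(f"{taxon:<{width}}  {seq}\n")


def summary(sm: Supermatrix) -> dict:
    return {
        "taxa": len(sm.rows),
        "sites": sm.length,
        "gap_percent": round(sm.gap_fraction, 4),
        "blocks": len(sm.blocks),
    }


def write_summary(sm: Supermatrix, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary(sm), indent=2) + "\n")
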