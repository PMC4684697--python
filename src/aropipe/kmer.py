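"""Genome-size estimation from the k-mer frequency spectrum of reads.

A read of length L contains L - K + 1 k-mers, so the k-mer coverage peak M
of the spectrum relates to the true base-level sequencing depth N by

    M = N * (L - K + 1) / L.

Genome size is then total sequenced bases divided by N.  The spectrum's
error peak (k-mers seen once or twice, produced by sequencing errors) is
excluded when locating M via a minimum-multiplicity threshold.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from statistics import median
from typing import Iterable

from Bio import SeqIO

DEFAULT_KS = (15, 17, 19, 21)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

_VALID = frozenset("ACGT")


@dataclass
class KmerHistogram:
    """Spectrum of distinct k-mer multiplicities.

    ``counts[m]`` is the number of distinct k-mers occurring exactly m
    times across the read set; ``total_bases`` is the total number of
    sequenced bases (gauges genome size once depth is known).
    """

    k: int
    counts: dict[int, int]
    total_bases: int
    read_length: int

    def total_occurrences(self) -> int:
        return sum(m * c for m, c in self.counts.items())


@dataclass
class DepthEstimate:
    M: int
    N: float
    K: int
    L: int
    genome_size: int


def count_kmers(
    reads: Iterable[str], k: int, canonical: bool = False
) -> KmerHistogram:
    """Count every length-k substring of every read.

    Substrings containing a non-A/C/G/T symbol are skipped.  With
    ``canonical=True`` each k-mer is merged with its reverse complement
    (the lexicographically smaller of the pair is counted).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    table: Counter[str] = Counter()
    total_bases = 0
    lengths: Counter[int] = Counter()
    for read in reads:
        read = read.upper()
        n = len(read)
        if k >= n + 1:
            raise ValueError(f"k={k} exceeds read length {n}")
        total_bases += n
        lengths[n] += 1
        clean = set(read) <= _VALID
        for i in range(n - k + 1):
            kmer = read[i : i + k]
            if not clean and not set(kmer) <= _VALID:
                continue
            if canonical:
                rc = kmer.translate(_COMPLEMENT)[::-1]
                if rc < kmer:
                    kmer = rc
            table[kmer] += 1
    if not table:
        raise ValueError("no reads supplied")
    hist = Counter(table.values())
    modal_length = max(lengths.items(), key=lambda kv: (kv[1], kv[0]))[0]
    return KmerHistogram(
        k=k, counts=dict(hist), total_bases=total_bases, read_length=modal_length
    )


def find_peak(
    hist: KmerHistogram, min_multiplicity: int = 3, refine: bool = False
) -> int:
    """Multiplicity of the spectrum's main peak.

    Returns the multiplicity with the most distinct k-mers among
    multiplicities >= ``min_multiplicity`` (excluding the error peak near
    multiplicity 1); ties go to the smaller multiplicity.

    With ``refine=True`` the raw mode is replaced by the rounded
    count-weighted mean multiplicity of the above-threshold spectrum.
    For the genomic (non-error) part of the spectrum the mean
    multiplicity equals the k-mer depth exactly, whereas the raw mode
    wobbles between adjacent bins whenever the k-mer depth falls near a
    bin boundary; the mean pools every bin and is stable against that
    sampling noise.
    """
    candidates = [
        (m, c) for m, c in hist.counts.items() if m >= min_multiplicity
    ]
    if not candidates:
        raise ValueError(
            f"no multiplicity >= {min_multiplicity} in the spectrum"
        )
    mode = min(candidates, key=lambda mc: (-mc[1], mc[0]))[0]
    if not refine:
        return mode
    weight = sum(c for _, c in candidates)
    centroid = sum(m * c for m, c in candidates) / weight
    return max(int(round(centroid)), min_multiplicity)


def estimate_depth(M: int, L: int, K: int) -> float:
    """Base-level depth N from the k-mer coverage peak: N = M * L / (L - K + 1)."""
    if K < 1 or L <= K:
        raise ValueError(f"need L > K >= 1, got L={L}, K={K}")
    if M < 1:
        raise ValueError("peak multiplicity must be >= 1")
    return M * L / (L - K + 1)


def estimate_genome_size(hist: KmerHistogram, N: float) -> int:
    """Genome size = total sequenced bases / real depth (floored to bases)."""
    if N <= 0:
        raise ValueError("depth must be positive")
    return math.floor(hist.total_bases / N)


def genome_size_from_reads(
    reads: list[str],
    ks: Iterable[int] = DEFAULT_KS,
    min_multiplicity: int = 3,
    canonical: bool = False,
    refine_peak: bool = True,
) -> dict:
    """Full estimator: one DepthEstimate per k plus the median genome size."""
    per_k: dict[int, DepthEstimate] = {}
    for k in ks:
        hist = count_kmers(reads, k, canonical=canonical)
        M = find_peak(hist, min_multiplicity, refine=refine_peak)
        N = estimate_depth(M, hist.read_length, k)
        per_k[k] = DepthEstimate(
            M=M, N=N, K=k, L=hist.read_length,
            genome_size=estimate_genome_size(hist, N),
        )
    sizes = [est.genome_size for est in per_k.values()]
    return {"per_k": per_k, "genome_size": median(sizes)}


def read_sequences(path: str | Path) -> list[str]:
    """Load reads from FASTA or FASTQ (extension-sniffed)."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in {".fq", ".fastq"} else "fasta"
    return [str(rec.seq) for rec in SeqIO.parse(str(path), fmt)]


def write_histogram(hist: KmerHistogram, path: str | Path) -> None:
    """Two-column multiplicity/count table, tab-separated."""
    with open(path, "w") as fh:
        for m in sorted(hist.counts):
            fh.write(f"{m}\t{hist.counts[m]}\n")
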