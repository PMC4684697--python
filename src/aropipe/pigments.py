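"""Screening predicted proteins against a curated pigmentation-gene catalog.

Similarity-search hits (BLASTP tabular output with subject length
appended) are filtered on e-value and subject-length coverage, the best
surviving hit per catalog gene is selected, and hits are reported grouped
by the catalog's functional categories (melanophore development,
melanosome components, pteridine synthesis, ...).  Catalog genes with no
surviving hit are reported as absent.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: standard BLAST outfmt-6 columns with subject length appended
HIT_COLUMNS = [
    "query_gene",
    "subject_id",
    "percent_identity",
    "align_length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "e_value",
    "bit_score",
    "subject_length",
]

_NUMERIC = [
    "percent_identity",
    "align_length",
    "e_value",
    "bit_score",
    "subject_length",
]

ABSENT = "-"


def read_hits(path: str | Path) -> pd.DataFrame:
    """Load a 13-column hit table; malformed rows are logged and skipped."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=HIT_COLUMNS, comment="#", dtype=str
    )
    for col in _NUMERIC:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df[_NUMERIC].isna().any(axis=1)
    if bad.any():
        logger.warning("skipping %d malformed hit rows", int(bad.sum()))
        df = df[~bad]
    return df.reset_index(drop=True)


def coverage(hits: pd.DataFrame) -> pd.Series:
    """Hit coverage = alignment length / subject length."""
    if (hits["subject_length"] < 1).any():
        raise ValueError("subject_length must be >= 1 for every hit")
    return hits["align_length"] / hits["subject_length"]


def filter_hits(
    hits: pd.DataFrame,
    e_threshold: float = 1e-40,
    min_coverage: float = 0.7,
) -> pd.DataFrame:
    """Keep hits with e-value <= threshold and coverage >= cutoff."""
    mask = (hits["e_value"] <= e_threshold) & (coverage(hits) >= min_coverage)
    return hits[mask].reset_index(drop=True)


def best_hit_per_gene(
    hits: pd.DataFrame, genes: Sequence[str] | None = None
) -> pd.DataFrame:
    """One best hit per catalog gene, or an absent record.

    Best = smallest e-value; ties broken by higher bit score, then higher
    percent identity, then lexicographically smallest subject id.  The
    result is invariant to the input row order.  ``genes`` fixes the set
    of genes to report (absent rows for genes with no surviving hit);
    by default the genes present in ``hits`` are reported.
    """
    ordered = hits.sort_values(
        by=["e_value", "bit_score", "percent_identity", "subject_id"],
        ascending=[True, False, False, True],
        kind="mergesort",
    )
    best = ordered.groupby("query_gene", as_index=False).first()
    if genes is not None:
        frame = pd.DataFrame({"query_gene": list(genes)})
        best = frame.merge(best, on="query_gene", how="left")
    return best.reset_index(drop=True)


def read_catalog(path: str | Path) -> pd.DataFrame:
    """Tab-separated catalog: gene, human accession, ';'-joined categories."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["gene", "human_accession", "categories"],
        comment="#",
        dtype=str,
    )
    if df["gene"].duplicated().any():
        dupes = df.loc[df["gene"].duplicated(), "gene"].tolist()
        raise ValueError(f"duplicate catalog gene symbols: {dupes}")
    df["categories"] = df["categories"].str.split(";")
    if (df["categories"].str.len() < 1).any():
        raise ValueError("every catalog entry needs at least one category")
    return df


def categorize(best_hits: pd.DataFrame, catalog: pd.DataFrame) -> pd.DataFrame:
    """Report table grouped by functional category.

    One row per (category, gene), ordered by category then gene; a gene
    carrying several categories appears once per category.  Genes in
    ``best_hits`` that are not in the catalog raise ``KeyError``.  Absent
    genes keep their row with '-' placeholders.
    """
    known = set(catalog["gene"])
    unknown = sorted(set(best_hits["query_gene"]) - known)
    if unknown:
        raise KeyError(f"genes not in catalog: {unknown}")
    hit_by_gene = best_hits.set_index("query_gene")
    rows = []
    for _, entry in catalog.iterrows():
        gene = entry["gene"]
        if gene in hit_by_gene.index:
            hit = hit_by_gene.loc[gene]
            found = not pd.isna(hit["subject_id"])
        else:
            found = False
        for category in entry["categories"]:
            rows.append(
                {
                    "category": category,
                    "gene": gene,
                    "human_accession": entry["human_accession"],
                    "subject_id": hit["subject_id"] if found else ABSENT,
                    "percent_identity": hit["percent_identity"]
                    if found
                    else np.nan,
                    "e_value": hit["e_value"] if found else np.nan,
                }
            )
    report = pd.DataFrame(rows)
    return report.sort_values(["category", "gene"], kind="mergesort").reset_index(
        drop=True
    )


def write_report(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, sep="\t", index=False, na_rep=ABSENT)
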