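"""Lineage evolutionary rates and Tajima relative rate tests.

The per-lineage rate is the sum of branch lengths (amino-acid
substitutions per site) from a tip back to a reference ancestral node —
here typically the split of ray-finned from lobe-finned fishes.  Tajima's
relative rate test compares two ingroup lineages against an outgroup:
with complete deletion of gapped/ambiguous columns, it counts the sites
where each ingroup sequence uniquely differs (m_a, m_b) and refers
(m_a - m_b)^2 / (m_a + m_b) to chi-square with 1 df.  Under equal rates
the two unique-difference counts have equal expectation regardless of the
substitution process, which is what makes the test model-free.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

#: the 20 standard amino acids; anything else triggers complete deletion
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class RateRecord:
    taxon: str
    rate: float


@dataclass
class TripletTestResult:
    taxon_a: str
    taxon_b: str
    outgroup: str
    n_sites: int
    m_a: int
    m_b: int
    chi2: float | None = None
    p: float | None = None
    alpha_corrected: float | None = None

    @property
    def reject(self) -> bool | None:
        if self.p is None or self.alpha_corrected is None:
            return None
        return self.p < self.alpha_corrected


def find_mrca(tree: dendropy.Tree, taxa: Sequence[str]) -> dendropy.Node:
    """Most recent common ancestor of the named tips (rooted tree)."""
    present = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = [t for t in taxa if t not in present]
    if missing:
        raise KeyError(f"taxa not in tree: {missing}")
    node = tree.mrca(taxon_labels=list(taxa))
    if node is None:
        raise ValueError(f"no common ancestor found for {list(taxa)}")
    return node


def lineage_rate(
    tree: dendropy.Tree, tip: str, reference: dendropy.Node
) -> RateRecord:
    """Sum of branch lengths along the tip -> reference path."""
    leaf = next(
        (l for l in tree.leaf_node_iter() if l.taxon.label == tip), None
    )
    if leaf is None:
        raise KeyError(f"tip {tip!r} not in tree")
    total = 0.0
    node = leaf
    while node is not reference:
        if node.parent_node is None:
            raise ValueError(
                f"reference node is not an ancestor of tip {tip!r}"
            )
        total += node.edge.length or 0.0
        node = node.parent_node
    return RateRecord(taxon=tip, rate=total)


def root_with_outgroup(
    tree: dendropy.Tree, outgroup_taxa: Sequence[str]
) -> dendropy.Tree:
    """Re-root on the edge separating the outgroup from the ingroup.

    The edge's length is split equally between the two root children.
    Raises ``ValueError`` if the outgroup is not consistent with any
    bipartition of the (unrooted) tree.  All tip-to-tip path lengths are
    preserved.
    """
    work = tree.clone(depth=1)
    outgroup = set(outgroup_taxa)
    all_tips = {leaf.taxon.label for leaf in work.leaf_node_iter()}
    if not outgroup <= all_tips:
        raise KeyError(f"outgroup taxa not in tree: {sorted(outgroup - all_tips)}")
    target = None
    for node in work.preorder_node_iter():
        if node is work.seed_node:
            continue
        below = {leaf.taxon.label for leaf in node.leaf_iter()}
        if below == outgroup or below == all_tips - outgroup:
            target = node
            break
    if target is None:
        raise ValueError(
            "outgroup is not bipartition-consistent (not monophyletic "
            "in the unrooted tree)"
        )
    length = target.edge.length or 0.0
    work.is_rooted = True
    work.reroot_at_edge(target.edge, length1=length / 2, length2=length / 2)
    work.suppress_unifurcations()
    return work


def tajima_counts(
    alignment: Mapping[str, str], a: str, b: str, outgroup: str
) -> TripletTestResult:
    """Unique-difference site counts for one triplet, complete deletion.

    Columns with any non-standard amino-acid symbol (gaps '-', missing
    '?', ambiguity 'X', ...) in any of the three rows are discarded.
    m_a counts columns where only ``a`` differs (b == outgroup), m_b the
    symmetric case; columns with three distinct states or an
    outgroup-unique state contribute to n_sites only.
    """
    for name in (a, b, outgroup):
        if name not in alignment:
            raise KeyError(f"taxon {name!r} not in alignment")
    sa = alignment[a].upper()
    sb = alignment[b].upper()
    so = alignment[outgroup].upper()
    if not (len(sa) == len(sb) == len(so)):
        raise ValueError("rows differ in length")
    n = m_a = m_b = 0
    for ca, cb, co in zip(sa, sb, so):
        if ca not in STANDARD_AA or cb not in STANDARD_AA or co not in STANDARD_AA:
            continue
        n += 1
        if ca != cb:
            if cb == co:
                m_a += 1
            elif ca == co:
                m_b += 1
    return TripletTestResult(
        taxon_a=a, taxon_b=b, outgroup=outgroup, n_sites=n, m_a=m_a, m_b=m_b
    )


def tajima_test(counts: TripletTestResult) -> TripletTestResult:
    """Chi-square statistic and p-value for one triplet.

    chi2 = (m_a - m_b)^2 / (m_a + m_b), referred to chi-square with 1 df;
    the upper-tail probability is erfc(sqrt(chi2 / 2)) in closed form.
    With m_a + m_b = 0 there is no evidence either way: chi2 = 0, p = 1.
    """
    total = counts.m_a + counts.m_b
    chi2 = (counts.m_a - counts.m_b) ** 2 / total if total > 0 else 0.0
    counts.chi2 = chi2
    counts.p = math.erfc(math.sqrt(chi2 / 2.0))
    return counts


def bonferroni(alpha: float, n_tests: int) -> float:
    """Family-wise corrected per-test critical value alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    return alpha / n_tests


def batch_relative_rate(
    alignment: Mapping[str, str],
    focal: str,
    others: Sequence[str],
    outgroups: Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All (other, outgroup) Tajima tests of a focal lineage.

    One row per pairing with a shared Bonferroni critical value
    alpha / (len(others) * len(outgroups)); ``reject`` flags p below it.
    """
    overlap = ({focal} & set(others)) | ({focal} & set(outgroups)) | (
        set(others) & set(outgroups)
    )
    if overlap:
        raise ValueError(f"focal/others/outgroups overlap: {sorted(overlap)}")
    critical = bonferroni(alpha, len(others) * len(outgroups))
    rows = []
    for other, out in itertools.product(others, outgroups):
        res = tajima_test(tajima_counts(alignment, focal, other, out))
        res.alpha_corrected = critical
        rows.append(
            {
                "taxon_a": res.taxon_a,
                "taxon_b": res.taxon_b,
                "outgroup": res.outgroup,
                "n_sites": res.n_sites,
                "m_a": res.m_a,
                "m_b": res.m_b,
                "chi2": res.chi2,
                "p": res.p,
                "alpha_corrected": res.alpha_corrected,
                "reject": res.reject,
            }
        )
    return pd.DataFrame(rows)


def rate_table(
    tree: dendropy.Tree, tips: Iterable[str], reference: dendropy.Node
) -> pd.DataFrame:
    """Per-tip path-sum rates relative to one reference node."""
    records = [lineage_rate(tree, tip, reference) for tip in tips]
    return pd.DataFrame(
        [{"taxon": r.taxon, "rate": r.rate} for r in records]
    )
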