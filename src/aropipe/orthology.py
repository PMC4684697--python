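"""Tree-surgery decomposition of homolog trees into ortholog groups.

Gene-family trees mix orthologs (related by speciation) with paralogs
(related by duplication) and the occasional spurious long-branch sequence.
The decomposition applies, in order: long-tip trimming (absolute and
relative cutoffs), masking of same-taxon monophyletic tip clusters,
cutting of long internal branches that separate orthologous groups, a
taxon-coverage filter, and finally paralogy pruning by maximum inclusion
(MI): iterative extraction of the rooted subtree covering the most
distinct taxa with no taxon repeated.

Trees are dendropy ``Tree`` objects whose tip labels carry taxon and gene
copy as ``taxon@copy`` (separator configurable).  Branch lengths are never
rescaled; suppression of degree-2 nodes sums the two merged branches, so
path lengths between surviving tips are conserved.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import skbio

DEFAULT_SEP = "@"


@dataclass
class PruningParams:
    """Cutoffs of the decomposition, in substitutions per site.

    A tip is trimmed when its terminal branch exceeds ``absolute_tip_cutoff``,
    or exceeds ``relative_tip_cutoff`` while also being more than
    ``relative_factor`` times the longest terminal branch among the tips of
    its sister clade.  Internal branches longer than
    ``internal_branch_cutoff`` are cut.  MI groups need at least
    ``min_taxa`` distinct taxa to be emitted.
    """

    absolute_tip_cutoff: float = 0.5
    relative_tip_cutoff: float = 0.2
    relative_factor: float = 10.0
    internal_branch_cutoff: float = 0.3
    min_taxa: int = 27

    def __post_init__(self) -> None:
        for name in (
            "absolute_tip_cutoff",
            "relative_tip_cutoff",
            "relative_factor",
            "internal_branch_cutoff",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.relative_tip_cutoff >= self.absolute_tip_cutoff:
            raise ValueError("relative_tip_cutoff must be < absolute_tip_cutoff")
        if self.min_taxa < 1:
            raise ValueError("min_taxa must be >= 1")


@dataclass
class OrthologGroup:
    family_id: str
    members: dict[str, str]  # taxon -> tip label
    source_subtree: dendropy.Tree | None = None

    @property
    def labels(self) -> frozenset[str]:
        return frozenset(self.members.values())


def taxon_of(label: str, sep: str = DEFAULT_SEP) -> str:
    return label.split(sep)[0]


def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def leaf_taxa(tree: dendropy.Tree, sep: str = DEFAULT_SEP) -> set[str]:
    return {taxon_of(lbl, sep) for lbl in leaf_labels(tree)}


def tree_from_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )


def read_gene_tree(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )


def write_gene_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)


def _clone(tree: dendropy.Tree) -> dendropy.Tree:
    return tree.clone(depth=1)


def _prune_to(tree: dendropy.Tree, keep: set[str]) -> dendropy.Tree:
    """Clone retaining only the tips in ``keep`` (degree-2 nodes suppressed)."""
    out = _clone(tree)
    drop = [
        leaf.taxon for leaf in out.leaf_node_iter() if leaf.taxon.label not in keep
    ]
    if drop:
        out.prune_taxa(drop, suppress_unifurcations=True)
    return out


def trim_tips(tree: dendropy.Tree, params: PruningParams) -> dendropy.Tree:
    """Remove spuriously long tips (absolute and relative cutoffs).

    Within each sweep every tip is judged against the current tree
    simultaneously; sweeps repeat until no rule fires, because suppressing
    a degree-2 node can lengthen a surviving terminal branch past a cutoff
    (this makes the operation idempotent).  Raises ``ValueError`` if fewer
    than 3 tips would remain.
    """
    if sum(1 for _ in tree.leaf_node_iter()) < 3:
        raise ValueError("trim_tips needs a tree with at least 3 tips")
    work = _clone(tree)
    while True:
        drop = []
        n_leaves = 0
        for leaf in work.leaf_node_iter():
            n_leaves += 1
            bl = leaf.edge.length or 0.0
            if bl > params.absolute_tip_cutoff:
                drop.append(leaf)
                continue
            if bl > params.relative_tip_cutoff and leaf.parent_node is not None:
                sister_terms = [
                    (sib_leaf.edge.length or 0.0)
                    for sib in leaf.parent_node.child_nodes()
                    if sib is not leaf
                    for sib_leaf in sib.leaf_iter()
                ]
                if sister_terms and bl > params.relative_factor * max(sister_terms):
                    drop.append(leaf)
        if not drop:
            return work
        if n_leaves - len(drop) < 3:
            raise ValueError(
                f"tip trimming would leave {n_leaves - len(drop)} tips (< 3)"
            )
        work.prune_taxa([leaf.taxon for leaf in drop], suppress_unifurcations=True)


def mask_monophyletic_tips(
    tree: dendropy.Tree, sep: str = DEFAULT_SEP
) -> dendropy.Tree:
    """Collapse each maximal same-taxon clade to one representative tip.

    The representative is the tip with the shortest terminal branch (ties
    broken lexicographically by label).  Trees whose taxa are already all
    distinct are returned unchanged (as a copy); the operation is
    idempotent.
    """
    work = _clone(tree)
    taxa_below: dict[dendropy.Node, set[str]] = {}
    for node in work.postorder_node_iter():
        if node.is_leaf():
            taxa_below[node] = {taxon_of(node.taxon.label, sep)}
        else:
            taxa_below[node] = set().union(
                *(taxa_below[c] for c in node.child_nodes())
            )
    drop = []
    for node in work.preorder_node_iter():
        if node.is_leaf() or len(taxa_below[node]) != 1:
            continue
        parent = node.parent_node
        if parent is not None and len(taxa_below[parent]) == 1:
            continue  # not maximal
        leaves = list(node.leaf_iter())
        keep = min(leaves, key=lambda l: ((l.edge.length or 0.0), l.taxon.label))
        drop.extend(l for l in leaves if l is not keep)
    if drop:
        work.prune_taxa([l.taxon for l in drop], suppress_unifurcations=True)
    return work


def cut_long_internal_branches(
    tree: dendropy.Tree, params: PruningParams
) -> list[dendropy.Tree]:
    """Cut internal branches longer than the cutoff into separate trees.

    The components' tip sets partition the input tip set.  When the root
    has exactly two children the two basal child edges represent a single
    unrooted edge and are judged by their combined length.
    """
    work = _clone(tree)
    components: list[dendropy.Tree] = []

    def find_cut(t: dendropy.Tree):
        seed = t.seed_node
        kids = seed.child_nodes()
        for node in t.preorder_node_iter():
            if node is seed or node.is_leaf():
                continue
            length = node.edge.length or 0.0
            if node.parent_node is seed and len(kids) == 2:
                sib = next(k for k in kids if k is not node)
                if sib.is_leaf():
                    continue  # unrooted edge is terminal on the other side
                length += sib.edge.length or 0.0
            if length > params.internal_branch_cutoff:
                return node
        return None

    while True:
        node = find_cut(work)
        if node is None:
            break
        node.parent_node.remove_child(node)
        node.edge.length = None
        part = dendropy.Tree(taxon_namespace=work.taxon_namespace)
        part.seed_node = node
        components.append(part)
        work.suppress_unifurcations()
    components.append(work)
    return components


def filter_by_taxa(
    trees: Iterable[dendropy.Tree],
    required_taxa: Sequence[str],
    sep: str = DEFAULT_SEP,
) -> list[dendropy.Tree]:
    """Keep trees whose tip taxa cover every required taxon."""
    required = set(required_taxa)
    return [t for t in trees if leaf_taxa(t, sep) >= required]


def max_inclusion_candidate(
    tree: dendropy.Tree, sep: str = DEFAULT_SEP
) -> frozenset[str] | None:
    """Best taxon-unique rooted subtree of an (implicitly unrooted) tree.

    Candidates are, for every edge, the tip sets on each of its two sides,
    plus the whole tree.  Among candidates with no repeated taxon the one
    covering the most distinct taxa wins; ties prefer smaller total branch
    length, then the lexicographically smallest sorted tip-label tuple.
    Returns ``None`` when no candidate is taxon-unique (cannot happen:
    single tips always are).
    """
    leaves_below: dict[dendropy.Node, frozenset[str]] = {}
    length_below: dict[dendropy.Node, float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            leaves_below[node] = frozenset([node.taxon.label])
            length_below[node] = 0.0
        else:
            kids = node.child_nodes()
            leaves_below[node] = frozenset().union(*(leaves_below[c] for c in kids))
            length_below[node] = sum(
                length_below[c] + (c.edge.length or 0.0) for c in kids
            )
    all_leaves = leaves_below[tree.seed_node]
    total_length = length_below[tree.seed_node]

    candidates: dict[frozenset[str], float] = {all_leaves: total_length}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        below = leaves_below[node]
        above = all_leaves - below
        for side, side_len in (
            (below, length_below[node]),
            (
                above,
                total_length - length_below[node] - (node.edge.length or 0.0),
            ),
        ):
            if side and (side not in candidates or side_len < candidates[side]):
                candidates[side] = side_len

    best: tuple | None = None
    best_set: frozenset[str] | None = None
    for side, side_len in candidates.items():
        taxa = [taxon_of(lbl, sep) for lbl in side]
        if len(set(taxa)) != len(taxa):
            continue
        key = (-len(taxa), side_len, tuple(sorted(side)))
        if best is None or key < best:
            best = key
            best_set = side
    return best_set


def prune_paralogy_MI(
    tree: dendropy.Tree,
    params: PruningParams,
    family_id: str = "",
    sep: str = DEFAULT_SEP,
) -> list[OrthologGroup]:
    """Paralogy pruning by maximum inclusion.

    Repeatedly: apply the tip cutoffs, pick the taxon-unique subtree
    covering the most taxa (``max_inclusion_candidate``), emit it as an
    ortholog group if it reaches ``min_taxa``, and delete its tips from
    the working tree.  Emitted groups are tip-disjoint; an empty result is
    valid.
    """
    work = _clone(tree)
    groups: list[OrthologGroup] = []
    while True:
        n_leaves = sum(1 for _ in work.leaf_node_iter())
        if n_leaves < params.min_taxa:
            break
        if n_leaves >= 3:
            try:
                work = trim_tips(work, params)
            except ValueError:
                break
            n_leaves = sum(1 for _ in work.leaf_node_iter())
            if n_leaves < params.min_taxa:
                break
        best = max_inclusion_candidate(work, sep)
        if best is None or len(best) < params.min_taxa:
            break
        members = {taxon_of(lbl, sep): lbl for lbl in sorted(best)}
        groups.append(
            OrthologGroup(
                family_id=family_id,
                members=members,
                source_subtree=_prune_to(work, set(best)),
            )
        )
        remaining = leaf_labels(work) - set(best)
        if len(remaining) < 2:
            break
        work = _prune_to(work, remaining)
    return groups


def decompose_family(
    tree: dendropy.Tree,
    params: PruningParams,
    required_taxa: Sequence[str],
    family_id: str = "",
    sep: str = DEFAULT_SEP,
) -> list[OrthologGroup]:
    """Full decomposition of one homolog tree.

    trim tips -> mask same-taxon monophyletic tips -> cut long internal
    branches -> keep components covering all required taxa -> MI pruning.
    """
    try:
        trimmed = trim_tips(tree, params)
    except ValueError:
        return []
    masked = mask_monophyletic_tips(trimmed, sep)
    parts = cut_long_internal_branches(masked, params)
    kept = filter_by_taxa(parts, required_taxa, sep)
    groups: list[OrthologGroup] = []
    for part in kept:
        groups.extend(prune_paralogy_MI(part, params, family_id=family_id, sep=sep))
    return groups


def pairwise_poisson_distances(
    alignment: dict[str, str], gap_chars: str = "-?Xx"
) -> tuple[list[str], np.ndarray]:
    """Poisson-corrected distances d = -ln(1 - p) from pairwise p-distances.

    Columns with a gap/ambiguity in either sequence of a pair are skipped
    for that pair.  Raises on saturated pairs (p >= 0.95), where the
    correction diverges.
    """
    labels = list(alignment)
    gaps = set(gap_chars)
    seqs = [alignment[l].upper() for l in labels]
    n = len(labels)
    if n < 3:
        raise ValueError("need at least 3 sequences")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("sequences must be aligned (equal length)")
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diffs = valid = 0
            for a, b in zip(seqs[i], seqs[j]):
                if a in gaps or b in gaps:
                    continue
                valid += 1
                if a != b:
                    diffs += 1
            p = diffs / valid if valid else 0.0
            if p >= 0.95:
                raise ValueError(
                    f"saturated p-distance ({p:.3f}) between "
                    f"{labels[i]!r} and {labels[j]!r}; Poisson correction undefined"
                )
            dm[i, j] = dm[j, i] = -math.log(1.0 - p)
    return labels, dm


def nj_from_distances(labels: list[str], dm: np.ndarray) -> dendropy.Tree:
    """Neighbor-joining tree from a symmetric distance matrix.

    Exact for additive matrices; deterministic for a fixed label order.
    """
    sk_dm = skbio.DistanceMatrix(dm, ids=labels)
    sk_tree = skbio.tree.nj(sk_dm)
    buf = io.StringIO()
    sk_tree.write(buf, format="newick")
    return tree_from_newick(buf.getvalue())


def nj_tree(alignment: dict[str, str]) -> dendropy.Tree:
    """Neighbor-joining tree from Poisson-corrected amino-acid distances.

    Stands in for external maximum-likelihood tree builders so the
    decomposition loop can run self-contained.
    """
    labels, dm = pairwise_poisson_distances(alignment)
    return nj_from_distances(labels, dm)


def write_groups(
    groups: Iterable[OrthologGroup], path: str | Path
) -> None:
    """Tab-separated group membership: family_id, taxon, tip_label."""
    with open(path, "w") as fh:
        for g in groups:
            for taxon in sorted(g.members):
                fh.write(f"{g.family_id}\t{taxon}\t{g.members[taxon]}\n")
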