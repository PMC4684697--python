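"""Synthetic data generation with known ground truth.

Produces every input the pipeline consumes: a species tree, gene families
with duplication/loss-generated paralogy and per-taxon rate multipliers,
amino-acid alignments evolved along the gene trees, and sequencing reads
drawn from a known-size genome.  Ground truth (ortholog membership,
contaminant tips, genome size) is recorded so recovery can be measured.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
from dendropy.simulate import treesim

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDES = "ACGT"

#: separator between taxon and gene-copy id in tip labels
COPY_SEP = "@"


@dataclass
class SimulationConfig:
    """Parameters of the gene-family simulator.

    Defaults mirror the structure of the empirical study the pipeline is
    built for: 27 taxa and 177 families.  Duplication and loss rates are
    events per unit branch length (branch lengths are amino-acid
    substitutions per site); ``tree_height`` is the root-to-tip depth of
    the species tree in the same units.
    """

    n_taxa: int = 27
    n_families: int = 177
    duplication_rate: float = 0.5
    loss_rate: float = 0.3
    site_count: int = 300
    rate_multipliers: dict[str, float] = field(default_factory=dict)
    contaminant_tip_rate: float = 0.0
    seed: int = 0
    tree_height: float = 0.2

    def __post_init__(self) -> None:
        if self.n_taxa < 4:
            raise ValueError(f"n_taxa must be >= 4, got {self.n_taxa}")
        for name in ("duplication_rate", "loss_rate", "contaminant_tip_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(m <= 0 for m in self.rate_multipliers.values()):
            raise ValueError("rate multipliers must be positive")


@dataclass
class SimulatedFamily:
    """One simulated gene family with its ground truth.

    ``true_ortholog_sets`` partitions the non-contaminant tips into
    taxon-unique groups: tips sharing a gene-copy lineage (all pairwise
    most recent common ancestors are speciation nodes).
    """

    family_id: str
    gene_tree: dendropy.Tree
    alignment: dict[str, str]
    true_ortholog_sets: list[frozenset[str]]
    contaminants: frozenset[str]


@dataclass
class ReadSimConfig:
    """Parameters for uniform shotgun read simulation."""

    genome_length: int
    depth: float
    read_length: int
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 2 or self.genome_length < self.read_length:
            raise ValueError("need genome_length >= read_length >= 2")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")


def simulate_species_tree(config: SimulationConfig) -> dendropy.Tree:
    """Simulate a rooted binary species tree with ``n_taxa`` tips.

    A pure-birth tree is drawn, tips are relabelled ``t01 .. tNN``, and
    branch lengths are rescaled so the maximum root-to-tip depth equals
    ``config.tree_height`` (substitutions per site).
    """
    rng = random.Random(config.seed)
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=config.n_taxa,
        rng=rng,
    )
    # the process stops at the n-th birth, leaving the youngest tips with
    # zero-length branches; extend all terminals by the waiting time to the
    # next (unrealized) event so branch lengths are strictly positive and
    # the tree stays ultrametric
    extra = rng.expovariate(config.n_taxa * 1.0)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    width = len(str(config.n_taxa))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"t{i:0{width}d}"
    depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    scale = config.tree_height / depth
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    tree.seed_node.edge.length = None
    return tree


def taxon_labels(tree: dendropy.Tree) -> list[str]:
    return sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())


def _evolve_along(
    seq: np.ndarray, branch_length: float, rng: np.random.Generator
) -> np.ndarray:
    """One step of the equal-exchangeability 20-state model.

    Substitution probability per site over branch length t is
    (19/20) * (1 - exp(-20/19 * t)), the 20-state Jukes-Cantor analog;
    a substituted site moves to one of the 19 other states uniformly.
    """
    p = (19 / 20) * (1 - np.exp(-(20 / 19) * branch_length))
    hit = rng.random(seq.size) < p
    jump = rng.integers(1, 20, size=seq.size)
    return np.where(hit, (seq + jump) % 20, seq)


def simulate_gene_family(
    species_tree: dendropy.Tree,
    config: SimulationConfig,
    family_index: int = 0,
) -> SimulatedFamily:
    """Run a birth-death walk along the species tree and evolve sequences.

    Duplication copies a gene lineage (the copy evolves independently from
    the duplication point on); loss removes it.  Tips are labelled
    ``taxon@copy``.  Per-taxon rate multipliers stretch terminal branches;
    the optional contaminant inflates one terminal branch by a factor of
    at least 10 (always past 0.5), emulating a misassembled or misassigned
    sequence that downstream tip trimming must remove.

    Raises ``RuntimeError`` if every gene lineage is lost before reaching
    a tip.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, family_index)))
    total_rate = config.duplication_rate + config.loss_rate
    copy_counter = itertools.count(1)
    truth: dict[str, list[str]] = {}

    def walk(sp_node: dendropy.Node, remaining: float, copy_id: str):
        # Competing Poisson events along the branch into sp_node.
        dt = rng.exponential(1 / total_rate) if total_rate > 0 else np.inf
        if dt >= remaining:
            sub = at_node(sp_node, copy_id)
            if sub is not None:
                sub.edge.length += remaining
            return sub
        if rng.random() < config.loss_rate / total_rate:
            return None
        new_id = f"{copy_id}.{next(copy_counter)}"
        kept = walk(sp_node, remaining - dt, copy_id)
        copied = walk(sp_node, remaining - dt, new_id)
        alive = [c for c in (kept, copied) if c is not None]
        if not alive:
            return None
        if len(alive) == 1:
            alive[0].edge.length += dt
            return alive[0]
        node = dendropy.Node()
        node.edge.length = dt
        for child in alive:
            node.add_child(child)
        return node

    def at_node(sp_node: dendropy.Node, copy_id: str):
        if sp_node.is_leaf():
            tip = dendropy.Node()
            tip.edge.length = 0.0
            tip.gene_label = f"{sp_node.taxon.label}{COPY_SEP}{copy_id}"
            truth.setdefault(copy_id, []).append(tip.gene_label)
            return tip
        kids = [
            walk(child, child.edge.length, copy_id)
            for child in sp_node.child_nodes()
        ]
        alive = [c for c in kids if c is not None]
        if not alive:
            return None
        if len(alive) == 1:
            return alive[0]
        node = dendropy.Node()
        node.edge.length = 0.0
        for child in alive:
            node.add_child(child)
        return node

    root = at_node(species_tree.seed_node, "0")
    if root is None:
        raise RuntimeError("all gene lineages lost before reaching any tip")

    tns = dendropy.TaxonNamespace()
    gene_tree = dendropy.Tree(taxon_namespace=tns)
    gene_tree.seed_node = root
    gene_tree.is_rooted = True
    root.edge.length = None
    for leaf in gene_tree.leaf_node_iter():
        leaf.taxon = tns.require_taxon(label=leaf.gene_label)

    # terminal-branch rate multipliers
    for leaf in gene_tree.leaf_node_iter():
        if leaf.edge.length is None:  # single-tip family
            continue
        taxon = leaf.taxon.label.split(COPY_SEP)[0]
        leaf.edge.length *= config.rate_multipliers.get(taxon, 1.0)

    # contaminant: one artificially long tip per family, flagged and
    # excluded from the ortholog truth partition
    contaminants: set[str] = set()
    leaves = list(gene_tree.leaf_node_iter())
    if (
        config.contaminant_tip_rate > 0
        and len(leaves) > 1
        and rng.random() < config.contaminant_tip_rate
    ):
        victim = leaves[int(rng.integers(len(leaves)))]
        factor = max(10.0, 0.6 / max(victim.edge.length, 1e-9))
        victim.edge.length *= factor
        contaminants.add(victim.taxon.label)

    alignment = _evolve_alignment(gene_tree, config.site_count, rng)

    sets = [
        frozenset(lbl for lbl in members if lbl not in contaminants)
        for members in truth.values()
    ]
    sets = [s for s in sets if s]
    return SimulatedFamily(
        family_id=f"fam{family_index:04d}",
        gene_tree=gene_tree,
        alignment=alignment,
        true_ortholog_sets=sets,
        contaminants=frozenset(contaminants),
    )


def _evolve_alignment(
    tree: dendropy.Tree, site_count: int, rng: np.random.Generator
) -> dict[str, str]:
    root_seq = rng.integers(0, 20, size=site_count)
    seqs: dict[str, str] = {}
    aa = np.array(list(AMINO_ACIDS))

    def descend(node: dendropy.Node, seq: np.ndarray) -> None:
        for child in node.child_nodes():
            child_seq = _evolve_along(seq, child.edge.length, rng)
            if child.is_leaf():
                seqs[child.taxon.label] = "".join(aa[child_seq])
            else:
                descend(child, child_seq)

    if tree.seed_node.is_leaf():
        seqs[tree.seed_node.taxon.label] = "".join(aa[root_seq])
    else:
        descend(tree.seed_node, root_seq)
    return seqs


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[dendropy.Tree, list[SimulatedFamily]]:
    """Species tree plus ``n_families`` independent gene families."""
    species_tree = simulate_species_tree(config)
    families = []
    for i in range(config.n_families):
        for attempt in range(20):
            try:
                fam = simulate_gene_family(species_tree, config, family_index=i + attempt * config.n_families)
                break
            except RuntimeError:
                continue
        else:
            raise RuntimeError(f"family {i}: all lineages lost in 20 attempts")
        fam.family_id = f"fam{i:04d}"
        families.append(fam)
    return species_tree, families


def simulate_genome(length: int, seed: int = 0) -> str:
    """Uniform random A/C/G/T genome."""
    if length < 1:
        raise ValueError("genome length must be positive")
    rng = np.random.default_rng(seed)
    return "".join(np.array(list(NUCLEOTIDES))[rng.integers(0, 4, size=length)])


def simulate_reads(genome: str, config: ReadSimConfig) -> list[str]:
    """Uniformly placed fixed-length reads at the configured depth.

    The read count is round(genome_length * depth / read_length), so total
    simulated bases equal reads * read_length exactly.  With
    ``error_rate == 0`` every read is an exact substring of the genome.
    """
    if not genome:
        raise ValueError("genome is empty")
    if len(genome) < config.read_length:
        raise ValueError("genome shorter than read length")
    rng = np.random.default_rng(config.seed)
    n_reads = int(round(len(genome) * config.depth / config.read_length))
    arr = np.frombuffer(genome.encode(), dtype="S1")
    starts = rng.integers(0, len(genome) - config.read_length + 1, size=n_reads)
    nts = np.frombuffer(NUCLEOTIDES.encode(), dtype="S1")
    reads = []
    for s in starts:
        read = arr[s : s + config.read_length].copy()
        if config.error_rate > 0:
            hit = rng.random(config.read_length) < config.error_rate
            if hit.any():
                shift = rng.integers(1, 4, size=int(hit.sum()))
                idx = np.searchsorted(nts, read[hit])
                read[hit] = nts[(idx + shift) % 4]
        reads.append(read.tobytes().decode())
    return reads
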