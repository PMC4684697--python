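"""Tree surgery: trimming, masking, cutting, MI pruning, NJ plumbing."""

import dendropy
import pytest

from aropipe import orthology as orth
from aropipe import simulate as sim
from aropipe.orthology import PruningParams, tree_from_newick


def brute_force_best_taxon_count(tree, sep="@"):
    """Independent MI oracle: enumerate rooted subtrees via bipartitions.

    Uses dendropy's bipartition encoding (a different route than the
    implementation's postorder accumulation) to list every edge side,
    plus the whole tip set, and returns the maximum distinct-taxon count
    over taxon-unique candidates.
    """
    t = tree.clone(depth=1)
    t.encode_bipartitions()
    all_tips = frozenset(l.taxon.label for l in t.leaf_node_iter())
    candidates = {all_tips}
    for bp in t.bipartition_encoding:
        side = frozenset(
            taxon.label for taxon in bp.leafset_taxa(t.taxon_namespace)
        )
        if side and side <= all_tips:
            candidates.add(side)
            candidates.add(all_tips - side)
    candidates.discard(frozenset())
    best = 0
    for side in candidates:
        taxa = [lbl.split(sep)[0] for lbl in side]
        if len(taxa) == len(set(taxa)):
            best = max(best, len(taxa))
    return best


def path_length_matrix(tree):
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
    by_label = {l.taxon.label: l.taxon for l in tree.leaf_node_iter()}
    return {
        (a, b): pdm.distance(by_label[a], by_label[b])
        for a in labels
        for b in labels
        if a < b
    }


def random_gene_trees(n, seed, **overrides):
    kwargs = dict(
        n_taxa=6,
        duplication_rate=0.8,
        loss_rate=0.4,
        site_count=20,
        seed=seed,
    )
    kwargs.update(overrides)
    cfg = sim.SimulationConfig(**kwargs)
    st = sim.simulate_species_tree(cfg)
    trees = []
    i = 0
    while len(trees) < n:
        try:
            fam = sim.simulate_gene_family(st, cfg, i)
        except RuntimeError:
            i += 1
            continue
        i += 1
        if sum(1 for _ in fam.gene_tree.leaf_node_iter()) >= 4:
            trees.append(fam.gene_tree)
    return trees


class TestTrimTips:
    def test_absolute_cutoff(self, loose_params):
        t = tree_from_newick("((A@1:0.6,B@1:0.1):0.05,(C@1:0.1,D@1:0.1):0.05);")
        out = orth.trim_tips(t, loose_params)
        assert orth.leaf_labels(out) == {"B@1", "C@1", "D@1"}

    def test_relative_cutoff(self, loose_params):
        # 0.25 > 0.2 and > 10 x 0.02 (longest sister-clade tip)
        t = tree_from_newick("((A@1:0.25,B@1:0.02):0.05,(C@1:0.1,D@1:0.1):0.05);")
        out = orth.trim_tips(t, loose_params)
        assert orth.leaf_labels(out) == {"B@1", "C@1", "D@1"}

    def test_short_tips_untouched(self, loose_params, quartet_tree):
        out = orth.trim_tips(quartet_tree, loose_params)
        assert orth.leaf_labels(out) == orth.leaf_labels(quartet_tree)

    def test_relative_cutoff_needs_both_conditions(self, loose_params):
        # 0.25 > 0.2 but sister tip is 0.1: 0.25 < 10 x 0.1 -> kept
        t = tree_from_newick("((A@1:0.25,B@1:0.1):0.05,(C@1:0.1,D@1:0.1):0.05);")
        out = orth.trim_tips(t, loose_params)
        assert "A@1" in orth.leaf_labels(out)

    def test_raises_below_three_tips(self, loose_params):
        t = tree_from_newick("((A@1:0.6,B@1:0.7):0.05,(C@1:0.1,D@1:0.1):0.05);")
        with pytest.raises(ValueError):
            orth.trim_tips(t, loose_params)

    def test_idempotent_on_random_trees(self, loose_params):
        for t in random_gene_trees(8, seed=51, contaminant_tip_rate=0.5):
            try:
                once = orth.trim_tips(t, loose_params)
            except ValueError:
                continue
            twice = orth.trim_tips(once, loose_params)
            assert orth.leaf_labels(once) == orth.leaf_labels(twice)

    def test_surviving_path_lengths_conserved(self, loose_params):
        for t in random_gene_trees(5, seed=52, contaminant_tip_rate=1.0):
            before = path_length_matrix(t)
            try:
                out = orth.trim_tips(t, loose_params)
            except ValueError:
                continue
            after = path_length_matrix(out)
            for pair, d in after.items():
                assert d == pytest.approx(before[pair], abs=1e-9)


class TestMaskMonophyleticTips:
    def test_sister_pair_keeps_shortest(self):
        t = tree_from_newick(
            "((human@g1:0.01,human@g2:0.03):0.05,(C@1:0.1,D@1:0.1):0.05);"
        )
        out = orth.mask_monophyletic_tips(t)
        assert orth.leaf_labels(out) == {"human@g1", "C@1", "D@1"}

    def test_all_distinct_is_identity(self, quartet_tree):
        out = orth.mask_monophyletic_tips(quartet_tree)
        assert orth.leaf_labels(out) == orth.leaf_labels(quartet_tree)

    def test_three_tip_clade_reduced_to_one(self):
        t = tree_from_newick(
            "(((x@1:0.02,x@2:0.01):0.01,x@3:0.05):0.1,(C@1:0.1,D@1:0.1):0.05);"
        )
        out = orth.mask_monophyletic_tips(t)
        labels = orth.leaf_labels(out)
        assert len([l for l in labels if l.startswith("x@")]) == 1
        assert labels >= {"C@1", "D@1"}

    def test_idempotent_on_random_trees(self):
        for t in random_gene_trees(10, seed=53):
            once = orth.mask_monophyletic_tips(t)
            twice = orth.mask_monophyletic_tips(once)
            assert orth.leaf_labels(once) == orth.leaf_labels(twice)

    def test_no_same_taxon_siblings_remain(self):
        for t in random_gene_trees(10, seed=54, duplication_rate=1.5):
            out = orth.mask_monophyletic_tips(t)
            for node in out.preorder_node_iter():
                kids = node.child_nodes()
                leaf_kids = [k for k in kids if k.is_leaf()]
                taxa = [orth.taxon_of(k.taxon.label) for k in leaf_kids]
                assert len(taxa) == len(set(taxa))


class TestCutLongInternalBranches:
    def test_no_long_edges_single_component(self, loose_params, quartet_tree):
        comps = orth.cut_long_internal_branches(quartet_tree, loose_params)
        assert len(comps) == 1
        assert orth.leaf_labels(comps[0]) == orth.leaf_labels(quartet_tree)

    def test_single_cut_splits_tip_sets(self, loose_params):
        t = tree_from_newick("((A@1:0.1,B@1:0.1):0.4,(C@1:0.1,D@1:0.1):0.05);")
        comps = orth.cut_long_internal_branches(t, loose_params)
        tip_sets = {frozenset(orth.leaf_labels(c)) for c in comps}
        assert tip_sets == {
            frozenset({"A@1", "B@1"}),
            frozenset({"C@1", "D@1"}),
        }

    def test_components_partition_tips(self, loose_params):
        for t in random_gene_trees(10, seed=55, tree_height=0.5):
            comps = orth.cut_long_internal_branches(t, loose_params)
            union = set()
            total = 0
            for c in comps:
                labels = orth.leaf_labels(c)
                total += len(labels)
                union |= labels
            assert union == orth.leaf_labels(t)
            assert total == len(union)

    def test_component_count_is_cuts_plus_one(self, loose_params):
        for t in random_gene_trees(10, seed=56, tree_height=0.6):
            # count long internal edges in the unrooted sense
            seed_node = t.seed_node
            kids = seed_node.child_nodes()
            long_edges = 0
            for node in t.preorder_node_iter():
                if node is seed_node or node.is_leaf():
                    continue
                length = node.edge.length or 0.0
                if node.parent_node is seed_node and len(kids) == 2:
                    sib = next(k for k in kids if k is not node)
                    if sib.is_leaf():
                        continue  # pendant edge in the unrooted sense
                    if node is kids[1]:
                        continue  # both basal children internal: count once
                    length += sib.edge.length or 0.0
                if length > loose_params.internal_branch_cutoff:
                    long_edges += 1
            comps = orth.cut_long_internal_branches(t, loose_params)
            assert len(comps) == long_edges + 1


class TestFilterByTaxa:
    def test_coverage_rule(self):
        full = tree_from_newick("((A@1:0.1,B@1:0.1):0.1,C@1:0.1);")
        partial = tree_from_newick("((A@1:0.1,B@1:0.1):0.1,B@2:0.1);")
        kept = orth.filter_by_taxa([full, partial], ["A", "B", "C"])
        assert kept == [full]


class TestMaxInclusion:
    def test_taxon_unique_tree_yields_whole_tree(self, loose_params):
        t = tree_from_newick(
            "((A@1:0.1,B@1:0.1):0.05,(C@1:0.1,D@1:0.1):0.05);"
        )
        groups = orth.prune_paralogy_MI(t, loose_params, family_id="f")
        assert len(groups) == 1
        assert groups[0].labels == orth.leaf_labels(t)

    def test_duplicated_taxon_excluded(self, loose_params):
        t = tree_from_newick(
            "(((A@1:0.1,B@1:0.1):0.1,(A@2:0.1,C@1:0.1):0.1):0.05,"
            "(D@1:0.1,E@1:0.1):0.05);"
        )
        best = orth.max_inclusion_candidate(t)
        assert best is not None
        taxa = [orth.taxon_of(l) for l in best]
        assert len(taxa) == len(set(taxa)) == brute_force_best_taxon_count(t)

    def test_agrees_with_bipartition_oracle(self):
        checked = 0
        for t in random_gene_trees(120, seed=57, duplication_rate=1.2):
            if sum(1 for _ in t.leaf_node_iter()) > 10:
                continue
            best = orth.max_inclusion_candidate(t)
            taxa = [orth.taxon_of(l) for l in best]
            assert len(set(taxa)) == len(taxa)
            assert len(taxa) == brute_force_best_taxon_count(t)
            checked += 1
        assert checked >= 50

    def test_groups_taxon_unique_and_disjoint(self):
        params = PruningParams(min_taxa=3)
        for t in random_gene_trees(15, seed=58, duplication_rate=1.2):
            groups = orth.prune_paralogy_MI(t, params)
            seen = set()
            for g in groups:
                taxa = list(g.members)
                assert len(taxa) == len(set(taxa))
                assert len(taxa) >= params.min_taxa
                assert not (g.labels & seen)
                seen |= g.labels

    def test_contaminants_never_emitted(self):
        cfg = sim.SimulationConfig(
            n_taxa=6,
            duplication_rate=0.5,
            loss_rate=0.3,
            site_count=20,
            contaminant_tip_rate=1.0,
            seed=59,
        )
        st = sim.simulate_species_tree(cfg)
        params = PruningParams(min_taxa=3)
        for i in range(20):
            fam = sim.simulate_gene_family(st, cfg, i)
            groups = orth.decompose_family(
                fam.gene_tree, params, required_taxa=[], family_id=fam.family_id
            )
            for g in groups:
                assert not (g.labels & fam.contaminants)


class TestNeighborJoining:
    def test_identical_sequences_zero_lengths(self):
        aln = {x: "ACDEFGHIKL" for x in "ABC"}
        t = orth.nj_tree(aln)
        for edge in t.preorder_edge_iter():
            if edge.head_node.parent_node is not None:
                assert (edge.length or 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_three_sequences_closed_form(self):
        # pairwise p-distances: AB=0.1, AC=0.2, BC=0.3 over 10 sites
        # one site where only B differs, two sites where all three differ:
        # p-distances AB=0.3, AC=0.2, BC=0.3 (satisfies the strict triangle
        # inequality after Poisson correction, so all NJ branches are >= 0)
        aln = {
            "A": "AAAAAAAAAA",
            "B": "CWWAAAAAAA",
            "C": "ACCAAAAAAA",
        }
        import math

        d = lambda p: -math.log(1 - p)
        dab, dac, dbc = d(0.3), d(0.2), d(0.3)
        t = orth.nj_tree(aln)
        pdm = path_length_matrix(t)
        assert pdm[("A", "B")] == pytest.approx(dab, abs=1e-9)
        assert pdm[("A", "C")] == pytest.approx(dac, abs=1e-9)
        assert pdm[("B", "C")] == pytest.approx(dbc, abs=1e-9)

    def test_additive_matrix_exact_recovery(self):
        # distances on the quartet AB|CD with terminal branches 1,2,3,4
        # and internal branch 1: additive by construction
        import numpy as np

        labels = ["A", "B", "C", "D"]
        dm = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        tree = orth.nj_from_distances(labels, dm)
        pdm = path_length_matrix(tree)
        for (i, a) in enumerate(labels):
            for (j, b) in enumerate(labels):
                if a < b:
                    assert pdm[(a, b)] == pytest.approx(dm[i, j], abs=1e-9)

    def test_saturated_distances_rejected(self):
        aln = {
            "A": "ACDEFGHIKL" * 2,
            "B": "LKIHGFEDCA" * 2,
            "C": "ACDEFGHIKL" * 2,
        }
        with pytest.raises(ValueError, match="saturat"):
            orth.nj_tree(aln)

    def test_deterministic_for_fixed_order(self):
        aln = {
            "A": "ACDEFGHIKL",
            "B": "ACDEFGHIKV",
            "C": "ACDEFGWIKL",
            "D": "MCDEFGHIKL",
        }
        assert orth.nj_tree(aln).as_string(schema="newick") == orth.nj_tree(
            aln
        ).as_string(schema="newick")
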