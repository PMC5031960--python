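"""Unit tests for reconciliation, polytomy resolution and tree selection."""

import numpy as np
import pytest

from oracles import all_rooted_shapes, brute_min_duploss_cost

from evorec.reconcile import (
    consensus_extended_majority,
    contract_low_support,
    enumerate_rootings,
    final_tree_and_support,
    generate_candidates,
    graft_losses,
    lca_reconcile,
    resolve_polytomies_min_cost,
    select_best,
)
from evorec.simulate import (
    evolve_sequences,
    random_binary_tree,
    simulate_gene_family,
)
from evorec.treebuild import bootstrap_supports
from evorec.trees import (
    build_tree,
    leaf_label,
    parse_tree,
    rf_distance,
    species_of,
    to_nhx,
)

SP_AB_C = parse_tree("((A:1,B:1):1,C:1);", rooted=True)


def random_gene_tree_over(species_labels, n_genes, rng):
    labels = [
        f"{species_labels[int(rng.integers(len(species_labels)))]}.g{i}"
        for i in range(n_genes)
    ]
    return random_binary_tree(labels, rng)


class TestLcaReconcile:
    def test_congruent_tree_no_events(self, six_taxon_tree):
        fam = simulate_gene_family(six_taxon_tree, 0.0, 0.0, seed=1)
        rec = lca_reconcile(fam.gene_tree_true, six_taxon_tree)
        assert rec.dup_count == 0 and rec.loss_count == 0

    def test_root_duplication(self):
        sp = parse_tree("(A:1,B:1);", rooted=True)
        gt = build_tree((("A.a1", "B.b1"), ("A.a2", "B.b2")))
        rec = lca_reconcile(gt, sp)
        assert rec.dup_count == 1 and rec.loss_count == 0

    def test_worked_example_cost_four(self):
        gt = build_tree((("A.a1", "C.c1"), "B.b1"))
        rec = lca_reconcile(gt, SP_AB_C)
        assert (rec.dup_count, rec.loss_count, rec.cost) == (1, 3, 4)
        assert rec.losses == [("A", 1), ("B", 1), ("C", 1)]

    def test_unknown_species_named_in_error(self):
        gt = build_tree((("A.a1", "Z.z1"), "B.b1"))
        with pytest.raises(ValueError, match="Z"):
            lca_reconcile(gt, SP_AB_C)

    def test_cost_is_minimum_over_valid_mappings(self, rng):
        for _ in range(25):
            ns = int(rng.integers(2, 7))
            sp = random_binary_tree([chr(65 + i) for i in range(ns)], rng)
            gt = random_gene_tree_over(
                [chr(65 + i) for i in range(ns)], int(rng.integers(2, 9)), rng
            )
            assert lca_reconcile(gt, sp).cost == brute_min_duploss_cost(
                gt, sp, species_of
            )

    def test_true_events_recovered_in_duplication_only_regime(
        self, six_taxon_tree
    ):
        for seed in range(20):
            fam = simulate_gene_family(six_taxon_tree, 0.3, 0.0, seed=seed)
            rec = lca_reconcile(fam.gene_tree_true, six_taxon_tree)
            assert rec.dup_count == fam.true_dup_count
            assert rec.loss_count == 0


class TestGraftLosses:
    def test_no_losses_tree_unchanged(self, six_taxon_tree):
        fam = simulate_gene_family(six_taxon_tree, 0.0, 0.0, seed=1)
        grafted, rec = graft_losses(fam.gene_tree_true, six_taxon_tree)
        assert rec.loss_count == 0
        assert rf_distance(grafted, fam.gene_tree_true) == 0

    def test_grafts_one_leaf_per_loss(self):
        gt = build_tree((("A.a1", "C.c1"), "B.b1"))
        grafted, rec = graft_losses(gt, SP_AB_C)
        loss_leaves = [
            leaf_label(l)
            for l in grafted.leaf_node_iter()
            if getattr(l, "is_loss", False)
        ]
        assert len(loss_leaves) == rec.loss_count == 3
        assert sorted(loss_leaves) == ["LOST_A", "LOST_B", "LOST_C"]

    def test_loss_labels_come_from_species_tree(self, six_taxon_tree):
        species_names = {
            l.taxon.label for l in six_taxon_tree.leaf_node_iter()
        }
        internal = {
            "+".join(sorted(x.taxon.label for x in n.leaf_iter()))
            for n in six_taxon_tree.preorder_node_iter()
            if not n.is_leaf()
        }
        for seed in range(6):
            fam = simulate_gene_family(six_taxon_tree, 0.4, 0.3, seed=seed)
            if fam.empty or sum(1 for _ in fam.gene_tree_true.leaf_node_iter()) < 2:
                continue
            grafted, _ = graft_losses(fam.gene_tree_true, six_taxon_tree)
            for l in grafted.leaf_node_iter():
                if getattr(l, "is_loss", False):
                    assert leaf_label(l)[5:] in species_names | internal


def _supported_tree():
    """5-leaf rooted tree with supports {95, 40} on its internal branches."""
    t = parse_tree("((A.a:1,B.b:1)95:1,(C.c:1,D.d:1)40:1,E.e:1);", rooted=False)
    for node in t.preorder_node_iter():
        if not node.is_leaf() and node.label is not None:
            node.support = float(node.label)
    return t


class TestContraction:
    def test_threshold_zero_identity(self, six_taxon_tree):
        fam = simulate_gene_family(six_taxon_tree, 0.2, 0.0, seed=3)
        aln = evolve_sequences(fam.gene_tree_true, 200, seed=3)
        tree = bootstrap_supports(aln, n_reps=10, seed=0)
        assert rf_distance(contract_low_support(tree, 0), tree) == 0

    def test_threshold_above_hundred_gives_star(self, six_taxon_tree):
        fam = simulate_gene_family(six_taxon_tree, 0.2, 0.0, seed=3)
        aln = evolve_sequences(fam.gene_tree_true, 200, seed=3)
        tree = bootstrap_supports(aln, n_reps=10, seed=0)
        star = contract_low_support(tree, 101)
        internal = [
            n
            for n in star.preorder_node_iter()
            if not n.is_leaf() and n.parent_node is not None
        ]
        assert internal == []

    def test_partial_contraction_creates_polytomy(self):
        t = _supported_tree()
        contracted = contract_low_support(t, 50)
        # the 40-branch collapses: the hub now joins C, D, E and the 95-clade
        hub = contracted.seed_node
        assert len(hub.child_nodes()) == 4
        n_internal_edges = sum(
            1
            for n in contracted.preorder_node_iter()
            if not n.is_leaf() and n.parent_node is not None
        )
        assert n_internal_edges == 1


class TestRootings:
    def test_binary_four_leaf_tree_has_five_rootings(self):
        t = parse_tree("((a:1,b:1):1,c:1,d:1);", rooted=False)
        assert len(enumerate_rootings(t)) == 5

    def test_star_tree_one_rooting_per_leaf(self):
        t = parse_tree("(a:1,b:1,c:1,d:1,e:1);", rooted=False)
        rootings = enumerate_rootings(t)
        assert len(rootings) == 5

    def test_leaf_set_preserved_and_rooted(self):
        t = parse_tree("((a:1,b:1):1,(c:1,d:1):1,e:1);", rooted=False)
        for rooted in enumerate_rootings(t):
            assert sorted(leaf_label(l) for l in rooted.leaf_node_iter()) == [
                "a",
                "b",
                "c",
                "d",
                "e",
            ]
            assert len(rooted.seed_node.child_nodes()) == 2


class TestPolytomyResolution:
    def test_binary_tree_returned_unchanged(self):
        gt = build_tree((("A.a1", "B.b1"), "C.c1"))
        sols = resolve_polytomies_min_cost(gt, SP_AB_C)
        assert len(sols) == 1
        assert rf_distance(sols[0], gt) == 0

    def test_star_resolution_zero_cost(self):
        star = build_tree(("A.a1", "B.b1", "C.c1"))
        sols = resolve_polytomies_min_cost(star, SP_AB_C, max_solutions=8)
        costs = {lca_reconcile(s, SP_AB_C).cost for s in sols}
        assert costs == {0}
        # the zero-cost refinement is ((a1,b1),c1)
        expected = build_tree((("A.a1", "B.b1"), "C.c1"))
        assert any(rf_distance(s, expected) == 0 for s in sols)

    def test_refinement_contracts_back_to_input(self, rng):
        sp = random_binary_tree(list("ABCD"), rng)
        labels = [f"{c}.g{i}" for i, c in enumerate("AABBCD")]
        star = build_tree(tuple(labels))
        for sol in resolve_polytomies_min_cost(star, sp, max_solutions=4):
            for node in sol.preorder_node_iter():
                assert len(node.child_nodes()) in (0, 2)
            assert sorted(leaf_label(l) for l in sol.leaf_node_iter()) == sorted(
                labels
            )

    def test_dp_matches_exhaustive_minimum(self, rng):
        for _ in range(15):
            ns = int(rng.integers(2, 5))
            species = [chr(65 + i) for i in range(ns)]
            sp = random_binary_tree(species, rng)
            degree = int(rng.integers(3, 7))
            labels = [
                f"{species[int(rng.integers(ns))]}.g{i}" for i in range(degree)
            ]
            star = build_tree(tuple(labels))
            sols = resolve_polytomies_min_cost(star, sp, max_solutions=2)
            dp_cost = lca_reconcile(sols[0], sp).cost
            oracle = min(
                lca_reconcile(build_tree(shape), sp).cost
                for shape in all_rooted_shapes(labels)
            )
            assert dp_cost == oracle

    def test_all_returned_solutions_attain_minimum(self, rng):
        sp = random_binary_tree(list("ABC"), rng)
        labels = ["A.g0", "A.g1", "B.g2", "C.g3", "B.g4"]
        star = build_tree(tuple(labels))
        sols = resolve_polytomies_min_cost(star, sp, max_solutions=16)
        costs = [lca_reconcile(s, sp).cost for s in sols]
        assert len(set(costs)) == 1

    def test_nested_polytomies(self, rng):
        sp = random_binary_tree(list("ABCD"), rng)
        nested = build_tree((("A.g0", "B.g1", "C.g2"), "D.g3", "A.g4"))
        sols = resolve_polytomies_min_cost(nested, sp, max_solutions=4)
        assert sols
        for sol in sols:
            for node in sol.preorder_node_iter():
                assert len(node.child_nodes()) in (0, 2)


@pytest.fixture(scope="module")
def family_setup():
    from evorec.trees import species_tree

    st = species_tree()
    fam = simulate_gene_family(st, 0.25, 0.0, seed=11)
    aln = evolve_sequences(fam.gene_tree_true, 400, seed=11)
    boot = bootstrap_supports(aln, n_reps=100, seed=2)
    return st, fam, aln, boot


class TestCandidates:
    def test_full_support_candidates_differ_only_by_rooting(self, family_setup):
        st, fam, aln, _ = family_setup
        tree = bootstrap_supports(
            {k: v for k, v in aln.items()}, n_reps=5, seed=0
        )
        for node in tree.preorder_node_iter():
            if getattr(node, "support", None) is not None:
                node.support = 100
        cands = generate_candidates(tree, st, aln, thresholds=(50,))
        n_edges = sum(
            1 for n in tree.preorder_node_iter() if n.parent_node is not None
        )
        assert 1 <= len(cands) <= n_edges
        for c in cands:
            assert rf_distance(c.tree, cands[0].tree) == 0  # same unrooted shape

    def test_star_threshold_refines_star(self, family_setup):
        st, fam, aln, boot = family_setup
        cands = generate_candidates(boot, st, aln, thresholds=(101,))
        assert cands
        for c in cands:
            for node in c.tree.preorder_node_iter():
                assert len(node.child_nodes()) in (0, 2)

    def test_candidate_cost_never_exceeds_unrefined_input(self, family_setup):
        st, fam, aln, boot = family_setup
        cands = generate_candidates(boot, st, aln)
        input_costs = []
        for rooted in enumerate_rootings(contract_low_support(boot, 0)):
            input_costs.append(lca_reconcile(rooted, st).cost)
        assert min(c.cost for c in cands) <= min(input_costs)

    def test_multiplicity_counts_sweep_size(self, family_setup):
        st, fam, aln, boot = family_setup
        cands = generate_candidates(boot, st, aln, thresholds=(20, 90))
        assert sum(c.multiplicity for c in cands) >= len(cands)


class TestSelection:
    def test_single_candidate_is_kept(self, family_setup):
        st, fam, aln, boot = family_setup
        cands = generate_candidates(boot, st, aln, thresholds=(50,))
        best = select_best(cands[:1])
        assert best == cands[:1]

    def test_dominated_candidate_never_retained(self, family_setup):
        st, fam, aln, boot = family_setup
        cands = generate_candidates(boot, st, aln)
        best = select_best(cands, seed=1)
        min_cost = min(c.cost for c in best)
        for b in best:
            assert b.cost == min_cost

    def test_identical_topologies_all_retained(self, family_setup):
        st, fam, aln, boot = family_setup
        cands = generate_candidates(boot, st, aln, thresholds=(50,))
        doubled = cands + cands
        kept = select_best(doubled, seed=2)
        keys = {id(c) for c in kept}
        for c in kept:
            twin = doubled[(doubled.index(c) + len(cands)) % len(doubled)]
            assert twin.site_loglik.total == c.site_loglik.total


class TestConsensus:
    def test_identical_inputs_return_same_tree(self, rng):
        t = random_binary_tree([f"x{i}" for i in range(6)], rng)
        cons = consensus_extended_majority([t, t, t])
        assert rf_distance(cons, t) == 0

    def test_majority_resolution_wins(self):
        t1 = build_tree((("a", "b"), ("c", "d")))
        t2 = build_tree((("a", "b"), ("c", "d")))
        t3 = build_tree((("a", "c"), ("b", "d")))
        cons = consensus_extended_majority([t1, t2, t3])
        clades = {
            frozenset(leaf_label(l) for l in n.leaf_iter())
            for n in cons.preorder_node_iter()
            if not n.is_leaf()
        }
        assert frozenset({"a", "b"}) in clades
        assert frozenset({"a", "c"}) not in clades

    def test_majority_clades_always_included(self, rng):
        trees = [
            random_binary_tree([f"x{i}" for i in range(6)], rng) for _ in range(5)
        ]
        counts = {}
        for t in trees:
            for n in t.preorder_node_iter():
                if n.is_leaf() or n.parent_node is None:
                    continue
                counts[frozenset(leaf_label(l) for l in n.leaf_iter())] = (
                    counts.get(frozenset(leaf_label(l) for l in n.leaf_iter()), 0)
                    + 1
                )
        cons = consensus_extended_majority(trees)
        clades = {
            frozenset(leaf_label(l) for l in n.leaf_iter())
            for n in cons.preorder_node_iter()
            if not n.is_leaf()
        }
        for clade, c in counts.items():
            if c > len(trees) / 2 and len(clade) < 6:
                assert clade in clades

    def test_leaf_set_mismatch_rejected(self, rng):
        t1 = random_binary_tree(list("abcd"), rng)
        t2 = random_binary_tree(list("abce"), rng)
        with pytest.raises(ValueError, match="leaf set"):
            consensus_extended_majority([t1, t2])


class TestFinalSupports:
    def test_identical_replicates_full_support(self, family_setup):
        st, fam, aln, boot = family_setup
        cands = generate_candidates(boot, st, aln, thresholds=(50,))
        one = [c for c in cands if c.cost == min(x.cost for x in cands)][:1]
        tree, rec = final_tree_and_support(one, one)
        for node in tree.preorder_node_iter():
            if not node.is_leaf():
                assert node.event_support == 1.0

    def test_duplication_nodes_strongly_supported(self, family_setup):
        st, fam, aln, boot = family_setup
        cands = generate_candidates(boot, st, aln)
        best = select_best(cands, seed=5)
        tree, rec = final_tree_and_support(best, cands, alignment=aln, seed=3)
        assert rec.dup_count == fam.true_dup_count
        for node, event in rec.events.items():
            if event == "duplication":
                assert node.event_support >= 0.5


class TestFamilyReport:
    def test_empty_input(self):
        from evorec.reconcile import family_report

        df = family_report({}, ["rha", "cof"])
        assert list(df.columns) == ["family", "rha", "cof", "duplications", "losses"]
        assert df.empty

    def test_counts_match_ground_truth(self, six_taxon_tree):
        from evorec.reconcile import family_report

        fam = simulate_gene_family(six_taxon_tree, 0.0, 0.0, seed=1)
        rec = lca_reconcile(fam.gene_tree_true, six_taxon_tree)
        species = sorted(l.taxon.label for l in six_taxon_tree.leaf_node_iter())
        df = family_report({"f1": (fam.gene_tree_true, rec)}, species)
        assert (df.loc[0, species] == 1).all()
        assert df.loc[0, "duplications"] == 0 and df.loc[0, "losses"] == 0
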