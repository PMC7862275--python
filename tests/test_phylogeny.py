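"""Mutation ordering, conflict detection, min-flip repair, clone trees."""

import numpy as np
import pytest

from clonalarch.clone_calling import call_clones
from clonalarch.genotype_io import GenotypeState
from clonalarch.phylogeny import (
    RepairError,
    build_clone_tree,
    export_newick,
    find_conflicts,
    order_mutations,
    parse_newick,
    repair_min_flips,
)
from clonalarch.synthetic import default_config, simulate_cells

from _oracles import exhaustive_min_flips, observed_parent_maps
from conftest import make_matrix, presence_to_matrix, random_conflict_free_presence, truth_tree


class TestOrderMutations:
    def test_ranked_by_pooled_frequency(self):
        rows = []
        for i in range(10):
            x = "HET" if i < 9 else "WT"
            y = "HET" if i < 5 else "WT"
            z = "HOM" if i < 1 else "WT"
            rows.append((f"c{i}", "T1", [z, x, y]))
        m = make_matrix(rows, ["Z", "X", "Y"])
        assert order_mutations(m).ranked_ids == ["X", "Y", "Z"]

    def test_tie_broken_by_catalog_order_and_stable(self):
        m = make_matrix(
            [("c1", "T1", ["HET", "HET"]), ("c2", "T1", ["WT", "WT"])], ["B", "A"]
        )
        assert order_mutations(m).ranked_ids == ["B", "A"]
        assert order_mutations(m).ranked_ids == ["B", "A"]

    def test_tie_broken_by_first_timepoint_frequency(self):
        m = make_matrix(
            [
                ("c1", "T1", ["HET", "WT"]),
                ("c2", "T2", ["WT", "HET"]),
            ],
            ["A", "B"],
        )
        # pooled 0.5 each; at T1, A leads
        assert order_mutations(m).ranked_ids == ["A", "B"]

    def test_invariant_under_row_permutation(self, rng):
        m = simulate_cells(default_config(), seed=2).observed
        ranked = order_mutations(m).ranked_ids
        for _ in range(3):
            perm = rng.permutation(m.n_cells)
            shuffled = m.subset(np.zeros(m.n_cells, bool))  # placeholder
            shuffled = m.copy()
            shuffled.cells = [m.cells[i] for i in perm]
            shuffled.timepoints = [m.timepoints[i] for i in perm]
            shuffled.calls = m.calls[perm]
            assert order_mutations(shuffled).ranked_ids == ranked

    def test_study_design_order_recovered(self):
        cfg = default_config(ado_rate=0, miscall_rate=0, missing_rate=0)
        m = simulate_cells(cfg).observed
        ranked = order_mutations(m).ranked_ids
        assert ranked[0] == "TET2a" and ranked[-1] == "FLT3"
        assert ranked == ["TET2a", "JAK2", "TET2b", "ASXL1", "SRSF2", "TP53", "FLT3"]


class TestFindConflicts:
    def test_nested_signatures_are_conflict_free(self):
        m = make_matrix(
            [("c1", "T1", ["HET", "WT"]), ("c2", "T1", ["HET", "HET"])], ["A", "B"]
        )
        assert find_conflicts(m).is_conflict_free

    def test_three_pattern_pair_reported_with_witness_counts(self):
        m = make_matrix(
            [("c1", "T1", ["HET", "WT"]), ("c2", "T1", ["WT", "HET"]),
             ("c3", "T1", ["HET", "HET"])],
            ["A", "B"],
        )
        rep = find_conflicts(m)
        assert len(rep.pairs) == 1
        pair = rep.pairs[0]
        assert (pair.mutation_i, pair.mutation_j) == ("A", "B")
        assert (pair.n11, pair.n10, pair.n01) == (1, 1, 1)

    def test_noiseless_simulator_output_always_conflict_free(self):
        for seed in range(5):
            cfg = default_config(ado_rate=0, miscall_rate=0, missing_rate=0)
            m = simulate_cells(cfg, seed=seed).observed
            assert find_conflicts(m).is_conflict_free

    def test_missing_calls_excluded_from_witnesses(self):
        m = make_matrix(
            [("c1", "T1", ["HET", "NA"]), ("c2", "T1", ["WT", "HET"]),
             ("c3", "T1", ["HET", "HET"])],
            ["A", "B"],
        )
        # the only would-be (1,0) witness has B missing
        assert find_conflicts(m).is_conflict_free


class TestRepairMinFlips:
    def test_conflict_free_matrix_untouched(self):
        m = make_matrix(
            [("c1", "T1", ["HET", "WT"]), ("c2", "T1", ["HET", "HOM"])], ["A", "B"]
        )
        repaired, flips = repair_min_flips(m, 3)
        assert flips == [] and (repaired.calls == m.calls).all()

    def test_singleton_conflict_resolved_with_one_flip(self):
        rows = [(f"a{i}", "T1", ["HET", "WT"]) for i in range(5)]
        rows += [("b0", "T1", ["WT", "HET"])]
        rows += [(f"ab{i}", "T1", ["HET", "HET"]) for i in range(5)]
        m = make_matrix(rows, ["A", "B"])
        repaired, flips = repair_min_flips(m, 2)
        assert len(flips) == 1
        assert flips[0][0] == "b0"  # the singleton cell is the one repaired
        assert find_conflicts(repaired).is_conflict_free

    def test_planted_miscall_repaired_back_to_truth(self):
        cfg = default_config(n_cells_per_timepoint=8, ado_rate=0, miscall_rate=0,
                             missing_rate=0)
        ds = simulate_cells(cfg, seed=1)
        m = ds.observed.subset(np.arange(ds.observed.n_cells) < 24)
        truth_presence = m.presence().copy()
        # plant one miscall: make one TET2b-negative cell TET2b-positive
        j = m.mutation_ids.index("TP53")
        i = int(np.flatnonzero(m.presence()[:, j] == 0)[0])
        m.calls[i, j] = GenotypeState.HET
        assert not find_conflicts(m).is_conflict_free
        repaired, flips = repair_min_flips(m, 3, exact_limit=(7, 30))
        assert len(flips) == 1
        assert (repaired.presence() == truth_presence).all()

    def test_budget_zero_with_conflict_raises(self):
        m = make_matrix(
            [("c1", "T1", ["HET", "WT"]), ("c2", "T1", ["WT", "HET"]),
             ("c3", "T1", ["HET", "HET"])],
            ["A", "B"],
        )
        with pytest.raises(RepairError):
            repair_min_flips(m, 0)

    def test_exact_matches_exhaustive_oracle_on_small_instances(self, rng):
        for _ in range(25):
            pres = random_conflict_free_presence(rng, 4, 10)
            k = rng.integers(1, 3)
            for _ in range(k):
                c, j = rng.integers(0, pres.shape[0]), rng.integers(0, pres.shape[1])
                pres[c, j] ^= 1
            oracle = exhaustive_min_flips(pres, 3)
            m = presence_to_matrix(pres)
            if oracle is None:
                with pytest.raises(RepairError):
                    repair_min_flips(m, 3)
            else:
                _, flips = repair_min_flips(m, 3)
                assert len(flips) == oracle

    def test_greedy_used_for_large_matrices_terminates_conflict_free(self):
        m = simulate_cells(default_config(), seed=3).observed
        assert m.n_cells > 30
        repaired, flips = repair_min_flips(m)
        assert find_conflicts(repaired).is_conflict_free
        assert len(flips) > 0


class TestBuildCloneTree:
    def _tree_from_presence(self, pres):
        m = presence_to_matrix(pres)
        return build_clone_tree(call_clones(m, "presence"), order_mutations(m))

    def test_chain_of_nested_clones(self):
        pres = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [1, 1, 1]])
        t = self._tree_from_presence(pres)
        names = []
        node = t.root
        while True:
            names.append(node.name)
            if not node.children:
                break
            assert len(node.children) == 1
            node = node.children[0]
        assert len(names) == 4
        assert t.root.signature == {"M0": "WT", "M1": "WT", "M2": "WT"}

    def test_branching_with_sibling_order_by_rank(self):
        # {A}x4, {A,B}x2, {A,C}x1 -> root A with children B (more frequent) then C
        pres = np.array([[1, 0, 0]] * 4 + [[1, 1, 0]] * 2 + [[1, 0, 1]])
        t = self._tree_from_presence(pres)
        root = t.root
        assert root.signature["M0"] == "MUT" and len(root.children) == 2
        assert [c.event for c in root.children] == ["+M1", "+M2"]

    def test_conflicting_signatures_rejected(self):
        pres = np.array([[1, 0], [0, 1], [1, 1]])
        m = presence_to_matrix(pres)
        with pytest.raises(ValueError, match="conflict"):
            build_clone_tree(call_clones(m, "presence"), order_mutations(m))

    def test_unobserved_intermediates_materialized(self):
        pres = np.array([[1, 0, 0], [1, 1, 1]])
        t = self._tree_from_presence(pres)
        chain = [t.root]
        while chain[-1].children:
            chain.append(chain[-1].children[0])
        assert [n.observed for n in chain] == [True, False, True]

    def test_noiseless_default_simulation_recovers_truth_tree(self):
        cfg = default_config(ado_rate=0, miscall_rate=0, missing_rate=0)
        m = simulate_cells(cfg).observed
        part = call_clones(m, "zygosity")
        t = build_clone_tree(part, order_mutations(m))
        assert t.topology() == truth_tree(cfg).topology()

    def test_zygosity_escalation_events_along_paths(self):
        cfg = default_config(ado_rate=0, miscall_rate=0, missing_rate=0)
        m = simulate_cells(cfg).observed
        t = build_clone_tree(call_clones(m, "zygosity"), order_mutations(m))

        def paths(node, acc):
            acc = acc + ([node.event] if node.event else [])
            if not node.children:
                yield acc
            for ch in node.children:
                yield from paths(ch, acc)

        for path in paths(t.root, []):
            per_mut: dict[str, list[str]] = {}
            for ev in path:
                mut = ev[1:] if ev.startswith("+") else ev.split(":")[0]
                per_mut.setdefault(mut, []).append(ev)
            for mut, evs in per_mut.items():
                assert len(evs) <= 2
                if len(evs) == 2:  # gain strictly before escalation
                    assert evs[0] == f"+{mut}" and evs[1] == f"{mut}:HET>HOM"

    def test_matches_brute_force_containment_oracle(self, rng):
        for _ in range(30):
            n_mut = int(rng.integers(2, 6))
            pres = random_conflict_free_presence(rng, n_mut, int(rng.integers(3, 20)))
            m = presence_to_matrix(pres)
            part = call_clones(m, "presence")
            t = build_clone_tree(part, order_mutations(m))
            # translate both to signature-mask parent maps
            label_mask = {
                c.label: sum(1 << j for j, s in enumerate(c.signature) if s > 0)
                for c in part.clones
            }
            got = frozenset(
                (label_mask[child], None if parent is None else label_mask[parent])
                for child, parent in t.observed_parent_map().items()
            )
            expected = observed_parent_maps(set(label_mask.values()), n_mut)
            assert len(expected) == 1
            assert got == next(iter(expected))


class TestNewick:
    def test_chain_rendering(self):
        pres = np.array([[0, 0], [1, 0], [1, 1]])
        m = presence_to_matrix(pres)
        t = build_clone_tree(call_clones(m, "presence"), order_mutations(m))
        nwk = export_newick(t)
        assert nwk.startswith("((") and nwk.endswith(";")
        assert "[&event=+M0]" in nwk and "[&event=+M1]" in nwk

    def test_single_node_tree(self):
        pres = np.array([[0, 0]])
        m = presence_to_matrix(pres)
        t = build_clone_tree(call_clones(m, "presence"), order_mutations(m))
        assert export_newick(t) == "A;"

    def test_round_trip_random_trees(self, rng):
        for seed in range(10):
            cfg = default_config(ado_rate=0, miscall_rate=0, missing_rate=0)
            m = simulate_cells(cfg, seed=seed).observed
            sub = m.subset(rng.random(m.n_cells) < 0.5)
            t = build_clone_tree(call_clones(sub, "zygosity"), order_mutations(sub))
            back = parse_newick(export_newick(t))

            def shape(n):
                return (n.name, n.event, tuple(shape(c) for c in n.children))

            assert shape(back.root) == shape(t.root)

    def test_structure_agrees_with_dendropy(self):
        dendropy = pytest.importorskip("dendropy")
        cfg = default_config(ado_rate=0, miscall_rate=0, missing_rate=0)
        m = simulate_cells(cfg).observed
        t = build_clone_tree(call_clones(m, "zygosity"), order_mutations(m))
        nwk = export_newick(t)
        dt = dendropy.Tree.get(data=nwk, schema="newick", suppress_internal_node_taxa=False)
        ours = sorted(n.name for n in t.nodes())
        theirs = sorted(
            (nd.taxon.label if nd.taxon else nd.label) for nd in dt.preorder_node_iter()
        )
        assert ours == theirs
        assert len(dt.leaf_nodes()) == sum(1 for n in t.nodes() if not n.children)
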