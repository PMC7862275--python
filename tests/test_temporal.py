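"""Temporal clone tracking, trajectories, zygosity evolution."""

import numpy as np
import pytest

from clonalarch.clone_calling import call_clones
from clonalarch.phylogeny import build_clone_tree, order_mutations
from clonalarch.synthetic import default_config, simulate_cells
from clonalarch.temporal import (
    frequency_trajectories,
    rescale_children,
    timescape_records,
    track_clones,
    zygosity_evolution,
)

from conftest import make_matrix


def noiseless_tracked(seed=0):
    cfg = default_config(ado_rate=0, miscall_rate=0, missing_rate=0, seed=seed)
    ds = simulate_cells(cfg)
    part = call_clones(ds.observed, "zygosity")
    tree = build_clone_tree(part, order_mutations(ds.observed))
    return cfg, ds, part, tree, track_clones(part, tree)


def test_rescale_children_proportional():
    assert rescale_children(0.5, [0.4, 0.2]) == pytest.approx([1 / 3, 1 / 6])
    # no rescale needed when children already fit
    assert rescale_children(0.7, [0.4, 0.2]) == [0.4, 0.2]


def test_clone_absent_then_present():
    m = make_matrix(
        [
            ("c1", "T1", ["HET", "WT"]),
            ("c2", "T2", ["HET", "WT"]),
            ("c3", "T2", ["HET", "HET"]),
        ],
        ["A", "B"],
    )
    part = call_clones(m, "zygosity")
    tree = build_clone_tree(part, order_mutations(m))
    table = track_clones(part, tree)
    child = part.clone_of_signature((1, 1)).label
    assert table.own(child, "T1") == 0.0
    assert table.own(child, "T2") == pytest.approx(0.5)


def test_noiseless_tracking_matches_truth_counts():
    cfg, ds, part, tree, table = noiseless_tracked()
    truth_counts = ds.truth.groupby(["timepoint", "clone_id"]).size()
    # map truth clone ids to partition labels via signatures
    sig_of = {c.id: tuple(int(x) for x in c.signature_codes(cfg.mutation_ids)) for c in cfg.clones}
    for tp in cfg.timepoint_order:
        n = cfg.n_cells[tp]
        for clone in cfg.clones:
            label = part.clone_of_signature(sig_of[clone.id]).label
            want = truth_counts.get((tp, clone.id), 0) / n
            assert table.own(label, tp) == pytest.approx(want, abs=1e-12)
            # nested prevalence equals own + descendants, per the config tree
            nested_truth = sum(
                truth_counts.get((tp, c2.id), 0)
                for c2 in cfg.clones
                if _is_descendant_or_self(cfg, c2.id, clone.id)
            ) / n
            assert table.nested(label, tp) == pytest.approx(nested_truth, abs=1e-9)


def _is_descendant_or_self(cfg, cid, anc):
    while cid is not None:
        if cid == anc:
            return True
        cid = cfg.clone_by_id(cid).parent
    return False


def test_nested_fractions_monotone_along_paths():
    for seed in range(3):
        cfg = default_config(seed=seed)
        ds = simulate_cells(cfg)
        part = call_clones(ds.observed, "zygosity", min_cells=5).major_only()
        from clonalarch.phylogeny import find_conflicts, repair_min_flips

        m = ds.observed
        if not find_conflicts(m).is_conflict_free:
            m, _ = repair_min_flips(m)
            part = call_clones(m, "zygosity", min_cells=5).major_only()
        tree = build_clone_tree(part, order_mutations(m))
        table = track_clones(part, tree)
        for parent, child in tree.edges():
            for tp in table.timepoint_order:
                assert table.nested(parent.name, tp) >= table.nested(child.name, tp) - 1e-9


def test_own_fractions_unbiased_over_seeds():
    """Noiseless pipeline prevalence estimates have no systematic error."""
    cfg = default_config(ado_rate=0, miscall_rate=0, missing_rate=0)
    errors = {("I", tp): [] for tp in cfg.timepoint_order}
    sig_of = {c.id: tuple(int(x) for x in c.signature_codes(cfg.mutation_ids)) for c in cfg.clones}
    for seed in range(40):
        ds = simulate_cells(cfg, seed=seed)
        part = call_clones(ds.observed, "zygosity")
        tree = build_clone_tree(part, order_mutations(ds.observed))
        table = track_clones(part, tree)
        for tp in cfg.timepoint_order:
            truth = cfg.clone_by_id("I").prevalence[tp]
            label = part.clone_of_signature(sig_of["I"]).label
            errors[("I", tp)].append(table.own(label, tp) - truth)
    for (cid, tp), errs in errors.items():
        errs = np.array(errs)
        p = default_config().clone_by_id(cid).prevalence[tp]
        se_mean = np.sqrt(p * (1 - p) / 300) / np.sqrt(len(errs))
        assert abs(errs.mean()) < 2 * se_mean, (cid, tp, errs.mean())


def test_trajectories_hand_built_matrix():
    m = make_matrix(
        [
            ("c1", "T1", ["HET", "WT"]),
            ("c2", "T1", ["HOM", "WT"]),
            ("c3", "T1", ["WT", "WT"]),
            ("c4", "T2", ["HET", "HET"]),
            ("c5", "T2", ["HET", "WT"]),
            ("c6", "T2", ["WT", "WT"]),
        ],
        ["A", "B"],
    )
    t = frequency_trajectories(m, order_mutations(m))
    assert t.fraction("A", "T1") == pytest.approx(2 / 3)
    assert t.fraction("A", "T2") == pytest.approx(2 / 3)
    assert t.fraction("B", "T1") == 0.0
    assert t.fraction("B", "T2") == pytest.approx(1 / 3)
    ranks = dict(zip(t.frame["mutation"], t.frame["rank"]))
    assert ranks["A"] == 0 and ranks["B"] == 1


def test_trajectory_of_absent_mutation_is_zero():
    m = make_matrix(
        [("c1", "T1", ["HET", "WT"]), ("c2", "T2", ["HET", "WT"])], ["A", "B"]
    )
    t = frequency_trajectories(m, order_mutations(m))
    assert t.fraction("B", "T1") == 0.0 and t.fraction("B", "T2") == 0.0


def test_trajectories_match_configured_study_frequencies():
    cfg = default_config(ado_rate=0, miscall_rate=0, missing_rate=0)
    m = simulate_cells(cfg, seed=13).observed
    t = frequency_trajectories(m, order_mutations(m))
    for tp, want in [("T1", 0.166), ("T2", 0.25), ("T3", 0.356)]:
        se = np.sqrt(want * (1 - want) / 300)
        assert abs(t.fraction("FLT3", tp) - want) <= 3 * se


def test_zygosity_evolution_constant_matrix():
    m = make_matrix(
        [("c1", "T1", ["HET"]), ("c2", "T2", ["HET"]), ("c3", "T3", ["HET"])], ["A"]
    )
    recs = zygosity_evolution(m, "A")
    assert [r.timepoint for r in recs] == ["T1", "T2", "T3"]
    assert all(r.proportions == recs[0].proportions for r in recs)


def test_flt3_homozygous_only_in_leukemic_phase():
    cfg = default_config(ado_rate=0, miscall_rate=0, missing_rate=0)
    m = simulate_cells(cfg, seed=21).observed
    recs = {r.timepoint: r for r in zygosity_evolution(m, "FLT3")}
    assert recs["T1"].proportions["HOM"] == 0.0
    assert recs["T2"].proportions["HOM"] == 0.0
    assert recs["T3"].proportions["HOM"] > 0.0


def test_zygosity_evolution_hand_count():
    m = make_matrix(
        [
            ("c1", "T1", ["HET"]), ("c2", "T1", ["HOM"]),
            ("c3", "T2", ["WT"]), ("c4", "T2", ["NA"]),
        ],
        ["A"],
    )
    recs = {r.timepoint: r for r in zygosity_evolution(m, "A")}
    assert recs["T1"].proportions == {"MISSING": 0.0, "WT": 0.0, "HET": 0.5, "HOM": 0.5}
    assert recs["T2"].proportions["MISSING"] == 0.5
    assert recs["T2"].defined_proportions["WT"] == 1.0


def test_timescape_records_cover_all_clone_timepoints():
    cfg, ds, part, tree, table = noiseless_tracked()
    records = timescape_records(table, tree)
    assert len(records) == len(tree.nodes()) * len(cfg.timepoint_order)
    for r in records:
        assert 0.0 <= r["clonal_prev"] <= 1.0
        assert r["own_prev"] <= r["clonal_prev"] + 1e-12


def test_signature_missing_from_tree_rejected():
    m = make_matrix(
        [("c1", "T1", ["HET", "WT"]), ("c2", "T1", ["HET", "HET"])], ["A", "B"]
    )
    part = call_clones(m, "zygosity")
    small = call_clones(m.subset([True, False]), "zygosity")
    tree = build_clone_tree(small, order_mutations(m))
    with pytest.raises(ValueError, match="absent from the clone tree"):
        track_clones(part, tree)
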