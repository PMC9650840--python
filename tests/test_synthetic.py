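import numpy as np
import pytest

import coreflow as cf
from coreflow.interspecies import attach_candidate
from coreflow.synthetic import default_gene_map


def test_generators_bit_reproducible():
    tree = cf.simulate_tree(8, "yule", depth=0.01, seed=6)
    params = cf.default_params(tree, length=8000, target_pi=0.02)
    a1, t1 = cf.simulate_population(params, recombination_rate=0.02, seed=9)
    a2, t2 = cf.simulate_population(params, recombination_rate=0.02, seed=9)
    assert np.array_equal(a1.matrix, a2.matrix)
    assert t1.events == t2.events
    assert t1.root_sequence == t2.root_sequence


def test_zero_recombination_equals_clonal_simulator_bitwise():
    tree = cf.simulate_tree(8, "yule", depth=0.01, seed=2)
    params = cf.default_params(tree, length=6000, target_pi=0.02)
    pop, truth = cf.simulate_population(params, recombination_rate=0.0, seed=77)
    clonal = cf.simulate_clonal(params, rescale=1.0, seed=77)
    assert pop.genome_ids == clonal.genome_ids
    assert np.array_equal(pop.matrix, clonal.matrix)
    assert truth.events == []


def test_event_log_replays_to_the_same_alignment():
    tree = cf.simulate_tree(10, "yule", depth=0.01, seed=3)
    params = cf.default_params(tree, length=10_000, target_pi=0.02)
    aln, truth = cf.simulate_population(
        params, recombination_rate=0.05, tract_mean=1000, seed=13
    )
    assert truth.events  # recombination actually happened
    replay, replay_truth = cf.simulate_population(
        params,
        recombination_rate=truth.params["recombination_rate"],
        tract_mean=truth.params["tract_mean"],
        seed=truth.seed,
    )
    assert replay_truth.events == truth.events
    assert np.array_equal(replay.matrix, aln.matrix)


def test_tract_mask_covers_terminal_branch_events():
    tree = cf.simulate_tree(10, "yule", depth=0.01, seed=3)
    params = cf.default_params(tree, length=10_000, target_pi=0.02)
    _, truth = cf.simulate_population(
        params, recombination_rate=0.05, tract_mean=1000, seed=13
    )
    leaves = set(params.tree.leaf_names)
    for ev in truth.events:
        if ev["recipient"] in leaves:
            mask = truth.tract_mask[ev["recipient"]]
            assert any(s <= ev["start"] and ev["end"] <= e for s, e in mask)


def test_balanced_four_leaf_topology_and_depth():
    tree = cf.simulate_tree(4, "balanced", depth=0.02, seed=1)
    tips = {t.name: t for t in tree.tree.tips()}
    assert set(tips) == {"G01", "G02", "G03", "G04"}
    assert tips["G01"].parent is tips["G02"].parent
    assert tips["G03"].parent is tips["G04"].parent
    assert len({t.length for t in tips.values()}) == 1
    # root-to-tip path equals the requested depth
    assert tips["G01"].length + tips["G01"].parent.length == pytest.approx(0.02)
    with pytest.raises(ValueError, match="power-of-two"):
        cf.simulate_tree(6, "balanced", depth=0.02)


def test_zero_depth_tree_has_zero_branch_lengths():
    tree = cf.simulate_tree(5, "yule", depth=0.0, seed=4)
    assert tree.total_length() == 0.0


def test_yule_tree_deterministic_and_scaled():
    t1 = cf.simulate_tree(9, "yule", depth=0.03, seed=8)
    t2 = cf.simulate_tree(9, "yule", depth=0.03, seed=8)
    assert t1.to_newick() == t2.to_newick()
    depths = {}
    for tip in t1.tree.tips():
        d, node = 0.0, tip
        while node.parent is not None:
            d += node.length
            node = node.parent
        depths[tip.name] = d
    assert all(abs(d - 0.03) < 1e-9 for d in depths.values())  # ultrametric


def test_make_candidate_exact_divergence_and_exchange_log(recombining_population):
    aln, truth = recombining_population
    seq, ct = cf.make_candidate(
        aln, 0.1, exchanging=False, seed=5, root_sequence=truth.root_sequence
    )
    mism = sum(a != b for a, b in zip(seq, truth.root_sequence))
    assert mism == int(np.ceil(0.1 * aln.length))
    assert ct.events == []
    seq2, ct2 = cf.make_candidate(
        aln, 0.05, exchanging=True, exchange_rate=0.1, tract_mean=500, seed=5
    )
    assert ct2.events
    assert all(ev["donor"] in aln.genome_ids for ev in ct2.events)
    with pytest.raises(ValueError):
        cf.make_candidate(aln, 0.0)


def test_inject_introgression_exact_window_count(recombining_population):
    aln, truth = recombining_population
    cand, _ = cf.make_candidate(
        aln, 0.1, exchanging=False, seed=5, root_sequence=truth.root_sequence
    )
    shared = attach_candidate(aln, "CAND", cand)
    n_windows = shared.length // 100
    injected, mask = cf.inject_introgression(shared, 5.0, tract=100, seed=7)
    assert len(mask) == round(0.05 * n_windows)
    for m in mask:
        assert m["recipient"] != "CAND"
        s, e = m["start"], m["end"]
        assert injected.sequence(m["recipient"])[s:e] == shared.sequence("CAND")[s:e]
    with pytest.raises(ValueError):
        cf.inject_introgression(shared, 0.0)
    with pytest.raises(ValueError):
        cf.inject_introgression(shared, 60.0)


def test_default_gene_map_tiles_in_frame():
    genes = default_gene_map(10_000, 900)
    assert genes[0] == ("g1", 0, 900)
    assert all((e - s) % 3 == 0 for _, s, e in genes)
    ends = [e for _, _, e in genes]
    starts = [s for _, s, _ in genes]
    assert starts[1:] == ends[:-1]
    assert ends[-1] <= 10_000
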