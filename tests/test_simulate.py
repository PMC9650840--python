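import numpy as np
import pytest

import coreflow as cf
from coreflow.alignment import CoreAlignment, encode, nucleotide_diversity
from coreflow.homoplasy import HmTally
from coreflow.simulate import (
    SimulationParams,
    clonality_test,
    convergent_mutation_null,
    estimate_params,
    rescale_sweep,
    simulate_clonal,
)


def _params(tree, length=6000, gc=0.5, kappa=3.0, rates=(1, 1, 1)):
    return SimulationParams(
        gc_content=gc,
        length=length,
        kappa=kappa,
        codon_rates=np.array(rates, dtype=float),
        tree=tree,
        gene_map=[("g1", 0, length)],
    )


def test_estimate_params_summary_statistics(quartet_tree):
    aln = CoreAlignment.from_sequences(
        {  # cols: 0 = A/G transition site, 1 = A/C transversion, rest G+C filler
            "A": "AAGGCC",
            "B": "AAGGCC",
            "C": "GAGGCC",
            "D": "GCGGCC",
        },
        gene_map=[("g1", 0, 6)],
    )
    p = estimate_params(aln, quartet_tree)
    # one transition site, one transversion site -> rate-ratio kappa 2*1/1
    assert p.kappa == pytest.approx(2.0)
    assert p.gc_content == pytest.approx(np.mean([c in "GC" for row in aln.sequences.values() for c in row]))
    assert p.length == 6


def test_estimated_kappa_round_trips_through_the_simulator():
    tree = cf.simulate_tree(12, "yule", depth=0.01, seed=5)
    params = cf.default_params(tree, length=80_000, target_pi=0.02)  # kappa 3
    aln, _ = cf.simulate_population(params, seed=5)
    est = estimate_params(aln, cf.build_guide_tree(cf.corrected_distance_matrix(aln, "K2P")))
    assert est.kappa == pytest.approx(3.0, rel=0.25)
    rel = est.codon_rates / est.codon_rates.mean()
    true = np.array([1, 0.5, 3.0]) / np.mean([1, 0.5, 3.0])
    assert np.allclose(rel, true, rtol=0.25)


def test_kappa_capped_without_transversions(quartet_tree):
    aln = CoreAlignment.from_sequences(
        {"A": "AAA", "B": "AAA", "C": "GAA", "D": "GAA"}, gene_map=[("g1", 0, 3)]
    )
    with pytest.warns(UserWarning, match="capping kappa"):
        p = estimate_params(aln, quartet_tree)
    assert p.kappa == 100.0


def test_rescale_zero_returns_root_everywhere(quartet_tree):
    aln = simulate_clonal(_params(quartet_tree), rescale=0.0, seed=2)
    assert len({s for s in aln.sequences.values()}) == 1
    assert nucleotide_diversity(aln) == 0.0


def test_transition_fraction_matches_kappa():
    # kappa=4 -> transitions are 4/6 of substitution events
    tree = cf.GuideTree.from_newick("(A:0.0,B:0.08);")
    params = _params(tree, length=60_000, kappa=4.0)
    aln = simulate_clonal(params, seed=3)
    a, b = (encode(aln.sequence(g)) for g in aln.genome_ids)
    diff = a != b
    ts = ((a ^ b) == 2) & diff
    frac = ts.sum() / diff.sum()
    assert frac == pytest.approx(4 / 6, abs=0.03)


def test_jukes_cantor_reduction_pairwise_identity():
    # kappa=1, equal rates: identity ~ 1/4 + 3/4 exp(-4d/3)
    d = 0.12
    tree = cf.GuideTree.from_newick(f"(A:0.0,B:{d});")
    params = _params(tree, length=51_000, kappa=1.0)
    obs = []
    for seed in range(6):
        aln = simulate_clonal(params, seed=seed)
        a, b = (encode(aln.sequence(g)) for g in aln.genome_ids)
        obs.append((a == b).mean())
    expected = 0.25 + 0.75 * np.exp(-4 * d / 3)
    assert np.mean(obs) == pytest.approx(expected, abs=0.01)


def test_codon_rate_heterogeneity_shapes_polymorphism():
    tree = cf.GuideTree.from_newick("(A:0.0,B:0.1);")
    params = _params(tree, length=30_000, rates=(1, 1, 8))
    aln = simulate_clonal(params, seed=9)
    a, b = (encode(aln.sequence(g)) for g in aln.genome_ids)
    diff = a != b
    by_pos = [diff[p::3].sum() for p in range(3)]
    assert by_pos[2] > 3 * max(by_pos[0], by_pos[1])


def test_rescale_sweep_self_consistency():
    tree = cf.simulate_tree(8, "yule", depth=0.01, seed=4)
    params = cf.default_params(tree, length=20_000, target_pi=0.02)
    target = nucleotide_diversity(simulate_clonal(params, rescale=1.0, seed=50))
    sweep = rescale_sweep(params, target, n_replicates=33, seed=50)
    assert 0.7 < sweep.factor < 1.4
    # selected replicate is the grid argmin
    best_err = min(abs(pi - target) for _, pi in sweep.log)
    assert abs(nucleotide_diversity(sweep.alignment) - target) == pytest.approx(best_err)


def test_rescale_sweep_unattainable_target_warns():
    tree = cf.simulate_tree(6, "yule", depth=0.01, seed=4)
    params = cf.default_params(tree, length=6_000, target_pi=0.02)
    with pytest.warns(UserWarning, match="grid edge"):
        sweep = rescale_sweep(params, 0.0, n_replicates=9, seed=1)
    assert sweep.factor == pytest.approx(0.05)


def _tally(ratio, sd):
    return HmTally(h=0, m=1, ratio=ratio, resample_ratios=[ratio], sd=sd)


def test_clonality_threshold_rule():
    assert clonality_test(_tally(0.5, 0.1), null_ratio=0.5).clonal
    assert not clonality_test(_tally(0.5 + 3.01 * 0.1, 0.1), null_ratio=0.5).clonal
    assert clonality_test(_tally(0.5 + 2.99 * 0.1, 0.1), null_ratio=0.5).clonal


def test_clonality_degenerate_sd_flagged():
    v = clonality_test(_tally(0.6, 0.0), null_ratio=0.5)
    assert not v.clonal and v.flags


def test_convergent_null_identity_and_exact_stopping():
    cons = "ACGT" * 2500
    assert convergent_mutation_null(cons, 0.0, seed=1) == cons
    out = convergent_mutation_null(cons, 0.05, seed=1)
    diffs = sum(a != b for a, b in zip(cons, out))
    assert diffs == 500  # first crossing on 10,000 columns


def test_convergent_null_leaves_n_untouched_and_range_checked():
    cons = "N" * 10 + "ACGT" * 100
    out = convergent_mutation_null(cons, 0.1, seed=2)
    assert out[:10] == "N" * 10
    with pytest.raises(ValueError):
        convergent_mutation_null("ACGT", 0.75)


def test_convergent_null_substitution_spectrum_uniform():
    from scipy.stats import chisquare

    cons = "A" * 30_000
    out = convergent_mutation_null(cons, 0.2, seed=7)
    counts = [out.count(b) for b in "CGT"]
    assert chisquare(counts).pvalue > 1e-3


def test_simulation_deterministic_given_seed(quartet_tree):
    p = _params(quartet_tree)
    a1 = simulate_clonal(p, seed=42)
    a2 = simulate_clonal(p, seed=42)
    assert np.array_equal(a1.matrix, a2.matrix)
    a3 = simulate_clonal(p, seed=43)
    assert not np.array_equal(a1.matrix, a3.matrix)
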