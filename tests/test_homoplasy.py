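import numpy as np
import pytest

import coreflow as cf
from conftest import binary_parsimony_oracle
from coreflow.alignment import CoreAlignment
from coreflow.homoplasy import (
    AlleleOriginRecord,
    allele_origins,
    classify_syn_nonsyn,
    detect_nonrecombining_genomes,
    tally_hm,
)


def test_clade_consistent_alleles_have_one_origin(quartet_tree, toy_aln):
    records = {r.allele: r for r in allele_origins(quartet_tree, toy_aln, 0)}
    assert records["T"].origins == 1 and not records["T"].homoplasic
    assert records["G"].origins == 1 and not records["G"].homoplasic


def test_scattered_allele_is_homoplasic(quartet_tree, toy_aln):
    # A=T, B=G, C=T, D=G: T needs two origins on ((A,B),(C,D))
    records = {r.allele: r for r in allele_origins(quartet_tree, toy_aln, 1)}
    assert records["T"].origins >= 2 and records["T"].homoplasic


def test_singleton_allele_single_origin(quartet_tree, toy_aln):
    records = {r.allele: r for r in allele_origins(quartet_tree, toy_aln, 2)}
    assert records["C"].carrier_count == 1
    assert records["C"].origins == 1 and not records["C"].homoplasic


def test_origins_match_exhaustive_oracle_with_missing_data(quartet_tree):
    aln = CoreAlignment.from_sequences(
        {"A": "T", "B": "N", "C": "T", "D": "G"}, gene_map=[]
    )
    rec = {r.allele: r for r in allele_origins(quartet_tree, aln, 0)}
    oracle = binary_parsimony_oracle(quartet_tree, {"A": 1, "B": None, "C": 1, "D": 0})
    assert rec["T"].origins == oracle == 1


def test_tally_counts_and_singleton_policy(quartet_tree, toy_aln):
    t = tally_hm(toy_aln, quartet_tree, resamples=8, seed=1)
    assert (t.h, t.m) == (1, 2)  # scattered T; clade T + singleton C
    assert t.ratio == pytest.approx(0.5)
    t_nosing = tally_hm(toy_aln, quartet_tree, resamples=8, include_singletons=False, seed=1)
    assert (t_nosing.h, t_nosing.m) == (1, 1)


def test_tally_invariant_to_genome_order(recombining_population):
    aln, _ = recombining_population
    tree = cf.build_guide_tree(cf.corrected_distance_matrix(aln, "K2P"))
    t1 = tally_hm(aln, tree, resamples=4, seed=1)
    order = list(reversed(range(aln.n_genomes)))
    shuffled = CoreAlignment(
        [aln.genome_ids[i] for i in order], aln.matrix[order], aln.gene_map
    )
    t2 = tally_hm(shuffled, tree, resamples=4, seed=1)
    assert (t1.h, t1.m) == (t2.h, t2.m)


def test_resampling_cycles_through_every_genome_before_repeating():
    aln = CoreAlignment.from_sequences(
        {
            "A": "TTAACG",
            "B": "TGAACG",
            "C": "GTAACG",
            "D": "GGCACG",
            "E": "GGAACG",
        },
        gene_map=[("g1", 0, 6)],
    )
    tree = cf.build_guide_tree(cf.corrected_distance_matrix(aln, "p-distance"))
    t = tally_hm(aln, tree, resamples=5, seed=3)
    assert len(t.loo_ratios) == 5
    # 5 resamples over 5 genomes = one full permutation, each exclusion once
    assert sorted(t.resample_ratios) == sorted(t.loo_ratios.values())
    assert t.sd == pytest.approx(np.std(t.resample_ratios, ddof=1))


def test_leaf_exclusion_never_increases_origins(recombining_population):
    aln, _ = recombining_population
    tree = cf.build_guide_tree(cf.corrected_distance_matrix(aln, "K2P"))
    cols = [c.column for c in cf.site_table(aln)[:20]]
    drop = aln.genome_ids[3]
    sub = aln.drop_genome(drop)
    sub_tree = tree.prune_leaf(drop)
    for col in cols:
        full = {r.allele: r.origins for r in allele_origins(tree, aln, col)}
        values = sub.matrix[:, col]
        if len({v for v in values if v < 4}) < 2:
            continue  # column no longer polymorphic after exclusion
        for r in allele_origins(sub_tree, sub, col):
            if r.allele in full:
                assert r.origins <= full[r.allele]


def test_classify_syn_nonsyn_rules():
    # gene of 3 codons: GAT|GAT|GAT reference background
    aln = CoreAlignment.from_sequences(
        {
            "A": "GATGATGAT",
            "B": "GACGATGAT",  # codon 1: GAT->GAC (Asp/Asp, synonymous)
            "C": "GATGCTGAT",  # codon 2: GAT->GCT (Asp/Ala, non-synonymous)
            "D": "GATGATACT",  # codon 3: two polymorphic sites -> excluded
            "E": "GATGATGCT",
        },
        gene_map=[("g1", 0, 9)],
    )
    records = [
        AlleleOriginRecord(2, "C", 1, 1, False),   # synonymous, m
        AlleleOriginRecord(4, "C", 1, 2, True),    # non-synonymous, h
        AlleleOriginRecord(6, "A", 1, 1, False),   # codon 3 excluded
        AlleleOriginRecord(7, "C", 1, 1, False),   # codon 3 excluded
    ]
    table = classify_syn_nonsyn(aln, records)
    assert (table.m_syn, table.h_nonsyn, table.m_nonsyn, table.h_syn) == (1, 1, 0, 0)
    assert not table.qualifying


def test_classify_warns_on_record_outside_genes(toy_aln):
    aln = CoreAlignment.from_sequences(
        {"A": "GATA", "B": "GACA", "C": "GATA", "D": "GATT"},
        gene_map=[("g1", 0, 3)],
    )
    with pytest.warns(UserWarning, match="outside any gene"):
        classify_syn_nonsyn(aln, [AlleleOriginRecord(3, "T", 1, 1, False)])


def test_alpha_zero_never_excludes(recombining_population):
    aln, _ = recombining_population
    retained, excluded = detect_nonrecombining_genomes(aln, alpha=0.0, resamples=10)
    assert excluded == []
    assert retained == aln.genome_ids


def test_clonal_outlier_genome_is_excluded():
    tree = cf.simulate_tree(10, "yule", depth=0.01, seed=21)
    params = cf.default_params(tree, length=30_000, target_pi=0.02)
    aln, truth = cf.simulate_population(
        params, recombination_rate=0.05, tract_mean=2000, seed=21
    )
    outlier, _ = cf.make_candidate(
        aln, 0.05, exchanging=False, seed=99, root_sequence=truth.root_sequence
    )
    with_outlier = aln.add_genome("OUT", outlier)
    retained, excluded = detect_nonrecombining_genomes(
        with_outlier, alpha=1e-4, min_drop=0.10, resamples=50, seed=4
    )
    assert "OUT" in excluded
    assert set(retained) >= set(aln.genome_ids[:5])
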