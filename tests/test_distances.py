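import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import union_find_components
from coreflow.alignment import CoreAlignment
from coreflow.distances import (
    AniMatrix,
    DistanceError,
    corrected_distance_matrix,
    pairwise_ani,
    single_linkage_species,
)


def _aln(seqs):
    return CoreAlignment.from_sequences(seqs, gene_map=[])


def test_pairwise_ani_identity_and_arithmetic():
    assert pairwise_ani(_aln({"a": "A" * 100, "b": "A" * 100})).value("a", "b") == 100.0
    # 50 comparable columns, 3 mismatches -> 94.0
    b = "T" * 3 + "A" * 47
    ani = pairwise_ani(_aln({"a": "A" * 50, "b": b}))
    assert ani.value("a", "b") == pytest.approx(94.0)


def test_pairwise_ani_excludes_gapped_columns():
    ani = pairwise_ani(_aln({"a": "AC-T", "b": "ACGT"}))
    assert ani.value("a", "b") == 100.0


def test_pairwise_ani_no_comparable_columns():
    with pytest.raises(DistanceError, match="no comparable columns"):
        pairwise_ani(_aln({"a": "A---", "b": "--GT"}))


def test_jc_correction_closed_form():
    # p = 0.10 -> -(3/4) ln(1 - 4*0.10/3) = 0.10733
    b = "T" * 10 + "A" * 90
    d = corrected_distance_matrix(_aln({"a": "A" * 100, "b": b}), "JC")
    assert d.value("a", "b") == pytest.approx(0.10732, abs=1e-4)
    ident = corrected_distance_matrix(_aln({"a": "ACGT", "b": "ACGT"}), "JC")
    assert ident.value("a", "b") == 0.0


def test_k2p_transitions_only_closed_form():
    # 5 A<->G transitions over 100 columns: P=0.05, Q=0 -> 0.05268
    b = "G" * 5 + "A" * 95
    d = corrected_distance_matrix(_aln({"a": "A" * 100, "b": b}), "K2P")
    assert d.value("a", "b") == pytest.approx(-0.5 * np.log(0.9), abs=1e-6)


def test_p_distance_matches_ani_on_gapfree():
    rng = np.random.default_rng(5)
    seqs = {
        f"g{i}": "".join(rng.choice(list("ACGT"), 200)) for i in range(4)
    }
    aln = _aln(seqs)
    ani = pairwise_ani(aln)
    p = corrected_distance_matrix(aln, "p-distance")
    assert np.allclose(ani.values, 100.0 * (1.0 - p.values))


def test_jc_saturation_error():
    b = "C" * 80 + "A" * 20
    with pytest.raises(DistanceError, match="p-distance"):
        corrected_distance_matrix(_aln({"a": "A" * 100, "b": b}), "JC")


def test_phylip_square_round_trip(tmp_path):
    rng = np.random.default_rng(3)
    seqs = {f"g{i}": "".join(rng.choice(list("ACGT"), 120)) for i in range(4)}
    d = corrected_distance_matrix(_aln(seqs), "p-distance")
    path = tmp_path / "dist.phy"
    d.to_phylip(path)
    from coreflow.distances import DistanceMatrix

    back = DistanceMatrix.from_phylip(path)
    assert back.ids == d.ids
    assert np.allclose(back.values, d.values, atol=1e-6)


def test_single_linkage_chaining_and_singletons():
    ids = ["A", "B", "C"]
    vals = np.array([[100, 95, 90], [95, 100, 94], [90, 94, 100]], dtype=float)
    part = single_linkage_species(AniMatrix(ids, vals), 94)
    assert len(set(part.assignment.values())) == 1  # chained through B
    low = AniMatrix(ids, np.array([[100, 93, 93], [93, 100, 93], [93, 93, 100]], dtype=float))
    part93 = single_linkage_species(low, 94)
    assert len(set(part93.assignment.values())) == 3
    assert part93.assignment["A"] == "SP_A"


def test_single_linkage_matches_union_find_oracle():
    rng = np.random.default_rng(30)
    n = 30
    ids = [f"G{i:02d}" for i in range(n)]
    vals = rng.uniform(88, 100, size=(n, n))
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 100.0)
    part = single_linkage_species(AniMatrix(ids, vals), 94)
    ours = {frozenset(m) for m in part.clusters().values()}
    assert ours == union_find_components(ids, vals, 94)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(
    st.integers(min_value=3, max_value=10),
    st.integers(min_value=0, max_value=2**31 - 1),
    st.floats(min_value=90.0, max_value=99.0),
)
def test_single_linkage_equals_union_find_on_arbitrary_matrices(n, seed, cutoff):
    rng = np.random.default_rng(seed)
    ids = [f"G{i}" for i in range(n)]
    vals = rng.uniform(85, 100, size=(n, n))
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 100.0)
    part = single_linkage_species(AniMatrix(ids, vals), cutoff)
    ours = {frozenset(m) for m in part.clusters().values()}
    assert ours == union_find_components(ids, vals, cutoff)


def test_raising_cutoff_only_refines_partitions():
    rng = np.random.default_rng(7)
    n = 20
    ids = [f"G{i}" for i in range(n)]
    vals = rng.uniform(90, 100, size=(n, n))
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 100.0)
    ani = AniMatrix(ids, vals)
    coarse = single_linkage_species(ani, 92).assignment
    fine = single_linkage_species(ani, 96).assignment
    # every fine cluster sits inside one coarse cluster
    for label in set(fine.values()):
        members = [g for g in ids if fine[g] == label]
        assert len({coarse[g] for g in members}) == 1


def test_partition_invariant_to_input_order():
    rng = np.random.default_rng(12)
    n = 12
    ids = [f"G{i}" for i in range(n)]
    vals = rng.uniform(90, 100, size=(n, n))
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 100.0)
    part = single_linkage_species(AniMatrix(ids, vals), 95).assignment
    order = rng.permutation(n)
    shuffled = single_linkage_species(
        AniMatrix([ids[i] for i in order], vals[np.ix_(order, order)]), 95
    ).assignment
    assert part == shuffled
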