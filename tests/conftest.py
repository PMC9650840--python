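"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import coreflow as cf
from coreflow.alignment import CoreAlignment


# -- independent oracles ----------------------------------------------------

def binary_parsimony_oracle(tree: cf.GuideTree, states: dict[str, int | None]) -> int:
    """Exhaustive minimum-change count for a presence/absence character.

    Enumerates every 0/1 assignment to internal nodes (and to leaves
    with missing state) of the tree as given — multifurcations
    included — and returns the minimum number of edges whose endpoints
    disagree. Independent of the package's Fitch implementation.
    """
    nodes = list(tree.tree.postorder())
    free = [n for n in nodes if not n.is_tip() or states[n.name] is None]
    fixed = {id(n): states[n.name] for n in nodes if n.is_tip() and states[n.name] is not None}
    best = None
    for assignment in itertools.product((0, 1), repeat=len(free)):
        lab = dict(fixed)
        for node, s in zip(free, assignment):
            lab[id(node)] = s
        changes = sum(
            1
            for n in nodes
            if n.parent is not None and lab[id(n)] != lab[id(n.parent)]
        )
        if best is None or changes < best:
            best = changes
    return best


def union_find_components(ids, values, cutoff):
    """Single-linkage clustering oracle via an explicit union-find."""
    parent = {g: g for g in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            if values[i][j] >= cutoff:
                parent[find(ids[i])] = find(ids[j])
    groups = {}
    for g in ids:
        groups.setdefault(find(g), set()).add(g)
    return {frozenset(v) for v in groups.values()}


def naive_identical_segments(seq1, seq2, L: int) -> int:
    """Position-by-position brute-force identical-window count."""
    n = len(seq1)
    count = 0
    for s in range(n - L + 1):
        if all(seq1[s + k] == seq2[s + k] for k in range(L)):
            count += 1
    return count


def r2_from_table(n11, n10, n01, n00) -> float:
    """r² from an explicit 2x2 haplotype contingency table."""
    n = n11 + n10 + n01 + n00
    pA = (n11 + n10) / n
    pB = (n11 + n01) / n
    pAB = n11 / n
    return (pAB - pA * pB) ** 2 / (pA * (1 - pA) * pB * (1 - pB))


# -- fixtures ---------------------------------------------------------------

@pytest.fixture
def quartet_tree() -> cf.GuideTree:
    return cf.GuideTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def toy_aln() -> CoreAlignment:
    """4 genomes, 3 columns: one clade-consistent minor allele, one
    scattered (homoplasic) allele, one singleton."""
    return CoreAlignment.from_sequences(
        {"A": "TTA", "B": "TGA", "C": "GTA", "D": "GGC"},
        gene_map=[("g1", 0, 3)],
    )


@pytest.fixture(scope="session")
def recombining_population():
    """Small recombining population reused by several modules."""
    tree = cf.simulate_tree(10, "yule", depth=0.01, seed=11)
    params = cf.default_params(tree, length=20_000, target_pi=0.02)
    aln, truth = cf.simulate_population(
        params, recombination_rate=0.03, tract_mean=2000, seed=11
    )
    return aln, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
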