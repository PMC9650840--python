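"""Ground-truthed synthetic core-genome data for every pipeline stage.

The generator emulates the kind of data the pipeline consumes in the
wild: a population of core-genome concatenates evolved forward in time
along a tree under a K2P + codon-position model, optionally with
within-population gene conversion (the bacterial mode of homologous
recombination: a contiguous tract copied from a contemporaneous donor
lineage); candidate genomes diverged from the population root with or
without ongoing exchange; and alignments with introgressed tracts
injected at known positions. Every generator is deterministic given
(parameters, seed) and returns a truth record sufficient to score any
downstream recovery experiment.

Default conditions mirror a typical bacterial species core genome:
GC 0.5, κ = 3, codon-position rates 1 : 0.5 : 3 (third positions most
polymorphic), gene length 900 bp, and a Yule genealogy scaled to a
target nucleotide diversity π ≈ 0.01.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

from .alignment import CoreAlignment, consensus_sequence, decode, encode
from .interspecies import SharedCoreAlignment
from .simulate import SimulationParams, _evolve_tree, jc_diverge_to, jc_mutate_n
from .tree import GuideTree

__all__ = [
    "PopulationTruth",
    "CandidateTruth",
    "simulate_tree",
    "default_params",
    "simulate_population",
    "make_candidate",
    "inject_introgression",
    "default_gene_map",
]

DEFAULT_GC = 0.5
DEFAULT_KAPPA = 3.0
DEFAULT_CODON_RATES = (1.0, 0.5, 3.0)
DEFAULT_GENE_LENGTH = 900


@dataclass
class PopulationTruth:
    """Replayable record of one simulated population."""

    tree_newick: str
    events: list[dict]
    params: dict
    seed: int
    root_sequence: str
    tract_mask: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def to_json_lines(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(json.dumps({"record": "params", **self.params, "seed": self.seed}) + "\n")
            for ev in self.events:
                fh.write(json.dumps({"record": "conversion", **ev}) + "\n")


@dataclass
class CandidateTruth:
    events: list[dict]
    target_divergence: float
    realized_divergence: float
    seed: int


def default_gene_map(length: int, gene_length: int = DEFAULT_GENE_LENGTH):
    """Tile the concatenate with equal in-frame genes (remainder dropped)."""
    gene_length -= gene_length % 3
    genes = []
    g = 0
    for start in range(0, length - gene_length + 1, gene_length):
        genes.append((f"g{g + 1}", start, start + gene_length))
        g += 1
    leftover = length - (g * gene_length)
    if leftover >= 3:
        genes.append((f"g{g + 1}", g * gene_length, g * gene_length + leftover - leftover % 3))
    return genes


# -- trees ------------------------------------------------------------------

def simulate_tree(n_leaves: int, model: str = "yule", depth: float = 0.01, seed: int = 1) -> GuideTree:
    """Random ultrametric genealogy with root-to-tip length ``depth``.

    ``yule`` grows a pure-birth tree; ``balanced`` builds a perfectly
    balanced topology (n_leaves must be a power of two).
    """
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves")
    names = [f"G{i + 1:02d}" for i in range(n_leaves)]
    if model == "balanced":
        levels = int(np.log2(n_leaves))
        if 2**levels != n_leaves:
            raise ValueError("balanced trees require a power-of-two leaf count")
        per_edge = depth / levels if levels else 0.0

        def build(sub):
            if len(sub) == 1:
                return TreeNode(name=sub[0], length=per_edge)
            node = TreeNode(length=per_edge)
            half = len(sub) // 2
            node.append(build(sub[:half]))
            node.append(build(sub[half:]))
            return node

        root = TreeNode()
        half = n_leaves // 2
        root.append(build(names[:half]))
        root.append(build(names[half:]))
        return GuideTree(root)
    if model != "yule":
        raise ValueError(f"unknown tree model {model!r}")
    rng = np.random.default_rng(seed)
    root = TreeNode()
    # active lineages: (parent TreeNode, birth time)
    active = [(root, 0.0), (root, 0.0)]
    t = 0.0
    while len(active) < n_leaves:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        parent, birth = active.pop(i)
        node = TreeNode(length=t - birth)
        parent.append(node)
        active.append((node, t))
        active.append((node, t))
    t_end = t + rng.exponential(1.0 / n_leaves)
    order = rng.permutation(len(active))
    for k, idx in enumerate(order):
        parent, birth = active[idx]
        parent.append(TreeNode(name=names[k], length=t_end - birth))
    factor = depth / t_end if t_end > 0 else 0.0
    for node in root.postorder():
        if node.length is not None:
            node.length *= factor
    return GuideTree(root)


def _mean_pairwise_path(tree: GuideTree) -> float:
    leaves = tree.leaf_names
    dm = tree.tree.tip_tip_distances()
    vals = dm.condensed_form()
    return float(np.mean(vals)) if vals.size else 0.0


def default_params(
    tree: GuideTree,
    length: int = 50_000,
    gc_content: float = DEFAULT_GC,
    kappa: float = DEFAULT_KAPPA,
    codon_rates=DEFAULT_CODON_RATES,
    gene_length: int = DEFAULT_GENE_LENGTH,
    target_pi: float | None = None,
) -> SimulationParams:
    """Simulation parameters with the generator's default conditions.

    When ``target_pi`` is given, branch lengths are rescaled so the
    expected pairwise divergence (mean tip-to-tip path) equals it.
    """
    if target_pi is not None:
        mean_path = _mean_pairwise_path(tree)
        if mean_path > 0:
            tree = tree.scale(target_pi / mean_path)
    return SimulationParams(
        gc_content=gc_content,
        length=length,
        kappa=kappa,
        codon_rates=np.asarray(codon_rates, dtype=float),
        tree=tree,
        gene_map=default_gene_map(length, gene_length),
    )


# -- populations ------------------------------------------------------------

def simulate_population(
    params: SimulationParams,
    recombination_rate: float = 0.0,
    tract_mean: float = 1000.0,
    seed: int = 1,
) -> tuple[CoreAlignment, PopulationTruth]:
    """Forward-in-time population with optional gene conversion.

    ``recombination_rate`` is in conversion events per site per
    substitution: along a branch of length b, the expected event count
    is rate · length · b, each copying a geometric tract (mean
    ``tract_mean``) from a contemporaneous donor lineage chosen
    uniformly. With rate 0 this is bitwise identical to the clonal
    simulator at the same seed.
    """
    events: list[dict] = []
    leaves, root_seq = _evolve_tree(
        params, 1.0, seed, recombination_rate, tract_mean, event_log=events
    )
    matrix = np.vstack([leaves[name] for name in leaves])
    aln = CoreAlignment(list(leaves), matrix, params.gene_map)
    # conversion coverage per leaf: union of tracts on its ancestral path
    mask: dict[str, list[tuple[int, int]]] = {g: [] for g in aln.genome_ids}
    by_recipient: dict[str, list[tuple[int, int]]] = {}
    for ev in events:
        by_recipient.setdefault(ev["recipient"], []).append((ev["start"], ev["end"]))
    for leaf in params.tree.tree.tips():
        node = leaf
        tracts = []
        while node is not None:
            if node.name in by_recipient:
                tracts.extend(by_recipient[node.name])
            node = node.parent
        mask[leaf.name] = _merge_intervals(tracts)
    truth = PopulationTruth(
        tree_newick=params.tree.to_newick(),
        events=events,
        params={
            "length": params.length,
            "gc_content": params.gc_content,
            "kappa": params.kappa,
            "codon_rates": list(map(float, params.codon_rates)),
            "recombination_rate": recombination_rate,
            "tract_mean": tract_mean,
        },
        seed=seed,
        root_sequence=decode(root_seq),
        tract_mask=mask,
    )
    return aln, truth


def _merge_intervals(tracts):
    out = []
    for s, e in sorted(tracts):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def make_candidate(
    reference: CoreAlignment,
    divergence: float,
    exchanging: bool = False,
    exchange_rate: float = 0.05,
    tract_mean: float = 1000.0,
    seed: int = 1,
    root_sequence: str | None = None,
) -> tuple[str, CandidateTruth]:
    """Candidate genome diverged from the reference population's origin.

    The candidate evolves from ``root_sequence`` (the population root
    if known, else the reference consensus) by Jukes-Cantor point
    mutations until the observed divergence from that origin first
    reaches ``divergence``. With ``exchanging``, gene-conversion events
    (rate ``exchange_rate`` events per site per substitution) copy
    tracts from extant reference genomes en route, and are logged.
    """
    if not 0.0 < divergence <= 0.3:
        raise ValueError("divergence must lie in (0, 0.3]")
    rng = np.random.default_rng(seed)
    start = encode(root_sequence if root_sequence is not None else consensus_sequence(reference))
    L = start.size
    target = int(np.ceil(divergence * L))
    events: list[dict] = []
    if not exchanging:
        seq = jc_diverge_to(start, start.copy(), target, rng)
    else:
        n_events = int(rng.poisson(exchange_rate * L * divergence))
        thresholds = np.sort(rng.integers(0, max(target, 1), size=n_events))
        seq = start.copy()
        applied = 0
        for thr in thresholds:
            jc_mutate_n(seq, int(thr) - applied, rng)
            applied = int(thr)
            donor = int(rng.integers(reference.n_genomes))
            s = int(rng.integers(L))
            tract = int(rng.geometric(1.0 / max(tract_mean, 1.0)))
            e = min(s + tract, L)
            seq[s:e] = reference.matrix[donor, s:e]
            events.append(
                {"donor": reference.genome_ids[donor], "start": s, "end": e}
            )
        jc_mutate_n(seq, target - applied, rng)
        if int((seq != start).sum()) < target:
            seq = jc_diverge_to(seq, start, target, rng)
    realized = float((seq != start).sum() / L)
    return decode(seq), CandidateTruth(events, divergence, realized, seed)


def inject_introgression(
    shared: SharedCoreAlignment,
    fraction: float,
    tract: int = 100,
    seed: int = 1,
) -> tuple[SharedCoreAlignment, list[dict]]:
    """Overwrite a known fraction of windows with the candidate haplotype.

    ``fraction`` is the percent of non-overlapping ``tract``-bp windows
    to introgress (0 < fraction ≤ 50); in each selected window one
    randomly chosen reference genome's sequence is replaced by the
    candidate's. Returns the modified alignment and the truth mask.
    """
    if not 0.0 < fraction <= 50.0:
        raise ValueError("fraction must lie in (0, 50] percent")
    n_windows = shared.length // tract
    k = int(round(fraction / 100.0 * n_windows))
    if k < 1:
        raise ValueError("fraction selects no whole window at this alignment length")
    rng = np.random.default_rng(seed)
    windows = np.sort(rng.choice(n_windows, size=k, replace=False))
    cand_idx = shared.genome_ids.index(shared.candidate_id)
    ref_idx = [i for i in range(shared.n_genomes) if i != cand_idx]
    matrix = shared.matrix.copy()
    mask = []
    for w in windows:
        s, e = int(w) * tract, (int(w) + 1) * tract
        recipient = ref_idx[int(rng.integers(len(ref_idx)))]
        matrix[recipient, s:e] = matrix[cand_idx, s:e]
        mask.append(
            {
                "window": int(w),
                "start": s,
                "end": e,
                "recipient": shared.genome_ids[recipient],
            }
        )
    out = SharedCoreAlignment(
        genome_ids=list(shared.genome_ids),
        matrix=matrix,
        gene_map=list(shared.gene_map),
        candidate_id=shared.candidate_id,
        gene_provenance=dict(shared.gene_provenance),
    )
    return out, mask
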