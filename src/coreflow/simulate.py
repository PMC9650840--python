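"""Forward-in-time clonal core-genome simulation and the clonality test.

Observed h/m ratios cannot be interpreted in isolation: even a strictly
clonal population accumulates some homoplasies through independent
convergent mutations, at a rate that depends on divergence, base
composition, the transition/transversion ratio κ, and rate
heterogeneity across codon positions. This module therefore simulates
each species' core genome *without recombination* under a K2P + codon
model parameterised from the data, and asks whether the real h/m is
compatible with that clonal null.

Because recombination inflates the branch lengths of trees estimated
from recombining data, the simulation is repeated across a grid of
branch-length rescaling factors (n = 99 by default) and the replicate
whose nucleotide diversity π best matches the real alignment is taken
as the null. A species is judged clonal when its real h/m does not
exceed the null h/m by more than ``k`` (default 3) resampling standard
deviations.

The same mutation machinery provides the *convergent-mutation null
sequence*: a copy of a species consensus evolved by Jukes-Cantor point
mutations until a target divergence is first reached, used to estimate
the h/m expected between species in the complete absence of gene flow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .alignment import CoreAlignment, GAP, allele_counts, decode, encode, nucleotide_diversity
from .tree import GuideTree

__all__ = [
    "SimulationParams",
    "ClonalityVerdict",
    "SweepResult",
    "estimate_params",
    "simulate_clonal",
    "rescale_sweep",
    "clonality_test",
    "run_clonality_simulation_test",
    "convergent_mutation_null",
]

KAPPA_CAP = 100.0

# transversion partners per base (A,C,G,T codes 0..3)
_TV_TABLE = np.array([[1, 3], [0, 2], [1, 3], [0, 2]], dtype=np.uint8)


@dataclass
class SimulationParams:
    """Everything the clonal simulator needs, estimated from one species."""

    gc_content: float
    length: int
    kappa: float
    codon_rates: np.ndarray  # 3 relative rates (free scale)
    tree: GuideTree
    gene_map: list[tuple[str, int, int]] = field(default_factory=list)
    recombination_rate: float = 0.0

    def __post_init__(self) -> None:
        self.codon_rates = np.asarray(self.codon_rates, dtype=float)
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")
        if self.codon_rates.shape != (3,) or (self.codon_rates < 0).any() or self.codon_rates.sum() == 0:
            raise ValueError("codon_rates must be 3 non-negative rates, not all zero")

    def site_rates(self) -> np.ndarray:
        """Per-column relative rate, normalised to mean 1."""
        rates = np.ones(self.length)
        rel = self.codon_rates / self.codon_rates.mean()
        for _, start, end in self.gene_map:
            rates[start:end] = rel[np.arange(end - start) % 3]
        return rates / rates.mean()


@dataclass
class ClonalityVerdict:
    real_ratio: float
    null_ratio: float
    sd: float
    k: float
    clonal: bool
    flags: list[str] = field(default_factory=list)


@dataclass
class SweepResult:
    alignment: CoreAlignment
    factor: float
    log: list[tuple[float, float]]  # (factor, pi)
    warnings: list[str] = field(default_factory=list)


# -- parameter estimation ---------------------------------------------------

def estimate_params(aln: CoreAlignment, tree: GuideTree) -> SimulationParams:
    """Summary statistics driving the clonal simulation.

    κ is the K2P transition/transversion *rate* ratio α/β. Under K2P a
    fraction κ/(κ+2) of substitutions are transitions, so κ is
    estimated as 2 × (transition-type / transversion-type biallelic
    polymorphic sites); this keeps the estimate→simulate round trip
    consistent (a simulation at the estimated κ reproduces the observed
    substitution spectrum). κ is capped at 100 when no transversions
    are seen. Codon rates are proportional to counts of polymorphic
    sites at codon positions 1/2/3; GC is taken over all non-gap
    characters.
    """
    counts = allele_counts(aln)
    n_alleles = (counts > 0).sum(axis=1)
    biallelic = np.flatnonzero(n_alleles == 2)
    ts = tv = 0
    for col in biallelic:
        b1, b2 = np.flatnonzero(counts[col] > 0)
        if (b1 ^ b2) == 2:
            ts += 1
        else:
            tv += 1
    if tv == 0:
        warnings.warn(f"no transversion sites observed; capping kappa at {KAPPA_CAP}")
        kappa = KAPPA_CAP
    else:
        kappa = min(2.0 * ts / tv, KAPPA_CAP)
    codon_pos = aln.codon_positions()
    poly = n_alleles >= 2
    pos_counts = np.array(
        [int((poly & (codon_pos == p)).sum()) for p in range(3)], dtype=float
    )
    if pos_counts.sum() == 0:
        pos_counts = np.ones(3)
    pos_counts = np.maximum(pos_counts, 1.0)  # keep every position mutable
    nongap = aln.matrix < GAP
    gc = float(((aln.matrix == 1) | (aln.matrix == 2))[nongap].sum() / nongap.sum())
    gc = min(max(gc, 1e-6), 1 - 1e-6)
    return SimulationParams(
        gc_content=gc,
        length=aln.length,
        kappa=kappa,
        codon_rates=pos_counts,
        tree=tree,
        gene_map=list(aln.gene_map),
    )


# -- mutation machinery -----------------------------------------------------

def _apply_k2p_events(seq: np.ndarray, sites: np.ndarray, kappa: float, rng: np.random.Generator) -> None:
    """Apply substitution events in order; repeated hits compose sequentially."""
    p_ts = kappa / (kappa + 2.0)
    while sites.size:
        _, first_idx = np.unique(sites, return_index=True)
        sel = np.sort(first_idx)
        pos = sites[sel]
        cur = seq[pos]
        is_ts = rng.random(pos.size) < p_ts
        tv_pick = (rng.random(pos.size) < 0.5).astype(np.intp)
        new = np.where(is_ts, cur ^ 2, _TV_TABLE[cur, tv_pick])
        seq[pos] = new.astype(np.uint8)
        mask = np.ones(sites.size, dtype=bool)
        mask[sel] = False
        sites = sites[mask]


def _draw_sites(n_events: int, cum_rates: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return np.searchsorted(cum_rates, rng.random(n_events) * cum_rates[-1], side="right")


def _random_root(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=probs).astype(np.uint8)


def _node_schedule(tree: GuideTree):
    """Branches ordered so every node's parent (and every possible donor's
    parent at any event time) is resolved first: ascending end depth,
    ancestors before descendants on ties."""
    root = tree.tree
    depth: dict[int, float] = {id(root): 0.0}
    order: list = []
    rank: dict[int, int] = {}
    for i, node in enumerate(root.preorder()):
        rank[id(node)] = i
        if node is not root:
            depth[id(node)] = depth[id(node.parent)] + (node.length or 0.0)
    branches = [n for n in root.preorder() if n is not root]
    branches.sort(key=lambda n: (depth[id(n)], rank[id(n)]))
    for node in branches:  # stable names for event logging
        if not node.name:
            node.name = f"node{rank[id(node)]}"
    return branches, depth


def _evolve_tree(
    params: SimulationParams,
    rescale: float,
    seed: int,
    recombination_rate: float = 0.0,
    tract_mean: float = 1000.0,
    event_log: list | None = None,
):
    """Shared engine: clonal K2P/codon evolution along the tree, with
    optional gene-conversion events from contemporaneous lineages.

    Returns (leaf name -> sequence codes) plus all internal node
    sequences keyed by id(node), and the root sequence.
    """
    rng = np.random.default_rng(seed)
    L = params.length
    rates = params.site_rates()
    cum = np.cumsum(rates)
    root = params.tree.tree
    branches, depth = _node_schedule(params.tree)
    seqs: dict[int, np.ndarray] = {id(root): _random_root(L, params.gc_content, rng)}
    for node in branches:
        b = (node.length or 0.0) * rescale
        seq = seqs[id(node.parent)].copy()
        t0 = depth[id(node.parent)] * rescale
        t1 = depth[id(node)] * rescale
        if recombination_rate > 0 and b > 0:
            n_rec = rng.poisson(recombination_rate * L * b)
            rec_times = np.sort(rng.uniform(t0, t1, size=n_rec))
        else:
            rec_times = np.empty(0)
        seg_bounds = np.concatenate([[t0], rec_times, [t1]])
        for k in range(len(seg_bounds) - 1):
            seg = seg_bounds[k + 1] - seg_bounds[k]
            if seg > 0:
                n_mut = rng.poisson(seg * L)
                if n_mut:
                    _apply_k2p_events(seq, _draw_sites(n_mut, cum, rng), params.kappa, rng)
            if k < len(rec_times):  # gene-conversion event at seg_bounds[k+1]
                t = rec_times[k]
                donors = [
                    d
                    for d in branches
                    if d is not node
                    and depth[id(d.parent)] * rescale <= t < depth[id(d)] * rescale
                    and id(d.parent) in seqs
                ]
                if not donors:
                    continue
                donor = donors[rng.integers(len(donors))]
                start = int(rng.integers(L))
                tract = int(rng.geometric(1.0 / max(tract_mean, 1.0)))
                end = min(start + tract, L)
                seq[start:end] = seqs[id(donor.parent)][start:end]
                if event_log is not None:
                    event_log.append(
                        {
                            "recipient": node.name,
                            "donor": donor.name,
                            "start": start,
                            "end": end,
                            "time": float(t),
                        }
                    )
        seqs[id(node)] = seq
    leaves = {leaf.name: seqs[id(leaf)] for leaf in root.tips()}
    return leaves, seqs[id(root)]


def simulate_clonal(params: SimulationParams, rescale: float = 1.0, seed: int = 1) -> CoreAlignment:
    """Simulate core-genome evolution without recombination.

    The root sequence is drawn i.i.d. with P(G)=P(C)=gc/2; substitutions
    occur per site as a Poisson process (rate ∝ codon-position rate,
    branch lengths multiplied by ``rescale``), transitions chosen with
    probability κ/(κ+2), each transversion 1/(κ+2).
    """
    leaves, _ = _evolve_tree(params, rescale, seed)
    matrix = np.vstack([leaves[name] for name in leaves])
    return CoreAlignment(list(leaves), matrix, params.gene_map)


def rescale_sweep(
    params: SimulationParams,
    target_pi: float,
    n_replicates: int = 99,
    seed: int = 1,
    grid: tuple[float, float] = (0.05, 5.0),
) -> SweepResult:
    """Branch-length rescaling sweep with diversity matching.

    One clonal replicate per factor on a geometric grid (replicate r
    uses seed + r); the replicate minimising \\|π_sim − target_pi\\| wins.
    """
    factors = np.geomspace(grid[0], grid[1], n_replicates)
    best = None
    log = []
    for r, f in enumerate(factors):
        aln = simulate_clonal(params, float(f), seed + r)
        pi = nucleotide_diversity(aln)
        log.append((float(f), pi))
        score = abs(pi - target_pi)
        if best is None or score < best[0]:
            best = (score, aln, float(f))
    warns = []
    if best[2] in (float(factors[0]), float(factors[-1])):
        msg = (
            f"best rescale factor {best[2]:g} sits at the grid edge; "
            "consider a wider grid"
        )
        warns.append(msg)
        warnings.warn(msg)
    return SweepResult(best[1], best[2], log, warns)


def clonality_test(real, null_ratio: float, k: float = 3.0) -> ClonalityVerdict:
    """3-SD clonality decision.

    ``real`` is the HmTally of the observed alignment; ``null_ratio``
    the h/m of the diversity-matched clonal simulation. Clonal iff
    real.ratio ≤ null_ratio + k·real.sd.
    """
    flags = []
    if real.sd == 0 and real.ratio > null_ratio:
        flags.append("degenerate SD (0) with real ratio above null")
    clonal = bool(real.ratio <= null_ratio + k * real.sd)
    return ClonalityVerdict(real.ratio, null_ratio, real.sd, k, clonal, flags)


def run_clonality_simulation_test(
    aln: CoreAlignment,
    seed: int = 1,
    k: float = 3.0,
    n_replicates: int = 99,
    resamples: int = 100,
    include_singletons: bool = True,
):
    """End-to-end simulation-based clonality test for one species.

    Builds the NJ guide tree, tallies the real h/m with resampling,
    estimates simulation parameters, runs the rescaling sweep against
    the real π, re-estimates a tree from the selected replicate, and
    applies the k·SD rule. Returns (ClonalityVerdict, HmTally, SweepResult).
    """
    from .distances import corrected_distance_matrix
    from .homoplasy import tally_hm, _hm_counts
    from .tree import build_guide_tree

    tree = build_guide_tree(corrected_distance_matrix(aln, "K2P"))
    real = tally_hm(aln, tree, resamples=resamples, include_singletons=include_singletons, seed=seed)
    params = estimate_params(aln, tree)
    sweep = rescale_sweep(params, nucleotide_diversity(aln), n_replicates, seed)
    null_aln = sweep.alignment
    null_tree = build_guide_tree(corrected_distance_matrix(null_aln, "K2P"))
    h0, m0 = _hm_counts(
        null_aln.matrix, null_aln.genome_ids, null_tree.fitch_arrays(), include_singletons
    )
    null_ratio = h0 / m0 if m0 else 0.0
    return clonality_test(real, null_ratio, k), real, sweep


# -- Jukes-Cantor divergence machinery --------------------------------------

def jc_mutate_n(seq: np.ndarray, n: int, rng: np.random.Generator, mutable: np.ndarray | None = None) -> None:
    """Apply exactly n uniform JC point mutations in place (with replacement)."""
    if n <= 0:
        return
    if mutable is None:
        pos = rng.integers(seq.size, size=n)
    else:
        pos = mutable[rng.integers(mutable.size, size=n)]
    while pos.size:
        _, first_idx = np.unique(pos, return_index=True)
        sel = np.sort(first_idx)
        p = pos[sel]
        cur = seq[p]
        # new base uniform over the 3 alternatives of the current base
        offset = rng.integers(1, 4, size=p.size).astype(np.uint8)
        seq[p] = (cur + offset) % 4
        mask = np.ones(pos.size, dtype=bool)
        mask[sel] = False
        pos = pos[mask]


def jc_diverge_to(
    seq: np.ndarray,
    reference: np.ndarray,
    target_mismatches: int,
    rng: np.random.Generator,
    mutable: np.ndarray | None = None,
) -> np.ndarray:
    """Mutate ``seq`` until it first differs from ``reference`` at exactly
    ``target_mismatches`` positions (JC point mutations, back-mutations
    allowed). Batched: each batch can raise the count by at most its
    size, so the stopping count is hit exactly."""
    seq = seq.copy()
    if mutable is None:
        mutable = np.arange(seq.size)
    cur = int((seq != reference).sum())
    max_reachable = mutable.size
    if target_mismatches > max_reachable:
        raise ValueError(
            f"target divergence unreachable: {target_mismatches} mismatches "
            f"requested but only {max_reachable} mutable positions"
        )
    guard = 0
    while cur < target_mismatches:
        jc_mutate_n(seq, target_mismatches - cur, rng, mutable)
        cur = int((seq != reference).sum())
        guard += 1
        if guard > 10_000:
            raise RuntimeError("divergence target not reached; check inputs")
    return seq


def convergent_mutation_null(consensus: str, target_divergence: float, seed: int = 1) -> str:
    """Null sequence for the convergent-mutation test.

    A copy of the species consensus with uniform Jukes-Cantor point
    mutations (with replacement; back-mutations possible) applied until
    the observed divergence from the consensus first reaches
    ``target_divergence``. Positions that are N in the consensus are
    left untouched and never count as differences.
    """
    if not 0.0 <= target_divergence < 0.75:
        raise ValueError("target_divergence must lie in [0, 0.75)")
    codes = encode(consensus)
    mutable = np.flatnonzero(codes < GAP)
    L = codes.size
    target = int(np.ceil(target_divergence * L))
    if target == 0:
        return consensus
    rng = np.random.default_rng(seed)
    out = jc_diverge_to(codes, codes.copy(), target, rng, mutable)
    return decode(out)
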