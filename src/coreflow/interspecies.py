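"""Between-species gene-flow tests: h/m_ref, h/m_cand, h/m_0, h/m_norm.

To decide whether a candidate genome belongs to a reference species
under a gene-flow (biological) species concept, the h/m statistic is
computed three ways on the shared core alignment:

* ``h/m_ref`` — the reference species alone;
* ``h/m_cand`` — the reference plus the candidate genome;
* ``h/m_0``   — the reference plus a *convergent-mutation null*: a copy
  of the reference consensus evolved without gene flow to the
  candidate's observed divergence.

The normalised ratio ``h/m_norm = (h/m_cand − h/m_0)/(h/m_ref − h/m_0)``
is 0 when the candidate adds no more homoplasy than convergent mutation
alone explains (no gene flow) and 1 when the candidate is as connected
by gene flow as a conspecific genome. Verdicts follow the resampling
rank-sum tests: a significant and substantial drop of h/m_cand below
h/m_ref marks a distinct species; otherwise, h/m_cand significantly
above h/m_0 marks the same species; anything else is ambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Seq import Seq
from scipy.stats import mannwhitneyu

from .alignment import GAP, CoreAlignment, consensus_sequence, decode, encode
from .distances import corrected_distance_matrix
from .homoplasy import HmTally, tally_hm
from .simulate import convergent_mutation_null
from .tree import build_guide_tree

__all__ = [
    "SharedCoreAlignment",
    "GeneFlowAssessment",
    "match_orthologs",
    "attach_candidate",
    "hm_norm",
    "assess_gene_flow",
]


@dataclass
class SharedCoreAlignment(CoreAlignment):
    """Core alignment of a reference species plus exactly one candidate."""

    candidate_id: str = ""
    gene_provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.candidate_id and self.genome_ids.count(self.candidate_id) != 1:
            raise ValueError("candidate must be present exactly once")

    @property
    def reference_ids(self) -> list[str]:
        return [g for g in self.genome_ids if g != self.candidate_id]

    def reference_only(self) -> CoreAlignment:
        return self.drop_genome(self.candidate_id)


@dataclass
class GeneFlowAssessment:
    hm_ref: float
    hm_cand: float
    hm_0: float
    hm_norm: float
    p_drop: float
    p_null: float
    median_drop: float
    candidate_divergence: float
    verdict: str  # same_species | distinct_species | ambiguous
    flags: list[str] = field(default_factory=list)
    tallies: dict[str, HmTally] = field(default_factory=dict)

    def to_row(self) -> dict:
        return {
            "hm_ref": self.hm_ref,
            "hm_cand": self.hm_cand,
            "hm_0": self.hm_0,
            "hm_norm": self.hm_norm,
            "p_drop": self.p_drop,
            "p_null": self.p_null,
            "median_drop": self.median_drop,
            "candidate_divergence": self.candidate_divergence,
            "verdict": self.verdict,
            "flags": ";".join(self.flags),
        }


def hm_norm(hm_cand: float, hm_ref: float, hm_0: float) -> float:
    """(h/m_cand − h/m_0) / (h/m_ref − h/m_0), not clipped to [0, 1]."""
    if hm_ref == hm_0:
        raise ValueError("h/m_norm undefined when h/m_ref equals h/m_0")
    return (hm_cand - hm_0) / (hm_ref - hm_0)


# -- ortholog matching ------------------------------------------------------

def _translate(nt: str) -> str:
    nt = nt[: len(nt) - len(nt) % 3]
    return str(Seq(nt.replace("-", "N")).translate()).rstrip("*")


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    # do not penalise terminal gaps; identity is computed on internal columns
    aligner.end_gap_score = 0
    return aligner


def _identity_and_alignment(aligner, a: str, b: str):
    """Percent identity over aligned columns excluding terminal gaps."""
    if not a or not b:
        return 0.0, None
    alignment = aligner.align(a.replace("*", "X"), b.replace("*", "X"))[0]
    ta, tb = str(alignment[0]), str(alignment[1])
    # trim terminal gap runs on either row
    start, end = 0, len(ta)
    while start < end and (ta[start] == "-" or tb[start] == "-"):
        start += 1
    while end > start and (ta[end - 1] == "-" or tb[end - 1] == "-"):
        end -= 1
    if end == start:
        return 0.0, alignment
    matches = sum(1 for i in range(start, end) if ta[i] == tb[i] and ta[i] != "-")
    ident = matches / (end - start) * 100.0
    return ident, alignment


def match_orthologs(
    reference: CoreAlignment,
    candidate_genes: dict[str, str],
    candidate_id: str = "candidate",
    min_identity: float = 70.0,
    min_length: float = 80.0,
) -> SharedCoreAlignment:
    """Shared core of a reference species and a candidate gene set.

    Each reference gene's consensus translation is compared to every
    candidate gene by global protein alignment. Best bidirectional hits
    with ≥``min_identity``% protein identity and ≥``min_length``% length
    conservation, single-copy in the candidate, are retained; candidate
    nucleotides are threaded codon-aware onto the reference alignment
    via the protein alignment, with gaps elsewhere.
    """
    aligner = _protein_aligner()
    cons = consensus_sequence(reference)
    ref_genes = {g: (s, e) for g, s, e in reference.gene_map}
    ref_prot = {g: _translate(cons[s:e]) for g, (s, e) in ref_genes.items()}
    cand_prot = {g: _translate(seq) for g, seq in candidate_genes.items()}

    scores: dict[tuple[str, str], tuple[float, object]] = {}
    for rg, rp in ref_prot.items():
        for cg, cp in cand_prot.items():
            lmin, lmax = sorted((len(rp), len(cp)))
            if lmax == 0 or lmin / lmax * 100.0 < min_length:
                continue
            ident, alignment = _identity_and_alignment(aligner, rp, cp)
            if ident >= min_identity:
                scores[(rg, cg)] = (ident, alignment)

    def best_for(keys, pick):
        out = {}
        for (rg, cg), (ident, _) in scores.items():
            k = rg if pick == "ref" else cg
            v = cg if pick == "ref" else rg
            if k not in out or ident > out[k][1]:
                out[k] = (v, ident)
        return out

    best_cand_of_ref = best_for(scores, "ref")
    best_ref_of_cand = best_for(scores, "cand")
    bbh = []
    for rg, (cg, _) in best_cand_of_ref.items():
        if best_ref_of_cand.get(cg, (None,))[0] == rg:
            bbh.append((rg, cg))
    # single-copy in the candidate: drop genes where a second candidate gene
    # also hits the same reference gene above thresholds
    retained = []
    for rg, cg in bbh:
        hits = [c for (r, c) in scores if r == rg]
        if len(hits) == 1:
            retained.append((rg, cg))
    if not retained:
        raise ValueError("no shared core: no gene passed the ortholog criteria")

    retained_set = {rg for rg, _ in retained}
    # build candidate row per retained gene, threaded through the protein
    # alignment (each consensus residue corresponds to one codon column)
    pieces: dict[str, np.ndarray] = {}
    for rg, cg in retained:
        s, e = ref_genes[rg]
        _, alignment = scores[(rg, cg)]
        ta, tb = str(alignment[0]), str(alignment[1])
        cand_nt = encode(candidate_genes[cg])
        row = np.full(e - s, GAP, dtype=np.uint8)
        ri = ci = 0
        for col in range(len(ta)):
            ra, ca = ta[col], tb[col]
            if ra != "-" and ca != "-":
                if 3 * (ci + 1) <= cand_nt.size:
                    row[3 * ri : 3 * ri + 3] = cand_nt[3 * ci : 3 * ci + 3]
                ri += 1
                ci += 1
            elif ra != "-":
                ri += 1
            else:
                ci += 1
        pieces[rg] = row

    keep_cols = []
    new_gene_map = []
    offset = 0
    cand_row_parts = []
    for g, s, e in reference.gene_map:
        if g in retained_set:
            keep_cols.append((s, e))
            new_gene_map.append((g, offset, offset + (e - s)))
            cand_row_parts.append(pieces[g])
            offset += e - s
    col_idx = np.concatenate([np.arange(s, e) for s, e in keep_cols])
    matrix = np.vstack([reference.matrix[:, col_idx], np.concatenate(cand_row_parts)])
    return SharedCoreAlignment(
        genome_ids=reference.genome_ids + [candidate_id],
        matrix=matrix,
        gene_map=new_gene_map,
        candidate_id=candidate_id,
        gene_provenance={rg: cg for rg, cg in retained},
    )


def attach_candidate(
    reference: CoreAlignment, candidate_id: str, candidate_sequence: str
) -> SharedCoreAlignment:
    """Shared alignment from a candidate already aligned to the concatenate."""
    row = encode(candidate_sequence)
    if row.size != reference.length:
        raise ValueError("candidate sequence length does not match the alignment")
    return SharedCoreAlignment(
        genome_ids=reference.genome_ids + [candidate_id],
        matrix=np.vstack([reference.matrix, row]),
        gene_map=reference.gene_map,
        candidate_id=candidate_id,
        gene_provenance={g: g for g, _, _ in reference.gene_map},
    )


# -- the gene-flow assessment ----------------------------------------------

def _mean_p_distance(shared: SharedCoreAlignment) -> float:
    cand = shared.matrix[shared.genome_ids.index(shared.candidate_id)]
    miss_c = cand >= GAP
    dists = []
    for gid in shared.reference_ids:
        row = shared.matrix[shared.genome_ids.index(gid)]
        ok = ~(miss_c | (row >= GAP))
        if ok.sum() == 0:
            continue
        dists.append(float((cand[ok] != row[ok]).sum() / ok.sum()))
    if not dists:
        raise ValueError("candidate shares no comparable columns with the reference")
    return float(np.mean(dists))


def _tally(aln: CoreAlignment, resamples: int, include_singletons: bool, seed: int) -> HmTally:
    tree = build_guide_tree(corrected_distance_matrix(aln, "K2P"))
    return tally_hm(aln, tree, resamples=resamples, include_singletons=include_singletons, seed=seed)


def assess_gene_flow(
    shared: SharedCoreAlignment,
    alpha: float = 1e-4,
    min_drop: float = 0.10,
    resamples: int = 100,
    include_singletons: bool = True,
    seed: int = 1,
    divergence_aggregator: str = "mean",
) -> GeneFlowAssessment:
    """Full between-species gene-flow test for one candidate genome.

    Computes h/m for the reference alone, the reference + candidate, and
    the reference + convergent-mutation null sequence (evolved from the
    reference consensus to the candidate's observed divergence), each
    with leave-one-out resampling; then applies the rank-sum verdict
    rules described in the module docstring.
    """
    ref = shared.reference_only()
    if ref.n_genomes < 5:
        raise ValueError("reference species needs at least 5 genomes")
    t_ref = _tally(ref, resamples, include_singletons, seed)
    t_cand = _tally(shared, resamples, include_singletons, seed)
    div = _mean_p_distance(shared)
    if divergence_aggregator == "max":
        cand = shared.matrix[shared.genome_ids.index(shared.candidate_id)]
        div = max(
            float(((cand != row) & (cand < GAP) & (row < GAP)).sum() / max(((cand < GAP) & (row < GAP)).sum(), 1))
            for row in ref.matrix
        )
    null_seq = convergent_mutation_null(consensus_sequence(ref), div, seed=seed)
    null_aln = attach_candidate(ref, "__null__", null_seq)
    t_null = _tally(null_aln, resamples, include_singletons, seed)

    p_drop = float(
        mannwhitneyu(t_cand.resample_ratios, t_ref.resample_ratios, alternative="less").pvalue
    )
    p_null = float(
        mannwhitneyu(t_cand.resample_ratios, t_null.resample_ratios, alternative="greater").pvalue
    )
    med_ref = float(np.median(t_ref.resample_ratios))
    med_cand = float(np.median(t_cand.resample_ratios))
    median_drop = (med_ref - med_cand) / med_ref if med_ref > 0 else 0.0

    flags = []
    try:
        norm = hm_norm(t_cand.ratio, t_ref.ratio, t_null.ratio)
    except ValueError:
        norm = float("nan")
        flags.append("hm_norm undefined (h/m_ref = h/m_0)")
    if abs(t_ref.ratio - t_null.ratio) <= t_ref.sd:
        flags.append("hm_norm unstable (h/m_ref within one SD of h/m_0)")
        verdict = "ambiguous"
    elif p_drop < alpha and median_drop >= min_drop:
        verdict = "distinct_species"
    elif p_null < alpha:
        verdict = "same_species"
    else:
        verdict = "ambiguous"
    return GeneFlowAssessment(
        hm_ref=t_ref.ratio,
        hm_cand=t_cand.ratio,
        hm_0=t_null.ratio,
        hm_norm=norm,
        p_drop=p_drop,
        p_null=p_null,
        median_drop=median_drop,
        candidate_divergence=div,
        verdict=verdict,
        flags=flags,
        tallies={"ref": t_ref, "cand": t_cand, "null": t_null},
    )
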