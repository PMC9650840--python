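"""Homoplasic vs non-homoplasic allele inference — the h/m gene-flow signal.

An allele is *homoplasic* when its distribution across genomes is
incompatible with a single mutational origin under vertical inheritance
on the guide tree. Operationally, each non-modal allele at a polymorphic
column is treated as a presence/absence character and its number of
origins is the unit-cost small-parsimony (Fitch) score of that character
on the tree, with gap/N leaves free to take either state. A score of 1
means the allele maps to a single clade (one origin); a score of 2 or
more means its carriers are scattered (recombination, or convergent
mutation). The ratio of homoplasic to non-homoplasic alleles, h/m, is
the package's central statistic: in a recombining population it sits
well above the level produced by convergent mutation alone.

The h/m ratio is resampled by leave-one-out genome exclusion; the
resampling distribution feeds the clonality decision (3-SD rule), the
detection of non-recombining outlier genomes, and the between-species
gene-flow tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from scipy.stats import mannwhitneyu

from .alignment import GAP, _ALPHABET, CoreAlignment, allele_counts, decode
from .distances import corrected_distance_matrix
from .tree import FitchArrays, GuideTree, build_guide_tree

__all__ = [
    "AlleleOriginRecord",
    "HmTally",
    "SynNonsynTable",
    "allele_origins",
    "tally_hm",
    "detect_nonrecombining_genomes",
    "classify_syn_nonsyn",
]

_CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"


@dataclass
class AlleleOriginRecord:
    column: int
    allele: str
    carrier_count: int
    origins: int
    homoplasic: bool


@dataclass
class HmTally:
    """Counts of homoplasic (h) and non-homoplasic (m) alleles."""

    h: int
    m: int
    ratio: float  # nan when m == 0 (flagged)
    resample_ratios: list[float]
    sd: float
    loo_ratios: dict[str, float] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


@dataclass
class SynNonsynTable:
    h_syn: int
    h_nonsyn: int
    m_syn: int
    m_nonsyn: int

    @property
    def qualifying(self) -> bool:
        return (self.h_syn + self.h_nonsyn >= 100) and (self.m_syn + self.m_nonsyn >= 100)


# -- vectorised binary Fitch ------------------------------------------------

def _fitch_scores(arrays: FitchArrays, present: np.ndarray, missing: np.ndarray) -> np.ndarray:
    """Unit-cost parsimony score of presence/absence characters.

    ``present`` and ``missing`` are (n_leaves, n_characters) boolean
    matrices in ``arrays.leaf_names`` row order; missing leaves may take
    either state. Returns the minimum number of state changes per
    character (exact for unit cost, ambiguous leaves included).
    """
    n_leaves = arrays.n_leaves
    n_internal = arrays.left.size
    n_char = present.shape[1]
    can1 = np.empty((n_leaves + n_internal, n_char), dtype=bool)
    can0 = np.empty_like(can1)
    can1[:n_leaves] = present | missing
    can0[:n_leaves] = ~present
    score = np.zeros(n_char, dtype=np.int32)
    for k in range(n_internal):
        l, r = arrays.left[k], arrays.right[k]
        i1 = can1[l] & can1[r]
        i0 = can0[l] & can0[r]
        empty = ~(i1 | i0)
        score += empty
        node = n_leaves + k
        can1[node] = np.where(empty, can1[l] | can1[r], i1)
        can0[node] = np.where(empty, can0[l] | can0[r], i0)
    return score


def _characters(matrix: np.ndarray, include_singletons: bool):
    """Enumerate non-modal allele characters of an encoded alignment.

    Returns (columns, bases, carrier_counts) for every allele that is
    present but not the modal allele of its column (modal ties broken
    alphabetically). ``include_singletons=False`` drops alleles carried
    by a single genome.
    """
    counts = np.empty((matrix.shape[1], 4), dtype=np.int32)
    for b in range(4):
        counts[:, b] = (matrix == b).sum(axis=0)
    modal = np.argmax(counts, axis=1)
    min_carriers = 1 if include_singletons else 2
    cols_all, bases_all, carr_all = [], [], []
    for b in range(4):
        mask = (counts[:, b] >= min_carriers) & (modal != b)
        cols = np.flatnonzero(mask)
        cols_all.append(cols)
        bases_all.append(np.full(cols.size, b, dtype=np.uint8))
        carr_all.append(counts[cols, b])
    return (
        np.concatenate(cols_all),
        np.concatenate(bases_all),
        np.concatenate(carr_all),
    )


def _hm_counts(
    matrix: np.ndarray,
    genome_ids: list[str],
    arrays: FitchArrays,
    include_singletons: bool,
) -> tuple[int, int]:
    cols, bases, carriers = _characters(matrix, include_singletons)
    if cols.size == 0:
        return 0, 0
    order = [genome_ids.index(name) for name in arrays.leaf_names]
    sub = matrix[order][:, cols]
    present = sub == bases[None, :]
    miss = sub >= GAP
    scores = _fitch_scores(arrays, present, miss)
    h = int((scores >= 2).sum())
    m = int((scores == 1).sum())
    return h, m


def allele_origins(tree: GuideTree, aln: CoreAlignment, column) -> list[AlleleOriginRecord]:
    """Minimum origins of every allele at one polymorphic column.

    ``column`` is a 0-based index or a SiteRecord. Unlike the h/m tally
    (which considers only non-modal alleles), this reports a record for
    each allele present at the column.
    """
    if hasattr(column, "column"):
        column = column.column
    counts = np.array([(aln.matrix[:, column] == b).sum() for b in range(4)])
    present_bases = [b for b in range(4) if counts[b] > 0]
    if len(present_bases) < 2:
        raise ValueError(f"column {column} is not polymorphic")
    arrays = tree.fitch_arrays()
    missing_names = set(aln.genome_ids) ^ set(arrays.leaf_names)
    if missing_names:
        raise ValueError(f"tree leaves and genomes differ: {sorted(missing_names)}")
    order = [aln.genome_ids.index(name) for name in arrays.leaf_names]
    col = aln.matrix[order, column]
    present = np.stack([col == b for b in present_bases], axis=1)
    miss = np.repeat((col >= GAP)[:, None], len(present_bases), axis=1)
    scores = _fitch_scores(arrays, present, miss)
    records = []
    for b, s in zip(present_bases, scores):
        origins = max(int(s), 1)
        records.append(
            AlleleOriginRecord(
                column=int(column),
                allele=_ALPHABET[b],
                carrier_count=int(counts[b]),
                origins=origins,
                homoplasic=origins >= 2,
            )
        )
    return records


def _resample_sequence(n: int, resamples: int, rng: np.random.Generator) -> np.ndarray:
    """Leave-one-out draw order: random permutations without replacement
    until the genome set is exhausted, then again (fresh permutations)."""
    reps = []
    while sum(len(r) for r in reps) < resamples:
        reps.append(rng.permutation(n))
    return np.concatenate(reps)[:resamples]


def tally_hm(
    aln: CoreAlignment,
    tree: GuideTree,
    resamples: int = 100,
    include_singletons: bool = True,
    seed: int = 1,
) -> HmTally:
    """h/m tally with leave-one-out resampling.

    The real ratio is recomputed once per distinct leave-one-out genome
    (pruning the corresponding leaf from the guide tree) and the
    ``resamples`` replicate ratios are drawn from those values in
    exclusion order; ``sd`` is their sample standard deviation.
    """
    if aln.n_genomes < 4:
        raise ValueError("h/m needs at least 4 genomes for meaningful parsimony")
    h, m = _hm_counts(aln.matrix, aln.genome_ids, tree.fitch_arrays(), include_singletons)
    flags = []
    if m == 0:
        flags.append("m=0: ratio undefined")
        ratio = float("nan")
    else:
        ratio = h / m
    loo: dict[str, float] = {}
    for idx, gid in enumerate(aln.genome_ids):
        keep = [i for i in range(aln.n_genomes) if i != idx]
        sub_ids = [aln.genome_ids[i] for i in keep]
        sub_tree = tree.prune_leaf(gid)
        h_g, m_g = _hm_counts(
            aln.matrix[keep], sub_ids, sub_tree.fitch_arrays(), include_singletons
        )
        loo[gid] = h_g / m_g if m_g else float("nan")
    rng = np.random.default_rng(seed)
    order = _resample_sequence(aln.n_genomes, resamples, rng)
    ratios = [loo[aln.genome_ids[i]] for i in order]
    sd = float(np.std(ratios, ddof=1)) if len(ratios) > 1 else 0.0
    return HmTally(h, m, ratio, ratios, sd, loo, flags)


def _nj_tree(aln: CoreAlignment, model: str = "K2P") -> GuideTree:
    return build_guide_tree(corrected_distance_matrix(aln, model))


def detect_nonrecombining_genomes(
    aln: CoreAlignment,
    alpha: float = 1e-4,
    min_drop: float = 0.10,
    resamples: int = 100,
    include_singletons: bool = True,
    seed: int = 1,
) -> tuple[list[str], list[str]]:
    """Greedy exclusion of genomes that depress the h/m signal.

    Iteratively removes the genome whose exclusion most increases the
    median resampled h/m, provided the with/without resample
    distributions differ (one-sided rank-sum, P < ``alpha``) and the
    median relative increase is at least ``min_drop``. Stops when no
    genome qualifies or when fewer than 4 genomes would remain.
    """
    if aln.n_genomes < 5:
        raise ValueError("outlier detection needs at least 5 genomes")
    current = aln
    excluded: list[str] = []
    while True:
        if current.n_genomes <= 4:
            warnings.warn("stopping: fewer than 4 genomes would remain")
            break
        base = tally_hm(
            current, _nj_tree(current), resamples, include_singletons, seed
        )
        base_median = float(np.median(base.resample_ratios))
        best = None
        for gid in current.genome_ids:
            sub = current.drop_genome(gid)
            t = tally_hm(sub, _nj_tree(sub), resamples, include_singletons, seed)
            med = float(np.median(t.resample_ratios))
            if best is None or med > best[1]:
                best = (gid, med, t)
        gid, med, t = best
        if base_median > 0:
            rel_increase = (med - base_median) / base_median
        else:
            rel_increase = float("inf") if med > 0 else 0.0
        if alpha <= 0:
            break
        p = mannwhitneyu(
            t.resample_ratios, base.resample_ratios, alternative="greater"
        ).pvalue
        if p < alpha and rel_increase >= min_drop:
            excluded.append(gid)
            current = current.drop_genome(gid)
        else:
            break
    return list(current.genome_ids), excluded


def classify_syn_nonsyn(
    aln: CoreAlignment, records: list[AlleleOriginRecord]
) -> SynNonsynTable:
    """Split non-modal allele records into synonymous/non-synonymous counts.

    Only codons with exactly one polymorphic site, that site biallelic,
    are counted (standard genetic code; codon phase from the gene map).
    Records at columns outside any gene are skipped with a warning.
    """
    if not aln.gene_map:
        raise ValueError("gene map required for synonymous classification")
    counts = allele_counts(aln)
    n_alleles = (counts > 0).sum(axis=1)
    polymorphic = n_alleles >= 2
    cons = np.argmax(counts, axis=1).astype(np.uint8)
    cons[counts.sum(axis=1) == 0] = 255  # untranslatable

    # codon eligibility: exactly one polymorphic site, biallelic there
    codon_of = {}
    eligible = {}
    for gene_id, start, end in aln.gene_map:
        for cstart in range(start, end, 3):
            cols = (cstart, cstart + 1, cstart + 2)
            n_poly = sum(polymorphic[c] for c in cols)
            ok = False
            if n_poly == 1:
                site = next(c for c in cols if polymorphic[c])
                ok = n_alleles[site] == 2 and all(cons[c] != 255 for c in cols)
            for c in cols:
                codon_of[c] = cstart
                eligible[c] = ok

    table = SynNonsynTable(0, 0, 0, 0)
    skipped = 0
    for rec in records:
        if rec.column not in codon_of:
            skipped += 1
            continue
        if not (polymorphic[rec.column] and eligible[rec.column]):
            continue
        cstart = codon_of[rec.column]
        ref_codon = list(cons[cstart : cstart + 3])
        alt_codon = list(ref_codon)
        alt_codon[rec.column - cstart] = _ALPHABET.index(rec.allele)
        aa_ref = _CODON_TABLE.get(decode(np.array(ref_codon, dtype=np.uint8)))
        aa_alt = _CODON_TABLE.get(decode(np.array(alt_codon, dtype=np.uint8)))
        if aa_ref is None or aa_alt is None:
            continue
        syn = aa_ref == aa_alt
        if rec.homoplasic:
            if syn:
                table.h_syn += 1
            else:
                table.h_nonsyn += 1
        else:
            if syn:
                table.m_syn += 1
            else:
                table.m_nonsyn += 1
    if skipped:
        warnings.warn(f"{skipped} allele record(s) outside any gene were skipped")
    return table
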