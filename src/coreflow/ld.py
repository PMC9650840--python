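"""Linkage-disequilibrium decay as a recombination signal.

In a recombining population, linkage between a pair of biallelic loci
(measured by r²) decays with the genomic distance separating them; in a
clonal population every locus shares the same genealogy and r² shows no
distance dependence. This module computes r² for all qualifying locus
pairs on the core-genome concatenate, profiles mean r² in consecutive
1,000-bp distance windows, and declares a species clonal when the
binned profile shows no significant negative Spearman correlation with
distance.

Locus filters: biallelic, minor allele in ≥2 genomes (singletons
excluded — they depress the recombination signal), <25% of genomes
missing at the column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr

from .alignment import GAP, CoreAlignment, allele_counts

__all__ = [
    "BiallelicLocus",
    "LdProfile",
    "LdVerdict",
    "r_squared",
    "qualifying_loci",
    "ld_decay_profile",
    "ld_clonality_test",
    "run_ld_clonality_test",
]


@dataclass
class BiallelicLocus:
    column: int
    major: str
    minor: str
    minor_count: int


@dataclass
class LdProfile:
    binned: list[tuple[float, float, int]]  # (window midpoint, mean r2, n pairs)
    window: int
    pairs: list[tuple[int, float]] | None = None  # (distance, r2); kept when small
    flags: list[str] = field(default_factory=list)


@dataclass
class LdVerdict:
    rho: float
    p_value: float
    clonal: bool
    n_bins: int
    flags: list[str] = field(default_factory=list)


def r_squared(pA: float, pB: float, pAB: float) -> float:
    """r² between two biallelic loci from allele and haplotype frequencies.

    r² = (pAB − pA·pB)² / (pA(1−pA)·pB(1−pB)), clipped to [0, 1]
    against floating error. Monomorphic input (pA or pB in {0, 1}) is an
    error — the denominator vanishes.
    """
    if not (0.0 < pA < 1.0 and 0.0 < pB < 1.0):
        raise ValueError("allele frequencies must lie strictly in (0, 1)")
    lo, hi = max(0.0, pA + pB - 1.0), min(pA, pB)
    if not lo - 1e-12 <= pAB <= hi + 1e-12:
        raise ValueError("pAB incompatible with marginal frequencies")
    val = (pAB - pA * pB) ** 2 / (pA * (1.0 - pA) * pB * (1.0 - pB))
    return float(min(max(val, 0.0), 1.0))


def qualifying_loci(
    aln: CoreAlignment, max_gap_fraction: float = 0.25, min_minor: int = 2
) -> list[BiallelicLocus]:
    """Biallelic loci passing the missingness and singleton filters."""
    from .alignment import _ALPHABET

    counts = allele_counts(aln)
    n = aln.n_genomes
    n_alleles = (counts > 0).sum(axis=1)
    gap_frac = 1.0 - counts.sum(axis=1) / n
    ok = (n_alleles == 2) & (gap_frac < max_gap_fraction)
    loci = []
    for col in np.flatnonzero(ok):
        bases = np.flatnonzero(counts[col] > 0)
        c = counts[col, bases]
        order = np.argsort(c)  # minor first (ties: alphabetically earlier minor)
        minor_b, major_b = bases[order[0]], bases[order[1]]
        if counts[col, minor_b] < min_minor:
            continue
        loci.append(
            BiallelicLocus(
                int(col), _ALPHABET[major_b], _ALPHABET[minor_b], int(counts[col, minor_b])
            )
        )
    return loci


def _pair_r2_block(
    minor: np.ndarray, missing: np.ndarray, i0: int, i1: int
) -> np.ndarray:
    """r² between loci [i0:i1) and all loci, pairwise deletion of missing
    genomes. minor/missing are (n_genomes, n_loci) boolean."""
    x = minor[:, i0:i1].astype(np.float64)
    mx = (~missing[:, i0:i1]).astype(np.float64)
    y = minor.astype(np.float64)
    my = (~missing).astype(np.float64)
    n = mx.T @ my  # genomes non-missing at both loci
    sx = (x * mx).T @ my
    sy = mx.T @ (y * my)
    sxy = (x * mx).T @ (y * my)
    with np.errstate(divide="ignore", invalid="ignore"):
        pA = sx / n
        pB = sy / n
        pAB = sxy / n
        num = (pAB - pA * pB) ** 2
        den = pA * (1 - pA) * pB * (1 - pB)
        r2 = num / den
    r2[(den <= 0) | (n < 2)] = np.nan
    return np.clip(r2, 0.0, 1.0)


def ld_decay_profile(
    aln: CoreAlignment,
    window: int = 1000,
    max_distance: int | None = None,
    max_kept_pairs: int = 2_000_000,
    block: int = 512,
) -> LdProfile:
    """r² against genomic distance, binned in consecutive distance windows.

    All qualifying locus pairs within ``max_distance`` on the
    concatenate coordinate are used; genomes missing at either locus are
    dropped pairwise. The raw (distance, r²) pairs are retained on the
    profile only when their number does not exceed ``max_kept_pairs``.
    """
    loci = qualifying_loci(aln)
    if len(loci) < 2:
        warnings.warn("fewer than 2 qualifying biallelic loci; empty LD profile")
        return LdProfile([], window, pairs=[], flags=["empty profile"])
    cols = np.array([l.column for l in loci])
    minor_codes = np.array([_base_code(l.minor) for l in loci], dtype=np.uint8)
    sub = aln.matrix[:, cols]
    minor = sub == minor_codes[None, :]
    missing = sub >= GAP
    S = cols.size
    if max_distance is None:
        max_distance = aln.length
    n_pairs_total = S * (S - 1) // 2
    keep_pairs = n_pairs_total <= max_kept_pairs
    raw: list[tuple[int, float]] = []
    n_bins = int(np.ceil(max_distance / window)) + 1
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for i0 in range(0, S, block):
        i1 = min(i0 + block, S)
        r2 = _pair_r2_block(minor, missing, i0, i1)
        dist = np.abs(cols[None, i0:i1].T - cols[None, :])
        # keep each unordered pair once: j > global index of row locus
        rows, cols_j = np.nonzero(
            (np.arange(S)[None, :] > np.arange(i0, i1)[:, None])
            & (dist <= max_distance)
            & (dist > 0)
            & ~np.isnan(r2)
        )
        d = dist[rows, cols_j]
        v = r2[rows, cols_j]
        b = d // window
        np.add.at(sums, b, v)
        np.add.at(counts, b, 1)
        if keep_pairs:
            raw.extend(zip(d.tolist(), v.tolist()))
    binned = [
        (float(b * window + window / 2), float(sums[b] / counts[b]), int(counts[b]))
        for b in range(n_bins)
        if counts[b] > 0
    ]
    flags = [] if binned else ["empty profile"]
    if not binned:
        warnings.warn("no qualifying locus pairs; empty LD profile")
    return LdProfile(binned, window, pairs=raw if keep_pairs else None, flags=flags)


def _base_code(base: str) -> int:
    return "ACGT".index(base)


def ld_clonality_test(profile: LdProfile, alpha: float = 1e-4, min_bins: int = 10) -> LdVerdict:
    """Clonality by absence of LD decay.

    Spearman rank correlation of (bin midpoint, mean r²); the species is
    called clonal unless the correlation is both negative and
    significant at ``alpha``. A flat (degenerate) profile is clonal with
    a flag. The conventional multiple-testing-adjusted threshold this
    alpha reflects is recorded in output metadata by callers (α=0.0226).
    """
    if len(profile.binned) < min_bins:
        raise ValueError(
            f"need at least {min_bins} non-empty distance bins, got {len(profile.binned)}"
        )
    mids = np.array([b[0] for b in profile.binned])
    means = np.array([b[1] for b in profile.binned])
    if np.allclose(means, means[0]):
        return LdVerdict(float("nan"), float("nan"), True, len(mids), ["degenerate profile"])
    rho, p = spearmanr(mids, means)
    clonal = not (rho < 0 and p < alpha)
    return LdVerdict(float(rho), float(p), bool(clonal), len(mids))


def run_ld_clonality_test(
    aln: CoreAlignment,
    alpha: float = 1e-4,
    window: int = 1000,
    max_distance: int | None = None,
    min_bins: int = 10,
) -> LdVerdict:
    """End-to-end LD clonality test for one species.

    Pairs are capped by default at half the concatenate length. Beyond
    that distance a bin can only be populated by loci near the
    alignment ends, so genomic position and pair distance become
    confounded and position-specific locus effects drift the binned
    means; capping at L/2 lets every locus contribute to every distance
    bin. Pass ``max_distance`` explicitly to override.
    """
    if max_distance is None:
        max_distance = aln.length // 2
    profile = ld_decay_profile(aln, window=window, max_distance=max_distance)
    return ld_clonality_test(profile, alpha=alpha, min_bins=min_bins)
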