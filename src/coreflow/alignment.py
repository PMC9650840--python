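"""Core-genome alignment container and per-site primitives.

The substrate of every analysis in this package is a *core-genome
concatenate*: the single-copy core genes of a set of genomes, aligned
gene by gene and concatenated into one equal-length nucleotide
alignment, together with a gene-boundary map giving the in-frame
coordinates of each gene on the concatenate.

Alphabet is {A, C, G, T, -, N}. ``U`` is mapped to ``T`` and every IUPAC
ambiguity code other than ``N`` is mapped to ``N`` (no allele semantics
are invented for partial ambiguity). Coordinates are 0-based half-open
internally; human-readable reports use 1-based inclusive positions.
"""

from __future__ import annotations

import gzip
import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

__all__ = [
    "CoreAlignment",
    "SiteRecord",
    "read_core_alignment",
    "write_core_alignment",
    "consensus_sequence",
    "nucleotide_diversity",
    "site_table",
]

# Integer codes used throughout the package: A C G T gap N.
_ALPHABET = "ACGT-N"
A, C, G, T, GAP, NCODE = range(6)
_CODE = np.full(256, NCODE, dtype=np.uint8)
for _i, _ch in enumerate(_ALPHABET):
    _CODE[ord(_ch)] = _i
    _CODE[ord(_ch.lower())] = _i
_CODE[ord("U")] = T
_CODE[ord("u")] = T
_CODE[ord(".")] = GAP


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes (A=0,C=1,G=2,T=3,-=4,N=5)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join(_ALPHABET[c] for c in codes)


class AlignmentError(ValueError):
    """Raised when an alignment or gene map violates its invariants."""


@dataclass
class CoreAlignment:
    """Equal-length aligned genomes plus an in-frame gene boundary map.

    Parameters
    ----------
    genome_ids
        Ordered unique genome labels.
    matrix
        uint8 array of shape (n_genomes, length) with codes from
        :func:`encode`.
    gene_map
        Ordered list of ``(gene_id, start, end)`` tuples in concatenate
        coordinates, 0-based half-open, each span divisible by 3,
        non-overlapping and sorted.
    """

    genome_ids: list[str]
    matrix: np.ndarray
    gene_map: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genome_ids = list(self.genome_ids)
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2:
            raise AlignmentError("alignment matrix must be 2-dimensional")
        if len(self.genome_ids) != self.matrix.shape[0]:
            raise AlignmentError("genome_ids and matrix row count differ")
        if len(set(self.genome_ids)) != len(self.genome_ids):
            raise AlignmentError("genome ids are not unique")
        if len(self.genome_ids) < 2:
            raise AlignmentError("a core alignment needs at least 2 genomes")
        self.gene_map = [(str(g), int(s), int(e)) for g, s, e in self.gene_map]
        last_end = 0
        for gene_id, start, end in self.gene_map:
            if not 0 <= start < end <= self.length:
                raise AlignmentError(
                    f"gene interval exceeds alignment: {gene_id} [{start},{end}) "
                    f"on {self.length} columns"
                )
            if start < last_end:
                raise AlignmentError(f"gene intervals overlap or are unsorted at {gene_id}")
            if (end - start) % 3:
                raise AlignmentError(f"gene {gene_id} span not divisible by 3")
            last_end = end

    # -- basic properties -------------------------------------------------
    @property
    def n_genomes(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def sequence(self, genome_id: str) -> str:
        return decode(self.matrix[self.genome_ids.index(genome_id)])

    @property
    def sequences(self) -> dict[str, str]:
        return {g: decode(row) for g, row in zip(self.genome_ids, self.matrix)}

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_genomes, length) mask of gap or N cells."""
        return self.matrix >= GAP

    def codon_positions(self) -> np.ndarray:
        """Per-column codon position (0, 1, 2) or -1 outside any gene."""
        pos = np.full(self.length, -1, dtype=np.int8)
        for _, start, end in self.gene_map:
            pos[start:end] = np.arange(end - start) % 3
        return pos

    # -- construction helpers --------------------------------------------
    @classmethod
    def from_sequences(
        cls,
        sequences: dict[str, str],
        gene_map: list[tuple[str, int, int]] | None = None,
    ) -> "CoreAlignment":
        ids = list(sequences)
        lengths = {len(s) for s in sequences.values()}
        if len(lengths) != 1:
            detail = ", ".join(f"{g}:{len(s)}" for g, s in sequences.items())
            raise AlignmentError(f"alignment length mismatch ({detail})")
        matrix = np.vstack([encode(sequences[g]) for g in ids])
        length = matrix.shape[1]
        if gene_map is None:
            gene_map = [("g1", 0, length - length % 3)]
        return cls(ids, matrix, gene_map)

    def drop_genome(self, genome_id: str) -> "CoreAlignment":
        idx = self.genome_ids.index(genome_id)
        keep = [i for i in range(self.n_genomes) if i != idx]
        return CoreAlignment(
            [self.genome_ids[i] for i in keep], self.matrix[keep], self.gene_map
        )

    def add_genome(self, genome_id: str, sequence: str) -> "CoreAlignment":
        if genome_id in self.genome_ids:
            raise AlignmentError(f"duplicate genome id {genome_id!r}")
        row = encode(sequence)
        if row.size != self.length:
            raise AlignmentError("alignment length mismatch for added genome")
        return CoreAlignment(
            self.genome_ids + [genome_id], np.vstack([self.matrix, row]), self.gene_map
        )


@dataclass
class SiteRecord:
    """Allele counts at one polymorphic alignment column."""

    column: int
    alleles: dict[str, int]
    gap_fraction: float


# -- IO -------------------------------------------------------------------

def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_gene_map(path: str | Path) -> list[tuple[str, int, int]]:
    """Read a 3-column TSV gene map (gene_id, start, end; 0-based half-open)."""
    genes: list[tuple[str, int, int]] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise AlignmentError(f"malformed gene map line: {line!r}")
            genes.append((fields[0], int(fields[1]), int(fields[2])))
    return genes


def read_core_alignment(fasta_path: str | Path, gene_map_path: str | Path | None = None) -> CoreAlignment:
    """Read an aligned multi-FASTA concatenate plus its gene map.

    All records must have identical length; characters are uppercased, U
    mapped to T, ambiguity codes other than N mapped to N.
    """
    ids: list[str] = []
    rows: list[np.ndarray] = []
    length: int | None = None
    with _open_text(fasta_path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq)
            if length is None:
                length = len(seq)
            elif len(seq) != length:
                raise AlignmentError(
                    f"alignment length mismatch: record {rec.id!r} has {len(seq)} "
                    f"columns, expected {length}"
                )
            ids.append(rec.id)
            rows.append(encode(seq))
    if length is None:
        raise AlignmentError(f"no FASTA records in {fasta_path}")
    gene_map = read_gene_map(gene_map_path) if gene_map_path is not None else None
    if gene_map is None:
        gene_map = [("g1", 0, length - length % 3)]
    return CoreAlignment(ids, np.vstack(rows), gene_map)


def write_core_alignment(aln: CoreAlignment, fasta_path: str | Path, gene_map_path: str | Path | None = None, width: int = 80) -> None:
    with open(fasta_path, "w") as fh:
        for gid, row in zip(aln.genome_ids, aln.matrix):
            fh.write(f">{gid}\n")
            seq = decode(row)
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    if gene_map_path is not None:
        with open(gene_map_path, "w") as fh:
            fh.write("#gene_id\tstart\tend\n")
            for gene_id, start, end in aln.gene_map:
                fh.write(f"{gene_id}\t{start}\t{end}\n")


# -- per-site primitives ---------------------------------------------------

def allele_counts(aln: CoreAlignment) -> np.ndarray:
    """(length, 4) counts of A, C, G, T per column (gap/N excluded)."""
    counts = np.empty((aln.length, 4), dtype=np.int32)
    for b in range(4):
        counts[:, b] = (aln.matrix == b).sum(axis=0)
    return counts


def consensus_sequence(aln: CoreAlignment) -> str:
    """Majority-rule consensus; ties broken alphabetically; all-gap columns 'N'."""
    counts = allele_counts(aln)
    # argmax returns the first (alphabetically smallest) maximal base
    cons = np.argmax(counts, axis=1).astype(np.uint8)
    cons[counts.sum(axis=1) == 0] = NCODE
    return decode(cons)


def nucleotide_diversity(aln: CoreAlignment) -> float:
    """Average pairwise nucleotide diversity π.

    Mean over unordered genome pairs of (differing comparable columns) /
    (comparable columns); a column is comparable for a pair when both
    genomes carry a plain nucleotide there. Pairs with zero comparable
    columns are excluded; if every pair is excluded an error is raised.
    """
    m = aln.matrix
    missing = aln.missing_mask()
    if not missing.any():
        # gap-free fast path: column-wise allele counts give the exact
        # mean pairwise difference fraction (all pairs share denominator L)
        n = aln.n_genomes
        counts = allele_counts(aln)
        same = (counts * (counts - 1) // 2).sum()
        pairs = n * (n - 1) // 2
        return float(1.0 - same / (pairs * aln.length))
    vals = []
    for i, j in itertools.combinations(range(aln.n_genomes), 2):
        comp = ~(missing[i] | missing[j])
        n_comp = int(comp.sum())
        if n_comp == 0:
            continue
        diff = int((m[i, comp] != m[j, comp]).sum())
        vals.append(diff / n_comp)
    if not vals:
        raise AlignmentError("no genome pair has comparable columns")
    return float(np.mean(vals))


def site_table(aln: CoreAlignment, columns: np.ndarray | None = None) -> list[SiteRecord]:
    """One SiteRecord per polymorphic column (≥2 distinct nucleotides).

    Records carry ``gap_fraction`` so callers can apply missingness
    filters (e.g. the 25% rule used for linkage disequilibrium) and
    singleton policies themselves.
    """
    counts = allele_counts(aln)
    n = aln.n_genomes
    poly = (counts > 0).sum(axis=1) >= 2
    if columns is not None:
        mask = np.zeros(aln.length, dtype=bool)
        mask[columns] = True
        poly &= mask
    gap_fraction = 1.0 - counts.sum(axis=1) / n
    records = []
    for col in np.flatnonzero(poly):
        alleles = {
            _ALPHABET[b]: int(counts[col, b]) for b in range(4) if counts[col, b] > 0
        }
        records.append(SiteRecord(int(col), alleles, float(gap_fraction[col])))
    return records
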