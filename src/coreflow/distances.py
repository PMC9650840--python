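"""Pairwise ANI of core genes, corrected distances, and ANI-species clustering.

ANI of core genes is the percent identity of a genome pair over the
comparable columns of the core-genome concatenate (columns with a gap or
N in either genome are excluded). Species are the connected components
of the graph joining pairs at or above the ANI cutoff (single linkage);
the cutoff used for delimitation is 94% core-gene identity.

Evolutionary distances are closed-form corrections of the pairwise
mismatch fraction: p-distance, Jukes-Cantor, or Kimura two-parameter
(the default used to feed the neighbor-joining guide tree).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .alignment import GAP, CoreAlignment

__all__ = [
    "AniMatrix",
    "DistanceMatrix",
    "SpeciesPartition",
    "pairwise_ani",
    "corrected_distance_matrix",
    "single_linkage_species",
]

# transitions are A<->G and C<->T; with codes A=0,C=1,G=2,T=3 a transition
# pair differs by exactly 2 (XOR with 2)
_TRANSITION_XOR = 2


class DistanceError(ValueError):
    pass


@dataclass
class _SquareMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise DistanceError("matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T):
            raise DistanceError("matrix is not symmetric")

    def value(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("id\t" + "\t".join(self.ids) + "\n")
            for gid, row in zip(self.ids, self.values):
                fh.write(gid + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path):
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
            rows = [line.rstrip("\n").split("\t")[1:] for line in fh if line.strip()]
        return cls(header, np.array(rows, dtype=float))


class AniMatrix(_SquareMatrix):
    """Symmetric percent-identity matrix, diagonal exactly 100."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.allclose(np.diag(self.values), 100.0):
            raise DistanceError("ANI diagonal must be 100")
        if self.values.min() < 0 or self.values.max() > 100:
            raise DistanceError("ANI values must lie in [0, 100]")


class DistanceMatrix(_SquareMatrix):
    """Symmetric non-negative distance matrix, zero diagonal."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.allclose(np.diag(self.values), 0.0):
            raise DistanceError("distance diagonal must be 0")
        if not np.isfinite(self.values).all() or self.values.min() < 0:
            raise DistanceError("distances must be finite and non-negative")

    def to_phylip(self, path) -> None:
        """Write in PHYLIP square format (names padded to 10 characters)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for gid, row in zip(self.ids, self.values):
                fh.write(f"{gid:<10s} " + " ".join(f"{v:.6f}" for v in row) + "\n")

    @classmethod
    def from_phylip(cls, path):
        with open(path) as fh:
            n = int(fh.readline().split()[0])
            ids, rows = [], []
            for _ in range(n):
                fields = fh.readline().split()
                ids.append(fields[0])
                rows.append([float(x) for x in fields[1:]])
        return cls(ids, np.array(rows))


@dataclass
class SpeciesPartition:
    """Genome → cluster assignment from single-linkage ANI clustering."""

    assignment: dict[str, str]
    cutoff: float

    def clusters(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for gid, label in self.assignment.items():
            out.setdefault(label, []).append(gid)
        return {k: sorted(v) for k, v in sorted(out.items())}

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#genome_id\tspecies\n")
            for gid in self.assignment:
                fh.write(f"{gid}\t{self.assignment[gid]}\n")


def _pair_counts(aln: CoreAlignment):
    """Per-pair comparable, mismatch, transition-mismatch counts."""
    m = aln.matrix
    missing = m >= GAP
    n = aln.n_genomes
    comp = np.zeros((n, n), dtype=np.int64)
    mism = np.zeros((n, n), dtype=np.int64)
    ts = np.zeros((n, n), dtype=np.int64)
    for i, j in itertools.combinations(range(n), 2):
        ok = ~(missing[i] | missing[j])
        d = (m[i] != m[j]) & ok
        t = d & ((m[i] ^ m[j]) == _TRANSITION_XOR)
        comp[i, j] = comp[j, i] = int(ok.sum())
        mism[i, j] = mism[j, i] = int(d.sum())
        ts[i, j] = ts[j, i] = int(t.sum())
    return comp, mism, ts


def pairwise_ani(aln: CoreAlignment) -> AniMatrix:
    """Percent identity per genome pair over comparable columns."""
    comp, mism, _ = _pair_counts(aln)
    n = aln.n_genomes
    off = ~np.eye(n, dtype=bool)
    if (comp[off] == 0).any():
        i, j = np.argwhere((comp == 0) & off)[0]
        raise DistanceError(
            f"no comparable columns between {aln.genome_ids[i]!r} and {aln.genome_ids[j]!r}"
        )
    values = np.full((n, n), 100.0)
    values[off] = 100.0 * (1.0 - mism[off] / comp[off])
    return AniMatrix(aln.genome_ids, values)


def corrected_distance_matrix(aln: CoreAlignment, model: str = "K2P") -> DistanceMatrix:
    """Closed-form corrected pairwise distances.

    Models: ``p-distance`` (raw mismatch fraction), ``JC``
    (d = -3/4 ln(1 - 4p/3)) or ``K2P``
    (d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q) with P, Q the transition
    and transversion mismatch fractions).
    """
    model = model.upper().replace("-DISTANCE", "").replace("P-", "P")
    if model not in {"P", "JC", "K2P"}:
        raise DistanceError(f"unknown distance model {model!r}")
    comp, mism, ts = _pair_counts(aln)
    n = aln.n_genomes
    off = ~np.eye(n, dtype=bool)
    if (comp[off] == 0).any():
        raise DistanceError("a genome pair has no comparable columns")
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(off, mism / np.maximum(comp, 1), 0.0)
        if model == "P":
            d = p
        elif model == "JC":
            arg = 1.0 - 4.0 * p / 3.0
            if (arg[off] <= 0).any():
                raise DistanceError(
                    "JC correction undefined (p >= 0.75); use the p-distance model"
                )
            d = -0.75 * np.log(arg)
        else:
            pt = np.where(off, ts / np.maximum(comp, 1), 0.0)
            q = p - pt
            a1 = 1.0 - 2.0 * pt - q
            a2 = 1.0 - 2.0 * q
            if (a1[off] <= 0).any() or (a2[off] <= 0).any():
                raise DistanceError(
                    "K2P correction undefined for a pair; use the p-distance model"
                )
            d = -0.5 * np.log(a1) - 0.25 * np.log(a2)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(aln.genome_ids, (d + d.T) / 2.0)


def single_linkage_species(ani: AniMatrix, cutoff: float = 94.0) -> SpeciesPartition:
    """Connected components of the ≥cutoff ANI graph.

    Cluster labels are ``SP_<smallest member id>`` so the partition is
    deterministic and invariant to genome input order.
    """
    n = len(ani.ids)
    adj = csr_matrix(ani.values >= cutoff)
    _, labels = connected_components(adj, directed=False)
    members: dict[int, list[str]] = {}
    for gid, lab in zip(ani.ids, labels):
        members.setdefault(int(lab), []).append(gid)
    names = {lab: f"SP_{min(ids)}" for lab, ids in members.items()}
    return SpeciesPartition(
        {gid: names[int(lab)] for gid, lab in zip(ani.ids, labels)}, float(cutoff)
    )
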