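"""Windowed introgression calling and the introgression score S_i.

Even when two species are distinct under the gene-flow test, tracts of
DNA may still cross the species boundary. A non-overlapping 100-bp
window on the shared core concatenate is called *introgressed* when at
least one genome of the reference species is strictly more similar to
the candidate genome in that window than it is to some other reference
genome, and the best candidate identity meets the threshold in force
(90, 95, 98 or 100% — increasingly recent events). S_i is the percent
of evaluated windows called introgressed.

The scan is only applicable when the candidate is an outgroup to the
reference species: every reference genome must be more distant from the
candidate than from every other reference genome (ties pass — strictly
"more related" is required to disqualify).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .alignment import GAP
from .distances import DistanceMatrix
from .interspecies import SharedCoreAlignment

__all__ = [
    "WindowCall",
    "IntrogressionProfile",
    "DEFAULT_THRESHOLDS",
    "applicability_check",
    "scan_windows",
    "introgression_score",
    "introgression_profile",
]

DEFAULT_THRESHOLDS = (90.0, 95.0, 98.0, 100.0)


@dataclass
class WindowCall:
    index: int
    start: int
    end: int
    best_cand_identity: float
    min_within_ref_identity: float
    introgressed: bool
    threshold: float


@dataclass
class IntrogressionProfile:
    calls: dict[float, list[WindowCall]]  # threshold -> calls
    s_i: dict[float, float]  # threshold -> percent introgressed
    applicable: bool
    skipped_windows: list[int] = field(default_factory=list)


def applicability_check(D: DistanceMatrix, candidate_id: str) -> bool:
    """True iff every reference genome is farther from the candidate than
    from every other reference genome (strict inequality disqualifies)."""
    ids = list(D.ids)
    c = ids.index(candidate_id)
    ref = [i for i in range(len(ids)) if i != c]
    for i in ref:
        d_cand = D.values[i, c]
        for j in ref:
            if j != i and D.values[i, j] > d_cand:
                return False
    return True


def _window_identities(block: np.ndarray, i: int, j: int, min_comparable: int):
    """Percent identity of rows i, j over comparable columns of a window."""
    a, b = block[i], block[j]
    ok = (a < GAP) & (b < GAP)
    n = int(ok.sum())
    if n < min_comparable:
        return None
    return 100.0 * (1.0 - float((a[ok] != b[ok]).sum()) / n)


def scan_windows(
    shared: SharedCoreAlignment,
    window: int = 100,
    threshold: float = 95.0,
    min_comparable: int = 50,
) -> list[WindowCall]:
    """Call introgression per non-overlapping window at one threshold.

    Per window, pairwise identities are computed on comparable columns
    (pairwise gap/N deletion); a window is skipped when any required
    pair has fewer than ``min_comparable`` comparable columns. The
    trailing remainder shorter than ``window`` is dropped.
    """
    cand_idx = shared.genome_ids.index(shared.candidate_id)
    ref_idx = [i for i in range(shared.n_genomes) if i != cand_idx]
    if len(ref_idx) < 2:
        raise ValueError("need at least 2 reference genomes")
    n_windows = shared.length // window
    calls: list[WindowCall] = []
    for w in range(n_windows):
        s, e = w * window, (w + 1) * window
        block = shared.matrix[:, s:e]
        ok = True
        best_cand = -np.inf
        for i in ref_idx:
            ident = _window_identities(block, i, cand_idx, min_comparable)
            if ident is None:
                ok = False
                break
            best_cand = max(best_cand, ident)
        if ok:
            min_ref = np.inf
            for a in range(len(ref_idx)):
                for b in range(a + 1, len(ref_idx)):
                    ident = _window_identities(block, ref_idx[a], ref_idx[b], min_comparable)
                    if ident is None:
                        ok = False
                        break
                    min_ref = min(min_ref, ident)
                if not ok:
                    break
        if not ok:
            continue
        introgressed = (best_cand > min_ref) and (best_cand >= threshold)
        calls.append(
            WindowCall(w, s, e, float(best_cand), float(min_ref), bool(introgressed), threshold)
        )
    return calls


def introgression_score(calls: list[WindowCall]) -> float:
    """Percent of evaluated windows called introgressed."""
    if not calls:
        raise ValueError("no evaluated windows; introgression score undefined")
    return 100.0 * sum(c.introgressed for c in calls) / len(calls)


def introgression_profile(
    shared: SharedCoreAlignment,
    D: DistanceMatrix | None = None,
    window: int = 100,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    min_comparable: int = 50,
) -> IntrogressionProfile:
    """S_i at every threshold, with the applicability guard applied.

    When a distance matrix over reference + candidate is supplied, the
    scan is marked inapplicable (and no windows are called) if any
    reference genome is more related to the candidate than to a fellow
    reference genome.
    """
    if D is not None and not applicability_check(D, shared.candidate_id):
        warnings.warn(
            "introgression score not computed: a reference genome is more "
            "related to the candidate than to another reference genome"
        )
        return IntrogressionProfile({}, {}, applicable=False)
    calls = {t: scan_windows(shared, window, t, min_comparable) for t in thresholds}
    s_i = {t: introgression_score(c) if c else float("nan") for t, c in calls.items()}
    evaluated = {c.index for t in calls for c in calls[t]}
    skipped = [w for w in range(shared.length // window) if w not in evaluated]
    return IntrogressionProfile(calls, s_i, applicable=True, skipped_windows=skipped)
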