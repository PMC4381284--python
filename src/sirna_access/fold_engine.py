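"""A desk-scale RNA folding engine.

This engine is a deliberately simple, exhaustively verifiable stand-in for
a thermodynamic folding server.  Structures are scored by hydrogen-bond
counts (GC=3, AU=2, GU=1) rather than nearest-neighbor free energies,
which keeps the optimum reproducible by brute force on short sequences and
matches the hydrogen-bond semantics of the accessibility index downstream.
Scores are negated bond counts, so "more negative = more stable" follows
the usual energy convention.  For Mfold/ViennaRNA-faithful numbers, feed
externally folded CT and ss-count files to the pipeline instead.

Provides:

* :func:`fold_optimal` — maximum-weight nested structure via Nussinov-style
  dynamic programming with a deterministic traceback;
* :func:`fold_constrained` — same, with an interval forced single-stranded;
* :func:`enumerate_structures` — branch-and-bound exhaustive enumeration of
  all structures within a score window of the optimum (short sequences);
* :func:`representative_ensemble` — a deterministic surrogate ensemble for
  sequences too long to enumerate;
* :func:`ss_count` — per-position single-stranded counts of an ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, List, Mapping, Optional, Tuple

import numpy as np

from .structure_io import (
    SecondaryStructure,
    SsCountVector,
    normalize_rna,
    write_ct,
    write_ss_count,
)

DEFAULT_PAIR_WEIGHTS: Mapping[str, int] = {"GC": 3, "AU": 2, "GU": 1}


@dataclass(frozen=True)
class FoldParams:
    """Scoring and enumeration parameters of the internal engine.

    ``pair_weights`` are hydrogen-bond counts per pair type (unitless);
    ``min_hairpin`` is the minimum number of unpaired nucleotides closed by
    a hairpin pair (steric minimum, default 3); ``suboptimal_window`` is
    the score width (in weight units) of the enumerated suboptimal set —
    ``None`` means 5% of the optimal weight; ``k_best`` optionally truncates
    the enumeration to the k best structures; ``max_enumeration_len`` caps
    exhaustive enumeration (it is exponential).
    """

    pair_weights: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PAIR_WEIGHTS)
    )
    min_hairpin: int = 3
    suboptimal_window: Optional[float] = None
    k_best: Optional[int] = None
    max_enumeration_len: int = 40

    def __post_init__(self) -> None:
        if self.min_hairpin < 3:
            raise ValueError("min_hairpin must be >= 3")
        if any(w <= 0 for w in self.pair_weights.values()):
            raise ValueError("pair weights must be positive")
        if self.suboptimal_window is not None and self.suboptimal_window < 0:
            raise ValueError("suboptimal_window must be >= 0")


@dataclass(frozen=True)
class StructureEnsemble:
    """Several structures of one sequence, best (lowest score) first."""

    sequence: str
    structures: Tuple[SecondaryStructure, ...]
    scores: Tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.structures:
            raise ValueError("ensemble must contain at least one structure")
        if len(self.structures) != len(self.scores):
            raise ValueError("structures and scores differ in length")
        for s in self.structures:
            if s.sequence != self.sequence:
                raise ValueError("all ensemble structures must share the sequence")
        keys = [(sc, st.pairs) for sc, st in zip(self.scores, self.structures)]
        if keys != sorted(keys):
            raise ValueError("ensemble must be sorted by score, ties by pair table")

    @property
    def size(self) -> int:
        return len(self.structures)

    @property
    def optimal(self) -> SecondaryStructure:
        return self.structures[0]


# ---------------------------------------------------------------------------
# Dynamic programming
# ---------------------------------------------------------------------------

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}


def _weight_table(params: FoldParams) -> np.ndarray:
    wt = np.zeros((4, 4), dtype=np.int64)
    for duo, w in params.pair_weights.items():
        a, b = duo[0], duo[1]
        wt[_BASE_INDEX[a], _BASE_INDEX[b]] = w
        wt[_BASE_INDEX[b], _BASE_INDEX[a]] = w
    return wt


def _pair_matrix(
    seq: str, params: FoldParams, forbidden: Optional[Tuple[int, int]] = None
) -> np.ndarray:
    """(n+2)x(n+2) matrix of pair weights, 1-based; 0 marks an illegal pair."""
    n = len(seq)
    idx = np.array([_BASE_INDEX[c] for c in seq], dtype=np.intp)
    wt = _weight_table(params)
    P = np.zeros((n + 2, n + 2), dtype=np.int64)
    P[1 : n + 1, 1 : n + 1] = wt[idx[:, None], idx[None, :]]
    if forbidden is not None:
        lo, hi = forbidden
        if not (1 <= lo <= hi <= n):
            raise ValueError(f"forbidden interval {forbidden} outside 1..{n}")
        P[lo : hi + 1, :] = 0
        P[:, lo : hi + 1] = 0
    return P


def _dp_table(n: int, P: np.ndarray, min_hairpin: int) -> np.ndarray:
    """Nussinov-style maximum-weight table W[i, j], 1-based, zero-padded."""
    W = np.zeros((n + 2, n + 2), dtype=np.int64)
    for d in range(min_hairpin + 1, n):
        i = np.arange(1, n - d + 1)
        j = i + d
        best = np.maximum(W[i + 1, j], W[i, j - 1])
        pw = P[i, j]
        paired = W[i + 1, j - 1] + pw
        np.maximum(best, np.where(pw > 0, paired, np.int64(-1)), out=best)
        for t in range(1, d):
            np.maximum(best, W[i, i + t] + W[i + t + 1, j], out=best)
        W[i, j] = best
    return W


def _traceback(W: np.ndarray, P: np.ndarray, n: int, min_hairpin: int) -> List[int]:
    """Deterministic traceback: prefer pairing (i, j), outermost pair first,
    then leaving i unpaired, then j, then the leftmost bifurcation."""
    pairs = [0] * (n + 1)
    stack: List[Tuple[int, int]] = [(1, n)] if n >= 1 else []
    while stack:
        i, j = stack.pop()
        while i < j:
            w = W[i, j]
            if w == 0:
                break
            if j - i > min_hairpin and P[i, j] > 0 and w == W[i + 1, j - 1] + P[i, j]:
                pairs[i], pairs[j] = j, i
                i, j = i + 1, j - 1
                continue
            if w == W[i + 1, j]:
                i += 1
                continue
            if w == W[i, j - 1]:
                j -= 1
                continue
            for k in range(i + 1, j):
                if W[i, k] + W[k + 1, j] == w:
                    stack.append((k + 1, j))
                    j = k
                    break
            else:  # pragma: no cover - DP invariant
                raise AssertionError("traceback failed to decompose the optimum")
    return pairs


def fold_optimal(seq: str, params: Optional[FoldParams] = None) -> SecondaryStructure:
    """Optimal (maximum pair-weight) nested structure of ``seq``.

    An unpairable sequence returns the open chain with score 0.
    """
    params = params or FoldParams()
    sequence = normalize_rna(seq, context="fold input")
    n = len(sequence)
    P = _pair_matrix(sequence, params)
    W = _dp_table(n, P, params.min_hairpin)
    pairs = _traceback(W, P, n, params.min_hairpin)
    return SecondaryStructure(
        sequence=sequence, pairs=tuple(pairs), energy=float(-W[1, n])
    )


def fold_constrained(
    seq: str, forbidden: Optional[Tuple[int, int]], params: Optional[FoldParams] = None
) -> SecondaryStructure:
    """Optimal structure with every position of ``forbidden`` kept unpaired.

    ``forbidden`` is a 1-based inclusive interval; ``None`` reduces to
    :func:`fold_optimal`.
    """
    params = params or FoldParams()
    sequence = normalize_rna(seq, context="fold input")
    n = len(sequence)
    P = _pair_matrix(sequence, params, forbidden=forbidden)
    W = _dp_table(n, P, params.min_hairpin)
    pairs = _traceback(W, P, n, params.min_hairpin)
    return SecondaryStructure(
        sequence=sequence, pairs=tuple(pairs), energy=float(-W[1, n])
    )


# ---------------------------------------------------------------------------
# Exhaustive enumeration (branch and bound)
# ---------------------------------------------------------------------------


def _enum(
    i: int,
    j: int,
    slack: float,
    W: np.ndarray,
    P: np.ndarray,
    min_hairpin: int,
) -> Iterator[Tuple[List[Tuple[int, int]], int]]:
    """Yield every nested structure of [i, j] whose weight >= W[i,j] - slack.

    Each structure is produced exactly once via the canonical first-position
    decomposition (position i is either unpaired or paired with some k).
    """
    if i >= j:
        yield [], 0
        return
    here = W[i, j]
    # position i unpaired
    s2 = slack - (here - W[i + 1, j])
    if s2 >= 0:
        yield from _enum(i + 1, j, s2, W, P, min_hairpin)
    # position i paired with k
    for k in range(i + min_hairpin + 1, j + 1):
        pw = P[i, k]
        if pw <= 0:
            continue
        ub = pw + W[i + 1, k - 1] + W[k + 1, j]
        s2 = slack - (here - ub)
        if s2 < 0:
            continue
        for left, wl in _enum(i + 1, k - 1, s2, W, P, min_hairpin):
            s3 = s2 - (W[i + 1, k - 1] - wl)
            for right, wr in _enum(k + 1, j, s3, W, P, min_hairpin):
                yield [(i, k)] + left + right, pw + wl + wr


def enumerate_structures(
    seq: str, params: Optional[FoldParams] = None
) -> StructureEnsemble:
    """All nested structures within the suboptimal window of the optimum.

    With ``suboptimal_window=math.inf`` every legal nested structure is
    produced.  Enumeration is exponential, hence the hard length cap.
    """
    params = params or FoldParams()
    sequence = normalize_rna(seq, context="fold input")
    n = len(sequence)
    if n > params.max_enumeration_len:
        raise ValueError(
            f"sequence too long for exhaustive enumeration ({n} > "
            f"{params.max_enumeration_len} nt); supply external structures"
        )
    P = _pair_matrix(sequence, params)
    W = _dp_table(n, P, params.min_hairpin)
    optimal = int(W[1, n]) if n >= 1 else 0
    if params.suboptimal_window is None:
        window: float = 0.05 * optimal
    else:
        window = params.suboptimal_window
    structures = []
    for pair_list, weight in _enum(1, n, window, W, P, params.min_hairpin):
        pairs = [0] * (n + 1)
        for a, b in pair_list:
            pairs[a], pairs[b] = b, a
        structures.append(
            SecondaryStructure(
                sequence=sequence, pairs=tuple(pairs), energy=float(-weight)
            )
        )
    structures.sort(key=lambda s: (s.energy, s.pairs))
    if params.k_best is not None:
        structures = structures[: params.k_best]
    return StructureEnsemble(
        sequence=sequence,
        structures=tuple(structures),
        scores=tuple(s.energy for s in structures),
    )


# ---------------------------------------------------------------------------
# Ensembles and ss-count
# ---------------------------------------------------------------------------


def ss_count(ensemble: StructureEnsemble) -> SsCountVector:
    """Number of ensemble structures in which each position is unpaired."""
    n = len(ensemble.sequence)
    counts = [0] * (n + 1)
    for s in ensemble.structures:
        for i in range(1, n + 1):
            if s.pairs[i] == 0:
                counts[i] += 1
    return SsCountVector(counts=tuple(counts), n_structures=ensemble.size)


def representative_ensemble(
    seq: str, params: Optional[FoldParams] = None, n_windows: int = 4
) -> StructureEnsemble:
    """A deterministic surrogate ensemble for sequences of any length.

    The ensemble holds the optimal fold plus the optimal folds constrained
    to leave each of ``n_windows`` contiguous, equal windows of the
    sequence single-stranded (duplicates dropped).  It stands in for a
    folding server's suboptimal set when exhaustive enumeration is
    infeasible; the ensemble size (the ss-count denominator) is therefore a
    parameter of the analysis, not a property of the molecule.
    """
    params = params or FoldParams()
    sequence = normalize_rna(seq, context="fold input")
    n = len(sequence)
    structures = [fold_optimal(sequence, params)]
    if n_windows > 0 and n >= 2:
        k = min(n_windows, n)
        bounds = np.linspace(0, n, k + 1).astype(int)
        for w in range(k):
            lo, hi = int(bounds[w]) + 1, int(bounds[w + 1])
            if lo > hi:
                continue
            structures.append(fold_constrained(sequence, (lo, hi), params))
    seen = set()
    unique = []
    for s in structures:
        if s.pairs not in seen:
            seen.add(s.pairs)
            unique.append(s)
    unique.sort(key=lambda s: (s.energy, s.pairs))
    return StructureEnsemble(
        sequence=sequence,
        structures=tuple(unique),
        scores=tuple(s.energy for s in unique),
    )


def write_ensemble(ensemble: StructureEnsemble, directory, prefix: str) -> None:
    """Serialize an ensemble as numbered CT files plus one ss-count file,
    so the internal engine and external folders are interchangeable."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for k, s in enumerate(ensemble.structures, start=1):
        write_ct(s, directory / f"{prefix}_{k:03d}.ct", title=f"{prefix} structure {k}")
    write_ss_count(
        ss_count(ensemble), directory / f"{prefix}.sscount", sequence=ensemble.sequence
    )
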