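"""Candidate rut-site discovery by sequence composition and folding propensity.

A rut (Rho-utilization) site is a C-rich, weakly structured stretch of
nascent mRNA where Rho's primary binding site engages.  The scanner slides a
window over a transcript-sense sequence, computes for each window the C/G
count ratio and a minimum folding free energy, and flags windows that are
simultaneously C-rich and unstructured; flagged windows are merged into
maximal intervals (0-based half-open, BED-ready).

The folding score is a deliberately self-contained pair-energy minimization
(GC -3, AU -2, GU -1 kcal/mol; hairpin loops >= 3 nt; nested structures
only; optional minimum helix length), solved by an O(n^3) dynamic program.
It is *not* a nearest-neighbour thermodynamic model: its absolute values are
comparative scores for ranking windows of equal length, and will not match
free energies printed by thermodynamic folding tools.  A brute-force
enumeration (:func:`fold_energy_reference`) provides the exact oracle for
short sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit

__all__ = [
    "RutWindow",
    "PAIR_ENERGIES",
    "fold_energy",
    "fold_energy_reference",
    "scan_windows",
    "call_rut_sites",
    "merge_intervals",
    "windows_to_bed",
]

#: Pair energies (kcal/mol) of the simple model.
PAIR_ENERGIES = {("G", "C"): -3.0, ("A", "U"): -2.0, ("G", "U"): -1.0}

#: Minimum number of unpaired nucleotides in a hairpin loop.
MIN_LOOP = 3

_ENC = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}


class SequenceError(ValueError):
    """Sequence contains characters outside {A, C, G, U, T}."""


@dataclass(frozen=True)
class RutWindow:
    """One scanned window: coordinates, composition and folding score.

    Coordinates are 0-based half-open on the transcript.  ``cg_ratio`` is
    C count / max(G count, 1) (a pseudocount of one G avoids division by
    zero on G-free windows); ``delta_g`` is the window's minimum folding
    energy (<= 0); ``score`` combines the two (higher = more rut-like);
    ``flagged`` marks windows passing the calling thresholds.
    """

    start: int
    end: int
    c_count: int
    g_count: int
    cg_ratio: float
    delta_g: float
    score: float = 0.0
    flagged: bool = False


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_ENC[c] for c in seq.upper()], dtype=np.int64)
    except KeyError as exc:
        raise SequenceError(f"invalid nucleotide {exc.args[0]!r}") from None


@njit(cache=True)
def _pair_e(a: int, b: int) -> float:
    if (a == 2 and b == 1) or (a == 1 and b == 2):
        return -3.0
    if (a == 0 and b == 3) or (a == 3 and b == 0):
        return -2.0
    if (a == 2 and b == 3) or (a == 3 and b == 2):
        return -1.0
    return 0.0


@njit(cache=True)
def _mfe_dp(seq: np.ndarray, min_helix: int) -> float:
    n = seq.shape[0]
    if n < 2 * min_helix + MIN_LOOP:
        return 0.0
    # maximal inward stack run starting at pair (i, j), and the summed energy
    # along that run
    maxrun = np.zeros((n, n), dtype=np.int64)
    esum = np.zeros((n, n), dtype=np.float64)
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            e = _pair_e(seq[i], seq[j])
            if e < 0.0:
                if j - i - 2 > MIN_LOOP and maxrun[i + 1, j - 1] > 0:
                    maxrun[i, j] = 1 + maxrun[i + 1, j - 1]
                    esum[i, j] = e + esum[i + 1, j - 1]
                else:
                    maxrun[i, j] = 1
                    esum[i, j] = e
    W = np.zeros((n, n), dtype=np.float64)
    V = np.zeros((n, n), dtype=np.float64)  # 0 => no admissible helix at (i,j)
    min_span = 2 * (min_helix - 1) + MIN_LOOP + 1
    for span in range(min_span, n):
        for i in range(0, n - span):
            j = i + span
            # V: pair (i,j) opens a helix of k >= min_helix stacked pairs
            best_v = 0.0
            kmax = maxrun[i, j]
            kgeo = (j - i - MIN_LOOP + 1) // 2  # innermost loop >= MIN_LOOP
            if kgeo < kmax:
                kmax = kgeo
            for k in range(min_helix, kmax + 1):
                if k < maxrun[i, j]:
                    run_e = esum[i, j] - esum[i + k, j - k]
                else:
                    run_e = esum[i, j]
                cand = run_e
                if i + k <= j - k:
                    cand += W[i + k, j - k]
                if cand < best_v:
                    best_v = cand
            V[i, j] = best_v
            # W: general minimum over nested structures of [i, j]
            best = W[i + 1, j]
            for l in range(i + min_span, j + 1):
                if V[i, l] < 0.0:
                    cand = V[i, l]
                    if l + 1 <= j:
                        cand += W[l + 1, j]
                    if cand < best:
                        best = cand
            W[i, j] = best
    return W[0, n - 1]


def fold_energy(seq: str, min_helix: int = 1) -> float:
    """Minimum folding energy of ``seq`` under the simple pair-energy model.

    T is accepted and read as U.  ``min_helix`` requires every helix to be a
    run of at least that many consecutively stacked pairs (1 = plain pair
    minimization).  Returns 0.0 when no admissible structure exists.
    """
    if min_helix < 1:
        raise ValueError("min_helix must be >= 1")
    arr = _encode(seq)
    if arr.size < 1:
        raise SequenceError("sequence must be non-empty")
    return float(_mfe_dp(arr, min_helix))


def fold_energy_reference(seq: str, min_helix: int = 1) -> float:
    """Exhaustive-enumeration oracle for :func:`fold_energy` (short sequences).

    Recursively enumerates every nested set of admissible pairs and returns
    the minimum total energy.  Exponential time; intended for n <= ~16.
    """
    arr = _encode(seq)
    n = arr.size
    e = np.zeros((n, n))
    for i in range(n):
        for j in range(i + MIN_LOOP + 1, n):
            e[i, j] = _pair_e(arr[i], arr[j])

    def structures(i: int, j: int):
        """Yield every nested pair set on [i, j] as a frozenset."""
        if i >= j:
            yield frozenset()
            return
        for rest in structures(i + 1, j):
            yield rest
        for l in range(i + MIN_LOOP + 1, j + 1):
            if e[i, l] < 0.0:
                for inner in structures(i + 1, l - 1):
                    for outer in structures(l + 1, j):
                        yield frozenset({(i, l)}) | inner | outer

    def helix_runs_ok(pairs: frozenset) -> bool:
        if min_helix <= 1:
            return True
        pset = set(pairs)
        for (a, b) in pairs:
            if (a - 1, b + 1) in pset:
                continue  # not the outermost pair of its run
            run = 1
            while (a + run, b - run) in pset:
                run += 1
            if run < min_helix:
                return False
        return True

    best = 0.0
    for s in structures(0, n - 1):
        if not helix_runs_ok(s):
            continue
        total = sum(e[a, b] for (a, b) in s)
        if total < best:
            best = total
    return best


def scan_windows(seq: str, window: int = 60, step: int = 1,
                 min_helix: int = 1) -> list[RutWindow]:
    """Slide a window over ``seq`` and score each position.

    The default 60-nt window matches the length scale of annotated
    Rho-loading segments in untranslated regions.  ``score`` is
    ``cg_ratio + delta_g``: it rewards C-richness and penalizes folding
    propensity on a single monotone scale used only for ranking.
    """
    arr = _encode(seq)
    n = arr.size
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    if window > n:
        raise ValueError(f"window ({window}) exceeds sequence length ({n})")
    out = []
    for start in range(0, n - window + 1, step):
        sub = arr[start:start + window]
        c = int(np.count_nonzero(sub == 1))
        g = int(np.count_nonzero(sub == 2))
        cg = c / max(g, 1)
        dg = float(_mfe_dp(sub, min_helix))
        out.append(RutWindow(start=start, end=start + window, c_count=c,
                             g_count=g, cg_ratio=cg, delta_g=dg,
                             score=cg + dg))
    return out


def merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or book-ended half-open intervals into maximal ones."""
    if not intervals:
        return []
    ordered = sorted(intervals)
    merged = [list(ordered[0])]
    for s, e in ordered[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def call_rut_sites(windows: Sequence[RutWindow], cg_min: float = 1.5,
                   dg_min: float = -55.0) -> list[tuple[int, int]]:
    """Flag rut-like windows and merge them into candidate site intervals.

    A window is rut-like when it is C-rich (``cg_ratio >= cg_min``) *and*
    weakly structured (``delta_g >= dg_min``, i.e. less negative).  The
    default ``dg_min`` is calibrated for 60-nt windows under the default
    energy model, sitting in the gap between unstructured C-rich windows and
    hairpin-dense background (see docs/methods.md); rescale it when changing
    the window length or ``min_helix``.
    """
    flagged = [(w.start, w.end) for w in windows
               if w.cg_ratio >= cg_min and w.delta_g >= dg_min]
    return merge_intervals(flagged)


def interval_match_stats(called: Sequence[tuple[int, int]],
                         truth: Sequence[tuple[int, int]],
                         min_overlap_frac: float = 0.5) -> dict[str, float]:
    """Site-level sensitivity and precision of called vs true intervals.

    A true site is recovered when some called interval covers at least
    ``min_overlap_frac`` of it; a called interval is correct when it covers
    at least that fraction of some true site.  Returns sensitivity,
    precision and the raw counts.
    """

    def covered(a: tuple[int, int], b: tuple[int, int]) -> float:
        ov = max(0, min(a[1], b[1]) - max(a[0], b[0]))
        return ov / max(b[1] - b[0], 1)

    tp_truth = sum(any(covered(c, t) >= min_overlap_frac for c in called)
                   for t in truth)
    tp_called = sum(any(covered(c, t) >= min_overlap_frac for t in truth)
                    for c in called)
    return {
        "sensitivity": tp_truth / len(truth) if truth else float("nan"),
        "precision": tp_called / len(called) if called else float("nan"),
        "n_truth": float(len(truth)),
        "n_called": float(len(called)),
    }


def windows_to_bed(intervals: Sequence[tuple[int, int]], name: str,
                   windows: Sequence[RutWindow] | None = None) -> list[str]:
    """Render called intervals as BED6 lines (score = scaled mean window score).

    Scores are the mean combined window score inside each interval, rank
    scaled to 0-1000 across the intervals.  Strand is '+' (transcript sense).
    """
    if not intervals:
        return []
    means = []
    for s, e in intervals:
        if windows:
            inside = [w.score for w in windows if w.start >= s and w.end <= e]
            means.append(float(np.mean(inside)) if inside else 0.0)
        else:
            means.append(0.0)
    order = np.argsort(np.argsort(means))
    n = len(intervals)
    lines = []
    for (s, e), rank in zip(intervals, order):
        score = 1000 if n == 1 else int(round(1000 * rank / (n - 1)))
        lines.append(f"{name}\t{s}\t{e}\t{name}_rut_{s}\t{score}\t+")
    return lines
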