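"""Circular binary segmentation (CBS) of per-sample LRR tracks.

The segmenter follows the classical CBS recursion: on the circularized
probe sequence of each sample/chromosome, find the arc (i, j] that
maximizes the two-sample mean-difference statistic

    T(i, j) = |mean(arc) - mean(complement)| / sqrt(1/k + 1/(n-k))

(the pooled-SD factor is omitted — permutations of the same values share
it, so it cancels in the permutation test), accept the split when the
observed maximum exceeds the permutation null at level alpha, recurse on
both sides, and finally merge adjacent segments whose means differ by
less than ``undo_sd`` residual standard deviations.

Ties in the maximum statistic are broken toward the smallest arc start i,
then the smallest arc end j. Segment coordinates are the positions of the
first and last member probes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ConfigurationError, SegmentTable, ValidationError
from .preprocess import LRRTrack

logger = logging.getLogger(__name__)

_TIE_TOL = 1e-9
_EXACT_MERGE_TOL = 1e-12


@dataclass
class CbsParams:
    """Segmentation tuning knobs (DNAcopy-like defaults, desk-scale nperm)."""

    alpha: float = 0.01
    nperm: int = 1000
    min_width: int = 2
    undo_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.nperm < 100:
            raise ConfigurationError("nperm must be >= 100")
        if self.min_width < 2:
            raise ConfigurationError("min_width must be >= 2")


def _admissible(n: int, min_width: int):
    """Arc lengths and start positions whose linear cut pieces all hold
    at least ``min_width`` probes.

    An arc (i, i+k] on the circle cuts the linear sequence into up to
    three pieces; a cell is admissible when every nonempty piece has
    >= min_width members. Returned as (ks, valid[k_index, i]) and shared
    between the observed statistic and the permutation null so both
    maximize over the identical candidate set.
    """
    ks = np.arange(min_width, n - min_width + 1)
    if ks.size == 0:
        return ks, None
    I = np.arange(n)
    K = ks[:, None]
    E = I[None, :] + K  # arc end (may wrap past n)
    left = I[None, :]  # size of [0, i]
    right = n - E  # size of (i+k, n] when no wrap
    no_wrap = E <= n
    ok_nowrap = ((left == 0) | (left >= min_width)) & ((right == 0) | (right >= min_width))
    e2 = E - n  # wrapped arc tail length = size of [0, e2]
    ok_wrap = (e2 >= min_width) & ((n - I[None, :]) >= min_width)
    return ks, np.where(no_wrap, ok_nowrap, ok_wrap)


def _arc_stats(x: np.ndarray, ks: np.ndarray, valid: np.ndarray):
    """Full T matrix over admissible arcs (k rows, arc start i cols)."""
    n = x.size
    S = np.concatenate(([0.0], np.cumsum(x)))
    total = S[-1]
    SS = np.concatenate((S, total + S[1:]))  # circular prefix sums, length 2n+1
    I = np.arange(n)
    W = SS[I[None, :] + ks[:, None]] - SS[I[None, :]]
    k = ks[:, None].astype(float)
    T = np.abs(W / k - (total - W) / (n - k)) / np.sqrt(1.0 / k + 1.0 / (n - k))
    return np.where(valid, T, -np.inf)


def _best_arc(x: np.ndarray, min_width: int):
    """Maximal arc statistic with lexicographic (i, j) tie-breaking.

    Returns (tmax, changepoints) where changepoints is a sorted list of
    1..n-1 cut indices (between x[c-1] and x[c]), or (0.0, []) when no
    admissible arc exists.
    """
    n = x.size
    ks, valid = _admissible(n, min_width)
    if valid is None or not valid.any():
        return 0.0, []
    T = _arc_stats(x, ks, valid)
    tmax = float(T.max())
    if tmax <= 0.0:
        return 0.0, []
    cand = np.argwhere(T >= tmax - _TIE_TOL * max(1.0, tmax))
    arcs = [(int(i), int(i) + int(ks[r])) for r, i in cand]
    i, j = min(arcs)
    cps = sorted({i % n, j % n} - {0})
    return tmax, cps


def _perm_max_stats(perms: np.ndarray, ks: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Max admissible arc statistic per row of a [perm x n] matrix."""
    b, n = perms.shape
    S = np.concatenate((np.zeros((b, 1)), np.cumsum(perms, axis=1)), axis=1)
    total = S[:, -1:]
    SS = np.concatenate((S, total + S[:, 1:]), axis=1)
    I = np.arange(n)
    best = np.zeros(b)
    for r, k in enumerate(ks):
        cols = I[valid[r]]
        if cols.size == 0:
            continue
        W = SS[:, cols + k] - SS[:, cols]
        t = np.abs(W / k - (total - W) / (n - k)) / np.sqrt(1.0 / k + 1.0 / (n - k))
        np.maximum(best, t.max(axis=1), out=best)
    return best


def _split_significant(
    x: np.ndarray, tmax: float, params: CbsParams, rng: np.random.Generator
) -> bool:
    """Permutation test of the observed maximal arc statistic.

    p = (1 + #{perm max >= observed}) / (1 + nperm) <= alpha. Permutations
    are evaluated in batches and the scan stops as soon as the exceedance
    count already exceeds the acceptance bound — the decision is identical
    to evaluating all nperm permutations.
    """
    allowed = int(np.floor(params.alpha * (params.nperm + 1) - 1 + 1e-9))
    if allowed < 0:
        return False
    ks, valid = _admissible(x.size, params.min_width)
    exceed = 0
    done = 0
    batch = 200
    while done < params.nperm:
        b = min(batch, params.nperm - done)
        perms = rng.permuted(np.tile(x, (b, 1)), axis=1)
        stats = _perm_max_stats(perms, ks, valid)
        exceed += int(np.sum(stats >= tmax - _TIE_TOL))
        done += b
        if exceed > allowed:
            return False
    return True


def _segment_sequence(x: np.ndarray, params: CbsParams, rng: np.random.Generator) -> list[int]:
    """Recursive CBS on one sequence; returns sorted interior cut indices."""
    cuts: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        n = seg.size
        if n < 2 * params.min_width:
            return
        if np.ptp(seg) < _EXACT_MERGE_TOL:
            return
        tmax, cps = _best_arc(seg, params.min_width)
        if not cps:
            return
        if not _split_significant(seg, tmax, params, rng):
            return
        bounds = [0] + cps + [n]
        for c in cps:
            cuts.append(lo + c)
        for a, b in zip(bounds[:-1], bounds[1:]):
            recurse(lo + a, lo + b)

    recurse(0, x.size)
    return sorted(cuts)


def _undo_merge(x: np.ndarray, cuts: list[int], undo_sd: float) -> list[int]:
    """Merge adjacent segments whose means are closer than undo_sd * residual SD."""
    cuts = list(cuts)
    while cuts:
        bounds = [0] + cuts + [x.size]
        means = np.array([x[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])])
        fitted = np.repeat(means, np.diff(bounds))
        resid = x - fitted
        rsd = float(np.std(resid, ddof=1)) if x.size > 1 else 0.0
        diffs = np.abs(np.diff(means))
        thresh = undo_sd * rsd
        mergeable = (diffs < thresh) | (diffs <= _EXACT_MERGE_TOL)
        if not mergeable.any():
            break
        worst = int(np.argmin(np.where(mergeable, diffs, np.inf)))
        del cuts[worst]
    return cuts


def _emit_segments(
    rows: list, sample: str, chrom: str, pos: np.ndarray, x: np.ndarray, cuts: list[int]
) -> None:
    bounds = [0] + list(cuts) + [x.size]
    for a, b in zip(bounds[:-1], bounds[1:]):
        rows.append(
            (sample, chrom, int(pos[a]), int(pos[b - 1]), b - a, float(x[a:b].mean()), None)
        )


def cbs_segment(track: LRRTrack, params: CbsParams | None = None) -> SegmentTable:
    """Segment every sample/chromosome of an LRR track.

    Emits one row per segment with ``num_mark`` (unmasked member probes),
    ``seg_mean`` (arithmetic mean of member LRRs) and probe-supported
    coordinates; segments tile all unmasked probes. Identical
    (track, params) inputs reproduce identical output (permutation RNG
    streams are derived from ``params.seed`` per sample/chromosome).
    """
    params = params or CbsParams()
    params.validate()
    rows: list = []
    positions = track.manifest.df["pos"].to_numpy()
    for si, sample in enumerate(track.sample_names):
        for ci, chrom in enumerate(track.manifest.chroms):
            ridx = track.manifest.chrom_rows(chrom)
            ok = ~track.mask[ridx, si]
            x = track.values[ridx, si][ok]
            pos = positions[ridx][ok]
            if x.size == 0:
                continue
            if not np.all(np.isfinite(x)):
                raise ValidationError(f"non-finite unmasked LRR in {sample}/{chrom}")
            if x.size < params.min_width:
                _emit_segments(rows, sample, chrom, pos, x, [])
                continue
            rng = np.random.default_rng(
                np.random.SeedSequence(params.seed, spawn_key=(si, ci))
            )
            cuts = _segment_sequence(x, params, rng)
            cuts = _undo_merge(x, cuts, params.undo_sd)
            _emit_segments(rows, sample, chrom, pos, x, cuts)
    df = pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "num_mark", "seg_mean", "state"])
    return SegmentTable(
        df,
        provenance={
            "routine": "cbs",
            "alpha": params.alpha,
            "nperm": params.nperm,
            "min_width": params.min_width,
            "undo_sd": params.undo_sd,
            "seed": params.seed,
        },
    )


# ---------------------------------------------------------------------------
# Exhaustive oracle
# ---------------------------------------------------------------------------

MAX_BRUTE_FORCE = 60


def _best_partition(x: np.ndarray, max_segments: int) -> list[int]:
    """Exhaustive least-squares partition; smallest segment count wins ties.

    Dynamic program over all breakpoint placements with at most
    ``max_segments`` pieces, minimizing the residual sum of squares.
    Among placements within 1e-10 of the optimum, the one with the fewest
    segments (then lexicographically smallest breakpoints) is returned.
    """
    n = x.size
    S = np.concatenate(([0.0], np.cumsum(x)))
    S2 = np.concatenate(([0.0], np.cumsum(x * x)))

    def cost(i: int, j: int) -> float:
        s = S[j] - S[i]
        return float(S2[j] - S2[i] - s * s / (j - i))

    m_max = min(max_segments, n)
    D = np.full((m_max + 1, n + 1), np.inf)
    B = np.zeros((m_max + 1, n + 1), dtype=int)
    D[0, 0] = 0.0
    for m in range(1, m_max + 1):
        for j in range(m, n + 1):
            best, arg = np.inf, -1
            for i in range(m - 1, j):
                if not np.isfinite(D[m - 1, i]):
                    continue
                cand = D[m - 1, i] + cost(i, j)
                if cand < best - 1e-12:
                    best, arg = cand, i
            D[m, j], B[m, j] = best, arg
    overall = float(np.min(D[1:, n]))
    for m in range(1, m_max + 1):
        if D[m, n] <= overall + 1e-10:
            break
    cuts = []
    j = n
    for mm in range(m, 0, -1):
        i = int(B[mm, j])
        if i > 0:
            cuts.append(i)
        j = i
    return sorted(cuts)


def brute_force_segment(track: LRRTrack, max_segments: int) -> SegmentTable:
    """Exhaustive least-squares segmentation (test oracle, <= 60 probes/chrom)."""
    rows: list = []
    positions = track.manifest.df["pos"].to_numpy()
    for si, sample in enumerate(track.sample_names):
        for chrom in track.manifest.chroms:
            ridx = track.manifest.chrom_rows(chrom)
            ok = ~track.mask[ridx, si]
            x = track.values[ridx, si][ok]
            pos = positions[ridx][ok]
            if x.size == 0:
                continue
            if x.size > MAX_BRUTE_FORCE:
                raise ValidationError(
                    f"brute_force_segment instance too large ({x.size} probes > {MAX_BRUTE_FORCE})"
                )
            cuts = _best_partition(x, max_segments)
            _emit_segments(rows, sample, chrom, pos, x, cuts)
    df = pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "num_mark", "seg_mean", "state"])
    return SegmentTable(df, provenance={"routine": "brute_force", "max_segments": max_segments})
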