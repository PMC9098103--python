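"""Shared fixtures-by-function and independent oracles for the test suite.

The oracles here deliberately re-derive expected values by brute force
(per-base sets, exhaustive enumeration, dense numeric density scans) so
they stay independent of the library code paths they check.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from methylcnv.core import ProbeManifest, SegmentTable
from methylcnv.preprocess import LRRTrack


def make_manifest(n: int, chrom: str = "chr1", spacing: int = 1000,
                  design: str = "typeII", arm: str | None = None) -> ProbeManifest:
    arm = arm or f"{chrom[3:]}p"
    return ProbeManifest(
        pd.DataFrame(
            {
                "probe_id": [f"{chrom}_p{i}" for i in range(n)],
                "chrom": chrom,
                "pos": np.arange(1, n + 1) * spacing,
                "design": design,
                "arm": arm,
            }
        )
    )


def make_track(values, chrom: str = "chr1", mask=None, sample: str = "S1") -> LRRTrack:
    x = np.asarray(values, dtype=float)[:, None]
    n = len(x)
    m = np.zeros((n, 1), dtype=bool) if mask is None else np.asarray(mask, bool)[:, None]
    return LRRTrack(make_manifest(n, chrom), x, m, [sample])


def segments_frame(rows) -> pd.DataFrame:
    """rows of (sample, chrom, start, end, num_mark, seg_mean, state)."""
    return pd.DataFrame(
        rows, columns=["sample", "chrom", "start", "end", "num_mark", "seg_mean", "state"]
    )


# ---------------------------------------------------------------------------
# Interval oracles: explicit per-base sets
# ---------------------------------------------------------------------------

def base_set(intervals) -> set[tuple[str, int]]:
    """Every (chrom, base) covered by a (chrom, start, end) frame — closed."""
    df = intervals.df if isinstance(intervals, SegmentTable) else pd.DataFrame(intervals)
    out: set[tuple[str, int]] = set()
    for chrom, s, e in zip(df["chrom"], df["start"], df["end"]):
        out.update((chrom, b) for b in range(int(s), int(e) + 1))
    return out


def oracle_count_overlaps(query, subject) -> int:
    sub = base_set(subject)
    df = pd.DataFrame(query)
    n = 0
    for chrom, s, e in zip(df["chrom"], df["start"], df["end"]):
        if any((chrom, b) in sub for b in range(int(s), int(e) + 1)):
            n += 1
    return n


def oracle_union_count(a, b) -> int:
    """Number of disjoint runs in the base-set union (closed-interval merge)."""
    bases = base_set(a) | base_set(b)
    count = 0
    for chrom in {c for c, _ in bases}:
        pos = sorted(p for c, p in bases if c == chrom)
        count += 1 + sum(1 for i in range(1, len(pos)) if pos[i] != pos[i - 1] + 1)
    return count


def oracle_recall(calls_df, n_df, t_df, mode: str):
    """ON/OT/ONT/TR/recall from explicit per-base sets."""
    from methylcnv.postprocess import is_neutral_state

    if mode == "state_matched":
        neutral = calls_df[calls_df["state"].map(is_neutral_state)]
        nonneutral = calls_df[~calls_df["state"].map(is_neutral_state)]
        ON = oracle_count_overlaps(n_df, neutral) if len(neutral) else 0
        OT = oracle_count_overlaps(t_df, nonneutral) if len(nonneutral) else 0
    else:
        ON = oracle_count_overlaps(n_df, calls_df) if len(calls_df) else 0
        OT = oracle_count_overlaps(t_df, calls_df) if len(calls_df) else 0
    ONT = oracle_count_overlaps(t_df, n_df)
    TR = oracle_union_count(n_df, t_df)
    recall = min(1.0, max(0.0, (ON + (OT - ONT)) / TR))
    return ON, OT, ONT, TR, recall


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=400, max_len=80) -> pd.DataFrame:
    rows = []
    for _ in range(n):
        chrom = rng.choice(chroms)
        s = int(rng.integers(1, span))
        e = s + int(rng.integers(0, max_len))
        rows.append((chrom, s, e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# Density-mode oracle: direct mixture evaluation + golden-section refine
# ---------------------------------------------------------------------------

def oracle_weighted_kde_mode(x, w, gridsize: int = 100_001, pad: float = 0.5) -> float:
    """Mode of the mark-weighted Gaussian mixture, by dense scan.

    Uses the same Silverman bandwidth rule the library documents but an
    independent dense-grid evaluation via scipy's normal pdf.
    """
    x = np.asarray(x, float)
    w = np.asarray(w, float)
    mu = np.average(x, weights=w)
    sd = np.sqrt(np.average((x - mu) ** 2, weights=w))
    order = np.argsort(x)
    cw = np.cumsum(w[order])
    q25 = np.interp(0.25 * cw[-1], cw, x[order])
    q75 = np.interp(0.75 * cw[-1], cw, x[order])
    iqr = q75 - q25
    neff = w.sum() ** 2 / (w ** 2).sum()
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    h = 0.9 * spread * neff ** (-0.2)
    if h <= 0:
        h = max(sd, 1e-3) * neff ** (-0.2)
    grid = np.linspace(x.min() - pad, x.max() + pad, gridsize)
    dens = (w[None, :] * sps.norm.pdf(grid[:, None], loc=x[None, :], scale=h)).sum(axis=1)
    return float(grid[np.argmax(dens)])


# ---------------------------------------------------------------------------
# Noise-free piecewise-constant track generator (segmentation oracle regime)
# ---------------------------------------------------------------------------

def random_step_track(rng, max_breakpoints: int = 2, min_piece: int = 8,
                      n_range=(24, 61)):
    """Noise-free staircase with pieces wide enough (>= min_piece probes)
    that the CBS permutation p-value of every true split is far below
    alpha, i.e. the regime where segmentation is deterministic."""
    nb = int(rng.integers(0, max_breakpoints + 1))
    n = int(rng.integers(*n_range))
    while True:
        if nb:
            cuts = sorted(rng.choice(np.arange(min_piece, n - min_piece + 1), size=nb, replace=False))
        else:
            cuts = []
        widths = np.diff([0] + list(cuts) + [n])
        if (widths >= min_piece).all():
            break
    levels = [0.0]
    for _ in range(nb):
        levels.append(levels[-1] + rng.uniform(0.4, 1.5) * rng.choice([-1.0, 1.0]))
    return np.repeat(levels, widths), cuts
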