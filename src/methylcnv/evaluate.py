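"""Recall benchmarking against gold-standard segment sets.

The benchmark statistic treats a high-density SNP-array segmentation as
truth, split into a normal reference N (copy-neutral segments) and a
tumor reference T (aberrant segments):

    R = (ON + (OT - ONT)) / TR

where ON is the number of N segments overlapping a call by >= 1 base
(true negatives), OT the same for T (true positives before correction),
ONT the number of T segments overlapping N (subtracted so that true
negatives are prioritized), and TR the number of disjoint intervals in
the merged union of N and T. All intervals are 1-based and fully closed,
so abutting intervals share no base but a union merges them.

Two modes are reported side by side: ``literal`` counts overlaps against
all calls exactly as the formula reads, while ``state_matched`` (default)
requires N segments to overlap neutral calls and T segments to overlap
non-neutral calls, which is what makes the TN/TP reading of ON/OT
coherent.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ConfigurationError, ProbeManifest, SegmentTable, ValidationError
from .postprocess import is_neutral_state

logger = logging.getLogger(__name__)

INTERVAL_COLUMNS = ("chrom", "start", "end")


def as_intervals(obj) -> pd.DataFrame:
    """Coerce a SegmentTable or frame-like into a (chrom, start, end) frame."""
    if isinstance(obj, SegmentTable):
        df = obj.df
    else:
        df = pd.DataFrame(obj)
    missing = [c for c in INTERVAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"interval collection missing column(s): {missing}")
    out = df.loc[:, list(INTERVAL_COLUMNS)].copy().reset_index(drop=True)
    out["start"] = out["start"].astype(np.int64)
    out["end"] = out["end"].astype(np.int64)
    if (out["start"] > out["end"]).any() or (out["start"] < 1).any():
        raise ValidationError("malformed interval (start > end or start < 1)")
    return out


@dataclass
class ReferenceSet:
    """Gold-standard normal (N) and tumor (T) interval collections."""

    N: pd.DataFrame
    T: pd.DataFrame
    provenance: str = ""

    def __post_init__(self):
        self.N = as_intervals(self.N) if len(self.N) else _empty_intervals()
        self.T = as_intervals(self.T) if len(self.T) else _empty_intervals()


def _empty_intervals() -> pd.DataFrame:
    return pd.DataFrame({"chrom": pd.Series(dtype=str), "start": pd.Series(dtype=np.int64), "end": pd.Series(dtype=np.int64)})


@dataclass
class RecallResult:
    ON: int
    OT: int
    ONT: int
    TR: int
    recall: float
    mode: str


def count_overlaps(query, subject) -> int:
    """Number of query intervals overlapping >= 1 subject interval.

    Overlap means sharing at least one base on the same chromosome
    (closed-interval semantics: chr1:100-200 and chr1:200-300 overlap at
    base 200). Each query interval is counted at most once.
    """
    q = as_intervals(query)
    s = as_intervals(subject)
    if len(q) == 0 or len(s) == 0:
        return 0
    count = 0
    for chrom, qg in q.groupby("chrom", sort=False):
        sg = s[s["chrom"] == chrom]
        if len(sg) == 0:
            continue
        ss = sg["start"].to_numpy()
        se = sg["end"].to_numpy()
        order = np.argsort(ss)
        ss, se = ss[order], se[order]
        run_max_end = np.maximum.accumulate(se)
        for qs, qe in zip(qg["start"].to_numpy(), qg["end"].to_numpy()):
            # candidate subjects with start <= qe; any of them ending >= qs?
            k = np.searchsorted(ss, qe, side="right")
            if k > 0 and run_max_end[k - 1] >= qs:
                count += 1
    return count


def range_union(a, b) -> pd.DataFrame:
    """Minimal set of disjoint closed intervals covering the union of a and b.

    Closed-interval adjacency merges: {100-200} u {201-300} -> {100-300}.
    """
    both = pd.concat([as_intervals(a), as_intervals(b)], ignore_index=True)
    rows = []
    for chrom in pd.unique(both["chrom"]):
        g = both[both["chrom"] == chrom].sort_values(["start", "end"])
        cur_s = cur_e = None
        for s, e in zip(g["start"], g["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e + 1:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=list(INTERVAL_COLUMNS)) if rows else _empty_intervals()


def compute_recall(
    calls: SegmentTable, ref: ReferenceSet, mode: str = "state_matched"
) -> RecallResult:
    """Recall of a call set against a normal/tumor reference pair.

    ``state_matched`` counts ON against neutral-state calls only and OT
    against non-neutral calls only; ``literal`` counts both against all
    calls. ONT is a property of the reference pair alone. The recall is
    clamped to [0, 1], with a warning when OT - ONT is negative.
    """
    if mode not in ("state_matched", "literal"):
        raise ConfigurationError(f"unknown recall mode {mode!r}")
    tr_frame = range_union(ref.N, ref.T)
    TR = len(tr_frame)
    if TR == 0:
        raise ValidationError("empty reference set (TR = 0)")
    df = calls.df
    if mode == "state_matched":
        if df["state"].isna().any():
            raise ValidationError("state_matched recall requires state-called segments")
        neutral = df[df["state"].map(is_neutral_state).astype(bool)]
        nonneutral = df[~df["state"].map(is_neutral_state).astype(bool)]
        ON = count_overlaps(ref.N, neutral) if len(neutral) else 0
        OT = count_overlaps(ref.T, nonneutral) if len(nonneutral) else 0
    else:
        ON = count_overlaps(ref.N, df) if len(df) else 0
        OT = count_overlaps(ref.T, df) if len(df) else 0
    ONT = count_overlaps(ref.T, ref.N)
    if OT - ONT < 0:
        logger.warning("OT - ONT = %d is negative; recall clamped at 0", OT - ONT)
    recall = float(np.clip((ON + (OT - ONT)) / TR, 0.0, 1.0))
    return RecallResult(ON, OT, ONT, TR, recall, mode)


def reference_from_gold(gold: SegmentTable, sample: str, provenance: str = "synthetic_gold") -> ReferenceSet:
    """Build a per-sample ReferenceSet from a state-annotated gold table.

    Neutral gold segments of the sample form N; non-neutral segments form
    T — the per-sample analogue of pairing tumor SNP segments with
    normal-adjacent ones.
    """
    g = gold.df[gold.df["sample"] == sample]
    if len(g) == 0:
        raise ValidationError(f"sample {sample!r} absent from gold standard")
    neutral = g[g["state"].map(is_neutral_state).astype(bool)]
    aberrant = g[~g["state"].map(is_neutral_state).astype(bool)]
    return ReferenceSet(N=neutral, T=aberrant, provenance=provenance)


def cohort_recall(
    calls: SegmentTable, gold: SegmentTable, mode: str = "state_matched"
) -> pd.DataFrame:
    """Per-sample recall for every call sample present in the gold table.

    Samples whose gold rows contain no aberrant segment contribute only
    when N is nonempty (TR > 0 always holds per sample here since the
    gold tiling covers every arm).
    """
    rows = []
    for sample in calls.samples:
        ref = reference_from_gold(gold, sample)
        res = compute_recall(calls.for_sample(sample), ref, mode)
        rows.append((sample, res.ON, res.OT, res.ONT, res.TR, res.recall, res.mode))
    return pd.DataFrame(rows, columns=["sample", "ON", "OT", "ONT", "TR", "recall", "mode"])


# ---------------------------------------------------------------------------
# Large-scale-event reference classification
# ---------------------------------------------------------------------------

def classify_reference_samples(
    gold: SegmentTable,
    manifest: ProbeManifest,
    arms: tuple[str, ...] = ("1p", "19q"),
    mark_min: int = 10_000,
    loss_cut: float = -0.2,
    gain_cut: float = 0.2,
) -> dict[str, str]:
    """Label samples tumor_ref / normal_ref / unclassified by arm-level CNVs.

    Per segment, the copy state is 1 when mean <= loss_cut, 3 when
    mean >= gain_cut, else 2. A sample is ``tumor_ref`` when every
    required arm harbors a state-1 segment with more than ``mark_min``
    marks (a large-scale deletion on both arms, e.g. a 1p/19q
    codeletion); ``normal_ref`` when every required arm instead meets the
    mark condition with a state-2 segment and no qualifying state-1
    segment exists on the required arms; anything else is unclassified.
    Arm membership is decided by the segment midpoint.
    """
    known_arms = set(manifest.df["arm"])
    for arm in arms:
        if arm not in known_arms:
            raise ConfigurationError(f"arm {arm!r} not present in manifest")
    labels: dict[str, str] = {}
    for sample, g in gold.df.groupby("sample", sort=False):
        mid = ((g["start"] + g["end"]) // 2).to_numpy()
        seg_arm = [manifest.arm_of(c, m) for c, m in zip(g["chrom"], mid)]
        means = g["seg_mean"].to_numpy()
        marks = g["num_mark"].to_numpy()
        state = np.where(means <= loss_cut, 1, np.where(means >= gain_cut, 3, 2))
        big = marks > mark_min
        arm_has_loss = {a: False for a in arms}
        arm_has_neutral = {a: False for a in arms}
        for a, st, b in zip(seg_arm, state, big):
            if a in arm_has_loss and b:
                if st == 1:
                    arm_has_loss[a] = True
                elif st == 2:
                    arm_has_neutral[a] = True
        if all(arm_has_loss.values()):
            labels[str(sample)] = "tumor_ref"
        elif all(arm_has_neutral.values()) and not any(arm_has_loss.values()):
            labels[str(sample)] = "normal_ref"
        else:
            labels[str(sample)] = "unclassified"
    return labels
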