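"""Route presets tying the stages together, plus run records and exports.

Four presets mirror the computational skeletons of the common
methylation CNV callers:

``standard``
    background -> dye bias -> masking -> median-of-controls reference ->
    LRR -> CBS -> threshold states (single-sample route).
``zscore``
    same preprocessing, then tumor and control copy-number signals are
    z-transformed per sample, the per-probe median of control z-scores is
    subtracted from each tumor z-track, each difference track is
    median-centered, and the result is segmented (control-cohort route).
``standard_median_ref``
    standard route against the cohort-median internal reference — needs
    no control samples (internal-reference route).
``custom``
    the standard route plus density-peak baseline autocorrection of the
    segment means before state calling.
"""
from __future__ import annotations

import json
import logging
import time
import tracemalloc
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    ConfigurationError,
    IntensityCohort,
    SampleSheet,
    SegmentTable,
    write_segments,
)
from .postprocess import (
    ConsensusRegion,
    StateCallParams,
    autocorrect_baseline,
    call_states,
    consensus_regions,
    consensus_to_frame,
)
from .preprocess import (
    background_correct,
    build_reference,
    compute_lrr,
    copy_number_signal,
    dye_bias_correct,
    mask_probes,
    zscore_transform,
)
from .segmentation import CbsParams, cbs_segment

logger = logging.getLogger(__name__)

ROUTES = ("standard", "zscore", "standard_median_ref", "custom")


@dataclass
class RunConfig:
    """Full run configuration; serializes losslessly to/from YAML."""

    route: str = "standard"
    reference_mode: str | None = None  # default chosen by route
    mask_p: float = 0.05
    cbs: CbsParams = field(default_factory=CbsParams)
    states: StateCallParams = field(default_factory=StateCallParams)
    consensus_density: float = 0.1
    consensus_rho: float = 0.5
    est_recur: bool = True
    autocorrect_weighted: bool = True
    seed: int = 0
    outdir: str | None = None

    def validate(self) -> None:
        if self.route not in ROUTES:
            raise ConfigurationError(f"unknown route {self.route!r}")
        self.cbs.validate()
        self.states.validate()

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cbs" in d and isinstance(d["cbs"], dict):
            d["cbs"] = CbsParams(**d["cbs"])
        if "states" in d and isinstance(d["states"], dict):
            d["states"] = StateCallParams(**d["states"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class PerfRecord:
    """Wall time / peak memory per run; recorded, never asserted on."""

    route: str
    wall_time_s: float
    peak_memory_mb: float
    n_samples: int
    n_probes: int


@dataclass
class PipelineResult:
    segments: SegmentTable
    consensus: list[ConsensusRegion]
    perf: PerfRecord


def _stage(log: list, name: str, **info) -> None:
    rec = {"stage": name, **info}
    log.append(rec)
    logger.info("stage %s: %s", name, info)


def run_pipeline(
    config: RunConfig, sheet: SampleSheet, cohort: IntensityCohort
) -> PipelineResult:
    """Execute one route preset end to end.

    Tumor samples are segmented against the route's reference; outputs
    (common-format segment CSV, consensus CSV, perf record, config
    snapshot, stage log) are written to ``config.outdir`` when set.
    Identical (config, seed, inputs) reproduce identical outputs.
    """
    config.validate()
    tumors = sheet.tumors
    if not tumors:
        raise ConfigurationError("at least one tumor sample is required")
    needs_controls = config.route in ("standard", "zscore", "custom") and (
        config.reference_mode in (None, "median_controls", "pooled_controls")
    )
    if needs_controls and not sheet.controls:
        raise ConfigurationError(
            f"route {config.route!r} requires control samples (none in sheet)"
        )
    t0 = time.perf_counter()
    tracemalloc.start()
    stage_log: list[dict] = []
    try:
        c = background_correct(cohort)
        _stage(stage_log, "background_correct", n_probes=c.manifest.n_probes)
        c = dye_bias_correct(c)
        _stage(stage_log, "dye_bias_correct")
        c = mask_probes(c, config.mask_p)
        _stage(stage_log, "mask_probes", p_threshold=config.mask_p, n_masked=int(c.mask.sum()))

        cbs_params = replace(config.cbs, seed=config.seed)
        if config.route == "zscore":
            track = _zscore_track(c, sheet, tumors)
            refmode = "median_controls"
        else:
            refmode = config.reference_mode or (
                "cohort_median" if config.route == "standard_median_ref" else "median_controls"
            )
            ref = build_reference(c, sheet, refmode)
            track = compute_lrr(c, ref, samples=tumors, route="standard", reference_mode=refmode)
        _stage(stage_log, "track", route=config.route, reference_mode=refmode,
               shape=list(track.values.shape))

        segments = cbs_segment(track, cbs_params)
        _stage(stage_log, "cbs_segment", n_segments=len(segments))
        if config.route == "custom":
            segments = autocorrect_baseline(segments, weighted=config.autocorrect_weighted)
            _stage(stage_log, "autocorrect_baseline", weighted=config.autocorrect_weighted)
        called = call_states(segments, config.states)
        called.provenance.update(route=config.route, reference_mode=refmode, seed=config.seed)
        _stage(stage_log, "call_states", mode=config.states.mode)

        consensus: list[ConsensusRegion] = []
        if len(tumors) >= 2 and len(called):
            consensus = consensus_regions(
                called,
                density=config.consensus_density,
                rho=config.consensus_rho,
                est_recur=config.est_recur,
            )
            _stage(stage_log, "consensus_regions", n_regions=len(consensus))
    finally:
        _, peak = tracemalloc.get_traced_memory()
        tracemalloc.stop()
    perf = PerfRecord(
        route=config.route,
        wall_time_s=time.perf_counter() - t0,
        peak_memory_mb=peak / 2**20,
        n_samples=cohort.n_samples,
        n_probes=cohort.manifest.n_probes,
    )
    if config.outdir:
        _write_outputs(config, called, consensus, perf, stage_log)
    return PipelineResult(called, consensus, perf)


def _zscore_track(c: IntensityCohort, sheet: SampleSheet, tumors: list[str]):
    controls = sheet.controls
    tumor_track = zscore_transform(copy_number_signal(c, tumors))
    control_track = zscore_transform(copy_number_signal(c, controls))
    ctrl = control_track.values.copy()
    ctrl[control_track.mask] = np.nan
    with np.errstate(all="ignore"):
        ref = np.nanmedian(ctrl, axis=1)
    out = tumor_track.copy()
    out.mask |= ~np.isfinite(ref)[:, None]
    out.values = out.values - ref[:, None]
    for j in range(out.values.shape[1]):
        ok = ~out.mask[:, j]
        out.values[ok, j] -= np.median(out.values[ok, j])  # per-sample centering
    out.values[out.mask] = np.nan
    return out


def _write_outputs(config, called, consensus, perf, stage_log) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_segments(called, outdir / "segments.csv")
    consensus_to_frame(consensus).to_csv(outdir / "consensus.csv", index=False)
    config.to_yaml(outdir / "config.yaml")
    with open(outdir / "perf.json", "w") as fh:
        json.dump(asdict(perf), fh, indent=2)
    with open(outdir / "run_log.jsonl", "w") as fh:
        for rec in stage_log:
            fh.write(json.dumps(rec) + "\n")


# ---------------------------------------------------------------------------
# State-matrix export
# ---------------------------------------------------------------------------

_STATE_CODES = {"loss": -1, "neutral": 0, "gain": 1}
MISSING_SENTINEL = ""


def export_state_matrix(
    tables: SegmentTable | list[SegmentTable], bin_size: int
) -> pd.DataFrame:
    """[sample x genomic bin] matrix of state codes for heatmap rendering.

    Bins are ``bin_size`` bp wide, tiled per chromosome from the smallest
    segment start; each bin takes the state of the segment covering its
    midpoint (-1 loss / 0 neutral / +1 gain, or the integer copy number
    in formula mode). Uncovered bins hold the empty-string sentinel.
    """
    if bin_size <= 0:
        raise ConfigurationError("bin_size must be > 0")
    if isinstance(tables, SegmentTable):
        df = tables.df
    else:
        df = pd.concat([t.df for t in tables], ignore_index=True)
    samples = list(pd.unique(df["sample"]))
    columns: list[str] = []
    mids: list[tuple[str, int]] = []
    for chrom in pd.unique(df["chrom"]):
        g = df[df["chrom"] == chrom]
        lo, hi = int(g["start"].min()), int(g["end"].max())
        b = lo
        while b <= hi:
            e = b + bin_size - 1
            columns.append(f"{chrom}:{b}-{e}")
            mids.append((chrom, b + bin_size // 2))
            b += bin_size
    mat = pd.DataFrame(MISSING_SENTINEL, index=samples, columns=columns, dtype=object)
    for sample in samples:
        g = df[df["sample"] == sample]
        for col, (chrom, mid) in zip(columns, mids):
            hit = g[(g["chrom"] == chrom) & (g["start"] <= mid) & (g["end"] >= mid)]
            if len(hit):
                state = hit["state"].iat[0]
                mat.at[sample, col] = _STATE_CODES.get(state, state)
    mat.index.name = "sample"
    return mat
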