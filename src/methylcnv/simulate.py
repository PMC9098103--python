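"""Synthetic intensity cohorts with known implanted copy-number truth.

The generator emulates the two large-scale lesion classes the pipeline is
aimed at: deep deletion of chromosome arm 3p (the hallmark of clear cell
renal cell carcinoma) and joint loss of arms 1p and 19q (the molecular
definition of classical oligodendroglioma), plus copy-neutral controls.

Intensity model
---------------
Each probe draws a log-normal baseline intensity once per manifest, shared
across samples. The expected total intensity of probe p in sample s is

    I[p, s] = baseline[p] * (CN[p, s] / 2) * 2**eps,   eps ~ N(0, noise_sd)

split into methylated/unmethylated channels by a per-probe methylation
fraction drawn Uniform(0.1, 0.9) — a free nuisance parameter, since the
copy-number signal is the combined channel intensity. Red-channel
measurements (unmethylated for type II probes, both alleles for type I
red probes, plus red out-of-band background) are scaled by a
multiplicative dye-bias factor, and every in-band measurement carries an
additive exponential background whose mean is ``background_level``.

Coordinates are synthetic: probes sit on a regular grid and arm
boundaries fall at the midpoint of each chromosome. Only arm-level
semantics matter to the methods under test.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    ConfigurationError,
    DESIGNS,
    IntensityCohort,
    ProbeManifest,
    SampleSheet,
    SegmentTable,
    ValidationError,
)

logger = logging.getLogger(__name__)

SCENARIOS = ("kirc_3p", "oligo_1p19q", "neutral")

#: seg_mean written to the gold standard for homozygous (CN=0) events,
#: standing in for log2(0/2) = -inf.
DEEP_LOSS_LRR = -5.0


@dataclass(frozen=True)
class TruthEvent:
    """A single implanted copy-number event (copy_number != 2)."""

    sample: str
    chrom: str
    start: int
    end: int
    copy_number: int

    def __post_init__(self):
        if self.copy_number == 2 or self.copy_number < 0:
            raise ValidationError("truth events must have copy_number >= 0 and != 2")
        if self.start > self.end or self.start < 1:
            raise ValidationError("truth event coordinates invalid")


@dataclass
class SimConfig:
    """Cohort-generation parameters.

    ``noise_sd`` is per-observation log2 noise; the default 0.25 makes
    segment detection nontrivial but reliable for arm-scale events.
    ``baseline_offset`` (log2 units) is applied to all tumor samples to
    exercise the baseline-autocorrection stage. ``gold_mark_spacing`` sets
    the SNP-array-like marker density (bp per mark) used for gold-standard
    ``num_mark`` values, so arm-scale events carry mark counts on the
    scale of real high-density SNP segments.
    """

    n_tumor: int = 10
    n_control: int = 5
    probes_per_chrom: int = 200
    chroms: tuple[str, ...] = ("chr1", "chr2", "chr3", "chr19")
    probe_spacing: int = 10_000
    baseline_log2_mean: float = 11.0
    baseline_log2_sd: float = 0.5
    noise_sd: float = 0.25
    dye_bias: float = 1.0
    background_level: float = 100.0
    baseline_offset: float = 0.0
    deletion_cn: int = 1
    gold_mark_spacing: int = 75
    seed: int = 0

    def validate(self) -> None:
        if self.n_tumor < 1 or self.n_control < 0 or self.probes_per_chrom < 2:
            raise ConfigurationError("counts must be positive")
        if self.noise_sd < 0 or self.baseline_log2_sd < 0:
            raise ConfigurationError("noise SDs must be >= 0")
        if self.dye_bias <= 0:
            raise ConfigurationError("dye_bias must be > 0")
        if self.deletion_cn not in (0, 1):
            raise ConfigurationError("deletion_cn must be 0 or 1")
        if not np.isfinite(self.baseline_offset):
            raise ConfigurationError("baseline_offset must be finite")


def _arm_labels(chrom: str, n: int) -> list[str]:
    stem = chrom[3:] if chrom.startswith("chr") else chrom
    half = n // 2
    return [f"{stem}p"] * half + [f"{stem}q"] * (n - half)


def build_manifest(config: SimConfig, rng: np.random.Generator) -> ProbeManifest:
    """Regular-grid manifest with midpoint arm boundaries and random designs."""
    rows = []
    for chrom in config.chroms:
        n = config.probes_per_chrom
        arms = _arm_labels(chrom, n)
        designs = rng.choice(DESIGNS, size=n, p=[0.2, 0.2, 0.6])
        for i in range(n):
            rows.append(
                (
                    f"cg_{chrom}_{i:05d}",
                    chrom,
                    (i + 1) * config.probe_spacing,
                    designs[i],
                    arms[i],
                )
            )
    return ProbeManifest(
        pd.DataFrame(rows, columns=["probe_id", "chrom", "pos", "design", "arm"])
    )


def _scenario_arms(config: SimConfig, scenario: str) -> list[tuple[str, int]]:
    if scenario == "kirc_3p":
        return [("3p", config.deletion_cn)]
    if scenario == "oligo_1p19q":
        return [("1p", 1), ("19q", 1)]
    if scenario == "neutral":
        return []
    raise ConfigurationError(f"unknown scenario {scenario!r}")


def _gold_marks(config: SimConfig, start: int, end: int) -> int:
    return max(1, (end - start + 1) // config.gold_mark_spacing)


def _gold_standard(
    config: SimConfig,
    manifest: ProbeManifest,
    samples: list[str],
    events: list[TruthEvent],
) -> SegmentTable:
    """One row per truth event plus neutral rows tiling every other arm."""
    by_sample: dict[str, dict[tuple[str, int, int], int]] = {}
    for ev in events:
        by_sample.setdefault(ev.sample, {})[(ev.chrom, ev.start, ev.end)] = ev.copy_number
    rows = []
    arm_order = list(pd.unique(manifest.df["arm"]))
    extents = {arm: manifest.arm_extent(arm) for arm in arm_order}
    for sample in samples:
        evmap = by_sample.get(sample, {})
        for arm in arm_order:
            chrom, a1, a2 = extents[arm]
            cn = evmap.get((chrom, a1, a2))
            if cn is None:
                mean, state = 0.0, "neutral"
            else:
                mean = DEEP_LOSS_LRR if cn == 0 else float(np.log2(cn / 2.0))
                state = "loss" if mean <= -0.2 else ("gain" if mean >= 0.2 else "neutral")
            rows.append((sample, chrom, a1, a2, _gold_marks(config, a1, a2), mean, state))
    df = pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "num_mark", "seg_mean", "state"])
    return SegmentTable(df, provenance={"routine": "synthetic_gold"})


def simulate_cohort(
    config: SimConfig, scenario: str
) -> tuple[IntensityCohort, SampleSheet, list[TruthEvent], SegmentTable]:
    """Generate a cohort with implanted truth for one lesion scenario.

    Returns the intensity cohort, its sample sheet, the list of truth
    events (empty for the neutral scenario) and a gold-standard segment
    table with one row per event plus neutral rows tiling every other arm.
    Identical (config, scenario) inputs reproduce identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    manifest = build_manifest(config, rng)
    tumors = [f"T{i + 1:02d}" for i in range(config.n_tumor)]
    controls = [f"C{i + 1:02d}" for i in range(config.n_control)]
    samples = tumors + controls

    events: list[TruthEvent] = []
    arm_cns = _scenario_arms(config, scenario)
    for sample in tumors:
        for arm, cn in arm_cns:
            chrom, a1, a2 = manifest.arm_extent(arm)  # raises ConfigurationError
            events.append(TruthEvent(sample, chrom, a1, a2, cn))

    n, s = manifest.n_probes, len(samples)
    cn = np.full((n, s), 2.0)
    pos = manifest.df["pos"].to_numpy()
    chrom_col = manifest.df["chrom"].to_numpy()
    col = {name: j for j, name in enumerate(samples)}
    for ev in events:
        rows = (chrom_col == ev.chrom) & (pos >= ev.start) & (pos <= ev.end)
        cn[rows, col[ev.sample]] = ev.copy_number

    baseline = 2.0 ** rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n)
    frac = rng.uniform(0.1, 0.9, n)
    noise = 2.0 ** rng.normal(0.0, config.noise_sd, (n, s)) if config.noise_sd > 0 else 1.0
    offset_fac = np.ones(s)
    if config.baseline_offset != 0.0:
        offset_fac[: len(tumors)] = 2.0 ** config.baseline_offset
    total = baseline[:, None] * (cn / 2.0) * noise * offset_fac[None, :]

    bg_meth = rng.exponential(config.background_level, (n, s)) if config.background_level > 0 else np.zeros((n, s))
    bg_unmeth = rng.exponential(config.background_level, (n, s)) if config.background_level > 0 else np.zeros((n, s))
    bg_oob = rng.exponential(config.background_level, (n, s)) if config.background_level > 0 else np.zeros((n, s))

    design = manifest.df["design"].to_numpy()
    t2 = design == "typeII"
    t1g = design == "typeI_grn"
    t1r = design == "typeI_red"

    meth = frac[:, None] * total + bg_meth
    unmeth = (1.0 - frac[:, None]) * total + bg_unmeth
    # dye bias scales red-channel measurements
    meth[t1r] *= config.dye_bias
    unmeth[t1r] *= config.dye_bias
    unmeth[t2] *= config.dye_bias
    oob = bg_oob.copy()
    oob[t2] = 0.0
    oob[t1g] *= config.dye_bias  # type I green probes leave red out-of-band signal

    cohort = IntensityCohort(
        manifest, meth, unmeth, oob, np.zeros((n, s), dtype=bool), samples
    )
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_name": samples,
                "intensity_path": [f"synthetic://{scenario}/{name}" for name in samples],
                "group": ["tumor"] * len(tumors) + ["control"] * len(controls),
                "platform": ["450k-like"] * s,
            }
        )
    )
    gold = _gold_standard(config, manifest, samples, events)
    return cohort, sheet, events, gold


def inject_baseline_offset(
    cohort: IntensityCohort, samples: list[str], offset: float
) -> IntensityCohort:
    """Shift the LRR of the listed samples by exactly ``offset`` log2 units.

    Operates on the intensity scale (multiplies both in-band channels by
    2**offset), so every downstream LRR of those samples moves by the
    offset while truth annotations are untouched.
    """
    if not np.isfinite(offset):
        raise ConfigurationError("offset must be finite")
    out = cohort.copy()
    factor = 2.0 ** offset
    for name in samples:
        j = cohort.sample_index(name)  # raises on unknown sample
        out.meth[:, j] *= factor
        out.unmeth[:, j] *= factor
    return out


def write_truth_events(events: list[TruthEvent], path) -> None:
    pd.DataFrame(
        [(e.sample, e.chrom, e.start, e.end, e.copy_number) for e in events],
        columns=["sample", "chrom", "start", "end", "copy_number"],
    ).to_csv(path, index=False)
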