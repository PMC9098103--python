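"""From raw two-channel intensities to per-probe log-R-ratio tracks.

The stage sequence mirrors the standard single-sample preprocessing of
methylation arrays: out-of-band background correction, red-to-green
dye-bias harmonization, detection-p-value masking, reference
construction, and the LRR computation LRR = log2(I_T / I_R) on the
combined (methylated + unmethylated) intensity. The background and
masking steps are deliberately simple re-implementations of the
out-of-band ideas (additive background estimated from the out-of-band
pool; empirical survival-function detection p) — the route structure,
not bit-level fidelity to any particular array toolkit, is what the
pipeline exercises.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import (
    ConfigurationError,
    IntensityCohort,
    ProbeManifest,
    SampleSheet,
    ValidationError,
)

logger = logging.getLogger(__name__)

REFERENCE_MODES = ("pooled_controls", "median_controls", "matched_normal", "cohort_median")


@dataclass
class LRRTrack:
    """Per-probe log2 ratio matrix [probe x sample] with mask and provenance."""

    manifest: ProbeManifest
    values: np.ndarray
    mask: np.ndarray
    sample_names: list[str]
    route: str = "standard"
    reference_mode: str = "median_controls"

    def __post_init__(self):
        n, s = self.manifest.n_probes, len(self.sample_names)
        if self.values.shape != (n, s) or self.mask.shape != (n, s):
            raise ValidationError("LRR track shape does not match manifest/samples")
        if self.mask.dtype != bool:
            self.mask = self.mask.astype(bool)
        if not np.all(np.isfinite(self.values[~self.mask])):
            raise ValidationError("unmasked LRR values must be finite")

    def copy(self) -> "LRRTrack":
        return LRRTrack(
            self.manifest,
            self.values.copy(),
            self.mask.copy(),
            list(self.sample_names),
            self.route,
            self.reference_mode,
        )


# ---------------------------------------------------------------------------
# Background correction
# ---------------------------------------------------------------------------

def background_correct(cohort: IntensityCohort) -> IntensityCohort:
    """Subtract a per-sample, per-channel background estimated out-of-band.

    The background of each colour channel is estimated as the mean of that
    channel's out-of-band pool (red pool = oob of type I green probes,
    green pool = oob of type I red probes) and subtracted from every
    in-band measurement of the channel, floored at zero. The transform is
    monotone per channel, so in-band signal order is preserved.
    """
    out = cohort.copy()
    design = cohort.manifest.df["design"].to_numpy()
    t2 = design == "typeII"
    t1g = design == "typeI_grn"
    t1r = design == "typeI_red"
    for j in range(cohort.n_samples):
        red_pool = cohort.oob[t1g, j]
        green_pool = cohort.oob[t1r, j]
        bg_red = float(np.mean(red_pool)) if red_pool.size else 0.0
        bg_green = float(np.mean(green_pool)) if green_pool.size else 0.0
        if red_pool.size == 0 or not np.any(red_pool > 0):
            if bg_red == 0.0:
                logger.warning(
                    "sample %s: empty/zero red out-of-band pool, red channel passed through",
                    cohort.sample_names[j],
                )
        if green_pool.size == 0 or not np.any(green_pool > 0):
            if bg_green == 0.0:
                logger.warning(
                    "sample %s: empty/zero green out-of-band pool, green channel passed through",
                    cohort.sample_names[j],
                )
        # green-channel measurements: meth of type II, both alleles of type I grn
        out.meth[t2, j] = np.maximum(cohort.meth[t2, j] - bg_green, 0.0)
        out.meth[t1g, j] = np.maximum(cohort.meth[t1g, j] - bg_green, 0.0)
        out.unmeth[t1g, j] = np.maximum(cohort.unmeth[t1g, j] - bg_green, 0.0)
        # red-channel measurements: unmeth of type II, both alleles of type I red
        out.unmeth[t2, j] = np.maximum(cohort.unmeth[t2, j] - bg_red, 0.0)
        out.meth[t1r, j] = np.maximum(cohort.meth[t1r, j] - bg_red, 0.0)
        out.unmeth[t1r, j] = np.maximum(cohort.unmeth[t1r, j] - bg_red, 0.0)
    return out


# ---------------------------------------------------------------------------
# Dye-bias correction
# ---------------------------------------------------------------------------

def _quantile_map(red_ref: np.ndarray, green_ref: np.ndarray):
    """Monotone map carrying the red reference distribution onto the green one."""
    rs = np.sort(red_ref)
    gs = np.sort(green_ref)

    def f(x: np.ndarray) -> np.ndarray:
        y = np.interp(x, rs, gs)
        lo = x < rs[0]
        hi = x > rs[-1]
        if rs[0] > 0:
            y[lo] = x[lo] * (gs[0] / rs[0])
        else:
            y[lo] = gs[0]
        if rs[-1] > 0:
            y[hi] = x[hi] * (gs[-1] / rs[-1])
        return np.maximum(y, 0.0)

    return f

def dye_bias_correct(cohort: IntensityCohort, min_type2: int = 100) -> IntensityCohort:
    """Map the red-channel distribution onto the green one, per sample.

    The map is the empirical quantile transform fit on unmasked type II
    probes (where the two channels interrogate the same loci) and applied
    to every red-channel measurement: type II unmethylated signal, both
    alleles of type I red probes, and the red out-of-band intensities of
    type I green probes. Green is never changed. With fewer than
    ``min_type2`` usable type II probes the correction falls back to
    median-ratio scaling.
    """
    out = cohort.copy()
    design = cohort.manifest.df["design"].to_numpy()
    t2 = design == "typeII"
    t1g = design == "typeI_grn"
    t1r = design == "typeI_red"
    for j in range(cohort.n_samples):
        usable = t2 & ~cohort.mask[:, j]
        red_ref = cohort.unmeth[usable, j]
        green_ref = cohort.meth[usable, j]
        if red_ref.size < min_type2:
            logger.warning(
                "sample %s: only %d type II probes, falling back to median-ratio dye scaling",
                cohort.sample_names[j],
                red_ref.size,
            )
            med_r = np.median(red_ref) if red_ref.size else 0.0
            ratio = (np.median(green_ref) / med_r) if med_r > 0 else 1.0
            f = lambda x, r=ratio: x * r  # noqa: E731
        else:
            f = _quantile_map(red_ref, green_ref)
        out.unmeth[t2, j] = f(cohort.unmeth[t2, j])
        out.meth[t1r, j] = f(cohort.meth[t1r, j])
        out.unmeth[t1r, j] = f(cohort.unmeth[t1r, j])
        out.oob[t1g, j] = f(cohort.oob[t1g, j])
    return out


# ---------------------------------------------------------------------------
# Detection masking
# ---------------------------------------------------------------------------

def mask_probes(cohort: IntensityCohort, p_threshold: float = 0.05) -> IntensityCohort:
    """Mask probe/sample entries whose signal is indistinguishable from background.

    The detection p-value of a probe is the empirical survival function of
    the sample's out-of-band pool at the probe's total in-band intensity:
    p = fraction of out-of-band values >= observed intensity. Entries with
    p > p_threshold are masked; existing mask flags are preserved (masking
    is monotone).
    """
    if not 0 < p_threshold < 1:
        raise ConfigurationError("p_threshold must be in (0, 1)")
    out = cohort.copy()
    design = cohort.manifest.df["design"].to_numpy()
    type1 = design != "typeII"
    total = cohort.total()
    for j in range(cohort.n_samples):
        pool = cohort.oob[type1, j]
        pool = pool[np.isfinite(pool)]
        if pool.size == 0:
            logger.warning(
                "sample %s: empty out-of-band pool, no detection masking applied",
                cohort.sample_names[j],
            )
            continue
        pool = np.sort(pool)
        # count of pool values >= intensity
        ge = pool.size - np.searchsorted(pool, total[:, j], side="left")
        p = ge / pool.size
        out.mask[:, j] |= p > p_threshold
    return out


# ---------------------------------------------------------------------------
# Reference construction and LRR
# ---------------------------------------------------------------------------

def _masked_total(cohort: IntensityCohort) -> np.ndarray:
    tot = cohort.total().astype(float)
    tot[cohort.mask] = np.nan
    return tot


def build_reference(
    cohort: IntensityCohort, sheet: SampleSheet, mode: str = "median_controls"
) -> np.ndarray:
    """Per-probe reference intensity vector I_R.

    Modes: ``median_controls`` (per-probe median over control samples),
    ``pooled_controls`` (per-probe mean over controls), ``cohort_median``
    (per-probe median over every sheet sample — an internal reference that
    needs no controls), and ``matched_normal`` (per-tumor reference from a
    ``matched_normal`` pairing column; returns a [probe x tumor] matrix).
    """
    if mode not in REFERENCE_MODES:
        raise ConfigurationError(f"unknown reference mode {mode!r}")
    tot = _masked_total(cohort)
    if mode in ("median_controls", "pooled_controls"):
        controls = [s for s in sheet.controls if s in cohort.sample_names]
        if not controls:
            raise ConfigurationError(f"reference mode {mode!r} requires >=1 control sample")
        cols = [cohort.sample_index(s) for s in controls]
        sub = tot[:, cols]
        with np.errstate(all="ignore"):
            ref = np.nanmedian(sub, axis=1) if mode == "median_controls" else np.nanmean(sub, axis=1)
        return ref
    if mode == "cohort_median":
        cols = [cohort.sample_index(s) for s in sheet.samples if s in cohort.sample_names]
        if not cols:
            raise ConfigurationError("cohort_median: no sheet samples present in cohort")
        with np.errstate(all="ignore"):
            return np.nanmedian(tot[:, cols], axis=1)
    # matched_normal
    if "matched_normal" not in sheet.df.columns:
        raise ConfigurationError("matched_normal mode requires a 'matched_normal' sheet column")
    tumors = sheet.tumors
    pairing = dict(zip(sheet.df["sample_name"], sheet.df["matched_normal"]))
    ref = np.empty((cohort.manifest.n_probes, len(tumors)))
    for k, t in enumerate(tumors):
        normal = pairing.get(t, "")
        if not normal or normal not in cohort.sample_names:
            raise ConfigurationError(f"tumor {t!r} has no matched normal in the cohort")
        ref[:, k] = tot[:, cohort.sample_index(normal)]
    return ref


def compute_lrr(
    cohort: IntensityCohort,
    reference: np.ndarray,
    samples: list[str] | None = None,
    route: str = "standard",
    reference_mode: str = "median_controls",
) -> LRRTrack:
    """LRR = log2(I_T / I_R) per probe and selected sample.

    ``reference`` is either a per-probe vector (applied to every sample)
    or a [probe x len(samples)] matrix of per-sample references. Probes
    with non-positive or undefined reference are masked cohort-wide;
    entries with zero test intensity are masked per sample.
    """
    samples = list(samples) if samples is not None else list(cohort.sample_names)
    cols = [cohort.sample_index(s) for s in samples]
    tot = cohort.total()[:, cols].astype(float)
    mask = cohort.mask[:, cols].copy()
    ref = np.asarray(reference, dtype=float)
    if ref.ndim == 1:
        ref = ref[:, None]
    elif ref.shape[1] != len(samples):
        raise ValidationError("reference matrix width does not match selected samples")
    bad_ref = ~np.isfinite(ref) | (ref <= 0)
    mask |= np.broadcast_to(bad_ref, mask.shape)
    mask |= tot <= 0
    values = np.full(tot.shape, np.nan)
    ok = ~mask
    refb = np.broadcast_to(ref, tot.shape)
    values[ok] = np.log2(tot[ok] / refb[ok])
    return LRRTrack(cohort.manifest, values, mask, samples, route, reference_mode)


def zscore_transform(track: LRRTrack) -> LRRTrack:
    """Standardize each sample's unmasked values to mean 0, SD 1 (ddof=1)."""
    out = track.copy()
    for j, name in enumerate(track.sample_names):
        ok = ~track.mask[:, j]
        x = track.values[ok, j]
        if x.size < 2:
            raise ValidationError(f"sample {name!r}: need >=2 unmasked values to z-transform")
        sd = float(np.std(x, ddof=1))
        if sd == 0.0:
            raise ValidationError(f"sample {name!r}: zero within-sample SD, cannot z-transform")
        out.values[ok, j] = (x - float(np.mean(x))) / sd
    out.route = "zscore"
    return out


def copy_number_signal(cohort: IntensityCohort, samples: list[str] | None = None) -> LRRTrack:
    """log2 total intensity per probe/sample (the raw copy-number signal).

    Used by the z-score route, which standardizes tumor and control
    signals separately before differencing rather than ratioing against a
    reference directly.
    """
    samples = list(samples) if samples is not None else list(cohort.sample_names)
    cols = [cohort.sample_index(s) for s in samples]
    tot = cohort.total()[:, cols].astype(float)
    mask = cohort.mask[:, cols] | (tot <= 0)
    values = np.full(tot.shape, np.nan)
    values[~mask] = np.log2(tot[~mask])
    return LRRTrack(cohort.manifest, values, mask, samples, "zscore", "median_controls")
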