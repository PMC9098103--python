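# Methods

## Data model and coordinates

All tables use 1-based, fully closed genomic intervals (the SNP-array
segment-CSV convention): `chr1:100-200` and `chr1:200-300` share base
200, and a range union merges abutting intervals (`100-200` ∪ `201-300`
→ `100-300`). Strand is ignored throughout. Every calling route reads
and writes one common segment format — `(sample, chrom, start, end,
num_mark, seg_mean, state)` — whose CSV round-trip is exact (floats are
serialized at full repr precision and parsed with round-trip parsing).
Segment coordinates are probe-supported extents: the positions of the
first and last member probes, not midpoints between probes.

## Synthetic cohorts

The generator emulates the two lesion classes the pipeline targets:
`kirc_3p` (whole-arm 3p deletion at copy number 1 by default, 0
optionally) and `oligo_1p19q` (copy number 1 over all of 1p and all of
19q), plus a copy-neutral scenario. Per probe p and sample s the total
intensity is

    I[p, s] = baseline[p] · (CN[p, s] / 2) · 2^ε,   ε ~ N(0, noise_sd),

with `baseline[p]` drawn log-normally once per manifest
(`2^N(11, 0.5)`, arbitrary units on the scale of real array
intensities) and split into channels by a per-probe methylation fraction
~ Uniform(0.1, 0.9). The methylation split is a nuisance parameter: the
copy-number signal is the combined intensity, so the split only
exercises the channel plumbing. Red-channel measurements are multiplied
by a dye-bias factor (default 1.0) and every in-band measurement gains
additive exponential background (mean `background_level`, default 100);
type I probes leave an out-of-band background draw in their silent
channel. A `baseline_offset` (log2 units, default 0) multiplies tumor
intensities by `2^offset` to exercise the autocorrection stage.

Defaults: 10 tumors, 5 controls, 4 chromosomes (chr1, chr2, chr3,
chr19) × 200 probes at 10 kb spacing, arm boundary at each chromosome's
midpoint, `noise_sd = 0.25`. The noise level is chosen to make CBS
detection of arm-scale events nontrivial but reliable; real 450k LRR
noise varies by sample quality and is not pinned by any published
value, so it is config-exposed.

The gold standard carries one row per implanted event plus neutral rows
tiling every other arm (per arm, not per chromosome, so whole-arm
neutral segments exist for the reference classifier). Gold `num_mark`
values use a separate SNP-array-like marker density (1 mark / 75 bp)
rather than methylation-probe counts: arm-scale events then carry
>10,000 marks, the scale of real high-density SNP segments, which is
what the large-scale-event filter expects. Arm extents below ~0.79 Mb
(e.g. fewer than ~160 probes per chromosome at default spacing) would
fall under that filter — the classifier tests therefore use default arm
sizes.

What the generator does **not** emulate: probe-type-specific chemistry
beyond the dye factor, spatial/batch artifacts, subclonal or focal
events, and real cytoband geometry. Passing tests therefore demonstrate
correctness of the computational stages under the stated intensity
model, not calling performance on real arrays.

## Preprocessing

* **Background correction** estimates each colour channel's background
  as the mean of the sample's out-of-band pool (red pool from type I
  green probes and vice versa) and subtracts it, floored at 0. This is a
  deliberately simple additive variant of out-of-band background
  correction: it is monotone per channel and exact for constant
  background, which is what the downstream contracts rely on.
* **Dye-bias correction** maps the red-channel empirical distribution
  onto the green one via the quantile transform fit on unmasked type II
  probes, extended linearly (through the origin) beyond the fitted
  range; below 100 usable type II probes it falls back to median-ratio
  scaling. Green is never altered.
* **Detection masking** computes p = empirical survival function of the
  sample's out-of-band pool at the probe's total in-band intensity and
  masks entries with p > 0.05 (default). Masking is monotone: no stage
  ever unmasks.
* **References**: per-probe median over controls (default), mean over
  controls, cohort median (no controls needed), or matched normals via
  a sample-sheet pairing column. Median combination is used wherever a
  choice existed, for robustness and consistency across routes.
* **LRR** = log2(total test intensity / reference); probes with
  non-positive reference are masked cohort-wide, zero-intensity entries
  per sample. The z-score route instead standardizes log2 total
  intensity per sample (ddof = 1), subtracts the per-probe median of
  control z-scores from each tumor z-track, and median-centers each
  difference track before segmentation.

## Segmentation

Classical circular binary segmentation. For a sequence of n probe
values, the arc (i, j] on the circularized sequence maximizes

    T(i, j) = |mean(arc) − mean(complement)| / sqrt(1/k + 1/(n−k)).

The pooled-SD factor of the usual t-statistic is omitted: permutations
of the same values share it, so it cancels from the permutation
comparison. A split is accepted when
p = (1 + #{permutation max ≥ observed}) / (1 + nperm) ≤ alpha
(defaults alpha = 0.01, nperm = 1000, seeded per sample/chromosome);
permutations are evaluated in batches with early stopping once the
exceedance bound is crossed — the decision is provably identical to
evaluating all permutations. Only arcs whose linear cut pieces all hold
at least `min_width` (default 2) probes are admissible, and the
admissible set is shared between the observed and permuted maxima. Ties
are broken toward the smallest arc start, then end. After recursion,
adjacent segments merge when their means differ by less than
`undo_sd` (default 1.0) residual standard deviations, or exactly
coincide. Constant subsequences stop the recursion immediately.

The exhaustive least-squares segmenter (`brute_force_segment`, ≤ 60
probes, dynamic program over all breakpoint placements, fewest segments
winning ties) is a test oracle only. CBS agrees with it deterministically
on noise-free staircases whose pieces hold ≥ 8 probes; below that the
true permutation p-value of a split (≈ n / #arrangements) approaches
alpha and the acceptance of small exact segments becomes a coin toss by
design of the test, not an implementation artifact.

## Postprocessing

* **Baseline autocorrection**: per sample, a Gaussian KDE of segment
  means weighted by `num_mark` (Silverman bandwidth on the weighted
  sample, 2048-point grid over [min − 0.5, max + 0.5], ties between
  equal peaks broken toward 0, grid peak refined sub-grid by bounded
  scalar optimization) locates the modal level, which is subtracted.
  Because the grid is anchored to the data range, the operation is
  shift-equivariant and idempotent to well below 1e−3. Mark-weighting
  is the default (`--autocorrect-unweighted` disables it): the modal
  level should be the level covering the most genome, not the most
  segments. A single-segment sample is centered on that segment with a
  warning.
* **State calling**: threshold mode (loss ≤ −0.2, gain ≥ +0.2,
  boundaries inclusive) or formula mode
  `state = round(2^seg_mean × 2)` with half-up rounding (documented
  because round-half-even would differ at exact halves: mean
  log2(1.25) → copy number 3).
* **Consensus regions** (defaults density = 0.1, rho = 0.5): losses and
  gains pool separately; calls cluster by single linkage on the
  reciprocal-overlap graph (overlap ≥ rho of both lengths); within a
  cluster, maximal subregions where ≥ density of cohort samples cover
  every base are emitted, with support counted after per-sample union.
  The `est_recur` flag marks a region recurrent when its support beats
  a one-sided binomial test at 0.05 against the cohort's mean
  non-neutral genome fraction; this recurrence formulation is this
  package's own and is labeled as such in exports.

## Evaluation

Recall R = (ON + (OT − ONT)) / TR, clamped to [0, 1] with a warning if
OT − ONT < 0 (negative handling is otherwise undefined). ONT is a
property of the reference pair alone. Two counting modes are always
available and reported side by side: `literal` (overlaps against all
calls, the formula exactly as written) and `state_matched` (default; N
against neutral calls, T against non-neutral calls), because equating
ON with true negatives is only coherent when call states participate.
Per-sample recalls are reported individually plus their mean; pooled
counting across samples is available by concatenating call tables.

Reference-sample classification: per gold segment, copy state 1 if
mean ≤ −0.2, 3 if ≥ 0.2, else 2; a sample is a tumor reference when
every required arm (default 1p and 19q) carries a state-1 segment with
more than 10,000 marks, a normal reference when every required arm
instead satisfies the mark filter with a state-2 segment and no
qualifying state-1 segment exists there. Arm membership is by segment
midpoint (unambiguous for arm-scale events; a fractional-coverage rule
was considered and rejected as needless complexity at arm scale).

## Problem sizes

The test suite and `scripts/acceptance.py` run cohorts of 2–10 tumors
with 100–200 probes per chromosome, 50–200 segmentation replicates and
200 randomized interval configurations; these sizes give stable rates
(binomial SE ≲ 3%) for every reported quantity while keeping a full run
in the minutes range on one core.

## Known limitations

Background and masking are simplified stand-ins for the out-of-band
algorithms used on real arrays (no normal-exponential deconvolution);
native binary IDAT ingestion is out of scope (the reference input is a
plain long-format intensity CSV behind the same cohort abstraction);
no multi-sample joint segmentation; no focal-event significance scoring
(GISTIC-style); performance records (wall time, peak traced memory) are
written for every run but never asserted on, being hardware-dependent.
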