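# methylcnv

Copy-number variation (CNV) calling from Illumina-style methylation-array
intensities, aimed at the large-scale chromosomal lesions that matter in
tumor classification: deep deletion of chromosome arm 3p (clear cell
renal cell carcinoma) and joint loss of arms 1p and 19q (classical
oligodendroglioma). The package is for methods-minded genomicists who
want a self-contained, reproducible pipeline — from raw two-channel
probe intensities to segmented copy-number calls, cross-sample consensus
regions, and an overlap-based recall benchmark — without any external
data downloads: a first-class synthetic-cohort generator with implanted
truth stands in for array IDAT content.

## The method

Copy number is inferred from the **combined** probe intensity (methylated
plus unmethylated channel). For test intensity `I_T` and reference
intensity `I_R` the log R ratio is

```
LRR = log2(I_T / I_R)
```

so copy-neutral probes sit near 0, hemizygous deletions near −1, and
gains above 0. The stages:

1. **Preprocessing** — out-of-band background subtraction, red→green
   quantile dye-bias harmonization, detection-p-value masking, and a
   configurable reference (`median_controls`, `pooled_controls`,
   `cohort_median`, `matched_normal`); an alternative z-score route
   standardizes tumor and control copy-number signals and segments their
   difference.
2. **Segmentation** — circular binary segmentation (CBS): recursively
   split each sample/chromosome at the arc maximizing a two-sample
   mean-difference statistic, accepting splits by permutation test,
   with an exhaustive least-squares segmenter as an in-repo oracle.
3. **Postprocessing** — density-peak baseline autocorrection (shift each
   sample so its modal, presumed copy-neutral segment level is 0); state
   calling either by the liberal ±0.2 LRR thresholds
   (loss ≤ −0.2, gain ≥ +0.2) or by the copy-number formula
   `state = round(2^seg_mean × 2)`; consensus regions across samples via
   reciprocal-overlap clustering (defaults `density = 0.1`, `rho = 0.5`).
4. **Evaluation** — recall against a gold-standard segment set split into
   normal (N) and tumor (T) references:

   ```
   R = (ON + (OT − ONT)) / TR
   ```

   with ≥1-base overlap semantics, `TR = |union(N, T)|`, plus
   arm-level reference-sample classification (±0.2 mean-intensity labels
   with a >10,000-mark large-scale filter on both 1p and 19q).

## Worked example

```
methylcnv simulate --scenario kirc_3p --seed 3 --n-tumor 2 --n-control 2 \
    --probes-per-chrom 60 --outdir sim
methylcnv run --sheet sim/sample_sheet.csv --intensities sim/intensities.csv \
    --manifest sim/manifest.csv --route custom --seed 3 --outdir out
methylcnv benchmark --calls out/segments.csv --gold sim/gold_standard.csv \
    --out recall.csv
```

which prints

```
wrote cohort (240 probes x 4 samples, 2 truth events) to sim
route=custom: 10 segments, 1 consensus regions, 0.4s wall, 0.9 MB peak
state_matched: mean recall 1.0000 over 2 samples
literal: mean recall 1.0000 over 2 samples
```

The simulated cohort carries a hemizygous 3p deletion in both tumor
samples. The run segments each tumor's LRR track into a −1 segment over
3p and neutral segments elsewhere (10 rows in `out/segments.csv`), the
two concordant 3p losses form one consensus region, and every
gold-standard reference segment is recovered, so per-sample recall is
1.0 in both counting modes. The same steps are available as library
calls (`simulate_cohort`, `run_pipeline`, `cohort_recall`).

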