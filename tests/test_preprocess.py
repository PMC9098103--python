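"""Background, dye-bias, masking, reference construction and LRR math."""
import numpy as np
import pandas as pd
import pytest

from methylcnv.core import ConfigurationError, IntensityCohort, SampleSheet, ValidationError
from methylcnv.preprocess import (
    background_correct,
    build_reference,
    compute_lrr,
    dye_bias_correct,
    mask_probes,
    zscore_transform,
)
from methylcnv.simulate import SimConfig, simulate_cohort
from helpers import make_manifest, make_track


def _cohort(meth, unmeth, oob=None, designs=None, samples=None):
    meth = np.asarray(meth, float)
    unmeth = np.asarray(unmeth, float)
    if meth.ndim == 1:
        meth = meth[:, None]
    if unmeth.ndim == 1:
        unmeth = unmeth[:, None]
    n, s = meth.shape
    oob = np.zeros((n, s)) if oob is None else np.asarray(oob, float).reshape(n, s)
    mf = make_manifest(n)
    if designs is not None:
        df = mf.df.copy()
        df["design"] = designs
        from methylcnv.core import ProbeManifest

        mf = ProbeManifest(df)
    samples = samples or [f"S{i+1}" for i in range(s)]
    return IntensityCohort(mf, meth, unmeth, oob, np.zeros((n, s), bool), samples)


class TestBackgroundCorrect:
    def test_zero_background_is_identity(self, rng):
        n = 50
        designs = ["typeI_grn"] * 10 + ["typeI_red"] * 10 + ["typeII"] * 30
        c = _cohort(rng.uniform(100, 5000, (n, 2)), rng.uniform(100, 5000, (n, 2)),
                    oob=np.zeros((n, 2)), designs=designs)
        out = background_correct(c)
        assert np.allclose(out.meth, c.meth)
        assert np.allclose(out.unmeth, c.unmeth)

    def test_constant_background_subtracted_exactly(self, rng):
        n, b = 60, 250.0
        designs = ["typeI_grn"] * 15 + ["typeI_red"] * 15 + ["typeII"] * 30
        signal_m = rng.uniform(500, 5000, (n, 1))
        signal_u = rng.uniform(500, 5000, (n, 1))
        c = _cohort(signal_m + b, signal_u + b, oob=np.full((n, 1), b), designs=designs)
        out = background_correct(c)
        assert np.allclose(out.meth, signal_m)
        assert np.allclose(out.unmeth, signal_u)

    def test_order_preserved_within_channel(self, rng):
        cfg = SimConfig(n_tumor=2, n_control=1, probes_per_chrom=80,
                        chroms=("chr1",), background_level=300.0, seed=4)
        cohort, *_ = simulate_cohort(cfg, "neutral")
        out = background_correct(cohort)
        t2 = (cohort.manifest.df["design"] == "typeII").to_numpy()
        for j in range(cohort.n_samples):
            pre = np.argsort(cohort.meth[t2, j], kind="stable")
            post = np.argsort(out.meth[t2, j], kind="stable")
            assert np.array_equal(pre, post)
        assert (out.meth >= 0).all() and (out.unmeth >= 0).all()


class TestDyeBias:
    def test_matching_distributions_are_untouched(self, rng):
        vals = rng.uniform(100, 4000, 200)
        c = _cohort(vals, vals.copy(), designs=["typeII"] * 200)
        out = dye_bias_correct(c)
        assert np.allclose(out.unmeth[:, 0], vals)

    def test_doubled_red_is_mapped_back_exactly(self, rng):
        green = rng.uniform(100, 4000, 300)
        c = _cohort(green, 2.0 * green, designs=["typeII"] * 300)
        out = dye_bias_correct(c)
        assert np.allclose(out.unmeth[:, 0], green)
        assert np.allclose(out.meth[:, 0], green)  # green never changes

    def test_map_is_monotone_on_red_channel(self, rng):
        green = rng.uniform(100, 4000, 250)
        red = rng.uniform(50, 8000, 250)
        c = _cohort(green, red, designs=["typeII"] * 250)
        out = dye_bias_correct(c)
        order = np.argsort(red)
        assert (np.diff(out.unmeth[order, 0]) >= -1e-9).all()

    def test_few_type2_probes_falls_back_to_median_ratio(self, rng):
        green = rng.uniform(100, 4000, 50)
        c = _cohort(green, 2.0 * green, designs=["typeII"] * 50)
        out = dye_bias_correct(c)
        assert np.allclose(out.unmeth[:, 0], green)  # median ratio = 0.5

    def test_lrr_invariant_to_global_red_factor(self, rng):
        """Dye correction + LRR neutralize any global red-channel scale."""
        cfg = SimConfig(n_tumor=2, n_control=2, probes_per_chrom=150, chroms=("chr1",),
                        noise_sd=0.1, background_level=0.0, seed=6)
        base, sheet, *_ = simulate_cohort(cfg, "neutral")
        tracks = {}
        for factor in (1.0, 0.5, 1.7):
            c = base.copy()
            design = c.manifest.df["design"].to_numpy()
            red_rows = design == "typeI_red"
            c.unmeth[design == "typeII"] *= factor
            c.meth[red_rows] *= factor
            c.unmeth[red_rows] *= factor
            c.oob[design == "typeI_grn"] *= factor
            corrected = dye_bias_correct(c)
            ref = build_reference(corrected, sheet, "median_controls")
            tracks[factor] = compute_lrr(corrected, ref, samples=sheet.tumors)
        for factor in (0.5, 1.7):
            assert np.allclose(tracks[factor].values, tracks[1.0].values,
                               atol=1e-9, equal_nan=True)


class TestMasking:
    def test_signal_above_all_oob_is_unmasked(self):
        designs = ["typeI_grn"] * 5 + ["typeII"] * 5
        oob = np.zeros((10, 1))
        oob[:5, 0] = [10, 20, 30, 40, 50]
        c = _cohort(np.full((10, 1), 500.0), np.full((10, 1), 500.0), oob=oob, designs=designs)
        out = mask_probes(c, 0.05)
        assert not out.mask.any()

    def test_signal_below_all_oob_is_masked(self):
        designs = ["typeI_grn"] * 5 + ["typeII"] * 5
        oob = np.zeros((10, 1))
        oob[:5, 0] = [1000, 2000, 3000, 4000, 5000]
        meth = np.full((10, 1), 400.0)
        meth[0, 0] = 1.0  # in-band total 2 < every oob value -> p = 1
        c = _cohort(meth, np.full((10, 1), 1.0), oob=oob, designs=designs)
        out = mask_probes(c, 0.5)
        assert out.mask[0, 0]

    def test_background_only_probes_masked_at_expected_rate(self, rng):
        """~5% implanted failed probes are caught at p_threshold = 0.05."""
        n = 2000
        designs = ["typeI_grn"] * n
        oob = rng.exponential(200.0, (n, 1))
        total = rng.uniform(3000, 8000, (n, 1))
        failed = rng.random(n) < 0.05
        # failed probes carry background-scale signal drawn from the oob law
        total[failed, 0] = rng.exponential(200.0, failed.sum())
        c = _cohort(total / 2, total / 2, oob=oob, designs=designs)
        out = mask_probes(c, 0.05)
        frac = out.mask.mean()
        assert 0.02 < frac < 0.08
        # the implanted failures make up the bulk of the masked set
        assert out.mask[failed, 0].mean() > 0.5

    def test_masking_is_monotone(self, rng):
        cfg = SimConfig(n_tumor=2, n_control=2, probes_per_chrom=100,
                        chroms=("chr1",), seed=8)
        cohort, *_ = simulate_cohort(cfg, "neutral")
        cohort.mask[3, 1] = True
        out = mask_probes(dye_bias_correct(background_correct(cohort)), 0.05)
        assert out.mask[3, 1]
        assert (out.mask | cohort.mask).sum() == out.mask.sum()

    def test_bad_threshold_rejected(self):
        c = _cohort([1.0], [1.0])
        with pytest.raises(ConfigurationError):
            mask_probes(c, 1.5)


class TestReference:
    def _sheet(self, names, groups):
        return SampleSheet(pd.DataFrame({
            "sample_name": names,
            "intensity_path": ["x"] * len(names),
            "group": groups,
        }))

    def test_median_of_single_control_is_that_sample(self):
        c = _cohort(np.array([[10.0, 5.0], [20.0, 7.0]]),
                    np.array([[10.0, 5.0], [20.0, 7.0]]), samples=["S1", "S2"])
        sheet = self._sheet(["S1", "S2"], ["tumor", "control"])
        ref = build_reference(c, sheet, "median_controls")
        assert np.allclose(ref, [10.0, 14.0])

    def test_median_of_three_controls(self):
        meth = np.array([[5.0, 10.0, 20.0]])
        c = _cohort(meth, meth.copy(), samples=["C1", "C2", "C3"])
        sheet = self._sheet(["C1", "C2", "C3"], ["control"] * 3)
        ref = build_reference(c, sheet, "median_controls")
        assert ref[0] == pytest.approx(20.0)  # totals (10, 20, 40) -> median 20

    def test_cohort_median_over_tumors(self, rng):
        meth = rng.uniform(100, 1000, (30, 5))
        unmeth = rng.uniform(100, 1000, (30, 5))
        names = [f"S{i+1}" for i in range(5)]
        c = _cohort(meth, unmeth, samples=names)
        sheet = self._sheet(names, ["tumor"] * 5)
        ref = build_reference(c, sheet, "cohort_median")
        assert np.allclose(ref, np.median(meth + unmeth, axis=1))

    def test_control_mode_without_controls_is_config_error(self):
        c = _cohort([[1.0]], [[1.0]])
        sheet = self._sheet(["S1"], ["tumor"])
        with pytest.raises(ConfigurationError):
            build_reference(c, sheet, "median_controls")


class TestLRR:
    @pytest.mark.parametrize("ratio,expected", [(1.0, 0.0), (2.0, 1.0), (0.5, -1.0)])
    def test_basic_ratios(self, ratio, expected):
        ref = np.full(20, 800.0)
        c = _cohort(np.full((20, 1), 400.0 * ratio), np.full((20, 1), 400.0 * ratio))
        track = compute_lrr(c, ref)
        assert np.allclose(track.values, expected)

    def test_zero_test_intensity_masked(self):
        c = _cohort(np.array([[0.0], [100.0]]), np.array([[0.0], [100.0]]))
        track = compute_lrr(c, np.array([100.0, 100.0]))
        assert track.mask[0, 0] and not track.mask[1, 0]

    def test_noise_free_pipeline_recovers_exact_copy_ratios(self):
        """median-controls reference + LRR give exactly log2(CN/2)."""
        cfg = SimConfig(n_tumor=3, n_control=3, probes_per_chrom=60,
                        chroms=("chr1", "chr3"), noise_sd=0.0,
                        background_level=0.0, seed=17)
        cohort, sheet, events, _ = simulate_cohort(cfg, "kirc_3p")
        ref = build_reference(cohort, sheet, "median_controls")
        track = compute_lrr(cohort, ref, samples=sheet.tumors)
        on_3p = (cohort.manifest.df["arm"] == "3p").to_numpy()
        assert np.allclose(track.values[on_3p, :], np.log2(cfg.deletion_cn / 2), atol=1e-12)
        assert np.allclose(track.values[~on_3p, :], 0.0, atol=1e-12)


class TestZScore:
    def test_hand_computed_values(self):
        track = make_track([-1.0, 0.0, 1.0])
        z = zscore_transform(track)
        assert np.allclose(z.values[:, 0], [-1.0, 0.0, 1.0])  # ddof=1 SD = 1

    def test_affine_invariance(self, rng):
        x = rng.normal(0, 1, 40)
        z1 = zscore_transform(make_track(x))
        z2 = zscore_transform(make_track(3.5 * x - 2.0))
        assert np.allclose(z1.values, z2.values)

    def test_constant_sample_is_an_error(self):
        with pytest.raises(ValidationError, match="S1"):
            zscore_transform(make_track(np.full(10, 2.0)))
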