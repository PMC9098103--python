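"""Baseline autocorrection, state calling, and consensus regions."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from methylcnv.core import ConfigurationError, SegmentTable
from methylcnv.postprocess import (
    StateCallParams,
    autocorrect_baseline,
    call_states,
    consensus_regions,
    kde_mode,
)
from helpers import oracle_weighted_kde_mode, segments_frame


def _table(means, marks, sample="S1"):
    rows = []
    start = 1
    for m, k in zip(means, marks):
        rows.append((sample, "chr1", start, start + 999, k, m, None))
        start += 1000
    return SegmentTable(segments_frame(rows))


class TestAutocorrect:
    def test_mode_matches_independent_density_scan(self):
        """Weighted density peak of {0.30, 0.31, 0.29, -0.70} sits near 0.30
        and correction moves those segments to ~{0, 0.01, -0.01, -1.00}."""
        means = [0.30, 0.31, 0.29, -0.70]
        marks = [1000, 1000, 1000, 100]
        expected_mode = oracle_weighted_kde_mode(np.array(means), np.array(marks, float))
        assert expected_mode == pytest.approx(0.30, abs=0.01)
        out = autocorrect_baseline(_table(means, marks))
        got = out.df["seg_mean"].to_numpy()
        assert np.allclose(got, np.array(means) - expected_mode, atol=2e-3)
        assert got[-1] == pytest.approx(-1.0, abs=0.01)

    def test_already_centered_table_is_unchanged(self):
        t = _table([0.0, 0.01, -0.01, -1.0], [500, 500, 500, 50])
        out = autocorrect_baseline(t)
        assert np.allclose(out.df["seg_mean"], t.df["seg_mean"], atol=1e-3)

    def test_single_segment_sample_centers_to_zero(self, caplog):
        t = _table([0.37], [100])
        out = autocorrect_baseline(t)
        assert out.df["seg_mean"].iloc[0] == pytest.approx(0.0)

    def test_coordinates_and_marks_untouched(self):
        t = _table([0.3, -0.6, 0.29], [200, 50, 300])
        out = autocorrect_baseline(t)
        assert (out.df[["start", "end", "num_mark"]].to_numpy()
                == t.df[["start", "end", "num_mark"]].to_numpy()).all()

    @given(
        st.lists(st.floats(-1.5, 1.5, allow_nan=False), min_size=2, max_size=8),
        st.integers(0, 1000),
    )
    def test_idempotent_and_shift_equivariant(self, means, salt):
        """Correcting twice equals correcting once; a global shift of the
        input changes nothing about the output."""
        rng = np.random.default_rng(salt)
        marks = rng.integers(10, 2000, len(means))
        t = _table(means, marks)
        once = autocorrect_baseline(t)
        twice = autocorrect_baseline(once)
        assert np.allclose(once.df["seg_mean"], twice.df["seg_mean"], atol=1e-3)
        shifted = _table([m + 0.4 for m in means], marks)
        out_shifted = autocorrect_baseline(shifted)
        assert np.allclose(out_shifted.df["seg_mean"], once.df["seg_mean"], atol=1e-6)

    def test_unweighted_mode_ignores_marks(self):
        means = [0.3, 0.31, -0.7, -0.71, -0.69]
        # marks favor 0.3; counts favor -0.7
        t = _table(means, [5000, 5000, 10, 10, 10])
        weighted = autocorrect_baseline(t, weighted=True)
        unweighted = autocorrect_baseline(t, weighted=False)
        assert weighted.df["seg_mean"].iloc[0] == pytest.approx(0.0, abs=0.02)
        assert unweighted.df["seg_mean"].iloc[2] == pytest.approx(0.0, abs=0.02)


class TestKdeMode:
    def test_tie_broken_toward_zero(self):
        mode = kde_mode(np.array([-0.8, 0.2]), np.array([1.0, 1.0]))
        assert mode == pytest.approx(0.2, abs=5e-3)

    def test_degenerate_inputs(self):
        assert kde_mode(np.array([0.4])) == pytest.approx(0.4)
        assert kde_mode(np.array([0.4, 0.4, 0.4])) == pytest.approx(0.4)


class TestCallStates:
    @pytest.mark.parametrize(
        "mean,expected",
        [(-0.2, "loss"), (-0.21, "loss"), (0.19, "neutral"), (0.2, "gain"), (0.0, "neutral")],
    )
    def test_threshold_boundaries(self, mean, expected):
        out = call_states(_table([mean], [10]), StateCallParams(mode="threshold"))
        assert out.df["state"].iloc[0] == expected

    @pytest.mark.parametrize("mean,cn", [(-1.0, 1), (0.0, 2), (1.0, 4)])
    def test_formula_copy_numbers(self, mean, cn):
        out = call_states(_table([mean], [10]), StateCallParams(mode="formula"))
        assert out.df["state"].iloc[0] == str(cn)

    def test_formula_rounds_half_up(self):
        # 2^seg_mean * 2 = 2.5 at seg_mean = log2(1.25)
        out = call_states(_table([np.log2(1.25)], [10]), StateCallParams(mode="formula"))
        assert out.df["state"].iloc[0] == "3"

    def test_neutrality_consistent_between_modes(self):
        t = _table([0.0], [10])
        thr = call_states(t, StateCallParams(mode="threshold"))
        frm = call_states(t, StateCallParams(mode="formula"))
        assert thr.df["state"].iloc[0] == "neutral" and frm.df["state"].iloc[0] == "2"

    def test_invalid_cuts_rejected(self):
        with pytest.raises(ConfigurationError):
            call_states(_table([0.0], [10]), StateCallParams(loss_cut=0.3, gain_cut=0.2))


def _called_table(rows):
    return SegmentTable(segments_frame(rows))


def _cohort_tables(n_samples, call=None, span=(1, 1000)):
    """n samples tiling chr3:1-10000 neutral, optionally with one call."""
    tables = []
    for i in range(n_samples):
        rows = []
        if call is not None and call[0] == i:
            s, e = call[1]
            if s > 1:
                rows.append((f"S{i}", "chr3", 1, s - 1, 10, 0.0, "neutral"))
            rows.append((f"S{i}", "chr3", s, e, 10, -0.8, "loss"))
            if e < 10_000:
                rows.append((f"S{i}", "chr3", e + 1, 10_000, 10, 0.0, "neutral"))
        else:
            rows.append((f"S{i}", "chr3", 1, 10_000, 10, 0.0, "neutral"))
        tables.append(_called_table(rows))
    return tables


class TestConsensus:
    def test_unanimous_call_gives_single_full_support_region(self):
        tables = []
        for i in range(10):
            tables.append(
                _called_table(
                    [
                        (f"S{i}", "chr3", 1, 1000, 10, -0.9, "loss"),
                        (f"S{i}", "chr3", 1001, 10_000, 10, 0.0, "neutral"),
                    ]
                )
            )
        regions = consensus_regions(tables, density=0.1, rho=0.5)
        assert len(regions) == 1
        r = regions[0]
        assert (r.chrom, r.start, r.end, r.support_frac) == ("chr3", 1, 1000, 1.0)
        assert r.recurrent  # unanimous support beats any background rate

    def test_density_threshold_controls_single_sample_call(self):
        tables = _cohort_tables(10, call=(0, (501, 1500)))
        low = consensus_regions(tables, density=0.1, rho=0.5, est_recur=False)
        assert len(low) == 1 and low[0].support_frac == pytest.approx(0.1)
        high = consensus_regions(tables, density=0.2, rho=0.5, est_recur=False)
        assert high == []

    def test_forty_percent_reciprocal_overlap_stays_split(self):
        """Two 1000-bp calls sharing 400 bp do not cluster at rho = 0.5."""
        tables = [
            _called_table([("S0", "chr3", 1, 1000, 10, -0.9, "loss")]),
            _called_table([("S1", "chr3", 601, 1600, 10, -0.9, "loss")]),
            _called_table([("S2", "chr3", 1, 10_000, 10, 0.0, "neutral")]),
        ]
        regions = consensus_regions(tables, density=0.1, rho=0.5, est_recur=False)
        # separate clusters -> the shared stretch is reported per cluster
        starts = sorted(r.start for r in regions)
        assert len(regions) >= 2
        assert starts[0] == 1 and max(r.end for r in regions) == 1600

    def test_gains_and_losses_pool_separately(self):
        tables = [
            _called_table([("S0", "chr3", 1, 1000, 10, -0.9, "loss")]),
            _called_table([("S1", "chr3", 1, 1000, 10, 0.9, "gain")]),
        ]
        regions = consensus_regions(tables, density=0.1, rho=0.5, est_recur=False)
        assert {r.direction for r in regions} == {"loss", "gain"}
        for r in regions:
            assert r.n_support == 1

    def test_monotone_in_density_and_rho(self, rng):
        tables = []
        for i in range(8):
            s = int(rng.integers(1, 4000))
            e = s + int(rng.integers(500, 3000))
            tables.append(
                _called_table(
                    [
                        (f"S{i}", "chr3", s, e, 10, -0.8, "loss"),
                        (f"S{i}", "chr3", e + 1, 20_000, 10, 0.0, "neutral"),
                    ]
                )
            )
        def covered(regions):
            return {(r.chrom, b) for r in regions for b in range(r.start, r.end + 1)}
        r_loose = consensus_regions(tables, density=0.1, rho=0.3, est_recur=False)
        r_dense = consensus_regions(tables, density=0.4, rho=0.3, est_recur=False)
        assert covered(r_dense) <= covered(r_loose)
        n_clusters_low = len(consensus_regions(tables, density=0.1, rho=0.2, est_recur=False))
        n_clusters_high = len(consensus_regions(tables, density=0.1, rho=0.9, est_recur=False))
        assert n_clusters_high >= n_clusters_low

    def test_parameter_validation(self):
        tables = _cohort_tables(2)
        with pytest.raises(ConfigurationError):
            consensus_regions(tables, density=0.0)
        with pytest.raises(ConfigurationError):
            consensus_regions(tables, rho=1.5)
        with pytest.raises(ConfigurationError):
            consensus_regions(tables[:1])
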