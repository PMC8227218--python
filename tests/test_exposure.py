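
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pipertdm import (
    BAND_ORDER,
    ExposureBand,
    attainment_fraction,
    band_distribution,
    bias_precision,
    classify_band,
    ft_above_mic,
    mortality_by_band,
    odds_ratio_woolf,
)


class TestClassifyBand:
    @pytest.mark.parametrize(
        "c,band",
        [
            (5.0, ExposureBand.LT16),
            (15.99, ExposureBand.LT16),
            (16.0, ExposureBand.B16_32),
            (31.99, ExposureBand.B16_32),
            (32.0, ExposureBand.B32_64),
            (54.0, ExposureBand.B32_64),  # cohort-median level is therapeutic
            (64.0, ExposureBand.B32_64),  # therapeutic band is closed
            (64.01, ExposureBand.B64_96),
            (96.0, ExposureBand.B64_96),
            (96.01, ExposureBand.GT96),
            (500.0, ExposureBand.GT96),
        ],
    )
    def test_boundary_convention(self, c, band):
        assert classify_band(c) is band

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            classify_band(0.0)

    @given(c=st.floats(0.01, 500))
    @settings(max_examples=100, deadline=None)
    def test_partition_is_complete(self, c):
        assert classify_band(c) in BAND_ORDER


class TestBandDistribution:
    def test_counts_sum_and_fractions_sum(self):
        rng = np.random.default_rng(3)
        obs = rng.uniform(1, 200, size=335)
        dist = band_distribution(obs)
        assert sum(dist.counts.values()) == 335
        assert sum(dist.fractions.values()) == pytest.approx(1.0)

    def test_reported_cohort_fractions(self, reported_band_counts):
        # {1, 18, 72, 66, 22} of 179 -> 0.6 / 10.1 / 40.2 / 36.9 / 12.3 %
        pct = [round(100 * f, 1) for f in reported_band_counts.fractions.values()]
        assert pct == [0.6, 10.1, 40.2, 36.9, 12.3]

    def test_fraction_above_therapeutic_floor(self, reported_band_counts):
        assert reported_band_counts.fraction_above(32.0) == pytest.approx(160 / 179)

    def test_degenerate_single_band(self):
        dist = band_distribution([50.0] * 7)
        assert dist.fractions[ExposureBand.B32_64] == 1.0

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            band_distribution([])

    def test_n_total_validation(self):
        with pytest.raises(ValueError):
            band_distribution([50.0, 40.0], n_total=1)

    def test_non_edge_threshold_rejected(self):
        dist = band_distribution([50.0])
        with pytest.raises(ValueError):
            dist.fraction_above(48.0)


class TestAttainment:
    def test_continuous_infusion_reduction(self):
        assert ft_above_mic(54.0, mic=16.0, multiple=1.0)
        assert not ft_above_mic(54.0, mic=16.0, multiple=4.0)

    def test_cohort_fraction_above_4x_mic(self, reported_band_counts):
        # above 4 x 16 mg/L = above the 64 mg/L band edge
        assert reported_band_counts.fraction_above(64.0) == pytest.approx(88 / 179)

    def test_attainment_fraction_from_series(self):
        assert attainment_fraction([10, 20, 70, 130], mic=16, multiple=4) == 0.5

    def test_validation(self):
        with pytest.raises(ValueError):
            ft_above_mic(54.0, mic=0.0)
        with pytest.raises(ValueError):
            ft_above_mic(54.0, multiple=0.5)


class TestBiasPrecision:
    def test_identity(self):
        bp = bias_precision([3.0, 5.0, 9.0], [3.0, 5.0, 9.0])
        assert bp.bias == 0.0 and bp.precision == 1.0

    def test_constant_ratio(self):
        bp = bias_precision([13.0, 6.5], [10.0, 5.0])
        assert bp.bias == pytest.approx(0.3)
        assert bp.precision == pytest.approx(1.3)

    def test_single_pair(self):
        bp = bias_precision([2.0], [1.0])
        assert bp.bias == 1.0 and bp.precision == 2.0 and bp.n == 1

    @given(scale=st.floats(0.01, 100))
    @settings(max_examples=40, deadline=None)
    def test_scale_invariance(self, scale):
        pred = np.array([4.0, 7.0, 2.5, 9.0])
        obs = np.array([3.0, 8.0, 2.0, 11.0])
        a = bias_precision(pred, obs)
        b = bias_precision(scale * pred, scale * obs)
        assert b.bias == pytest.approx(a.bias, rel=1e-12)
        assert b.precision == pytest.approx(a.precision, rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            bias_precision([1.0, -1.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            bias_precision([], [])


class TestOddsRatioWoolf:
    def test_high_band_table(self):
        r = odds_ratio_woolf(13, 8, 17, 55)
        assert round(r.or_value, 3) == 5.257
        assert round(r.ci_low, 3) == 1.867
        assert round(r.ci_high, 3) == 14.802
        assert r.ci_low < r.or_value < r.ci_high

    def test_moderate_band_table(self):
        r = odds_ratio_woolf(30, 36, 17, 55)
        assert round(r.or_value, 3) == 2.696
        assert round(r.ci_low, 3) == 1.301
        assert round(r.ci_high, 3) == 5.586

    def test_symmetric_table_is_null(self):
        r = odds_ratio_woolf(9, 9, 9, 9)
        assert r.or_value == 1.0

    def test_zero_cell_instructs_haldane(self):
        with pytest.raises(ValueError, match="[Hh]aldane"):
            odds_ratio_woolf(0, 10, 5, 5)
        r = odds_ratio_woolf(0, 10, 5, 5, haldane=True)
        assert r.or_value == pytest.approx((0.5 * 5.5) / (10.5 * 5.5))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio_woolf(-1, 2, 3, 4)

    def test_reference_swap_inverts(self):
        r = odds_ratio_woolf(13, 8, 17, 55)
        s = odds_ratio_woolf(17, 55, 13, 8)
        assert s.or_value == pytest.approx(1.0 / r.or_value, rel=1e-12)
        assert s.ci_low == pytest.approx(1.0 / r.ci_high, rel=1e-12)
        assert s.ci_high == pytest.approx(1.0 / r.ci_low, rel=1e-12)

    def test_against_independent_implementation(self):
        # statsmodels' Table2x2 implements the same log-OR interval
        # independently of this package
        sm_ct = pytest.importorskip("statsmodels.stats.contingency_tables")
        rng = np.random.default_rng(11)
        for _ in range(200):
            a, b, c, d = rng.integers(1, 200, size=4)
            mine = odds_ratio_woolf(int(a), int(b), int(c), int(d))
            table = sm_ct.Table2x2(np.array([[a, b], [c, d]]))
            lo, hi = table.oddsratio_confint(0.05)
            assert mine.or_value == pytest.approx(table.oddsratio, rel=1e-10)
            assert mine.ci_low == pytest.approx(lo, rel=1e-10)
            assert mine.ci_high == pytest.approx(hi, rel=1e-10)


class TestMortalityByBand:
    def test_reported_rates(self):
        bands = (
            [ExposureBand.GT96] * 21
            + [ExposureBand.B32_64] * 72
        )
        outcomes = [1] * 13 + [0] * 8 + [1] * 17 + [0] * 55
        table = mortality_by_band(bands, outcomes)
        assert table[ExposureBand.GT96]["rate"] == pytest.approx(13 / 21)
        assert round(100 * table[ExposureBand.GT96]["rate"]) == 62
        assert round(100 * table[ExposureBand.B32_64]["rate"]) == 24
        r = table[ExposureBand.GT96]["or"]
        assert round(r.or_value, 3) == 5.257

    def test_all_survivors_gives_zero_rates_and_no_ors(self):
        bands = [ExposureBand.B32_64] * 5 + [ExposureBand.GT96] * 5
        table = mortality_by_band(bands, [0] * 10)
        assert table[ExposureBand.B32_64]["rate"] == 0.0
        assert table[ExposureBand.GT96]["or"] is None

    def test_empty_band_rate_undefined(self):
        table = mortality_by_band([ExposureBand.B32_64] * 4, [1, 0, 0, 1])
        assert table[ExposureBand.LT16]["rate"] is None
        assert table[ExposureBand.LT16]["or"] is None

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mortality_by_band([ExposureBand.B32_64], [0, 1])
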