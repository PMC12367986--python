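"""Duration/pattern classification and the ADD/LADD/ADR dose metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ltlrisk.exposure import (
    ConcentrationPolicy,
    ConcentrationSeries,
    DoseMode,
    DurationBin,
    ExposureScenario,
    PopulationGroup,
    classify_duration,
    classify_pattern,
    dose_metrics,
    evaluate_peaks,
    select_exposure_concentration,
)


def scenario(cw=0.0054, group=None, ed_days=140.0, **kw):
    return ExposureScenario(cw_mg_per_L=cw,
                            group=group or PopulationGroup.adult(),
                            ed_days=ed_days, **kw)


class TestClassifyDuration:
    @pytest.mark.parametrize("ed,expected", [
        (140, DurationBin.short),          # the 20-week case study
        (1, DurationBin.acute),
        (14, DurationBin.acute),           # right edge of the acute bin
        (14.0001, DurationBin.short),
        (365, DurationBin.short),
        (366, DurationBin.intermediate),
        (7 * 365, DurationBin.intermediate),
        (10 * 365, DurationBin.beyond_LTL),
    ])
    def test_bins(self, ed, expected):
        assert classify_duration(ed) is expected

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            classify_duration(0)

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(min_value=1e-3, max_value=1e5))
    def test_partition_no_gaps_or_overlaps(self, ed):
        assert classify_duration(ed) in DurationBin


class TestClassifyPattern:
    def test_constant_series_is_continuous(self):
        s = ConcentrationSeries(np.arange(10.0), np.full(10, 5.4))
        assert classify_pattern(s).value == "continuous"

    def test_oscillating_no_zero_series_is_fluctuating(self):
        t = np.arange(140.0)
        v = 3.9 + 1.5 * np.sin(t / 3)  # oscillates 2.4..5.4, never near zero
        s = ConcentrationSeries(t, v)
        assert classify_pattern(s).value == "fluctuating"

    def test_pulse_train_with_gaps_is_intermittent(self):
        # Direct-scan oracle: constant pulses separated by below-floor gaps.
        v = np.array([5.0] * 7 + [0.0] * 7 + [5.0] * 7 + [0.0] * 7 + [5.0] * 7)
        s = ConcentrationSeries(np.arange(float(len(v))), v)
        assert classify_pattern(s).value == "intermittent"

    def test_gaps_plus_within_episode_variability_is_mixed(self):
        v = np.array([2.0, 9.0, 3.0, 8.0] + [0.0] * 5 + [9.0, 2.0, 8.0, 3.0])
        s = ConcentrationSeries(np.arange(float(len(v))), v)
        assert classify_pattern(s).value == "mixed"


class TestDoseMetrics:
    def test_adult_case_study_add(self):
        dm = dose_metrics(scenario())
        assert round(dm.add, 5) == pytest.approx(1.5e-4, rel=1e-6)

    def test_child_case_study_add(self):
        dm = dose_metrics(scenario(group=PopulationGroup.child()))
        assert dm.add == pytest.approx(4.5e-4)

    def test_zero_concentration_gives_zero_everything(self):
        dm = dose_metrics(scenario(cw=0.0))
        assert dm.add == dm.ladd == dm.adr == 0.0

    def test_ladd_scales_add_by_duration_over_lifetime(self):
        # Hand arithmetic: LADD = ADD x 140 / (70 x 365) = ADD x 140/25550
        dm = dose_metrics(scenario())
        assert dm.ladd == pytest.approx(dm.add * 140.0 / 25550.0)
        assert dm.ladd == pytest.approx(8.4e-7, rel=0.01)

    def test_metric_ordering_adr_add_ladd(self):
        dm = dose_metrics(scenario(ef_fraction=0.5))
        assert dm.adr >= dm.add >= dm.ladd

    def test_ladd_equals_add_when_exposure_spans_lifetime(self):
        dm = dose_metrics(scenario(ed_days=70 * 365.0))
        assert dm.ladd == pytest.approx(dm.add)

    def test_intake_in_micrograms(self):
        dm = dose_metrics(scenario())
        assert dm.intake_ug_per_day() == pytest.approx(5.4 * 2)  # Cw(µg/L) x IR

    @settings(derandomize=True, max_examples=100)
    @given(cw=st.floats(min_value=1e-6, max_value=10.0),
           ir=st.floats(min_value=0.1, max_value=5.0),
           bw=st.floats(min_value=3.0, max_value=120.0),
           k=st.floats(min_value=0.1, max_value=10.0))
    def test_linearity_in_cw_and_ir_inverse_in_bw(self, cw, ir, bw, k):
        g = PopulationGroup("custom", bw, ir)
        base = dose_metrics(scenario(cw=cw, group=g)).add
        assert dose_metrics(scenario(cw=k * cw, group=g)).add == pytest.approx(k * base)
        g2 = PopulationGroup("custom", bw, k * ir)
        assert dose_metrics(scenario(cw=cw, group=g2)).add == pytest.approx(k * base)
        g3 = PopulationGroup("custom", k * bw, ir)
        assert dose_metrics(scenario(cw=cw, group=g3)).add == pytest.approx(base / k)


class TestSelectExposureConcentration:
    def case_series(self):
        t = np.arange(140.0) * 86400
        v = 3.9 + 1.5 * np.sin(np.arange(140.0) / 3)
        return ConcentrationSeries(t, v)

    def test_peak_policy_returns_maximum(self):
        s = ConcentrationSeries(np.arange(3.0), np.array([2.4, 5.4, 3.8]))
        assert select_exposure_concentration(s, ConcentrationPolicy.peak) == 5.4

    def test_constant_series_same_under_every_policy(self):
        s = ConcentrationSeries(np.arange(5.0), np.full(5, 3.3))
        for policy in ConcentrationPolicy:
            assert select_exposure_concentration(s, policy) == pytest.approx(3.3)

    def test_sawtooth_time_weighted_mean_is_midpoint(self):
        # Closed form: a 0..10 triangle wave integrates to mean 5.
        t = np.arange(201.0)
        v = np.abs((t % 20) - 10)
        s = ConcentrationSeries(t, v)
        tw = select_exposure_concentration(s, ConcentrationPolicy.time_weighted_mean)
        assert tw == pytest.approx(5.0, rel=1e-6)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=100), min_size=2, max_size=50))
    def test_peak_dominates_time_weighted_mean_dominates_min(self, values):
        s = ConcentrationSeries(np.arange(float(len(values))), np.array(values))
        peak = select_exposure_concentration(s, ConcentrationPolicy.peak)
        tw = select_exposure_concentration(s, ConcentrationPolicy.time_weighted_mean)
        assert peak >= tw >= min(values) - 1e-12


class TestEvaluatePeaks:
    def series(self, peak=5.4):
        return ConcentrationSeries(np.arange(3.0), np.array([2.4, peak, 3.8]))

    def test_small_peak_does_not_exceed_arfd(self):
        v = evaluate_peaks(self.series(), scenario(), arfd=0.5)
        assert not v.exceeds and v.basis == "arfd"
        assert v.adr == pytest.approx(5.4e-3 * 2 / 70)

    def test_equality_is_not_exceedance(self):
        sc = scenario()
        adr = evaluate_peaks(self.series(), sc, arfd=1.0).adr
        assert not evaluate_peaks(self.series(), sc, arfd=adr).exceeds

    def test_fallback_route_uses_factor_times_chronic_value(self):
        sc = scenario()
        adr = evaluate_peaks(self.series(), sc, arfd=1.0).adr
        below = evaluate_peaks(self.series(), sc, fallback_factor=3.0,
                               chronic_hbgv=adr / 2)
        assert not below.exceeds and below.basis == "pragmatic_fallback"
        above = evaluate_peaks(self.series(), sc, fallback_factor=3.0,
                               chronic_hbgv=adr / 4)
        assert above.exceeds

    def test_no_arfd_and_no_chronic_value_cannot_evaluate(self):
        with pytest.raises(ValueError):
            evaluate_peaks(self.series(), scenario())


class TestSeriesIO:
    def test_csv_round_trip(self, tmp_path):
        s = ConcentrationSeries(np.array([0.0, 60.0, 120.0]),
                                np.array([1.0, 2.0, 3.0]), label="x")
        p = s.to_csv(tmp_path / "s.csv")
        s2 = ConcentrationSeries.from_csv(p)
        np.testing.assert_allclose(s2.time_s, s.time_s)
        np.testing.assert_allclose(s2.ug_per_L, s.ug_per_L)

    def test_invalid_series_rejected(self):
        with pytest.raises(ValueError):
            ConcentrationSeries(np.array([1.0, 1.0]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            ConcentrationSeries(np.array([0.0]), np.array([-1.0]))
        with pytest.raises(ValueError):
            ConcentrationSeries(np.array([]), np.array([]))
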