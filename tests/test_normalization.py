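"""Two-point bead normalization: peak detection, model algebra, study-level."""

import numpy as np
import pytest

from cytoconsensus import (
    PeakPair,
    apply_norm,
    detect_control_peaks,
    fit_two_point_norm,
    generate_study,
    normalize_study,
    reference_design,
)
from cytoconsensus.errors import (
    DegenerateControlError,
    TooFewEventsError,
    UnimodalError,
)
from cytoconsensus.io_model import SampleType
from cytoconsensus.popstats import tx_compare


class TestDetectControlPeaks:
    def test_degenerate_two_spikes(self):
        values = np.r_[np.full(500, 100.0), np.full(500, 10_000.0)]
        pair = detect_control_peaks(values)
        assert pair.low == 100.0
        assert pair.high == 10_000.0

    def test_lognormal_mixture_medians(self):
        rng = np.random.default_rng(17)
        low = 200.0 * np.exp(rng.normal(0, 0.3, 2500))
        high = 5000.0 * np.exp(rng.normal(0, 0.3, 2500))
        pair = detect_control_peaks(np.r_[low, high])
        # oracle: exhaustive threshold scan between the component supports
        values = np.r_[low, high]
        split = np.exp((np.log(200) + np.log(5000)) / 2)
        lo_med = np.median(values[values <= split])
        hi_med = np.median(values[values > split])
        assert abs(pair.low - lo_med) / lo_med < 0.02
        assert abs(pair.high - hi_med) / hi_med < 0.02
        assert abs(pair.low - 200) / 200 < 0.05
        assert abs(pair.high - 5000) / 5000 < 0.05

    def test_unimodal_raises(self):
        rng = np.random.default_rng(2)
        with pytest.raises(UnimodalError):
            detect_control_peaks(1000 * np.exp(rng.normal(0, 0.3, 3000)))

    def test_too_few_events(self):
        with pytest.raises(TooFewEventsError):
            detect_control_peaks(np.r_[np.full(50, 1.0), np.full(50, 100.0)])

    def test_mean_statistic(self):
        values = np.r_[np.full(500, 100.0), np.full(500, 10_000.0)]
        pair = detect_control_peaks(values, statistic="mean")
        assert pair.statistic == "mean"
        assert pair.low == 100.0


class TestTwoPointModel:
    def test_worked_example(self):
        model = fit_two_point_norm(PeakPair(100, 1100), PeakPair(50, 550), "ICAM1")
        assert model.slope_ratio == pytest.approx(2.0)
        assert apply_norm(model, np.array([550.0]))[0] == pytest.approx(1100.0)

    def test_identity_when_pairs_equal(self):
        pair = PeakPair(120.0, 9000.0)
        model = fit_two_point_norm(pair, pair, "CD31")
        x = np.linspace(-100, 1e5, 50)
        np.testing.assert_allclose(apply_norm(model, x), x, rtol=1e-12)

    def test_matches_line_through_two_points_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            lo1, lo2 = rng.uniform(10, 500, 2)
            hi1, hi2 = lo1 + rng.uniform(100, 5e4), lo2 + rng.uniform(100, 5e4)
            model = fit_two_point_norm(PeakPair(lo1, hi1), PeakPair(lo2, hi2), "c")
            x = rng.uniform(-1e3, 1e5, 100)
            # oracle: unique affine map through (lo2, lo1) and (hi2, hi1)
            slope = (hi1 - lo1) / (hi2 - lo2)
            expected = lo1 + slope * (x - lo2)
            np.testing.assert_allclose(apply_norm(model, x), expected, rtol=1e-9)

    def test_anchors_map_exactly(self):
        model = fit_two_point_norm(PeakPair(80, 7000), PeakPair(30, 2500), "c")
        assert apply_norm(model, np.array([30.0]))[0] == pytest.approx(80.0)
        assert apply_norm(model, np.array([2500.0]))[0] == pytest.approx(7000.0)

    def test_monotone(self):
        model = fit_two_point_norm(PeakPair(80, 7000), PeakPair(30, 2500), "c")
        x = np.sort(np.random.default_rng(1).uniform(0, 1e4, 200))
        assert np.all(np.diff(apply_norm(model, x)) > 0)

    def test_variance_scaling(self):
        model = fit_two_point_norm(PeakPair(100, 1100), PeakPair(50, 550), "c")
        x = np.random.default_rng(8).lognormal(5, 1, 5000)
        out = apply_norm(model, x)
        assert np.var(out) == pytest.approx(model.slope_ratio**2 * np.var(x),
                                            rel=1e-12)

    def test_composition_is_identity(self):
        d1, d2 = PeakPair(100, 1100), PeakPair(50, 550)
        fwd = fit_two_point_norm(d1, d2, "c")
        back = fit_two_point_norm(d2, d1, "c")
        x = np.random.default_rng(4).uniform(-100, 1e4, 300)
        np.testing.assert_allclose(apply_norm(back, apply_norm(fwd, x)), x,
                                   rtol=1e-12, atol=1e-9)

    def test_degenerate_source_raises(self):
        with pytest.raises((DegenerateControlError, Exception)):
            fit_two_point_norm(PeakPair(1, 2), PeakPair(5.0, 5.0), "c")


@pytest.fixture(scope="module")
def normalized(small_study):
    return normalize_study(small_study)


class TestNormalizeStudy:

    def test_distorted_channel_gets_nonidentity_model(self, normalized):
        _, report = normalized
        day2 = report[report.day == 2].set_index("channel")
        assert not day2.loc["ICAM1", "identity"]
        assert day2.loc["ICAM1", "slope_ratio"] > 2.0  # inverse of 0.4 gain

    def test_bead_peaks_align_after_norm(self, normalized):
        study, _ = normalized
        from cytoconsensus.normalization import detect_control_peaks
        pairs = {}
        for day in (1, 2):
            beads = study.select(SampleType.bead_single_stain, day=day,
                                 stain_channel="ICAM1")[0][1]
            pairs[day] = detect_control_peaks(beads.channel("ICAM1"))
        assert pairs[2].high == pytest.approx(pairs[1].high, rel=0.02)
        assert pairs[2].low == pytest.approx(pairs[1].low, rel=0.05)

    def test_labeled_cells_agree_in_distribution(self, small_study, normalized):
        """After correction, day-2 unlabeled cells are statistically
        exchangeable with day-1 on the distorted channel."""
        study, _ = normalized
        def unl(s, day):
            return s.select(SampleType.unlabeled_cells, day=day)[0][1]
        before = tx_compare(unl(small_study, 1).channel("ICAM1"),
                            unl(small_study, 2).channel("ICAM1")).tx
        after = tx_compare(unl(study, 1).channel("ICAM1"),
                           unl(study, 2).channel("ICAM1")).tx
        assert before > 10.0
        assert after < 3.0

    def test_untouched_channels_identity(self, normalized):
        _, report = normalized
        day2 = report[report.day == 2].set_index("channel")
        assert day2.loc["CD31", "identity"] or \
            day2.loc["CD31", "slope_ratio"] == pytest.approx(1.0, abs=0.02)

    def test_no_batch_effect_means_exchangeable_beads(self):
        design = reference_design(batch_gain=1.0, batch_offset=0.0,
                                  events_per_sample={"bead": 2000,
                                                     "unlabeled": 500,
                                                     "labeled": 500})
        study = generate_study(design, seed=31)
        txs = []
        for ch in design.panel.channels:
            d1 = study.select(SampleType.bead_single_stain, day=1,
                              stain_channel=ch)[0][1].channel(ch)
            d2 = study.select(SampleType.bead_single_stain, day=2,
                              stain_channel=ch)[0][1].channel(ch)
            txs.append(tx_compare(d1, d2, B_requested=50).tx)
        assert np.mean(txs) < 1.0
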