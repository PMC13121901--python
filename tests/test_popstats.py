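"""Probability binning, T(x) calibration, adjusted significance, tables."""

import numpy as np

import pytest

from cytoconsensus import (
    ChannelPanel,
    EventMatrix,
    control_adjusted_tx,
    marker_positivity,
    population_table,
    probability_bins,
    tx_score,
)
from cytoconsensus.errors import ParameterError, TooFewEventsError
from cytoconsensus.popstats import tx_compare


class TestProbabilityBins:
    def test_ten_percent_cap(self):
        rng = np.random.default_rng(0)
        scheme = probability_bins(rng.normal(size=2453), B_requested=1000)
        assert scheme.B == 245

    def test_equal_occupancy(self):
        values = np.arange(1.0, 101.0)
        scheme = probability_bins(values, B_requested=4)
        counts = np.bincount(scheme.assign(values), minlength=4)
        assert list(counts) == [25, 25, 25, 25]

    def test_occupancy_max_minus_min_le_1(self):
        rng = np.random.default_rng(1)
        values = rng.lognormal(5, 1, 1003)
        scheme = probability_bins(values, B_requested=40)
        counts = np.bincount(scheme.assign(values), minlength=scheme.B)
        assert counts.max() - counts.min() <= 1

    def test_multivariate_partitions_space(self):
        rng = np.random.default_rng(2)
        control = rng.normal(size=(1200, 3))
        scheme = probability_bins(control, B_requested=64)
        test = rng.normal(size=(5000, 3))
        bins = scheme.assign(test)
        # exhaustive check: every event lands in exactly one leaf
        assert bins.min() >= 0 and bins.max() < scheme.B
        assert bins.size == 5000
        # control occupancy near-even
        c = np.bincount(scheme.assign(control), minlength=scheme.B)
        assert c.max() - c.min() <= 1

    def test_too_few_events(self):
        with pytest.raises(TooFewEventsError):
            probability_bins(np.arange(15.0), B_requested=10)


class TestTxScore:
    def test_self_comparison_is_zero(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=2000)
        scheme = probability_bins(v, B_requested=100)
        assert tx_score(scheme, v, v).tx == 0.0

    def test_null_calibration(self):
        """Same-distribution pairs: the standardized chi-squared averages
        ~0 and the floored score rarely clears 3."""
        rng = np.random.default_rng(4)
        res = [tx_compare(rng.normal(size=10_000), rng.normal(size=10_000),
                          B_requested=100)
               for _ in range(200)]
        assert abs(np.mean([r.z for r in res])) < 0.3
        assert np.mean([r.tx > 3 for r in res]) < 0.05

    def test_unit_shift_is_huge(self):
        rng = np.random.default_rng(5)
        r = tx_compare(rng.normal(size=10_000), rng.normal(size=10_000) + 1.0,
                       B_requested=100)
        assert r.tx > 10

    def test_monotone_transform_invariance(self):
        """Quantile bins commute with strictly monotone maps."""
        rng = np.random.default_rng(6)
        c, t = rng.lognormal(4, 1, 4000), rng.lognormal(4.2, 1, 4000)
        raw = tx_compare(c, t, B_requested=80)
        mapped = tx_compare(np.arcsinh(c / 150), np.arcsinh(t / 150),
                            B_requested=80)
        assert raw.chi2 == pytest.approx(mapped.chi2, rel=1e-9)
        assert raw.tx == pytest.approx(mapped.tx, rel=1e-9)

    def test_bin_cap_honored_in_result(self):
        rng = np.random.default_rng(7)
        r = tx_compare(rng.normal(size=1000), rng.normal(size=400),
                       B_requested=500)
        assert r.B <= min(r.n_control, r.n_test) // 10

    def test_oversized_scheme_rejected(self):
        rng = np.random.default_rng(8)
        scheme = probability_bins(rng.normal(size=2000), B_requested=150)
        with pytest.raises(ParameterError):
            tx_score(scheme, rng.normal(size=2000), rng.normal(size=300))

    def test_empty_test_rejected(self):
        rng = np.random.default_rng(9)
        scheme = probability_bins(rng.normal(size=1000), B_requested=50)
        with pytest.raises(ParameterError):
            tx_score(scheme, rng.normal(size=1000), np.array([]))


class TestControlAdjusted:
    @staticmethod
    def _controls(rng, n=3000):
        # modest day-to-day drift gives the controls a realistic
        # variability level for the subtraction to work against
        unl = {1: rng.normal(size=n), 2: rng.normal(0.15, 1.0, size=n)}
        beads = {"beads_X": {1: rng.normal(size=n),
                             2: rng.normal(0.1, 1.0, size=n)}}
        return unl, beads

    def test_null_population_not_significant(self):
        rng = np.random.default_rng(10)
        unl, beads = self._controls(rng)
        res = control_adjusted_tx({"p": rng.normal(size=3000)}, unl, beads)
        assert not res.significant["p"]

    def test_shifted_population_significant(self):
        rng = np.random.default_rng(11)
        unl, beads = self._controls(rng)
        res = control_adjusted_tx({"p": rng.normal(size=3000) + 5.0}, unl, beads)
        assert res.significant["p"]
        assert res.adjusted["p"] > 0

    def test_overvariable_control_excluded(self):
        """A control whose day-to-day T(x) exceeds the unlabeled-cells
        level is dropped from the variability max."""
        rng = np.random.default_rng(12)
        unl, _ = self._controls(rng)
        beads = {"beads_amplified": {1: rng.normal(size=3000),
                                     2: rng.normal(size=3000) + 2.0}}
        res = control_adjusted_tx({"p": rng.normal(size=3000)}, unl, beads)
        assert "beads_amplified" in res.excluded_controls
        assert res.control_variability < res.control_tx["beads_amplified"]

    def test_missing_day_raises(self):
        rng = np.random.default_rng(13)
        with pytest.raises(ParameterError):
            control_adjusted_tx({"p": rng.normal(size=500)},
                                {1: rng.normal(size=500)}, {})


class TestMarkerPositivity:
    @staticmethod
    def _setup(shifts: dict[str, float], rng):
        panel = ChannelPanel(("CD45", "CD31", "PDPN", "ICAM1", "VCAM1"))
        n = 2500

        def draw(shift_map):
            cols = [np.abs(rng.normal(1, 0.3, n)) + shift_map.get(ch, 0.0)
                    for ch in panel.channels]
            return EventMatrix(np.column_stack(cols), panel)

        pop = draw(shifts)
        unl = {1: draw({}), 2: draw({})}
        controls = {"beads": {1: draw({}), 2: draw({})}}
        return pop, unl, controls

    def test_null_population_unassigned(self):
        rng = np.random.default_rng(14)
        pop, unl, ctl = self._setup({}, rng)
        call = marker_positivity(pop, unl, ctl)
        assert not any(call.positive.values())
        assert call.phenotype == "unassigned"

    @pytest.mark.parametrize("shifts,phenotype", [
        ({"VCAM1": 10.0}, "PvC"),
        ({"CD31": 10.0, "PDPN": 10.0, "ICAM1": 10.0, "VCAM1": 10.0}, "LEC"),
        ({"PDPN": 10.0, "VCAM1": 10.0}, "FRC"),
        ({"PDPN": 10.0, "ICAM1": 10.0, "VCAM1": 10.0}, "MRC-like"),
        ({ch: 10.0 for ch in ("CD45", "CD31", "PDPN", "ICAM1", "VCAM1")},
         "hematopoietic"),
    ])
    def test_phenotype_patterns(self, shifts, phenotype):
        rng = np.random.default_rng(15)
        pop, unl, ctl = self._setup(shifts, rng)
        call = marker_positivity(pop, unl, ctl)
        assert call.phenotype == phenotype


class TestPopulationTable:
    def test_reference_breakdown(self):
        """Frozen reference breakdown: four populations across two
        passages; derived percentages must reproduce exactly."""
        counts = {"population_1": (7052, 8), "population_2": (4910, 252),
                  "population_3": (366, 5388), "population_4": (77922, 86660)}
        labels, passages = [], []
        for name, (p5, p12) in counts.items():
            labels += [name] * (p5 + p12)
            passages += [5] * p5 + [12] * p12
        table = population_table(np.array(labels), np.array(passages),
                                 order=list(counts)).table.set_index("population")
        assert table.loc["Total labeled cells", "count"] == 182_558
        assert list(table["pct_total"].iloc[:4]) == [3.87, 2.83, 3.15, 90.15]
        assert table.loc["population_1", "count_P5"] == 7052
        assert table.loc["population_1", "pct_P5"] == 7.81
        assert table.loc["Total labeled cells", "count_P5"] == 90_250
        assert table.loc["population_4", "pct_P12"] == 93.88

    def test_single_population_is_hundred_percent(self):
        table = population_table(np.array(["only"] * 10),
                                 np.array([5] * 10)).table
        assert table["pct_total"].iloc[0] == 100.00

    def test_percentages_rederive_from_counts(self):
        rng = np.random.default_rng(16)
        labels = rng.choice(["a", "b", "c"], size=1000)
        passages = rng.choice([5, 12], size=1000)
        t = population_table(labels, passages).table.set_index("population")
        total = t.loc["Total labeled cells", "count"]
        for name in ("a", "b", "c"):
            expected = round(100.0 * t.loc[name, "count"] / total + 1e-9, 2)
            assert t.loc[name, "pct_total"] == pytest.approx(expected, abs=0.005)
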