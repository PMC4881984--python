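"""Count-based phagocytosis metrics against hand sums and enumeration oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phagoquant import (
    CellCensus,
    UndefinedMetricError,
    ValidationError,
    baseline_mean_coupling,
    cell_density,
    distance_histogram,
    linear_r2,
    net_phagocytosis,
    ph_a_coupling,
    ph_index,
    summarize_censuses,
    weighted_capacity,
)


class TestPhIndex:
    def test_half_engulfed(self, simple_census):
        assert ph_index(simple_census) == 0.5

    def test_zero_numerator(self):
        c = CellCensus("s", "g", apo_total=7, apo_phagocytosed=0, microglia_total=10)
        assert ph_index(c) == 0.0

    def test_all_engulfed_gives_one(self):
        c = CellCensus("s", "g", apo_total=9, apo_phagocytosed=9, microglia_total=10)
        assert ph_index(c) == 1.0

    def test_undetectable_apoptosis_is_an_error_naming_the_sample(self):
        c = CellCensus("ctrl7", "g", apo_total=0, apo_phagocytosed=0, microglia_total=5)
        with pytest.raises(UndefinedMetricError, match="ctrl7"):
            ph_index(c)

    def test_binomial_sampling_concentrates_on_engulfment_probability(self, rng):
        n = 10_000
        engulfed = rng.binomial(n, 0.9)
        c = CellCensus("s", "g", n, int(engulfed), 10)
        assert ph_index(c) == pytest.approx(0.9, abs=0.01)


class TestWeightedCapacity:
    @pytest.mark.parametrize(
        "hist,total,expected",
        [
            ({1: 15, 2: 5}, 100, 0.25),
            ({}, 50, 0.0),
            ({7: 40}, 40, 7.0),  # every cell at the observed maximum
        ],
    )
    def test_hand_cases(self, hist, total, expected):
        assert weighted_capacity(hist, total) == pytest.approx(expected)

    def test_zero_cells_undefined(self):
        with pytest.raises(UndefinedMetricError):
            weighted_capacity({1: 1}, 0)

    def test_histogram_exceeding_total_rejected(self):
        with pytest.raises(ValidationError):
            weighted_capacity({1: 30, 2: 30}, 50)

    @given(
        pouches=st.lists(st.integers(min_value=0, max_value=7), min_size=1, max_size=60)
    )
    @settings(max_examples=200, derandomize=True)
    def test_equals_per_cell_enumeration_oracle(self, pouches):
        """Capacity is the arithmetic mean of per-cell pouch counts."""
        hist: dict[int, int] = {}
        for p in pouches:
            if p > 0:
                hist[p] = hist.get(p, 0) + 1
        assert weighted_capacity(hist, len(pouches)) == pytest.approx(
            float(np.mean(pouches))
        )


class TestCouplingAndNet:
    def test_net_phagocytosis_hand_product(self, simple_census):
        assert net_phagocytosis(simple_census) == pytest.approx(100 * 0.25)

    def test_one_pouch_each_equals_microglia_count(self):
        c = CellCensus("s", "g", 50, 40, 40, pouch_histogram={1: 40})
        assert net_phagocytosis(c) == 40

    def test_raw_coupling_hand_case(self):
        c = CellCensus("s", "g", 50, 25, 100, pouch_histogram={1: 15, 2: 5})
        raw, fold = ph_a_coupling(c)
        assert raw == pytest.approx(0.25 * 100 / 50)
        assert fold is None

    def test_self_normalization_gives_fold_one(self, simple_census):
        raw, _ = ph_a_coupling(simple_census)
        _, fold = ph_a_coupling(simple_census, baseline_raw=raw)
        assert fold == pytest.approx(1.0)

    def test_scale_invariance(self):
        """Doubling net phagocytosis and apoptosis together leaves coupling fixed."""
        a = CellCensus("a", "g", 50, 25, 100, pouch_histogram={1: 20})
        b = CellCensus("b", "g", 100, 50, 200, pouch_histogram={1: 40})
        assert ph_a_coupling(a)[0] == pytest.approx(ph_a_coupling(b)[0])

    def test_baseline_mean_over_group(self):
        cs = [
            CellCensus("a", "ctrl", 10, 5, 10, {1: 2}),
            CellCensus("b", "ctrl", 20, 10, 10, {1: 8}),
            CellCensus("c", "ka", 40, 5, 10, {1: 2}),
        ]
        expected = np.mean([2 / 10, 8 / 20])
        assert baseline_mean_coupling(cs, "ctrl") == pytest.approx(expected)


class TestDensityAndDistances:
    def test_density_hand_division(self):
        assert cell_density(150, 0.05) == pytest.approx(3000.0)

    def test_density_round_trip(self):
        assert cell_density(123, 0.07) * 0.07 == pytest.approx(123)

    def test_invalid_volume(self):
        with pytest.raises(ValidationError):
            cell_density(1, 0.0)

    def test_distance_histogram_hand_binning(self):
        props = distance_histogram(
            [0.2, 0.4, 5, 12, 0.3], (0.0, 0.5, 3.0, 10.0, math.inf)
        )
        assert props == pytest.approx([0.6, 0.0, 0.2, 0.2])

    def test_all_touching(self):
        props = distance_histogram([0.0, 0.0, 0.0])
        assert props[0] == pytest.approx(1.0)

    @given(
        st.lists(st.floats(min_value=0, max_value=50), min_size=1, max_size=40),
    )
    @settings(max_examples=100, derandomize=True)
    def test_proportions_sum_to_one_and_order_invariant(self, distances):
        props = distance_histogram(distances)
        assert props.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(props, distance_histogram(distances[::-1]))

    def test_empty_distances_undefined(self):
        with pytest.raises(UndefinedMetricError):
            distance_histogram([])


class TestLinearR2:
    def test_collinear_is_one(self):
        assert linear_r2([1, 2, 3, 4], [2, 4, 6, 8]) == pytest.approx(1.0)

    def test_independent_y_is_near_zero(self, rng):
        x = np.arange(2000.0)
        y = rng.normal(size=2000)
        assert linear_r2(x, y) < 0.01

    def test_matches_residual_formula(self, rng):
        x = rng.normal(size=30)
        y = 2 * x + rng.normal(size=30)
        slope, intercept = np.polyfit(x, y, 1)
        ss_res = np.sum((y - slope * x - intercept) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert linear_r2(x, y) == pytest.approx(1 - ss_res / ss_tot)

    def test_constant_x_undefined(self):
        with pytest.raises(UndefinedMetricError):
            linear_r2([1, 1, 1], [1, 2, 3])


class TestSummaries:
    def test_determinism(self, simple_census):
        a = summarize_censuses([simple_census], "control")
        b = summarize_censuses([simple_census], "control")
        assert a.equals(b)

    def test_undefined_metrics_become_missing_with_reason(self):
        c = CellCensus("s0", "ctrl", 0, 0, 10, {1: 1})
        df = summarize_censuses([c])
        assert np.isnan(df.loc[0, "ph_index"])
        assert "zero_apoptotic_cells" in df.loc[0, "notes"]

    def test_invariant_violations_rejected(self):
        with pytest.raises(ValidationError):
            CellCensus("s", "g", apo_total=3, apo_phagocytosed=5, microglia_total=1)
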