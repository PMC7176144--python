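"""Strip-transect band correction: geometry, hand-checked arithmetic, variance."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import riversurvey as rs
from riversurvey.strip_estimator import BandCounts, StripEstimatorError
from conftest import strip_cell_scenario

P1, P2 = 0.960, 0.630


class TestBandCorrectionMap:
    def test_default_geometry_maps_outer_bands_to_p2(self):
        band_map = rs.band_correction_map(200.0, 100.0, P1, P2)
        assert band_map == {"b0_50": P2, "b50_100": P1, "b100_150": P1, "b150_200": P2}

    def test_mid_strip_trackline_is_symmetric(self):
        band_map = rs.band_correction_map(200.0, 100.0, P1, P2)
        assert band_map["b0_50"] == band_map["b150_200"]
        assert band_map["b50_100"] == band_map["b100_150"]

    def test_shore_trackline_is_monotone_in_distance(self):
        band_map = rs.band_correction_map(200.0, 0.0, P1, P2)
        values = [band_map[b] for b in ("b0_50", "b50_100", "b100_150", "b150_200")]
        assert values == sorted(values, reverse=True)
        assert values[0] == P1

    def test_wrong_width_does_not_partition(self):
        with pytest.raises(StripEstimatorError, match="partition"):
            rs.band_correction_map(250.0, 100.0, P1, P2)


class TestStripDensity:
    def test_hand_evaluated_estimator(self):
        # counts (1,1,1,1), E(s)=1, W=0.2 km, L=10 km, g0=1:
        # (1/0.63 + 1/0.96 + 1/0.96 + 1/0.63) / 2 = 2.62896...
        counts = BandCounts(1, 1, 1, 1)
        d = rs.strip_density(counts, 1.0, 10.0, 1.0, P1, P2)
        expected = (2 / P2 + 2 / P1) / 2.0
        assert d == pytest.approx(expected, rel=1e-12)
        assert d == pytest.approx(2.629, abs=5e-4)

    def test_perfect_detection_reduces_to_census(self):
        counts = BandCounts(3, 2, 4, 1)
        d = rs.strip_density(counts, 1.5, 20.0, 1.0, 1.0, 1.0)
        assert d == pytest.approx(1.5 * 10 / (0.2 * 20.0), rel=1e-12)

    def test_no_sightings_gives_zero(self):
        assert rs.strip_density(BandCounts(), 1.5, 20.0, 1.0, P1, P2) == 0.0

    def test_zero_effort_rejected(self):
        with pytest.raises(StripEstimatorError, match="effort"):
            rs.strip_density(BandCounts(1, 0, 0, 0), 1.0, 0.0, 1.0, P1, P2)

    @given(
        n1=st.integers(0, 20),
        n2=st.integers(0, 20),
        n3=st.integers(0, 20),
        n4=st.integers(0, 20),
        g0=st.floats(0.3, 1.0),
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_matches_per_sighting_horvitz_thompson_sum(self, n1, n2, n3, n4, g0):
        # the band formula must equal the brute-force sum over individual
        # groups of 1/P(band), whatever the configuration
        counts = BandCounts(n1, n2, n3, n4)
        band_map = rs.band_correction_map(200.0, 100.0, P1, P2)
        groups = (
            ["b0_50"] * n1 + ["b50_100"] * n2 + ["b100_150"] * n3 + ["b150_200"] * n4
        )
        brute = sum(1.0 / band_map[b] for b in groups)
        es, L = 1.7, 12.5
        expected = es * brute / (0.2 * L * g0)
        assert rs.strip_density(counts, es, L, g0, P1, P2) == pytest.approx(expected, rel=1e-9)

    def test_monotone_nonincreasing_in_probabilities(self):
        counts = BandCounts(2, 3, 1, 2)
        base = rs.strip_density(counts, 1.0, 10.0, 0.8, 0.9, 0.6)
        assert rs.strip_density(counts, 1.0, 10.0, 0.8, 0.95, 0.6) <= base
        assert rs.strip_density(counts, 1.0, 10.0, 0.8, 0.9, 0.65) <= base
        assert rs.strip_density(counts, 1.0, 10.0, 0.9, 0.9, 0.6) <= base


class TestStripCV:
    def test_zero_components_give_zero_cv(self):
        cv = rs.strip_density_cv([2.0, 2.0], [3.0, 3.0], 0.0, 0.0)
        assert cv == pytest.approx(0.0, abs=1e-12)

    def test_three_four_five_combination(self):
        # craft transects whose corrected encounter rate has CV 0.3, combine
        # with E(s) CV 0.4 and g0 CV 0: sqrt(0.09 + 0.16) = 0.5
        cv = rs.strip_density_cv([1.0, 1.0], [1.3, 0.7], 0.4, 0.0)
        assert cv == pytest.approx(0.5, rel=1e-9)

    def test_single_transect_cv_unavailable(self):
        assert math.isnan(rs.strip_density_cv([2.0], [3.0], 0.1, 0.1))

    def test_delta_agrees_with_transect_bootstrap(self):
        # resample transects of one simulated cell and compare the bootstrap
        # density CV against the delta-method combination
        scenario = strip_cell_scenario(seed=3, density=3.0, n_transects=40)
        transects, sightings, _ = rs.simulate_survey(scenario)
        config = rs.AnalysisConfig()
        est = rs.strip_cell_estimate(
            sightings, transects, "river_margin", 1.0, 0.0, config, stratum="downstream"
        )
        band_map = rs.band_correction_map(200.0, 100.0, config.p1, config.p2)
        by_tid = {t.transect_id: [] for t in transects}
        for s in rs.unique_groups(sightings):
            by_tid[s.transect_id].append(s)
        corr = np.array(
            [
                rs.band_counts_from_sightings(by_tid[t.transect_id]).corrected_total(band_map)
                for t in transects
            ]
        )
        lengths = np.array([t.length_km for t in transects])
        rng = np.random.default_rng(4)
        boots = []
        for _ in range(2000):
            idx = rng.integers(0, len(transects), len(transects))
            boots.append(corr[idx].sum() / lengths[idx].sum())
        cv_boot = np.std(boots, ddof=1) / np.mean(boots)
        cv_delta_er = math.sqrt(est.cv_density**2 - est.cv_group_size**2)
        assert cv_boot == pytest.approx(cv_delta_er, rel=0.2)


class TestBandDerivation:
    def test_band_derived_from_trackline_distance(self):
        s = rs.SightingRecord(
            "s1", "t1", "bow", 30.0, 90.0, 1, "river_margin", "downstream"
        )  # perp 30 m from the trackline -> inner bands (P1 side)
        counts = rs.band_counts_from_sightings([s])
        assert counts.n_b50_100 + counts.n_b100_150 == 1

    def test_unplaceable_record_dropped_with_warning(self):
        s = rs.SightingRecord(
            "s1", "t1", "bow", float("nan"), 45.0, 1, "river_margin", "downstream",
            perp_distance_m=float("nan"),
        )
        with pytest.warns(UserWarning, match="excluded"):
            counts = rs.band_counts_from_sightings([s])
        assert counts.total == 0


class TestStripRecovery:
    def test_unbiased_with_exact_band_probabilities(self):
        # detection uses exactly P1/P2 per band with one effective platform
        # and known g0 = 1, so the Horvitz-Thompson correction is exact:
        # the mean density ratio over 200 replicates stays within 3 MC SE of 1
        true_density = 2.0
        rng = np.random.default_rng(55)
        config = rs.AnalysisConfig()
        ratios = []
        for rep in range(200):
            scenario = strip_cell_scenario(seed=rep, density=true_density)
            transects, sightings, _ = rs.simulate_survey(scenario, rng=rng)
            est = rs.strip_cell_estimate(
                sightings, transects, "river_margin", 1.0, 0.0, config, stratum="downstream"
            )
            ratios.append(est.density / true_density)
        mean = float(np.mean(ratios))
        se = float(np.std(ratios, ddof=1)) / math.sqrt(len(ratios))
        assert abs(mean - 1.0) < 3 * se
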