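"""Line-transect density: hand-checked arithmetic, variance, recovery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import riversurvey as rs
from riversurvey.line_estimator import LineEstimatorError
from conftest import known_g0


def stub_fit(esw_m=200.0, cv_esw=0.0, truncation_m=300.0):
    """A DetectionFit with prescribed ESW, for arithmetic-only tests."""
    return rs.DetectionFit(
        key="half_normal",
        covariates=(),
        params=np.array([math.log(esw_m / math.sqrt(math.pi / 2))]),
        loglik=0.0,
        n_obs=1,
        n_params=1,
        aicc=0.0,
        esw_m=esw_m,
        f0_per_km=1000.0 / esw_m,
        p_avg=esw_m / truncation_m,
        cv_esw=cv_esw,
        truncation_m=truncation_m,
    )


def cell_fixture(n_sightings=4, group_size=2, effort_km=10.0, n_transects=2):
    transects = [
        rs.TransectRecord(f"t{i}", "line", effort_km / n_transects, "downstream", "river_channel")
        for i in range(n_transects)
    ]
    sightings = [
        rs.SightingRecord(
            f"s{i}",
            transects[i % n_transects].transect_id,
            "bow",
            60.0,
            30.0,
            group_size,
            "river_channel",
            "downstream",
        )
        for i in range(n_sightings)
    ]
    return transects, sightings


class TestLineDensity:
    def test_hand_evaluated_estimator(self):
        # n=4 groups, E(s)=2, ESW=0.2 km (f0 = 5/km), L=10 km, g0=1:
        # D = 4 * 2 * 5 / (2 * 10) = 2.0 individuals/km^2
        transects, sightings = cell_fixture()
        est = rs.line_density(
            sightings, transects, stub_fit(200.0), known_g0(), "river_channel", "downstream"
        )
        assert est.density == pytest.approx(2.0, rel=1e-12)
        assert est.n_groups == 4 and est.mean_group_size == 2.0

    def test_halving_g0_doubles_density(self):
        transects, sightings = cell_fixture()
        d1 = rs.line_density(
            sightings, transects, stub_fit(), known_g0(1.0), "river_channel", "downstream"
        ).density
        d2 = rs.line_density(
            sightings, transects, stub_fit(), known_g0(0.5), "river_channel", "downstream"
        ).density
        assert d2 == pytest.approx(2 * d1, rel=1e-12)

    def test_zero_sightings_gives_zero_density_flagged(self):
        transects, _ = cell_fixture()
        with pytest.warns(UserWarning, match="zero sightings"):
            est = rs.line_density(
                [], transects, stub_fit(), known_g0(), "river_channel", "downstream"
            )
        assert est.density == 0.0 and math.isnan(est.cv_density)

    def test_no_effort_is_an_error(self):
        with pytest.raises(LineEstimatorError, match="no line effort"):
            rs.line_density([], [], stub_fit(), known_g0(), "river_channel", "downstream")

    def test_sightings_beyond_truncation_excluded(self):
        transects, sightings = cell_fixture()
        far = rs.SightingRecord(
            "far", "t0", "bow", 600.0, 80.0, 2, "river_channel", "downstream"
        )
        est = rs.line_density(
            sightings + [far], transects, stub_fit(), known_g0(), "river_channel", "downstream"
        )
        assert est.n_groups == 4

    @given(
        n=st.integers(1, 60),
        es=st.integers(1, 4),
        esw=st.floats(20.0, 290.0),
        effort=st.floats(1.0, 100.0),
        g0=st.floats(0.2, 1.0),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_estimator_identity(self, n, es, esw, effort, g0):
        # D * (2 L g0 ESW) = n * E(s) is the estimator rearranged, and must
        # hold to floating-point accuracy for any cell
        transects = [rs.TransectRecord("t0", "line", effort, "upstream", "river_channel")]
        sightings = [
            rs.SightingRecord(
                f"s{i}", "t0", "bow", 50.0, 40.0, es, "river_channel", "upstream"
            )
            for i in range(n)
        ]
        est = rs.line_density(
            sightings, transects, stub_fit(esw), known_g0(g0), "river_channel", "upstream"
        )
        lhs = est.density * 2 * effort * g0 * (esw / 1000.0)
        assert lhs == pytest.approx(n * es, rel=1e-9)


class TestEncounterRateVariance:
    def test_identical_rates_have_zero_cv(self):
        rate, cv = rs.encounter_rate_variance([2.0, 2.0, 2.0], [4, 4, 4])
        assert rate == pytest.approx(2.0)
        assert cv == pytest.approx(0.0, abs=1e-12)

    def test_two_transect_hand_computation(self):
        # lengths 1 km each, counts 0 and 2: rate = 1 group/km and the
        # length-weighted between-transect variance is
        # 2/(4*1) * [1*(0-1)^2 + 1*(2-1)^2] = 1, so CV = 1
        rate, cv = rs.encounter_rate_variance([1.0, 1.0], [0, 2])
        assert rate == pytest.approx(1.0)
        assert cv == pytest.approx(1.0, rel=1e-12)

    def test_single_transect_has_undefined_cv(self):
        rate, cv = rs.encounter_rate_variance([5.0], [3])
        assert rate == pytest.approx(0.6)
        assert math.isnan(cv)

    def test_mean_of_ratios_mode(self):
        rate, _ = rs.encounter_rate_variance([1.0, 4.0], [1, 4], mode="mean_of_ratios")
        assert rate == pytest.approx(1.0)
        pooled, _ = rs.encounter_rate_variance([1.0, 4.0], [2, 4])
        assert pooled == pytest.approx(1.2)

    def test_poisson_counts_match_theoretical_cv(self):
        # independent Poisson counts on equal-length transects: the empirical
        # CV of the pooled rate should approach 1/sqrt(total expected count)
        rng = np.random.default_rng(21)
        k, length, lam = 40, 2.0, 3.0
        theory = 1.0 / math.sqrt(k * lam)
        cvs = []
        for _ in range(500):
            counts = rng.poisson(lam, size=k)
            if counts.sum() == 0:
                continue
            _, cv = rs.encounter_rate_variance([length] * k, counts)
            cvs.append(cv)
        assert np.mean(cvs) == pytest.approx(theory, rel=0.1)

    def test_length_mismatch_rejected(self):
        with pytest.raises(LineEstimatorError):
            rs.encounter_rate_variance([1.0, 2.0], [1])


class TestDensityRecovery:
    def test_mean_density_ratio_near_one(self):
        # simulate half-normal detection with one effective platform and a
        # known g0 = 1; fit the matching key and run the full estimator.
        # 200 replicates at roughly 100 sightings each should recover the
        # true density within Monte-Carlo error and inside [0.9, 1.1].
        from conftest import line_cell_scenario

        true_density = 7.5
        rng = np.random.default_rng(99)
        ratios = []
        for rep in range(200):
            scenario = line_cell_scenario(seed=rep, density=true_density)
            transects, sightings, _ = rs.simulate_survey(scenario, rng=rng)
            fit = rs.fit_detection(sightings, "half_normal", (), truncation_m=300.0)
            est = rs.line_density(
                sightings, transects, fit, known_g0(), "river_channel", "downstream"
            )
            ratios.append(est.density / true_density)
        mean = float(np.mean(ratios))
        se = float(np.std(ratios, ddof=1)) / math.sqrt(len(ratios))
        assert abs(mean - 1.0) < 3 * se
        assert 0.9 < mean < 1.1
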