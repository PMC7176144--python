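"""Shared fixtures: tiny hand-built surveys and single-cell simulation scenarios."""

from __future__ import annotations

import math

import numpy as np
import pytest

import riversurvey as rs


@pytest.fixture
def tiny_survey():
    """Two transects (one line, one strip) and three hand-built sightings."""
    transects = [
        rs.TransectRecord("L1", "line", 5.0, "downstream", "river_channel"),
        rs.TransectRecord("S1", "strip", 4.0, "downstream", "river_margin"),
    ]
    sightings = [
        rs.SightingRecord("a", "L1", "bow", 100.0, 30.0, 2, "river_channel", "downstream"),
        rs.SightingRecord(
            "b", "L1", "stern", 40.0, 45.0, 1, "river_channel", "downstream", duplicate_of="a"
        ),
        rs.SightingRecord(
            "c", "S1", "bow", 80.0, 60.0, 1, "river_margin", "downstream", shore_band="b50_100"
        ),
    ]
    return transects, sightings


def draw_hazard_distances(
    rng: np.random.Generator, n: int, sigma: float = 80.0, b: float = 2.5, w: float = 300.0
) -> np.ndarray:
    """Rejection-sample perpendicular distances from a hazard-rate detection
    density on [0, w] (g <= 1 is its own envelope under a uniform proposal)."""
    out: list[float] = []
    while len(out) < n:
        x = rng.uniform(0.0, w, size=4 * n)
        g = 1.0 - np.exp(-np.minimum((x / sigma) ** (-b), 700.0))
        out.extend(x[rng.random(4 * n) < g].tolist())
    return np.asarray(out[:n])


def line_cell_scenario(
    seed: int,
    density: float = 7.5,
    n_transects: int = 40,
    length_km: float = 2.5,
    key: str = "half_normal",
    sigma: float = 80.0,
    shape: float = 2.5,
    platform_effect: float = 0.0,
    p_bow: float = 1.0,
    p_stern: float = 1e-12,
    es_mean: float = 1.5,
    max_perp_m: float = 300.0,
) -> rs.SimulationScenario:
    """Single line-transect cell with known density.

    The default near-zero stern probability makes the bow the only effective
    platform, so observed distances follow the key function exactly and the
    trackline probability is known to be 1.
    """
    return rs.SimulationScenario(
        areas=rs.AreaTable({("river_channel", "downstream"): 100.0}),
        true_density={("river_channel", "downstream"): density},
        detection=rs.DetectionSpec(
            key=key,
            scale_m=sigma,
            shape=shape,
            platform_effect=platform_effect,
            p_bow_trackline=p_bow,
            p_stern_trackline=p_stern,
        ),
        effort_plan=[
            rs.EffortPlanEntry("downstream", "river_channel", "line", n_transects, length_km)
        ],
        group_size_mean={"river_channel": es_mean},
        seed=seed,
        max_perp_m=max_perp_m,
    )


def strip_cell_scenario(
    seed: int,
    density: float = 2.0,
    n_transects: int = 30,
    length_km: float = 2.0,
    p1: float = 0.960,
    p2: float = 0.630,
    es_mean: float = 1.4,
    stratum: str = "downstream",
) -> rs.SimulationScenario:
    """Single strip cell detected with the exact band probabilities P1/P2
    (one effective platform), so the strip estimator with known g0 = 1 is
    unbiased by construction."""
    return rs.SimulationScenario(
        areas=rs.AreaTable({("river_margin", stratum): 50.0}),
        true_density={("river_margin", stratum): density},
        detection=rs.DetectionSpec(
            key="half_normal",
            scale_m=100.0,
            p_bow_trackline=1.0,
            p_stern_trackline=1e-12,
            strip_band_p=(p1, p2),
        ),
        effort_plan=[
            rs.EffortPlanEntry(stratum, "river_margin", "strip", n_transects, length_km)
        ],
        group_size_mean={"river_margin": es_mean},
        seed=seed,
    )


def known_g0(g0: float = 1.0, cv: float = 0.0) -> rs.G0Estimate:
    """A fixed external trackline probability for estimator-isolation tests."""
    q = math.sqrt(max(1.0 - g0, 0.0))
    return rs.G0Estimate(n1=1, n01=0, q_hat=q, g0=g0, cv=cv)
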