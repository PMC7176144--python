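"""Trackline detection probability g(0) from two semi-independent platforms.

Stern observers search unaware of bow detections ("one-way" independence),
so stern sightings close to the trackline act as trials of whether the bow
missed a group that was certainly there.  With n1 stern sightings within the
trackline band and n01 of them missed by the bow, the probability a group on
the line escapes one platform is q = n01/n1 and the probability it escapes
both is q^2, giving

    g(0) = 1 - q^2

Only stern sightings inform q; bow-conditional recaptures are not used.
The default CV treats q as a binomial proportion and propagates through the
square by the delta method; a seeded nonparametric bootstrap over the stern
band sightings is available as an alternative and as the fallback when the
delta method degenerates (q = 0 or 1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import survey_data as sd


class PerceptionError(ValueError):
    pass


@dataclass(frozen=True)
class G0Estimate:
    n1: int
    n01: int
    q_hat: float
    g0: float
    cv: float

    def __post_init__(self) -> None:
        if self.n01 > self.n1:
            raise PerceptionError(f"n01 ({self.n01}) cannot exceed n1 ({self.n1})")


def g0_from_counts(n1: int, n01: int) -> float:
    """g(0) = 1 - (n01/n1)^2."""
    if n1 <= 0:
        raise PerceptionError(
            "no stern sightings within the trackline band; supply a fixed "
            "external g(0) instead"
        )
    if n01 > n1 or n01 < 0:
        raise PerceptionError(f"need 0 <= n01 <= n1, got n01={n01}, n1={n1}")
    q = n01 / n1
    return 1.0 - q * q


def g0_cv(
    n1: int,
    n01: int,
    method: str = "delta",
    n_boot: int = 10_000,
    seed: int = 0,
) -> float:
    """CV of the g(0) estimate.

    ``delta``: Var(q) = q(1-q)/n1, |dg0/dq| = 2q, CV = 2q sqrt(Var(q)) / g0.
    ``bootstrap``: resample the n1 missed/seen indicators with replacement.
    Degenerate delta cases (n01 = 0 or n01 = n1) fall back to the bootstrap
    with a warning.
    """
    g0 = g0_from_counts(n1, n01)
    q = n01 / n1
    if method == "delta" and (n01 == 0 or n01 == n1):
        warnings.warn(
            f"delta-method CV degenerate at n01={n01}, n1={n1}; using bootstrap",
            stacklevel=2,
        )
        method = "bootstrap"
    if method == "delta":
        var_q = q * (1.0 - q) / n1
        se_g0 = 2.0 * q * math.sqrt(var_q)
        return se_g0 / g0
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        indicators = np.zeros(n1)
        indicators[:n01] = 1.0
        draws = rng.choice(indicators, size=(n_boot, n1), replace=True)
        q_b = draws.mean(axis=1)
        g0_b = 1.0 - q_b * q_b
        denom = g0 if g0 > 0 else float(np.mean(g0_b)) or 1.0
        return float(np.std(g0_b, ddof=1)) / denom
    raise PerceptionError(f"unknown CV method {method!r}")


def estimate_g0(
    sightings: Sequence[sd.SightingRecord],
    trackline_band_m: float = 50.0,
    cv_method: str = "delta",
    n_boot: int = 10_000,
    seed: int = 0,
) -> G0Estimate:
    """Estimate g(0) from double-platform line-transect sightings.

    n1 counts stern sightings with perpendicular distance within the band;
    n01 the subset without a ``duplicate_of`` link (missed by the bow).
    A degenerate survey where the bow missed every banded stern group
    (q = 1) yields g0 = 0 with an error-level warning: density is then
    undefined and the caller should fall back to an external g(0).
    """
    stern_band = [
        s
        for s in sightings
        if s.platform == "stern" and s.perp_distance_m <= trackline_band_m
    ]
    n1 = len(stern_band)
    n01 = sum(1 for s in stern_band if s.duplicate_of is None)
    g0 = g0_from_counts(n1, n01)
    if g0 == 0.0:
        warnings.warn(
            "every trackline-band stern sighting was missed by the bow: "
            "g(0) = 0 and density is undefined",
            stacklevel=2,
        )
        cv = math.nan
    else:
        cv = g0_cv(n1, n01, method=cv_method, n_boot=n_boot, seed=seed)
    return G0Estimate(n1=n1, n01=n01, q_hat=n01 / n1, g0=g0, cv=cv)
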