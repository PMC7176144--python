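"""Line-transect density per habitat x stratum cell.

Density of individuals follows the classical distance-sampling estimator

    D = n * E(s) * f(0) / (2 * L * g(0))

with n detected groups in the cell, E(s) the observed mean group size,
f(0) = 1/ESW the detection density at zero distance from the pooled fit,
L the cell's transect length and g(0) the trackline detection probability.
The detection function is fitted once, pooled across strata, and applied
per cell; only the encounter rate and group size are stratified.

The CV combines the independent components by the delta method:

    CV^2(D) = CV^2(n/L) + CV^2(ESW) + CV^2(E(s)) + CV^2(g0)

where the encounter-rate variance is the classical between-transect
estimator with transects weighted by length.
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import numpy as np

from . import survey_data as sd
from .detection import DetectionFit
from .perception import G0Estimate
from .results import StratumEstimate


class LineEstimatorError(ValueError):
    pass


def encounter_rate_variance(
    transect_lengths_km: Sequence[float],
    transect_counts: Sequence[int],
    mode: str = "pooled",
) -> tuple[float, float]:
    """Encounter rate (groups/km) and its CV for one cell.

    ``pooled`` (default): rate = total groups / total length with the
    length-weighted between-transect variance

        var(n/L) = k / (L^2 (k-1)) * sum_i l_i^2 (n_i/l_i - n/L)^2

    ``mean_of_ratios``: rate = mean of per-transect n_i/l_i with the plain
    sample variance of the ratios over k.  A single transect gives CV = NaN
    (variance unavailable).
    """
    lengths = np.asarray(transect_lengths_km, dtype=float)
    counts = np.asarray(transect_counts, dtype=float)
    if len(lengths) != len(counts):
        raise LineEstimatorError("length/count vectors differ in size")
    if len(lengths) == 0 or not np.all(lengths > 0):
        raise LineEstimatorError("need >= 1 transect with positive length")
    k = len(lengths)
    L = float(lengths.sum())
    if mode == "pooled":
        rate = float(counts.sum()) / L
        if k < 2:
            return rate, math.nan
        per = counts / lengths
        var = k / (L * L * (k - 1)) * float(np.sum(lengths**2 * (per - rate) ** 2))
    elif mode == "mean_of_ratios":
        per = counts / lengths
        rate = float(per.mean())
        if k < 2:
            return rate, math.nan
        var = float(per.var(ddof=1)) / k
    else:
        raise LineEstimatorError(f"unknown encounter-rate mode {mode!r}")
    if rate <= 0:
        return rate, math.nan
    return rate, math.sqrt(var) / rate


def line_density(
    sightings: Sequence[sd.SightingRecord],
    transects: Sequence[sd.TransectRecord],
    fit: DetectionFit,
    g0: G0Estimate,
    habitat: str,
    stratum: str | None = None,
    encounter_rate_mode: str = "pooled",
) -> StratumEstimate:
    """Density estimate for one habitat (x stratum) line-transect cell.

    ``stratum=None`` pools strata within the habitat.  Sightings beyond the
    fit's truncation distance are excluded; double-platform records are
    deduplicated to unique groups.  Zero sightings give density 0 with CV
    NaN (flagged by a warning).
    """
    if not 0 < g0.g0 <= 1:
        raise LineEstimatorError(f"g0 must be in (0, 1], got {g0.g0}")
    cell_transects = [
        t
        for t in transects
        if t.kind == "line"
        and t.habitat == habitat
        and (stratum is None or t.stratum == stratum)
    ]
    if not cell_transects:
        raise LineEstimatorError(f"no line effort for cell ({habitat}, {stratum or 'pooled'})")
    effort = sum(t.length_km for t in cell_transects)
    tids = {t.transect_id for t in cell_transects}
    groups = [
        s
        for s in sd.unique_groups(list(sightings))
        if s.transect_id in tids and s.perp_distance_m <= fit.truncation_m
    ]
    n = len(groups)
    if n == 0:
        warnings.warn(
            f"cell ({habitat}, {stratum or 'pooled'}): zero sightings; density 0 with undefined CV",
            stacklevel=2,
        )
        return StratumEstimate(
            habitat=habitat,
            stratum=stratum,
            protocol="line",
            n_groups=0,
            effort_km=effort,
            mean_group_size=math.nan,
            cv_group_size=math.nan,
            encounter_rate=0.0,
            cv_encounter_rate=math.nan,
            density=0.0,
            cv_density=math.nan,
        )

    sizes = np.array([s.group_size for s in groups], dtype=float)
    es = float(sizes.mean())
    cv_es = float(sizes.std(ddof=1)) / (es * math.sqrt(n)) if n > 1 else 0.0

    counts = {tid: 0 for tid in tids}
    for s in groups:
        counts[s.transect_id] += 1
    lengths = [t.length_km for t in cell_transects]
    per_counts = [counts[t.transect_id] for t in cell_transects]
    rate, cv_er = encounter_rate_variance(lengths, per_counts, mode=encounter_rate_mode)

    # units: f0_per_km [1/km] x n x E(s) / (2 L [km] g0) -> individuals/km^2
    density = n * es * fit.f0_per_km / (2.0 * effort * g0.g0)

    components = [cv_er, fit.cv_esw, cv_es, g0.cv]
    if any(math.isnan(c) for c in components):
        cv_d = math.nan
    else:
        cv_d = math.sqrt(sum(c * c for c in components))

    return StratumEstimate(
        habitat=habitat,
        stratum=stratum,
        protocol="line",
        n_groups=n,
        effort_km=effort,
        mean_group_size=es,
        cv_group_size=cv_es,
        encounter_rate=rate,
        cv_encounter_rate=cv_er,
        density=density,
        cv_density=cv_d,
    )
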