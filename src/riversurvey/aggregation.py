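"""Abundance per cell, stratified totals, total CV and confidence intervals.

Cell abundance scales density by the cell's surface area, N = D * A, with
SE(N) = SE(D) * A since areas are treated as known.  The total over cells is
the plain sum, and its CV is the ratio of summed standard errors to summed
abundances,

    CV(N_t) = sum SE(N_ij) / sum N_ij

(the sum of SEs, deliberately not the root-sum-of-squares).  Confidence
intervals use the conventional distance-sampling log-normal form

    N * exp(-+ z * sqrt(ln(1 + CV^2)))

Two stratification modes are supported: ``habitat_only`` (the pre-survey
habitat stratification, strata pooled) and ``geographic_post`` (habitat x
geographic stratum cells).  Post-stratification absorbs spatial density
heterogeneity and typically lowers the total CV when encounter rates differ
strongly among sub-regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy import stats

from . import survey_data as sd
from .results import StratumEstimate

STRATIFICATIONS = ("habitat_only", "geographic_post")


class AggregationError(ValueError):
    pass


def cell_abundance(density: float, area_km2: float, se_density: float = math.nan) -> tuple[float, float]:
    """N = D * A and SE(N) = SE(D) * A for one cell."""
    if not area_km2 > 0:
        raise AggregationError(f"area must be positive, got {area_km2}")
    return density * area_km2, se_density * area_km2


def total_cv(rows: Sequence[StratumEstimate]) -> float:
    """CV of the summed abundance: sum of SEs over sum of abundances."""
    total_n = sum(r.abundance for r in rows)
    if total_n == 0:
        return math.nan
    missing = [
        (r.habitat, r.stratum)
        for r in rows
        if r.abundance > 0 and not math.isfinite(r.se_abundance)
    ]
    if missing:
        raise AggregationError(
            f"cells with abundance but no SE: {missing}; cannot form the total CV"
        )
    total_se = sum(r.se_abundance for r in rows if r.abundance > 0)
    return total_se / total_n


def total_ci(total_n: float, cv: float, level: float = 0.95) -> tuple[float, float]:
    """Log-normal confidence interval for an abundance estimate."""
    if cv < 0:
        raise AggregationError(f"cv must be >= 0, got {cv}")
    if cv == 0:
        return total_n, total_n
    z = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
    c = math.exp(z * math.sqrt(math.log1p(cv * cv)))
    return total_n / c, total_n * c


@dataclass(frozen=True)
class AbundanceTable:
    """Stratified abundance report: one row per cell plus totals."""

    rows: tuple[StratumEstimate, ...]
    total_n: float
    total_cv: float
    total_ci: tuple[float, float]
    stratification: str

    def to_frame(self, rounded: bool = True) -> pd.DataFrame:
        """Report table with the survey-report column convention:
        E(s), n, L, Er, D, N, CV, A plus a TOTAL row.  Display rounding is
        N to integer, D and CV to 2 decimals; full precision is retained on
        the estimate objects."""
        recs = []
        for r in self.rows:
            recs.append(
                {
                    "habitat": r.habitat,
                    "stratum": r.stratum if r.stratum is not None else "all",
                    "Es": r.mean_group_size,
                    "n": r.n_groups,
                    "L": r.effort_km,
                    "Er": r.encounter_rate,
                    "D": r.density,
                    "N": r.abundance,
                    "CV": r.cv_density,
                    "A": r.area_km2,
                }
            )
        total_L = sum(r.effort_km for r in self.rows)
        total_n_groups = sum(r.n_groups for r in self.rows)
        total_area = sum(r.area_km2 for r in self.rows if math.isfinite(r.area_km2))
        recs.append(
            {
                "habitat": "TOTAL",
                "stratum": "",
                "Es": math.nan,
                "n": total_n_groups,
                "L": total_L,
                "Er": (total_n_groups / total_L) if total_L > 0 else math.nan,
                "D": (self.total_n / total_area) if total_area > 0 else math.nan,
                "N": self.total_n,
                "CV": self.total_cv,
                "A": total_area,
            }
        )
        frame = pd.DataFrame(recs, columns=["habitat", "stratum", "Es", "n", "L", "Er", "D", "N", "CV", "A"])
        if rounded:
            frame["N"] = frame["N"].round(0)
            for col in ("Es", "Er", "D", "CV"):
                frame[col] = frame[col].round(2)
            frame["L"] = frame["L"].round(1)
            frame["A"] = frame["A"].round(1)
        return frame

    def summary(self, level_label: str = "95%") -> dict:
        return {
            "stratification": self.stratification,
            "total_abundance": self.total_n,
            "total_cv": self.total_cv,
            f"ci_{level_label}": list(self.total_ci),
            "most_conservative_abundance": self.total_ci[0],
        }


def build_table(
    line_estimates: Sequence[StratumEstimate],
    strip_estimates: Sequence[StratumEstimate],
    areas: sd.AreaTable,
    mode: str = "geographic_post",
    ci_level: float = 0.95,
) -> AbundanceTable:
    """Assemble the abundance table from per-cell density estimates.

    Each habitat belongs to exactly one protocol, so a (habitat, stratum)
    cell appearing in both inputs is an error.  Rows that already carry an
    abundance (e.g. rebuilt from a published report) are kept as-is;
    otherwise N = D * A with the area looked up per cell (habitat total
    across strata when the row pools strata).  A cell with sightings but no
    area is an error naming the cell.
    """
    if mode not in STRATIFICATIONS:
        raise AggregationError(f"unknown stratification mode {mode!r}")
    keys = {}
    for r in list(line_estimates) + list(strip_estimates):
        key = (r.habitat, r.stratum)
        if key in keys and keys[key] != r.protocol:
            raise AggregationError(
                f"cell {key} estimated by both protocols; each habitat belongs to one protocol"
            )
        keys[key] = r.protocol

    out_rows: list[StratumEstimate] = []
    for r in list(line_estimates) + list(strip_estimates):
        if math.isfinite(r.abundance):
            out_rows.append(r)
            continue
        area = areas.area(r.habitat, r.stratum)
        if area is None:
            if r.n_groups > 0 or r.density > 0:
                raise AggregationError(
                    f"no area for cell ({r.habitat}, {r.stratum or 'pooled'}) with sightings"
                )
            continue  # empty cell with no frame: contributes nothing
        n_hat, se = cell_abundance(r.density, area, r.se_density)
        row = r.with_abundance(n_hat, se, area)
        if math.isfinite(row.cv_abundance) and row.abundance > 0:
            row = row.with_ci(*total_ci(row.abundance, row.cv_abundance, ci_level))
        out_rows.append(row)

    total_n = sum(r.abundance for r in out_rows)
    if out_rows and any(r.abundance > 0 for r in out_rows):
        cv = total_cv(out_rows)
        ci = total_ci(total_n, cv, ci_level) if math.isfinite(cv) else (math.nan, math.nan)
    else:
        cv = math.nan
        ci = (0.0, 0.0) if not out_rows else (math.nan, math.nan)
        total_n = float(total_n)
    return AbundanceTable(
        rows=tuple(out_rows),
        total_n=total_n,
        total_cv=cv,
        total_ci=ci,
        stratification=mode,
    )


def estimate_from_report_row(
    habitat: str,
    stratum: str | None,
    density: float,
    cv: float,
    area_km2: float,
    abundance: float | None = None,
    n_groups: int = 0,
    effort_km: float = math.nan,
    mean_group_size: float = math.nan,
    encounter_rate: float = math.nan,
    protocol: str = "line",
) -> StratumEstimate:
    """Build a StratumEstimate from published report numbers (D, CV, A and
    optionally the printed N), for rebuilding report tables from print."""
    n_hat = abundance if abundance is not None else density * area_km2
    se = cv * n_hat if math.isfinite(cv) else math.nan
    est = StratumEstimate(
        habitat=habitat,
        stratum=stratum,
        protocol=protocol,
        n_groups=n_groups,
        effort_km=effort_km,
        mean_group_size=mean_group_size,
        cv_group_size=math.nan,
        encounter_rate=encounter_rate,
        cv_encounter_rate=math.nan,
        density=density,
        cv_density=cv,
    )
    return est.with_abundance(n_hat, se, area_km2)
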