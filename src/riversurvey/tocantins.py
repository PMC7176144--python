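"""Published summaries of the 2014 Tocantins River Araguaian boto survey.

These are the printed effort, density and abundance tables of the survey
this package's estimators are designed around: 585.9 km of mixed line/strip
effort over a ~600 km stretch of the Tocantins River split by the Tucurui
dam into downstream, reservoir (two sections) and upstream strata.  The raw
sighting-level records were not deposited, so these tables serve as
arithmetic inputs for rebuilding the report-level quantities (abundance from
density x area, stratification contrasts, the g(0) consistency numbers) and
as realistic anchors for the synthetic-survey scenarios.

Row layout mirrors the published abundance table: habitat, stratum (None in
the habitat-only panel), E(s) mean group size, n groups, L effort km,
Er groups/km, D individuals/km^2, N individuals, CV, A km^2.
"""

from __future__ import annotations

from dataclasses import dataclass

from .aggregation import estimate_from_report_row
from .results import StratumEstimate

#: realized effort (km)
EFFORT_LINE_KM = 276.6
EFFORT_STRIP_KM = 309.3
EFFORT_TOTAL_KM = 585.9

#: two-platform trackline detection probability and its CV
G0 = 0.659
G0_CV = 0.262

#: fixed band-correction probabilities used for strip transects
P1 = 0.960
P2 = 0.630

#: per-stratum effort and sightings (area km^2, line L/k/n, strip L/k/n)
EFFORT_BY_STRATUM = {
    "downstream": {"area_km2": 1169.0, "line": (67.8, 34, 4), "strip": (184.8, 81, 21)},
    "reservoir1": {"area_km2": 331.0, "line": (42.1, 17, 4), "strip": None},
    "reservoir2": {"area_km2": 342.0, "line": (93.93, 43, 42), "strip": None},
    "upstream": {"area_km2": 385.0, "line": (72.7, 39, 32), "strip": (124.5, 58, 25)},
}


@dataclass(frozen=True)
class ReportRow:
    habitat: str
    stratum: str | None
    es: float
    n: int
    effort_km: float
    er: float
    density: float
    abundance: float
    cv: float
    area_km2: float


#: habitat-only panel (strata pooled before the survey)
UNSTRATIFIED_ROWS = (
    ReportRow("river_margin", None, 1.5, 24, 205.61, 0.10, 0.21, 195, 2.70, 927.76),
    ReportRow("river_channel", None, 1.56, 33, 140.54, 0.64, 0.94, 300, 0.40, 318.90),
    ReportRow("reservoir", None, 1.30, 46, 136.03, 0.33, 2.82, 1897, 0.30, 673.00),
    ReportRow("channel", None, 2.0, 5, 34.37, 0.29, 1.86, 139, 2.12, 74.97),
    ReportRow("island_margin", None, 1.10, 10, 69.24, 0.74, 0.70, 163, 0.36, 232.76),
)
UNSTRATIFIED_TOTAL_N = 2694
UNSTRATIFIED_TOTAL_CV = 1.78

#: geographic post-stratification panel (habitat x stratum cells)
POST_STRATIFIED_ROWS = (
    ReportRow("river_margin", "downstream", 1.86, 9, 106.14, 0.07, 0.23, 30, 0.92, 133.5),
    ReportRow("river_channel", "downstream", 1.44, 4, 67.83, 0.05, 0.02, 16, 0.67, 794.2),
    ReportRow("channel", "downstream", 2.0, 3, 27.39, 0.25, 1.68, 96, 1.27, 57.3),
    ReportRow("island_margin", "downstream", 1.08, 6, 47.83, 0.18, 1.24, 228, 0.50, 184.4),
    ReportRow("reservoir", "reservoir1", 1.25, 4, 42.10, 0.09, 0.76, 244, 0.55, 331.0),
    ReportRow("reservoir", "reservoir2", 1.43, 42, 93.93, 0.44, 3.97, 1306, 0.39, 342.0),
    ReportRow("river_margin", "upstream", 1.40, 29, 99.47, 0.10, 0.72, 63, 0.53, 87.4),
    ReportRow("river_channel", "upstream", 1.45, 15, 72.71, 0.38, 0.13, 30, 0.40, 231.6),
    ReportRow("channel", "upstream", 1.0, 2, 6.98, 0.10, 1.06, 19, 1.81, 17.7),
    ReportRow("island_margin", "upstream", 1.0, 4, 21.41, 0.21, 2.32, 112, 0.27, 48.4),
)
POST_STRATIFIED_TOTAL_N = 2144
POST_STRATIFIED_TOTAL_CV = 0.52

#: reservoir-habitat rows where the printed D is too coarse to rebuild the
#: printed N by D x A (the report carried more decimals than it printed)
ROUNDING_LIMITED_CELLS = (("reservoir", "reservoir1"), ("reservoir", "reservoir2"))


def report_row_estimates(
    rows: tuple[ReportRow, ...], use_printed_abundance: bool = True
) -> list[StratumEstimate]:
    """Convert published report rows to StratumEstimate objects.

    With ``use_printed_abundance`` the printed N is kept (so panel totals
    reproduce the printed totals exactly); otherwise N is rebuilt as D x A.
    """
    out = []
    for r in rows:
        protocol = "line" if r.habitat in ("river_channel", "reservoir") else "strip"
        out.append(
            estimate_from_report_row(
                r.habitat,
                r.stratum,
                r.density,
                r.cv,
                r.area_km2,
                abundance=r.abundance if use_printed_abundance else None,
                n_groups=r.n,
                effort_km=r.effort_km,
                mean_group_size=r.es,
                encounter_rate=r.er,
                protocol=protocol,
            )
        )
    return out
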