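"""Domain types, validation and delimited-text I/O for river-dolphin surveys.

The survey protocol mixes two transect kinds: *line* transects crossing the
river channel (analyzed with a fitted detection function) and *strip*
transects running parallel to the shore (a fixed 200 m band corrected by
per-band detection probabilities).  Each detected dolphin group is recorded
with the platform that saw it (bow or stern of a double-decker boat), the
radial distance and angle to the group, its size, habitat and geographic
stratum.  Stern observers work blind to bow detections, so a stern record
matched to a bow record carries a ``duplicate_of`` link; these links drive
the trackline detection probability g(0).

All distances are meters, effort is kilometers (see :mod:`riversurvey.units`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .units import M_PER_KM

STRATA = ("downstream", "reservoir1", "reservoir2", "upstream")
HABITATS = (
    "river_margin",
    "river_channel",
    "channel",
    "island_margin",
    "reservoir",
    "confluence",
    "lake",
    "tributary",
)
#: habitats surveyed by cross-channel line transects
LINE_HABITATS = ("river_channel", "reservoir")
#: margin-side habitats surveyed by shore-parallel strip transects
STRIP_HABITATS = ("river_margin", "island_margin", "channel")
SHORE_BANDS = ("b0_50", "b50_100", "b100_150", "b150_200")
TRANSECT_KINDS = ("line", "strip")

EFFORT_COLUMNS = ("transect_id", "kind", "length_km", "stratum", "habitat")
SIGHTING_COLUMNS = (
    "sighting_id",
    "transect_id",
    "platform",
    "radial_distance_m",
    "radial_angle_deg",
    "shore_band",
    "group_size",
    "habitat",
    "stratum",
    "duplicate_of",
)
AREA_COLUMNS = ("habitat", "stratum", "area_km2")


class SurveyDataError(ValueError):
    """Invalid survey record, file, or configuration."""


def perpendicular_distance(radial_distance_m: float, radial_angle_deg: float) -> float:
    """Perpendicular distance of a sighting from the trackline.

    Observers measure the radial distance to the group and the radial angle
    off the trackline with angle boards; the perpendicular distance is
    ``r * sin(angle)``.  Angles beyond abeam (90 deg) are rejected rather
    than folded: the search protocol covers 10 deg on the opposite side to
    90 deg on the observer's own side, so angles behind abeam indicate a
    recording error.
    """
    if radial_distance_m < 0:
        raise SurveyDataError(f"radial distance must be >= 0, got {radial_distance_m}")
    if not 0.0 <= radial_angle_deg <= 90.0:
        raise SurveyDataError(
            f"radial angle must be in [0, 90] degrees, got {radial_angle_deg}"
        )
    return radial_distance_m * math.sin(math.radians(radial_angle_deg))


@dataclass(frozen=True)
class TransectRecord:
    """One survey line: a cross-channel line or a shore-parallel strip."""

    transect_id: str
    kind: str
    length_km: float
    stratum: str
    habitat: str

    def __post_init__(self) -> None:
        if self.kind not in TRANSECT_KINDS:
            raise SurveyDataError(f"unknown transect kind {self.kind!r}")
        if not self.length_km > 0:
            raise SurveyDataError(
                f"transect {self.transect_id}: length_km must be > 0, got {self.length_km}"
            )
        if self.stratum not in STRATA:
            raise SurveyDataError(f"transect {self.transect_id}: unknown stratum {self.stratum!r}")
        if self.habitat not in HABITATS:
            raise SurveyDataError(f"transect {self.transect_id}: unknown habitat {self.habitat!r}")
        if self.kind == "line" and self.habitat not in LINE_HABITATS:
            raise SurveyDataError(
                f"transect {self.transect_id}: line transects survey {LINE_HABITATS}, got {self.habitat!r}"
            )
        if self.kind == "strip" and self.habitat not in STRIP_HABITATS:
            raise SurveyDataError(
                f"transect {self.transect_id}: strip transects survey margin-side habitats "
                f"{STRIP_HABITATS}, got {self.habitat!r}"
            )


@dataclass(frozen=True)
class SightingRecord:
    """One detected dolphin group.

    ``duplicate_of`` on a stern record names the bow sighting of the same
    group; bow records never carry it.  ``shore_band`` is set for strip
    sightings only (distance-from-shore band in 50 m cuts).
    """

    sighting_id: str
    transect_id: str
    platform: str
    radial_distance_m: float
    radial_angle_deg: float
    group_size: int
    habitat: str
    stratum: str
    shore_band: str | None = None
    duplicate_of: str | None = None
    perp_distance_m: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.platform not in ("bow", "stern"):
            raise SurveyDataError(
                f"sighting {self.sighting_id}: platform must be bow|stern, got {self.platform!r}"
            )
        if self.group_size < 1 or int(self.group_size) != self.group_size:
            raise SurveyDataError(
                f"sighting {self.sighting_id}: group_size must be a positive integer, got {self.group_size}"
            )
        if self.habitat not in HABITATS:
            raise SurveyDataError(f"sighting {self.sighting_id}: unknown habitat {self.habitat!r}")
        if self.stratum not in STRATA:
            raise SurveyDataError(f"sighting {self.sighting_id}: unknown stratum {self.stratum!r}")
        if self.shore_band is not None and self.shore_band not in SHORE_BANDS:
            raise SurveyDataError(
                f"sighting {self.sighting_id}: unknown shore band {self.shore_band!r}"
            )
        if self.perp_distance_m is None:
            object.__setattr__(
                self,
                "perp_distance_m",
                perpendicular_distance(self.radial_distance_m, self.radial_angle_deg),
            )
        if self.perp_distance_m > self.radial_distance_m + 1e-9:
            raise SurveyDataError(
                f"sighting {self.sighting_id}: perpendicular distance "
                f"{self.perp_distance_m} exceeds radial distance {self.radial_distance_m}"
            )
        if self.platform == "bow" and self.duplicate_of is not None:
            raise SurveyDataError(
                f"sighting {self.sighting_id}: only stern records may carry duplicate_of"
            )


@dataclass(frozen=True)
class AreaTable:
    """Habitat x stratum surface areas (km^2), the inference frame for abundance."""

    entries: Mapping[tuple[str, str], float]

    def __post_init__(self) -> None:
        for (habitat, stratum), area in self.entries.items():
            if habitat not in HABITATS:
                raise SurveyDataError(f"area table: unknown habitat {habitat!r}")
            if stratum not in STRATA:
                raise SurveyDataError(f"area table: unknown stratum {stratum!r}")
            if not area > 0:
                raise SurveyDataError(
                    f"area table: area for ({habitat}, {stratum}) must be > 0, got {area}"
                )

    def area(self, habitat: str, stratum: str | None = None) -> float | None:
        """Area of one cell, or the habitat total across strata if ``stratum`` is None."""
        if stratum is not None:
            return self.entries.get((habitat, stratum))
        total = sum(a for (h, _), a in self.entries.items() if h == habitat)
        return total if total > 0 else None

    def total_km2(self) -> float:
        return sum(self.entries.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"habitat": h, "stratum": s, "area_km2": a}
            for (h, s), a in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=list(AREA_COLUMNS))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AreaTable":
        entries: dict[tuple[str, str], float] = {}
        for i, row in frame.iterrows():
            key = (str(row["habitat"]), str(row["stratum"]))
            if key in entries:
                raise SurveyDataError(f"area table row {i}: duplicate cell {key}")
            entries[key] = float(row["area_km2"])
        return cls(entries)


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis constants shared across the pipeline.

    ``p1``/``p2`` are the global band-correction detection probabilities for
    strip transects; ``trackline_band_m`` is the perpendicular window within
    which stern sightings enter the g(0) mark-recapture counts.
    """

    truncation_m: float = 300.0
    strip_width_m: float = 200.0
    trackline_band_m: float = 50.0
    p1: float = 0.960
    p2: float = 0.630
    ci_level: float = 0.95
    seed: int = 0
    encounter_rate: str = "pooled"  # or "mean_of_ratios"
    g0_cv_method: str = "delta"  # or "bootstrap"

    def __post_init__(self) -> None:
        if not self.truncation_m > 0 or not self.strip_width_m > 0:
            raise SurveyDataError("truncation_m and strip_width_m must be positive")
        for name in ("p1", "p2"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise SurveyDataError(f"{name} must be in (0, 1], got {v}")
        if self.p2 > self.p1:
            raise SurveyDataError(f"p2 ({self.p2}) must not exceed p1 ({self.p1})")
        if not 0 < self.ci_level < 1:
            raise SurveyDataError(f"ci_level must be in (0, 1), got {self.ci_level}")
        if self.encounter_rate not in ("pooled", "mean_of_ratios"):
            raise SurveyDataError(f"unknown encounter_rate mode {self.encounter_rate!r}")
        if self.g0_cv_method not in ("delta", "bootstrap"):
            raise SurveyDataError(f"unknown g0_cv_method {self.g0_cv_method!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise SurveyDataError(f"config file {path} must hold a mapping")
        known = cls.__dataclass_fields__.keys()
        unknown = set(raw) - set(known)
        if unknown:
            raise SurveyDataError(f"config file {path}: unknown keys {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


# ---------------------------------------------------------------------------
# readers / writers


def _require_columns(frame: pd.DataFrame, required: Sequence[str], path: object) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SurveyDataError(f"{path}: missing column(s) {missing}")


def _opt(value: object) -> str | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    text = str(value).strip()
    return text or None


def read_effort(path: str | Path, column_map: Mapping[str, str] | None = None) -> list[TransectRecord]:
    frame = pd.read_csv(path)
    if column_map:
        frame = frame.rename(columns=dict(column_map))
    _require_columns(frame, EFFORT_COLUMNS, path)
    records = []
    for i, row in frame.iterrows():
        try:
            records.append(
                TransectRecord(
                    transect_id=str(row["transect_id"]),
                    kind=str(row["kind"]),
                    length_km=float(row["length_km"]),
                    stratum=str(row["stratum"]),
                    habitat=str(row["habitat"]),
                )
            )
        except (SurveyDataError, ValueError) as exc:
            raise SurveyDataError(f"{path} row {i + 2}: {exc}") from exc
    ids = [t.transect_id for t in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if ids.count(x) > 1})
        raise SurveyDataError(f"{path}: duplicate transect_id(s) {dupes}")
    return records


def read_sightings(
    path: str | Path,
    transects: Iterable[TransectRecord] | None = None,
    column_map: Mapping[str, str] | None = None,
) -> list[SightingRecord]:
    frame = pd.read_csv(path)
    if column_map:
        frame = frame.rename(columns=dict(column_map))
    _require_columns(frame, [c for c in SIGHTING_COLUMNS if c not in ("shore_band", "duplicate_of")], path)
    by_id = {t.transect_id: t for t in transects} if transects is not None else None
    records = []
    for i, row in frame.iterrows():
        try:
            record = SightingRecord(
                sighting_id=str(row["sighting_id"]),
                transect_id=str(row["transect_id"]),
                platform=str(row["platform"]),
                radial_distance_m=float(row["radial_distance_m"]),
                radial_angle_deg=float(row["radial_angle_deg"]),
                group_size=int(row["group_size"]),
                habitat=str(row["habitat"]),
                stratum=str(row["stratum"]),
                shore_band=_opt(row.get("shore_band")),
                duplicate_of=_opt(row.get("duplicate_of")),
            )
        except (SurveyDataError, ValueError) as exc:
            raise SurveyDataError(f"{path} row {i + 2}: {exc}") from exc
        if by_id is not None:
            parent = by_id.get(record.transect_id)
            if parent is None:
                raise SurveyDataError(
                    f"{path} row {i + 2}: sighting {record.sighting_id} references "
                    f"unknown transect_id {record.transect_id!r}"
                )
            # shore band present iff the parent transect is a strip
            if parent.kind == "line" and record.shore_band is not None:
                raise SurveyDataError(
                    f"{path} row {i + 2}: line-transect sighting {record.sighting_id} "
                    f"must not carry a shore band"
                )
        records.append(record)
    return records


def read_areas(path: str | Path) -> AreaTable:
    frame = pd.read_csv(path)
    _require_columns(frame, AREA_COLUMNS, path)
    try:
        return AreaTable.from_frame(frame)
    except SurveyDataError as exc:
        raise SurveyDataError(f"{path}: {exc}") from exc


def read_survey(
    effort_path: str | Path, sightings_path: str | Path
) -> tuple[list[TransectRecord], list[SightingRecord]]:
    """Read and cross-validate the effort + sightings CSV pair."""
    transects = read_effort(effort_path)
    sightings = read_sightings(sightings_path, transects=transects)
    return transects, sightings


def transects_to_frame(transects: Iterable[TransectRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{c: getattr(t, c) for c in EFFORT_COLUMNS} for t in transects],
        columns=list(EFFORT_COLUMNS),
    )


def sightings_to_frame(sightings: Iterable[SightingRecord]) -> pd.DataFrame:
    cols = list(SIGHTING_COLUMNS) + ["perp_distance_m"]
    return pd.DataFrame(
        [{c: getattr(s, c) for c in cols} for s in sightings], columns=cols
    )


def write_survey(
    transects: Iterable[TransectRecord],
    sightings: Iterable[SightingRecord],
    effort_path: str | Path,
    sightings_path: str | Path,
) -> None:
    transects_to_frame(transects).to_csv(effort_path, index=False)
    frame = sightings_to_frame(sightings).drop(columns=["perp_distance_m"])
    frame.to_csv(sightings_path, index=False)


def unique_groups(sightings: Iterable[SightingRecord]) -> list[SightingRecord]:
    """Deduplicate double-platform records to one row per detected group.

    Keeps every bow sighting plus stern sightings that are *not* marked as
    duplicates of a bow record — the set used to fit the detection function.
    """
    return [
        s
        for s in sightings
        if s.platform == "bow" or s.duplicate_of is None
    ]


def summarize_effort(
    transects: Sequence[TransectRecord], sightings: Sequence[SightingRecord]
) -> pd.DataFrame:
    """Effort summary per (stratum, kind): total length L, transect count k,
    unique-group sighting count n, plus a TOTAL row."""
    tframe = transects_to_frame(transects)
    groups = unique_groups(sightings)
    kind_by_id = {t.transect_id: t.kind for t in transects}
    counts: dict[tuple[str, str], int] = {}
    for s in groups:
        key = (s.stratum, kind_by_id.get(s.transect_id, "line"))
        counts[key] = counts.get(key, 0) + 1

    rows = []
    if not tframe.empty:
        grouped = tframe.groupby(["stratum", "kind"], sort=False)
        for (stratum, kind), sub in grouped:
            rows.append(
                {
                    "stratum": stratum,
                    "kind": kind,
                    "length_km": float(sub["length_km"].sum()),
                    "n_transects": int(len(sub)),
                    "n_sightings": counts.get((stratum, kind), 0),
                }
            )
    summary = pd.DataFrame(
        rows, columns=["stratum", "kind", "length_km", "n_transects", "n_sightings"]
    )
    total = {
        "stratum": "TOTAL",
        "kind": "all",
        "length_km": float(summary["length_km"].sum()) if not summary.empty else 0.0,
        "n_transects": int(summary["n_transects"].sum()) if not summary.empty else 0,
        "n_sightings": int(summary["n_sightings"].sum()) if not summary.empty else 0,
    }
    if summary.empty:
        return pd.DataFrame([total])
    return pd.concat([summary, pd.DataFrame([total])], ignore_index=True)
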