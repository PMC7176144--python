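"""End-to-end survey analysis: fit -> g(0) -> densities -> abundance table.

`estimate_abundance` is the library entry point: given validated records,
an area frame and an `AnalysisConfig` it selects a detection model for the
line data, estimates g(0) from the double-platform duplicates, runs the
line and strip estimators per cell and assembles the abundance table for
one stratification mode.  `run_pipeline` wraps it with file I/O, a manifest
(config snapshot, input digests, seed, timings, warnings) and deterministic
outputs for reproducible shell runs.
"""

from __future__ import annotations

import hashlib
import json
import math
import time
import warnings
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version as pkg_version
from pathlib import Path
from typing import Sequence

from . import survey_data as sd
from .aggregation import AbundanceTable, build_table
from .detection import DEFAULT_CANDIDATES, DetectionFit, RankedModel, fit_report, select_model
from .line_estimator import line_density
from .perception import G0Estimate, estimate_g0
from .strip_estimator import strip_cell_estimate


class PipelineError(RuntimeError):
    pass


def _package_version() -> str:
    try:
        return pkg_version("riversurvey")
    except PackageNotFoundError:
        return "unknown"


@dataclass
class RunManifest:
    config: dict
    seed: int
    software_version: str = field(default_factory=_package_version)
    input_digests: dict = field(default_factory=dict)
    output_digests: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True, default=str)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass(frozen=True)
class AnalysisResult:
    ranked_models: tuple[RankedModel, ...]
    g0: G0Estimate
    tables: dict[str, AbundanceTable]

    @property
    def best_fit(self) -> DetectionFit:
        return self.ranked_models[0].fit

    @property
    def best_model(self) -> str:
        return self.ranked_models[0].name


def _cells(
    transects: Sequence[sd.TransectRecord], kind: str, stratified: bool
) -> list[tuple[str, str | None]]:
    seen = []
    for t in transects:
        if t.kind != kind:
            continue
        key = (t.habitat, t.stratum if stratified else None)
        if key not in seen:
            seen.append(key)
    return seen


def estimate_abundance(
    transects: Sequence[sd.TransectRecord],
    sightings: Sequence[sd.SightingRecord],
    areas: sd.AreaTable,
    config: sd.AnalysisConfig,
    stratifications: Sequence[str] = ("habitat_only", "geographic_post"),
    candidates: Sequence[str] = DEFAULT_CANDIDATES,
    fit: DetectionFit | None = None,
    g0: G0Estimate | None = None,
) -> AnalysisResult:
    """Full analysis for the requested stratification modes.

    A pre-fitted detection function / g(0) can be injected (e.g. external
    constants); otherwise both are estimated from the line-transect data.
    The detection function is fitted once on the pooled line data and
    applied to every cell; only encounter rate and group size vary by cell.
    """
    line_tids = {t.transect_id for t in transects if t.kind == "line"}
    line_sightings = [s for s in sightings if s.transect_id in line_tids]
    strip_sightings = [s for s in sightings if s.transect_id not in line_tids]

    ranked: tuple[RankedModel, ...]
    if fit is None:
        ranked = tuple(
            select_model(
                line_sightings,
                candidates=candidates,
                truncation_m=config.truncation_m,
                seed=config.seed,
            )
        )
        fit = ranked[0].fit
    else:
        ranked = (RankedModel(name=f"fixed:{fit.key}", fit=fit, delta_aicc=0.0),)
    if g0 is None:
        g0 = estimate_g0(
            line_sightings,
            trackline_band_m=config.trackline_band_m,
            cv_method=config.g0_cv_method,
            seed=config.seed,
        )

    tables: dict[str, AbundanceTable] = {}
    for mode in stratifications:
        stratified = mode == "geographic_post"
        line_estimates = [
            line_density(
                line_sightings,
                transects,
                fit,
                g0,
                habitat,
                stratum,
                encounter_rate_mode=config.encounter_rate,
            )
            for habitat, stratum in _cells(transects, "line", stratified)
        ]
        strip_estimates = [
            strip_cell_estimate(
                strip_sightings,
                transects,
                habitat,
                g0.g0,
                g0.cv if math.isfinite(g0.cv) else 0.0,
                config,
                stratum=stratum,
            )
            for habitat, stratum in _cells(transects, "strip", stratified)
        ]
        tables[mode] = build_table(
            line_estimates, strip_estimates, areas, mode=mode, ci_level=config.ci_level
        )
    return AnalysisResult(ranked_models=ranked, g0=g0, tables=tables)


def run_pipeline(
    effort_path: str | Path,
    sightings_path: str | Path,
    areas_path: str | Path,
    config: sd.AnalysisConfig | str | Path,
    out_dir: str | Path,
    stratifications: Sequence[str] = ("habitat_only", "geographic_post"),
    candidates: Sequence[str] = DEFAULT_CANDIDATES,
) -> tuple[AnalysisResult, RunManifest]:
    """Run the full seeded pipeline on CSV inputs and write report files.

    Outputs under ``out_dir``: one abundance table CSV per stratification,
    the model-selection report, a JSON summary (total N, CV, CI, g(0),
    selected model) and ``manifest.json`` with input/output digests and
    per-stage timings.  Outputs are deterministic given config + inputs.
    """
    if not isinstance(config, sd.AnalysisConfig):
        config = sd.AnalysisConfig.from_yaml(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), seed=config.seed)
    paths = {
        "effort": Path(effort_path),
        "sightings": Path(sightings_path),
        "areas": Path(areas_path),
    }
    for name, p in paths.items():
        if not p.exists():
            raise PipelineError(f"input file missing: {name} ({p})")
        manifest.input_digests[name] = _digest(p)

    t0 = time.perf_counter()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        transects, sightings = sd.read_survey(paths["effort"], paths["sightings"])
        areas = sd.read_areas(paths["areas"])
        manifest.timings_s["read"] = round(time.perf_counter() - t0, 4)

        t1 = time.perf_counter()
        try:
            result = estimate_abundance(
                transects,
                sightings,
                areas,
                config,
                stratifications=stratifications,
                candidates=candidates,
            )
        except Exception as exc:
            raise PipelineError(f"estimation stage failed: {exc}") from exc
        manifest.timings_s["estimate"] = round(time.perf_counter() - t1, 4)
    manifest.warnings = [str(w.message) for w in caught]

    t2 = time.perf_counter()
    outputs: dict[str, Path] = {}
    for mode, table in result.tables.items():
        p = out / f"abundance_{mode}.csv"
        table.to_frame().to_csv(p, index=False, float_format="%.6g")
        outputs[f"abundance_{mode}"] = p
    report_path = out / "model_selection.csv"
    fit_report(result.ranked_models).to_csv(report_path, index=False)
    outputs["model_selection"] = report_path

    summary = {
        "selected_model": result.best_model,
        "g0": result.g0.g0,
        "g0_cv": result.g0.cv,
        "g0_counts": {"n1": result.g0.n1, "n01": result.g0.n01},
        "esw_m": result.best_fit.esw_m,
        "p_avg": result.best_fit.p_avg,
        "tables": {mode: t.summary() for mode, t in result.tables.items()},
    }
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    outputs["summary"] = summary_path
    manifest.timings_s["write"] = round(time.perf_counter() - t2, 4)

    for name, p in outputs.items():
        manifest.output_digests[name] = _digest(p)
    (out / "manifest.json").write_text(manifest.to_json())
    return result, manifest
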