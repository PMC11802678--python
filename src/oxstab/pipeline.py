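"""End-to-end pipeline: injury → dose-response → exposure → flux → report.

Two entry points:

* :func:`reference_summary` — the deterministic desk-scale analysis over
  the bundled study tables: per species and zone it refits the exponential
  baselines, recomputes oxidative stability, inverts the −0.05 threshold,
  and converts the critical dose to a seasonal average concentration.
* :func:`run_full_pipeline` — the file-driven variant: conductivity CSV +
  hourly met CSVs + species parameter sets in, per-species summary table,
  JSON report and run log out.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import tables
from .dose_response import OXS_THRESHOLD_DEFAULT, ExposureSeries, critical_dose
from .el_injury import injury_table, read_conductivity_csv
from .errors import ValidationError
from .season_exposure import (GrowingSeason, cumulative_exposure,
                              detect_growing_season, read_env_csv, sum_to_avg)
from .stomatal_flux import (pod_from_series, project_cl_oxs, species_preset,
                            tolerance_utilisation)

log = logging.getLogger(__name__)


def growing_season_for_zone(zone: str) -> GrowingSeason:
    """The study's published season bounds (5 °C rule) for a zone."""
    info = tables.GROWING_SEASON[zone]
    return GrowingSeason(pd.Timestamp(info["start"]), pd.Timestamp(info["end"]))


def reference_summary(degree: int = 2,
                      threshold: float = OXS_THRESHOLD_DEFAULT) -> pd.DataFrame:
    """Recompute the desk-scale chain from the bundled study tables.

    One row per (zone, species) with the fitted baseline INX(0), the
    recomputed OxS series, the inverted critical dose sumO₃(OxS), its
    seasonal-average conversion, and — where the published flux summary
    provides the POD0 pair — the tolerance-utilisation percentage.
    """
    rows = []
    for (zone, species), inx in tables.INJURY_INDEX_PCT.items():
        series = ExposureSeries(species=species, zone=zone,
                                sum_o3=tables.SUM_O3_PPM[zone],
                                inx=tuple(inx[1:]))
        result = critical_dose(series, degree=degree, threshold=threshold)
        gs = growing_season_for_zone(zone)
        flux = tables.FLUX_SUMMARY.get((zone, species), {})
        row = {"zone": zone, "species": species,
               "inx0_fit": result["baseline"].a,
               "fit_r": result["baseline"].r, "fit_p": result["baseline"].p,
               "sum_o3_oxs_ppm": result["sum_o3_oxs"],
               "avg_o3_oxs_ppb": sum_to_avg(result["sum_o3_oxs"], gs),
               "gs_hours": gs.hours}
        for n, oxs in enumerate(result["oxs"], start=1):
            row[f"oxs_{n}"] = oxs
        if flux:
            row["utilisation_pct"] = tolerance_utilisation(
                flux["pod0_ambient"], flux["pod0_cl"])
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PipelineConfig:
    """File-driven pipeline configuration."""

    conductivity_csv: str | Path
    doses_csv: str | Path  # columns: zone, series_index, sum_o3_ppm
    env_csv_by_zone: dict[str, str | Path]
    output_dir: str | Path
    species_zones: tuple[tuple[str, str], ...] = ()  # (zone, species) pairs
    degree: int = 2
    threshold: float = OXS_THRESHOLD_DEFAULT
    coverage_floor: float = 0.9
    y_threshold: float = 0.0

    def __post_init__(self) -> None:
        if not -1.0 < self.threshold < 0.0:
            raise ValidationError("threshold must lie in (-1, 0)")
        if self.degree < 1:
            raise ValidationError("degree must be >= 1")


def run_full_pipeline(cfg: PipelineConfig) -> pd.DataFrame:
    """Execute injury → dose-response → season → flux over input files.

    Writes ``summary.csv`` and ``report.json`` into ``cfg.output_dir``
    (atomically: complete outputs only) and returns the summary frame.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    measurements = read_conductivity_csv(cfg.conductivity_csv)
    inx = injury_table(measurements)
    doses = pd.read_csv(cfg.doses_csv)
    for col in ("zone", "series_index", "sum_o3_ppm"):
        if col not in doses.columns:
            raise ValidationError(f"{cfg.doses_csv}: missing column {col!r}")
    inx = inx.merge(doses[["zone", "series_index", "sum_o3_ppm"]],
                    on=["zone", "series_index"], how="left")
    if inx["sum_o3_ppm"].isna().any():
        missing = inx.loc[inx["sum_o3_ppm"].isna(),
                          ["zone", "series_index"]].drop_duplicates()
        raise ValidationError(
            f"dose-response stage: no sum_o3_ppm for "
            f"{missing.to_dict(orient='records')}")

    env, season, avg_ambient, pod_ambient_cache = {}, {}, {}, {}
    for zone, path in cfg.env_csv_by_zone.items():
        env[zone] = read_env_csv(path)
        season[zone] = detect_growing_season(env[zone])
        sum_ppm = cumulative_exposure(env[zone], season[zone],
                                      coverage_floor=cfg.coverage_floor)
        avg_ambient[zone] = sum_to_avg(sum_ppm, season[zone])

    pairs = cfg.species_zones or tuple(sorted(
        {(r.zone, r.species) for r in inx.itertuples()}))
    rows = []
    for zone, species in pairs:
        sub = inx[(inx.zone == zone) & (inx.species == species)] \
            .sort_values("series_index")
        if sub.empty:
            raise ValidationError(
                f"injury stage: no measurements for {species} in {zone}")
        if zone not in env:
            raise ValidationError(f"season stage: no met series for zone {zone}")
        gs = season[zone]
        series = ExposureSeries(species=species, zone=zone,
                                sum_o3=tuple(sub["sum_o3_ppm"]),
                                inx=tuple(sub["inx_pct"]))
        result = critical_dose(series, degree=cfg.degree,
                               threshold=cfg.threshold)
        avg_cl = sum_to_avg(result["sum_o3_oxs"], gs)
        params = species_preset(species)
        pod_key = (zone, species_preset(species).name)
        if pod_key not in pod_ambient_cache:
            pod_ambient_cache[pod_key] = pod_from_series(
                env[zone], gs, params, y=cfg.y_threshold)["pod"]
        pod_ambient = pod_ambient_cache[pod_key]
        pod_cl = project_cl_oxs(avg_cl, env[zone], gs, params,
                                y=cfg.y_threshold)
        row = {"zone": zone, "species": species,
               "inx0_fit": result["baseline"].a,
               "sum_o3_oxs_ppm": result["sum_o3_oxs"],
               "avg_o3_ambient_ppb": avg_ambient[zone],
               "avg_o3_cl_ppb": avg_cl,
               "pod0_ambient": pod_ambient, "cl_oxs_pod0": pod_cl,
               "utilisation_pct": tolerance_utilisation(pod_ambient, pod_cl),
               "gs_start": str(gs.start.date()), "gs_end": str(gs.end.date())}
        for n, oxs in enumerate(result["oxs"], start=1):
            row[f"oxs_{n}"] = oxs
        rows.append(row)
    summary = pd.DataFrame(rows)

    tmp_csv = out / "summary.csv.tmp"
    summary.to_csv(tmp_csv, index=False)
    tmp_csv.replace(out / "summary.csv")
    report = {"config": {k: str(v) for k, v in dataclasses.asdict(cfg).items()},
              "rows": summary.to_dict(orient="records")}
    tmp_json = out / "report.json.tmp"
    tmp_json.write_text(json.dumps(report, indent=2, default=float))
    tmp_json.replace(out / "report.json")
    log.info("pipeline wrote %s", out / "summary.csv")
    return summary
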