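"""One-command pipeline: generate/read -> link -> tables -> Moran -> model -> maps.

Every stage writes plain-text artifacts (CSV/JSON/GeoJSON) into the output
directory and the run ends with a manifest listing each artifact with its
SHA-256 hash, so a rerun with the same seed and config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping

from . import geodata, geostat, spatial, survey
from .geodata import GeoPoint, WomanRecord, link_nearest_sdp
from .synthetic import SimConfig, generate_survey, make_region_polygons

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "choropleth_aggregate", "lattice_points"]

#: Coverage-gap contrasts: (factor, advantaged level, disadvantaged level)
DEFAULT_CONTRASTS = [
    ("wealth", "high", "low"),
    ("sdp_distance", "le2km", "gt6km"),
    ("education", "secondary+", "never"),
    ("residence", "urban", "rural"),
]


@dataclass
class PipelineConfig:
    """Configuration of one end-to-end run (synthetic or CSV input mode)."""

    mode: str = "synthetic"                     # synthetic | csv
    outdir: str | Path = "results/pipeline"
    seed: int = 0
    sim: SimConfig | None = None                # synthetic mode
    women_csv: str | Path | None = None         # csv mode
    sdps_csv: str | Path | None = None
    polygons_geojson: str | Path | None = None
    model: geostat.ModelSpec | None = None
    moran_k: int = 8
    n_perm: int = 999
    lattice_res: int = 25
    n_draws: int = 2000
    fit_model: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "csv"):
            raise ValueError(f"mode must be synthetic or csv, got {self.mode!r}")
        if self.mode == "csv" and self.women_csv is None:
            raise ValueError("csv mode requires women_csv")


def lattice_points(polygon, res: int) -> list[GeoPoint]:
    """Regular res x res lattice over the polygon's bbox, clipped to it."""
    lon_min, lat_min, lon_max, lat_max = polygon.bounds
    lons = np.linspace(lon_min, lon_max, res)
    lats = np.linspace(lat_min, lat_max, res)
    LO, LA = np.meshgrid(lons, lats)
    inside = shapely.intersects_xy(polygon, LO.ravel(), LA.ravel())
    return [GeoPoint(float(lo), float(la))
            for lo, la, ok in zip(LO.ravel(), LA.ravel(), inside) if ok]


def choropleth_aggregate(
    records: Sequence[WomanRecord], polygons: dict[str, object]
) -> tuple[pd.DataFrame, dict]:
    """Per-polygon weighted coverage; returns a table and a GeoJSON dict.

    Points are assigned by containment (boundary points go to the first
    covering polygon in feature order, logged); unassigned points are counted.
    """
    if not polygons:
        raise ValueError("empty polygon set")
    names = list(polygons)
    assignments: dict[str, list[WomanRecord]] = {n: [] for n in names}
    unassigned = 0
    for r in records:
        pt = shapely.Point(r.household_location.lon, r.household_location.lat)
        placed = False
        for n in names:
            if polygons[n].covers(pt):
                assignments[n].append(r)
                placed = True
                break
        if not placed:
            unassigned += 1
    if unassigned:
        logger.warning("choropleth: %d records outside all polygons", unassigned)
    rows, features = [], []
    for n in names:
        recs = assignments[n]
        if recs:
            est = survey.weighted_proportion(recs)
            cov = est.estimate
            rows.append({"name": n, "n": len(recs), "coverage": cov,
                         "ci_low": est.ci_low, "ci_high": est.ci_high})
        else:
            cov = None
            rows.append({"name": n, "n": 0, "coverage": None,
                         "ci_low": None, "ci_high": None})
        features.append({
            "type": "Feature",
            "properties": {"name": n, "coverage": cov, "n": len(recs)},
            "geometry": mapping(polygons[n]),
        })
    table = pd.DataFrame(rows)
    table.attrs["unassigned"] = unassigned
    gj = {"type": "FeatureCollection", "features": features}
    assigned = sum(len(v) for v in assignments.values())
    assert assigned + unassigned == len(records), "assignment counts do not reconcile"
    return table, gj


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the manifest (also written to disk)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    stage = "setup"
    try:
        # ------------------------------------------------------ input stage
        stage = "input"
        if config.mode == "synthetic":
            sim = config.sim or SimConfig(seed=config.seed)
            real = generate_survey(sim)
            women, sdps = real.women, real.sdps
            ea_locations = real.ea_centroids
            polygons = make_region_polygons(sim.polygon().bounds)
            boundary = sim.polygon()
            geodata.write_records(women, out / "women.csv")
            geodata.write_sdps(sdps, out / "sdps.csv")
            artifacts += [out / "women.csv", out / "sdps.csv"]
        else:
            women = geodata.read_records(config.women_csv)
            sdps = geodata.read_sdps(config.sdps_csv) if config.sdps_csv else []
            ea_locations = None
            polygons = (geodata.read_polygons(config.polygons_geojson)
                        if config.polygons_geojson else {})
            boundary = (shapely.unary_union(list(polygons.values()))
                        if polygons else None)
        logger.info("stage=input women=%d sdps=%d", len(women), len(sdps))

        stage = "distance linkage"
        if sdps and any(w.sdp_distance_km is None for w in women):
            women = link_nearest_sdp(women, sdps)
        logger.info("stage=linkage women=%d", len(women))

        # ------------------------------------------------------ tables
        stage = "summary tables"
        background_table = survey.background_table(women)
        background_table.to_csv(out / "background_table.csv", index=False)
        mix = survey.method_mix_table(women, by=None)
        for factor in ("age_group", "education", "wealth", "sdp_distance",
                       "partner_discussion", "residence", "region"):
            mix = pd.concat(
                [mix, survey.method_mix_table(women, by=factor)], ignore_index=True
            )
        mix.to_csv(out / "method_mix_table.csv", index=False)
        dist_tab = survey.distance_summary_table(women, by="region")
        dist_tab.to_csv(out / "distance_table.csv", index=False)
        overall = survey.weighted_proportion(women)
        _write_json(
            {"coverage_percent": overall.estimate * 100.0,
             "ci_low_percent": overall.ci_low * 100.0,
             "ci_high_percent": overall.ci_high * 100.0,
             "n": overall.n_unweighted},
            out / "coverage.json",
        )
        artifacts += [out / "background_table.csv", out / "method_mix_table.csv",
                      out / "distance_table.csv", out / "coverage.json"]
        logger.info("stage=tables rows=%d", len(background_table) + len(mix) + len(dist_tab))

        # ------------------------------------------------------ Moran
        stage = "spatial autocorrelation"
        pts, props, ids = spatial.ea_proportions(women, ea_locations)
        w = spatial.knn_weights(pts, k=min(config.moran_k, len(pts) - 1))
        moran = spatial.morans_i_permutation(props, w, n_perm=config.n_perm,
                                             seed=config.seed)
        w.to_gal(out / "moran_weights.gal", ids=ids)
        _write_json(
            {"I": moran.I, "expected_I": moran.expected_I, "z": moran.z,
             "p_analytic": moran.p, "p_permutation": moran.p_perm,
             "k": int(min(config.moran_k, len(pts) - 1)), "n_clusters": len(pts)},
            out / "moran.json",
        )
        artifacts += [out / "moran.json", out / "moran_weights.gal"]
        logger.info("stage=moran I=%.4f z=%.2f", moran.I, moran.z)

        # ------------------------------------------------------ choropleth
        stage = "choropleth aggregation"
        if polygons:
            chor_tab, chor_gj = choropleth_aggregate(women, polygons)
            chor_tab.to_csv(out / "region_coverage.csv", index=False)
            _write_json(chor_gj, out / "region_coverage.geojson")
            artifacts += [out / "region_coverage.csv", out / "region_coverage.geojson"]
            logger.info("stage=choropleth polygons=%d unassigned=%d",
                        len(polygons), chor_tab.attrs["unassigned"])

        manifest: dict = {"mode": config.mode, "seed": config.seed}

        # ------------------------------------------------------ model
        if config.fit_model:
            stage = "geostatistical model"
            spec = config.model or geostat.ModelSpec()
            loc_map = ({k: v for k, v in ea_locations.items()}
                       if ea_locations is not None else None)
            fit = geostat.fit_laplace(women, spec, ea_locations=loc_map,
                                      seed=config.seed)
            por = geostat.posterior_odds_ratios(fit)
            por.to_csv(out / "coefficients.csv", index=False)
            fit.theta_table.to_csv(out / "spatial_effects.csv", index=False)
            artifacts += [out / "coefficients.csv", out / "spatial_effects.csv"]
            logger.info("stage=model coefficients=%d nodes=%d",
                        fit.n_coef, len(fit.nodes))

            stage = "disparity contrasts"
            disp_rows = []
            for factor, hi, lo in DEFAULT_CONTRASTS:
                try:
                    disp_rows.append(survey.coverage_disparity(
                        women, factor, hi, lo, seed=config.seed))
                except ValueError as exc:
                    logger.warning("disparity %s skipped: %s", factor, exc)
            disp = pd.DataFrame(disp_rows)
            disp.to_csv(out / "disparity_table.csv", index=False)
            artifacts.append(out / "disparity_table.csv")

            stage = "prediction surface"
            if boundary is not None:
                lat = lattice_points(boundary, config.lattice_res)
                surf = geostat.predict_surface(
                    fit, lat, n_draws=config.n_draws, seed=config.seed)
                sf = surf.to_frame()
                sf.to_csv(out / "surface.csv", index=False)
                feats = [{
                    "type": "Feature",
                    "properties": {
                        "prev_mean": float(row["prev_mean"]),
                        "prev_q2.5": float(row["prev_q2.5"]),
                        "prev_q97.5": float(row["prev_q97.5"]),
                        "field_mean": float(row["field_mean"]),
                        "field_sd": float(row["field_sd"]),
                    },
                    "geometry": {"type": "Point",
                                 "coordinates": [float(row["lon"]), float(row["lat"])]},
                } for _, row in sf.iterrows()]
                _write_json({"type": "FeatureCollection", "features": feats},
                            out / "surface.geojson")
                artifacts += [out / "surface.csv", out / "surface.geojson"]
                logger.info("stage=surface nodes=%d", len(lat))

        # ------------------------------------------------------ manifest
        stage = "manifest"
        manifest["artifacts"] = {
            p.name: _sha256(p) for p in sorted(artifacts, key=lambda q: q.name)
        }
        _write_json(manifest, out / "manifest.json")
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
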