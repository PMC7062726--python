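"""File interchange: rasters as TIFF, inventories as CSV, geometry as GeoJSON.

Rasters are written as plain float32 multi-band TIFFs in pixel coordinates
(NaN encodes nodata); stem censuses round-trip through the flat CSV schema
plot_id, stem_id, dbh_cm, group, status, canopy_class, break_height_m,
branch_pct, height_m; plot footprints travel as GeoJSON polygons carrying
plot_id and area_ha properties.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import tifffile

from .inventory import PlotRecord, TreeRecord
from .synthetic import SceneConfig

INVENTORY_COLUMNS = [
    "plot_id",
    "stem_id",
    "dbh_cm",
    "group",
    "status",
    "canopy_class",
    "break_height_m",
    "branch_pct",
    "height_m",
]


def save_raster(path, raster: np.ndarray) -> None:
    """Write a (rows, cols) or (bands, rows, cols) raster as float32 TIFF."""
    tifffile.imwrite(str(path), np.asarray(raster, dtype=np.float32))


def load_raster(path) -> np.ndarray:
    return np.asarray(tifffile.imread(str(path)), dtype=float)


def inventory_to_csv(plots: list, path) -> None:
    rows = []
    for plot in plots:
        for tree in plot.trees:
            rows.append(
                {
                    "plot_id": plot.plot_id,
                    "stem_id": tree.stem_id,
                    "dbh_cm": tree.dbh_cm,
                    "group": tree.group,
                    "status": tree.status,
                    "canopy_class": tree.canopy_class,
                    "break_height_m": tree.break_height_m,
                    "branch_pct": tree.branch_pct,
                    "height_m": tree.height_m,
                }
            )
    pd.DataFrame(rows, columns=INVENTORY_COLUMNS).to_csv(path, index=False)


def inventory_from_csv(path, areas: dict | None = None) -> list:
    """Rebuild PlotRecords from the flat stem CSV.

    ``areas`` maps plot_id → area_ha (e.g. read from the GeoJSON footprints);
    missing plots default to 1 ha.
    """
    df = pd.read_csv(path)
    plots = []
    for plot_id, grp in df.groupby("plot_id", sort=True):
        trees = []
        for _, row in grp.iterrows():
            trees.append(
                TreeRecord(
                    dbh_cm=float(row["dbh_cm"]),
                    group=str(row["group"]),
                    status=str(row["status"]),
                    canopy_class=str(row["canopy_class"]),
                    break_height_m=None if pd.isna(row["break_height_m"]) else float(row["break_height_m"]),
                    branch_pct=None if pd.isna(row["branch_pct"]) else float(row["branch_pct"]),
                    height_m=None if pd.isna(row["height_m"]) else float(row["height_m"]),
                    stem_id=str(row["stem_id"]),
                )
            )
        area = (areas or {}).get(plot_id, 1.0)
        plots.append(PlotRecord(plot_id=str(plot_id), area_ha=area, trees=trees))
    return plots


def plots_to_geojson(plots: list, path) -> None:
    features = []
    for plot in plots:
        if plot.geometry is None:
            continue
        features.append(
            {
                "type": "Feature",
                "geometry": shapely.geometry.mapping(plot.geometry),
                "properties": {"plot_id": plot.plot_id, "area_ha": plot.area_ha},
            }
        )
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def geojson_to_geometries(path) -> dict:
    """GeoJSON → {plot_id: (shapely geometry, area_ha)}."""
    payload = json.loads(Path(path).read_text())
    out = {}
    for feat in payload["features"]:
        geom = shapely.geometry.shape(feat["geometry"])
        props = feat.get("properties", {})
        out[props.get("plot_id")] = (geom, props.get("area_ha"))
    return out


def config_to_json(config: SceneConfig, path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(config), indent=2))


def config_from_json(path) -> SceneConfig:
    payload = json.loads(Path(path).read_text())
    if "pre_fractions" in payload:
        payload["pre_fractions"] = tuple(payload["pre_fractions"])
    return SceneConfig(**payload)


def endmembers_from_csv(path):
    """Endmember CSV (one row per band; columns gv, npv, shade) → EndmemberSet."""
    from .imaging import EndmemberSet

    df = pd.read_csv(path)
    return EndmemberSet(df[["gv", "npv", "shade"]].to_numpy(dtype=float))


def endmembers_to_csv(endmembers, path) -> None:
    pd.DataFrame(endmembers.spectra, columns=["gv", "npv", "shade"]).to_csv(path, index=False)
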