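"""Plain-text readers and writers for pipeline artifacts.

Geometry travels as GeoJSON FeatureCollections (via shapely's mapping/shape),
tabular data as CSV with fixed float formatting so identical runs are
byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .datatypes import GridForecast, PlumeSet, RegionMap

__all__ = [
    "write_region_map", "read_region_map", "write_grids", "read_grids",
    "write_plumes", "read_plumes", "write_table", "read_table",
]

FLOAT_FMT = "%.10g"


def _fc(features: list[dict]) -> dict:
    return {"type": "FeatureCollection", "features": features}


def write_region_map(region: RegionMap, outdir: str | Path) -> None:
    """Write areas, population points and monitors as GeoJSON files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    areas = [{"type": "Feature", "properties": {"area_id": aid},
              "geometry": mapping(poly)} for aid, poly in region.areas]
    (outdir / "areas.geojson").write_text(json.dumps(_fc(areas)))
    pts = [{"type": "Feature",
            "properties": {"point_id": r.point_id, "area_id": r.area_id,
                           "population": int(r.population)},
            "geometry": {"type": "Point", "coordinates": [r.x_km, r.y_km]}}
           for r in region.population_points.itertuples()]
    (outdir / "population_points.geojson").write_text(json.dumps(_fc(pts)))
    mons = [{"type": "Feature", "properties": {"monitor_id": r.monitor_id},
             "geometry": {"type": "Point", "coordinates": [r.x_km, r.y_km]}}
            for r in region.monitors.itertuples()]
    (outdir / "monitors.geojson").write_text(json.dumps(_fc(mons)))


def read_region_map(indir: str | Path) -> RegionMap:
    indir = Path(indir)
    areas_fc = json.loads((indir / "areas.geojson").read_text())
    areas = [(f["properties"]["area_id"], shape(f["geometry"]))
             for f in areas_fc["features"]]
    pts_fc = json.loads((indir / "population_points.geojson").read_text())
    pts = pd.DataFrame([
        {"point_id": f["properties"]["point_id"],
         "area_id": f["properties"]["area_id"],
         "x_km": f["geometry"]["coordinates"][0],
         "y_km": f["geometry"]["coordinates"][1],
         "population": f["properties"]["population"]}
        for f in pts_fc["features"]])
    mons_fc = json.loads((indir / "monitors.geojson").read_text())
    mons = pd.DataFrame([
        {"monitor_id": f["properties"]["monitor_id"],
         "x_km": f["geometry"]["coordinates"][0],
         "y_km": f["geometry"]["coordinates"][1]}
        for f in mons_fc["features"]])
    return RegionMap(areas=areas, population_points=pts, monitors=mons)


def write_grids(grids: dict[int, GridForecast], path: str | Path) -> None:
    """Long-format CSV: day, cell_row, cell_col, x_min_km, y_min_km, value.

    Only positive cells are written (zero elsewhere); a header row per day in
    a companion meta file records grid shape, origin and availability.
    """
    path = Path(path)
    rows = []
    meta = {}
    for day in sorted(grids):
        g = grids[day]
        meta[str(day)] = {"n_rows": g.values.shape[0],
                          "n_cols": g.values.shape[1],
                          "x0_km": g.x0_km, "y0_km": g.y0_km,
                          "cell_km": g.cell_km, "available": bool(g.available)}
        rr, cc = np.nonzero(g.values > 0)
        for i, j in zip(rr, cc):
            rows.append((day, int(i), int(j),
                         g.x0_km + j * g.cell_km, g.y0_km + i * g.cell_km,
                         g.values[i, j]))
    df = pd.DataFrame(rows, columns=["day", "cell_row", "cell_col",
                                     "x_min_km", "y_min_km", "value"])
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, sort_keys=True))


def read_grids(path: str | Path) -> dict[int, GridForecast]:
    df = pd.read_csv(path)
    meta = json.loads(Path(str(path) + ".meta.json").read_text())
    grids = {}
    for day_s, m in meta.items():
        day = int(day_s)
        values = np.zeros((m["n_rows"], m["n_cols"]))
        sub = df[df["day"] == day]
        values[sub["cell_row"].to_numpy(), sub["cell_col"].to_numpy()] = \
            sub["value"].to_numpy()
        grids[day] = GridForecast(day=day, x0_km=m["x0_km"], y0_km=m["y0_km"],
                                  cell_km=m["cell_km"], values=values,
                                  available=m["available"])
    return grids


def write_plumes(plumes: dict[int, PlumeSet], path: str | Path) -> None:
    """One GeoJSON FeatureCollection; each feature is a day's plume union."""
    feats = []
    for day in sorted(plumes):
        p = plumes[day]
        geom = None if p.is_empty() else mapping(p.union())
        feats.append({"type": "Feature",
                      "properties": {"day": day, "source": p.source},
                      "geometry": geom})
    Path(path).write_text(json.dumps(_fc(feats)))


def read_plumes(path: str | Path) -> dict[int, PlumeSet]:
    fc = json.loads(Path(path).read_text())
    out = {}
    for f in fc["features"]:
        day = int(f["properties"]["day"])
        source = f["properties"].get("source", "observed")
        if f["geometry"] is None:
            out[day] = PlumeSet(day=day, polygons=[], source=source)
        else:
            geom = shape(f["geometry"])
            polys = list(geom.geoms) if geom.geom_type == "MultiPolygon" else [geom]
            out[day] = PlumeSet(day=day, polygons=polys, source=source)
    return out


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """CSV with deterministic float formatting."""
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, **kwargs)
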