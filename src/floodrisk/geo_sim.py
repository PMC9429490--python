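"""Attach scenarios and risk levels to regions; aggregate and render maps.

Works on the toy subdistrict geometries of :mod:`floodrisk.synthetic_data`
(or any GeoJSON with the same properties).  Each subdistrict gets a scenario
(F, H, P), a risk score via :mod:`floodrisk.risk_score`, a level from the
percentile table and a legend colour; results can be rolled up to district or
province level and rendered as a choropleth PNG or exported as GeoJSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .risk_score import (
    LEVEL_COLOURS,
    LoadingSet,
    RiskLevelTable,
    Scenario,
    _score_arrays,
    level_to_colour,
)
from .synthetic_data import RegionSet

__all__ = [
    "ScenarioAssignment",
    "ChoroplethResult",
    "simulate_map",
    "aggregate",
    "render_map",
    "export_geojson",
    "load_geojson_result",
]

AGG_METHODS = ("mean", "max", "area_weighted_mean")


@dataclass
class ScenarioAssignment:
    """region_id -> Scenario for every subdistrict."""

    scenarios: dict[str, Scenario]

    @classmethod
    def uniform(cls, regions: RegionSet, scenario: Scenario) -> "ScenarioAssignment":
        return cls({r.region_id: scenario for r in regions.regions})

    @classmethod
    def from_csv(cls, path_or_buf) -> "ScenarioAssignment":
        df = pd.read_csv(path_or_buf)
        required = {"region_id", "F", "H", "P"}
        if not required.issubset(df.columns):
            raise ValueError(f"scenario CSV needs columns {sorted(required)}")
        return cls(
            {
                str(r.region_id): Scenario(F=float(r.F), H=float(r.H), P=float(r.P))
                for r in df.itertuples()
            }
        )


@dataclass
class ChoroplethResult:
    """Per-region scores/levels/colours at one administrative level."""

    table: pd.DataFrame  # region_id, F, H, P, score, level, colour
    admin_level: str  # subdistrict | district | province
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.admin_level not in ("subdistrict", "district", "province"):
            raise ValueError(f"unknown admin level {self.admin_level!r}")


def simulate_map(
    regions: RegionSet,
    assignment: ScenarioAssignment,
    loadings: LoadingSet,
    table: RiskLevelTable,
    *,
    eq10_printed: bool = False,
) -> ChoroplethResult:
    """Score every subdistrict's scenario and bin it through the level table."""
    missing = [r.region_id for r in regions.regions if r.region_id not in assignment.scenarios]
    if missing:
        raise ValueError(f"no scenario assigned for regions: {missing}")
    rows = []
    for r in regions.regions:
        sc = assignment.scenarios[r.region_id]
        s = float(
            _score_arrays(
                np.asarray(sc.F), np.asarray(sc.H), np.asarray(sc.P), loadings, eq10_printed
            )
        )
        lv = table.level(s)
        rows.append(
            {
                "region_id": r.region_id,
                "F": sc.F,
                "H": sc.H,
                "P": sc.P,
                "score": s,
                "level": lv,
                "colour": level_to_colour(lv)[0],
            }
        )
    return ChoroplethResult(
        table=pd.DataFrame(rows),
        admin_level="subdistrict",
        provenance={"loadings": loadings.to_dict(), "cutoffs": [float(c) for c in table.cutoffs]},
    )


def aggregate(
    result: ChoroplethResult,
    regions: RegionSet,
    level: str,
    table: RiskLevelTable,
    method: str = "area_weighted_mean",
) -> ChoroplethResult:
    """Roll subdistrict results up to district or province level.

    Child scores (and F, H, P) combine by ``mean``, ``max`` or
    ``area_weighted_mean``; the combined score is re-binned through the same
    level table so levels stay comparable across administrative levels.
    """
    if result.admin_level != "subdistrict":
        raise ValueError("aggregation starts from a subdistrict-level result")
    if level not in ("district", "province"):
        raise ValueError("aggregate to 'district' or 'province'")
    if method not in AGG_METHODS:
        raise ValueError(f"unknown aggregation method {method!r}; use one of {AGG_METHODS}")
    key = "district_id" if level == "district" else "province_id"
    meta = pd.DataFrame(
        [
            {
                "region_id": r.region_id,
                key: getattr(r, key),
                "area": r.geometry.area,
            }
            for r in regions.regions
        ]
    )
    merged = result.table.merge(meta, on="region_id", validate="one_to_one")
    rows = []
    for gid, grp in merged.groupby(key, sort=True):
        if method == "max":
            agg = grp[["F", "H", "P", "score"]].max()
        elif method == "mean":
            agg = grp[["F", "H", "P", "score"]].mean()
        else:
            w = grp["area"].to_numpy()
            agg = grp[["F", "H", "P", "score"]].apply(lambda c: float(np.average(c, weights=w)))
        lv = table.level(float(agg["score"]))
        rows.append(
            {
                "region_id": gid,
                "F": float(agg["F"]),
                "H": float(agg["H"]),
                "P": float(agg["P"]),
                "score": float(agg["score"]),
                "level": lv,
                "colour": level_to_colour(lv)[0],
            }
        )
    prov = dict(result.provenance, aggregation=method)
    return ChoroplethResult(table=pd.DataFrame(rows), admin_level=level, provenance=prov)


def _geometries_at_level(regions: RegionSet, admin_level: str):
    """region_id -> geometry at the requested admin level (unions of children)."""
    from shapely.ops import unary_union

    if admin_level == "subdistrict":
        return {r.region_id: r.geometry for r in regions.regions}
    key = "district_id" if admin_level == "district" else "province_id"
    groups: dict[str, list] = {}
    for r in regions.regions:
        groups.setdefault(getattr(r, key), []).append(r.geometry)
    return {gid: unary_union(geoms) for gid, geoms in groups.items()}


def render_map(
    result: ChoroplethResult,
    regions: RegionSet,
    out_path,
    *,
    title: str | None = None,
    dpi: int = 150,
) -> None:
    """Render the choropleth to a PNG with the fixed 11-level legend.

    Pure view: data are never modified.  Output bytes are stable for fixed
    inputs and matplotlib version.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Patch

    geoms = _geometries_at_level(regions, result.admin_level)
    missing = [rid for rid in result.table["region_id"] if rid not in geoms]
    if missing:
        raise ValueError(f"no geometry for regions: {missing}")
    fig, ax = plt.subplots(figsize=(8, 6))
    for row in result.table.itertuples():
        geom = geoms[row.region_id]
        polys = geom.geoms if geom.geom_type == "MultiPolygon" else [geom]
        colour = LEVEL_COLOURS[int(row.level)][1]
        for poly in polys:
            xs, ys = poly.exterior.xy
            ax.fill(xs, ys, facecolor=colour, edgecolor="black", linewidth=0.6)
    handles = [
        Patch(facecolor=LEVEL_COLOURS[lv][1], edgecolor="black", label=f"{lv}: {LEVEL_COLOURS[lv][0]}")
        for lv in range(10, -1, -1)
    ]
    ax.legend(handles=handles, loc="center left", bbox_to_anchor=(1.01, 0.5), fontsize=8, title="Risk level")
    ax.set_aspect("equal")
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out_path, dpi=dpi, metadata={"Software": "floodrisk"})
    plt.close(fig)


def export_geojson(result: ChoroplethResult, regions: RegionSet) -> dict:
    """FeatureCollection with per-region scenario, score, level and colour.

    Lossless for properties: scores round-trip at full float precision.
    """
    from shapely.geometry import mapping

    geoms = _geometries_at_level(regions, result.admin_level)
    missing = [rid for rid in result.table["region_id"] if rid not in geoms]
    if missing:
        raise ValueError(f"no geometry for regions: {missing}")
    features = []
    for row in result.table.itertuples():
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(geoms[row.region_id]),
                "properties": {
                    "region_id": row.region_id,
                    "F": float(row.F),
                    "H": float(row.H),
                    "P": float(row.P),
                    "score": float(row.score),
                    "level": int(row.level),
                    "colour": row.colour,
                },
            }
        )
    return {
        "type": "FeatureCollection",
        "features": features,
        "properties": {"admin_level": result.admin_level, **result.provenance},
    }


def write_geojson(result: ChoroplethResult, regions: RegionSet, path) -> None:
    with open(path, "w") as fh:
        json.dump(export_geojson(result, regions), fh, indent=1)


def load_geojson_result(doc: dict) -> ChoroplethResult:
    """Rebuild a ChoroplethResult from an exported FeatureCollection."""
    rows = [f["properties"] for f in doc["features"]]
    props = doc.get("properties", {})
    return ChoroplethResult(
        table=pd.DataFrame(rows, columns=["region_id", "F", "H", "P", "score", "level", "colour"]),
        admin_level=props.get("admin_level", "subdistrict"),
        provenance={k: v for k, v in props.items() if k != "admin_level"},
    )
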