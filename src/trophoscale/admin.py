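"""Administrative layout: raster cells nested in municipalities nested in counties.

Herbivore statistics resolve to municipalities and carnivore harvests to
counties, so every grid cell must belong to exactly one municipality and
every municipality to exactly one county.  Rangeland (the unimproved land
over which consumer densities are expressed) is the union of forest and
open cells; the ``other`` class stands in for cultivated/urban land.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import box, mapping, shape
from shapely.ops import unary_union

from .config import FOREST, LAND_COVER_CLASSES, OPEN

__all__ = ["AdminLayout", "municipality_id", "county_id"]


def county_id(county_index: int) -> str:
    return f"c{county_index:02d}"


def municipality_id(county_index: int, mun_index: int) -> str:
    return f"m{county_index:02d}{mun_index:02d}"


@dataclass(frozen=True)
class AdminLayout:
    """Partition of a raster grid into municipalities and counties.

    Attributes
    ----------
    grid_shape:
        (rows, cols) of the cell grid.
    cell_area:
        Area of one cell in km^2.
    municipality_index, county_index:
        Integer arrays of shape ``grid_shape`` mapping each cell to its
        municipality / county ordinal.
    land_cover:
        Integer array of shape ``grid_shape``; codes index into
        ``LAND_COVER_CLASSES`` (0 forest, 1 open, 2 other).
    units:
        One row per municipality: ``unit_id``, ``county_id``, ``n_cells``,
        ``forest_cells``, ``open_cells``, ``rangeland_area_km2``.
    """

    grid_shape: tuple[int, int]
    cell_area: float
    municipality_index: np.ndarray
    county_index: np.ndarray
    land_cover: np.ndarray
    units: pd.DataFrame

    def __post_init__(self) -> None:
        for arr in (self.municipality_index, self.county_index, self.land_cover):
            if arr.shape != tuple(self.grid_shape):
                raise ValueError("cell arrays must share grid_shape")

    # ---- identifiers -------------------------------------------------

    @property
    def municipality_ids(self) -> list[str]:
        return list(self.units["unit_id"])

    @property
    def county_ids(self) -> list[str]:
        return list(dict.fromkeys(self.units["county_id"]))

    # ---- areas -------------------------------------------------------

    def rangeland_area(self, unit_id: str) -> float:
        """Rangeland (forest + open) area of a municipality in km^2."""
        row = self.units.loc[self.units["unit_id"] == unit_id]
        if row.empty:
            raise KeyError(f"unknown unit {unit_id!r}")
        return float(row["rangeland_area_km2"].iloc[0])

    def ecosystem_area(self, unit_id: str, ecosystem: str) -> float:
        """Area of a municipality's cells for one ecosystem.

        ``all`` counts forest + open cells, ``forest`` only forest,
        ``alpine`` only open (tundra above the treeline plus lowland heaths
        fall in the open class).
        """
        row = self.units.loc[self.units["unit_id"] == unit_id]
        if row.empty:
            raise KeyError(f"unknown unit {unit_id!r}")
        if ecosystem == "all":
            n = row["forest_cells"].iloc[0] + row["open_cells"].iloc[0]
        elif ecosystem == "forest":
            n = row["forest_cells"].iloc[0]
        elif ecosystem == "alpine":
            n = row["open_cells"].iloc[0]
        else:
            raise ValueError(f"unknown ecosystem {ecosystem!r}")
        return float(n) * self.cell_area

    def county_table(self) -> pd.DataFrame:
        """Aggregate the unit table to counties (cell counts and areas sum)."""
        agg = (
            self.units.groupby("county_id", sort=True)[
                ["n_cells", "forest_cells", "open_cells", "rangeland_area_km2"]
            ]
            .sum()
            .reset_index()
        )
        return agg

    def county_rangeland_area(self, cid: str) -> float:
        tab = self.county_table()
        row = tab.loc[tab["county_id"] == cid]
        if row.empty:
            raise KeyError(f"unknown county {cid!r}")
        return float(row["rangeland_area_km2"].iloc[0])

    # ---- cell selection ----------------------------------------------

    def unit_mask(self, unit_id: str) -> np.ndarray:
        """Boolean cell mask of a municipality (or county ``c..`` id)."""
        if unit_id.startswith("c"):
            ordinal = self.county_ids.index(unit_id)
            return self.county_index == ordinal
        ordinal = self.municipality_ids.index(unit_id)
        return self.municipality_index == ordinal

    def ecosystem_mask(self, ecosystem: str) -> np.ndarray:
        forest = self.land_cover == LAND_COVER_CLASSES.index(FOREST)
        open_ = self.land_cover == LAND_COVER_CLASSES.index(OPEN)
        if ecosystem == "all":
            return forest | open_
        if ecosystem == "forest":
            return forest
        if ecosystem == "alpine":
            return open_
        raise ValueError(f"unknown ecosystem {ecosystem!r}")

    # ---- GeoJSON -----------------------------------------------------

    def to_geojson(self, path) -> None:
        """Write municipality polygons with rangeland areas as GeoJSON.

        Cells are unit squares scaled so each has area ``cell_area``; the
        polygon of a unit is the union of its cell boxes.
        """
        side = math.sqrt(self.cell_area)
        rows, _ = self.grid_shape
        features = []
        for ordinal, rec in self.units.iterrows():
            cells = np.argwhere(self.municipality_index == ordinal)
            boxes = [
                box(c * side, (rows - 1 - r) * side, (c + 1) * side, (rows - r) * side)
                for r, c in cells
            ]
            geom = unary_union(boxes)
            features.append(
                {
                    "type": "Feature",
                    "geometry": mapping(geom),
                    "properties": {
                        "unit_id": rec["unit_id"],
                        "county_id": rec["county_id"],
                        "rangeland_area_km2": float(rec["rangeland_area_km2"]),
                    },
                }
            )
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)

    def join_geojson(self, attributes: pd.DataFrame, key: str = "unit_id") -> dict:
        """Return a FeatureCollection of unit polygons joined with attributes.

        ``attributes`` must carry the join key; remaining columns become
        feature properties (suitable for choropleth rendering).
        """
        side = math.sqrt(self.cell_area)
        rows, _ = self.grid_shape
        attr = attributes.set_index(key)
        features = []
        for ordinal, rec in self.units.iterrows():
            uid = rec["unit_id"]
            cells = np.argwhere(self.municipality_index == ordinal)
            boxes = [
                box(c * side, (rows - 1 - r) * side, (c + 1) * side, (rows - r) * side)
                for r, c in cells
            ]
            props = {"unit_id": uid, "county_id": rec["county_id"]}
            if uid in attr.index:
                props.update(
                    {k: (None if pd.isna(v) else v) for k, v in attr.loc[uid].items()}
                )
            features.append(
                {
                    "type": "Feature",
                    "geometry": mapping(unary_union(boxes)),
                    "properties": props,
                }
            )
        return {"type": "FeatureCollection", "features": features}


def read_geojson_areas(path) -> pd.DataFrame:
    """Read unit polygons written by :meth:`AdminLayout.to_geojson`.

    Returns a table of unit_id, county_id, rangeland_area_km2 and the parsed
    shapely geometry.
    """
    with open(path) as fh:
        fc = json.load(fh)
    rows = []
    for feat in fc["features"]:
        props = feat["properties"]
        rows.append(
            {
                "unit_id": props["unit_id"],
                "county_id": props["county_id"],
                "rangeland_area_km2": props["rangeland_area_km2"],
                "geometry": shape(feat["geometry"]),
            }
        )
    return pd.DataFrame(rows)
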