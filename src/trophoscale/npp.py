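"""Net primary productivity layer: unit conversion and zonal aggregation.

NPP is the resource base of the trophic pyramid.  Annual rasters (one grid
per calendar year, kg C km^-2 yr^-1, NaN for missing) are masked to
rangeland and averaged per administrative unit, optionally restricted to an
ecosystem class (forest, or alpine = the open/tundra class).

Rasters travel as plain-grid CSV: one file per year, a rows x cols table of
cell values with no header.  Land cover is a categorical grid in the
:class:`~trophoscale.admin.AdminLayout`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .admin import AdminLayout

logger = logging.getLogger(__name__)

__all__ = [
    "NPPRaster",
    "convert_npp_units",
    "zonal_mean_npp",
    "multi_year_mean_npp",
    "national_mean_npp",
    "write_raster_csv",
    "read_raster_csv",
]


@dataclass(frozen=True)
class NPPRaster:
    """One year of NPP on the analysis grid.

    values are kg C km^-2 yr^-1, NaN where missing; the grid must be
    congruent with the layout it will be aggregated over.
    """

    year: int
    values: np.ndarray
    cell_area: float

    def __post_init__(self) -> None:
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite < 0).any():
            raise ValueError("NPP values must be >= 0 or missing")


def convert_npp_units(
    raw_grid: np.ndarray,
    scale_factor: float,
    to_km2_factor: float,
    year: int,
    cell_area: float,
    fill_value: float | None = None,
) -> NPPRaster:
    """Convert a raw productivity grid to kg C km^-2 yr^-1.

    value = raw * scale_factor * to_km2_factor.  With the MOD17 convention
    the raw integers carry a 1e-4 scale to kg C m^-2, and 1e6 m^2 per km^2
    gives the km^2 basis.  Cells equal to ``fill_value`` and cells that
    convert to negative numbers are mapped to NaN; negatives are counted in
    a log message because they indicate an upstream fill code leaking
    through.
    """
    if scale_factor <= 0 or to_km2_factor <= 0:
        raise ValueError("scale factors must be positive")
    raw = np.asarray(raw_grid, dtype=float)
    values = raw * (scale_factor * to_km2_factor)
    if fill_value is not None:
        values = np.where(raw == fill_value, np.nan, values)
    negative = np.isfinite(values) & (values < 0)
    n_neg = int(negative.sum())
    if n_neg:
        logger.warning("convert_npp_units: %d negative cells mapped to missing", n_neg)
        values = np.where(negative, np.nan, values)
    return NPPRaster(year=year, values=values, cell_area=cell_area)


def _eligible_mask(raster: NPPRaster, layout: AdminLayout, ecosystem: str) -> np.ndarray:
    if raster.values.shape != tuple(layout.grid_shape):
        raise ValueError(
            f"raster grid {raster.values.shape} does not match layout "
            f"{tuple(layout.grid_shape)}"
        )
    return layout.ecosystem_mask(ecosystem) & np.isfinite(raster.values)


def zonal_mean_npp(
    raster: NPPRaster,
    layout: AdminLayout,
    ecosystem: str = "all",
    level: str = "municipality",
) -> pd.DataFrame:
    """Unweighted mean NPP over rangeland cells, per administrative unit.

    Only non-missing cells of the requested class set contribute (all =
    forest + open, alpine = open).  Units with no eligible cell are reported
    with ``mean_npp`` NaN and ``n_cells`` 0 so gaps stay visible.

    Returns columns: unit_id, year, ecosystem, mean_npp, n_cells.
    """
    eligible = _eligible_mask(raster, layout, ecosystem)
    if level == "municipality":
        ids = layout.municipality_ids
        index = layout.municipality_index
    elif level == "county":
        ids = layout.county_ids
        index = layout.county_index
    else:
        raise ValueError(f"unknown level {level!r}")
    rows = []
    for ordinal, uid in enumerate(ids):
        mask = eligible & (index == ordinal)
        n = int(mask.sum())
        mean = float(raster.values[mask].mean()) if n else float("nan")
        rows.append(
            {
                "unit_id": uid,
                "year": raster.year,
                "ecosystem": ecosystem,
                "mean_npp": mean,
                "n_cells": n,
            }
        )
    return pd.DataFrame(rows)


def multi_year_mean_npp(
    rasters: list[NPPRaster],
    layout: AdminLayout,
    year_range: tuple[int, int],
    ecosystem: str = "all",
    level: str = "municipality",
) -> pd.DataFrame:
    """Mean over years of the annual zonal means, for rasters within range.

    The label column ``year`` carries the "y0-y1" range string.
    """
    y0, y1 = year_range
    selected = [r for r in rasters if y0 <= r.year <= y1]
    if not selected:
        raise ValueError(f"no rasters within year range {year_range}")
    annual = pd.concat(
        [zonal_mean_npp(r, layout, ecosystem, level) for r in selected],
        ignore_index=True,
    )
    out = (
        annual.groupby("unit_id", sort=False)
        .agg(mean_npp=("mean_npp", "mean"), n_cells=("n_cells", "max"))
        .reset_index()
    )
    out.insert(1, "year", f"{y0}-{y1}")
    out.insert(2, "ecosystem", ecosystem)
    return out


def national_mean_npp(
    raster: NPPRaster, layout: AdminLayout, masked: bool = True
) -> float:
    """National mean NPP over all non-missing cells.

    With ``masked=True`` (default) only rangeland (forest + open) cells
    enter the mean, mirroring the zonal aggregation; ``masked=False`` gives
    the unmasked all-land summary.
    """
    if masked:
        mask = _eligible_mask(raster, layout, "all")
    else:
        mask = np.isfinite(raster.values)
    if not mask.any():
        return float("nan")
    return float(raster.values[mask].mean())


def write_raster_csv(raster: NPPRaster, path) -> None:
    """Write the value grid as a headerless rows x cols CSV."""
    np.savetxt(path, raster.values, delimiter=",")


def read_raster_csv(path, year: int, cell_area: float) -> NPPRaster:
    """Read a headerless plain-grid CSV written by :func:`write_raster_csv`."""
    values = np.loadtxt(path, delimiter=",", ndmin=2)
    return NPPRaster(year=year, values=values, cell_area=cell_area)
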