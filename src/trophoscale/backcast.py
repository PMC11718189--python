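"""Carnivore population backcasting from harvest records.

Past carnivore abundance is reconstructed per county by inverting a
growth-then-harvest recurrence.  Forward, a population grows by the annual
rate lambda and then loses the recorded kills; backwards from a modern
monitoring anchor N(anchor_year):

    N_{t-1} = (N_t + H_t) / lambda

A feasibility floor enforces that the reconstructed population of a year is
never smaller than that year's recorded kill; floored years are flagged.
Abundances stay real-valued — rounding is left to reporting so that errors
do not compound over a century-scale series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .admin import AdminLayout

__all__ = [
    "CarnivoreModelParams",
    "backcast_population",
    "carnivore_biomass_density",
    "decadal_snapshot",
    "sensitivity_scan",
]


@dataclass(frozen=True)
class CarnivoreModelParams:
    """Backcast model constants for one species in one county.

    lam is the annual multiplicative growth rate (> 0); the anchor is a
    modern abundance (monitoring-based in real use, ground truth in
    synthetic use) at anchor_year.
    """

    species: str
    lam: float
    anchor_year: int
    anchor_abundance: float
    mean_body_mass: float

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ValueError("lambda must be > 0")
        if self.anchor_abundance < 0:
            raise ValueError("anchor abundance must be >= 0")
        if not self.mean_body_mass > 0:
            raise ValueError("body mass must be > 0")


def _harvest_map(harvest: pd.DataFrame) -> dict[int, float]:
    kills = harvest.set_index("year")["kills"]
    if (kills < 0).any():
        raise ValueError("kills must be >= 0")
    years = sorted(kills.index)
    missing = [y for y in range(years[0], years[-1] + 1) if y not in kills.index]
    if missing:
        raise ValueError(
            f"harvest series has unmarked gaps at {missing}; fill or mark them"
        )
    return {int(y): float(k) for y, k in kills.items()}


def backcast_population(
    harvest: pd.DataFrame, params: CarnivoreModelParams, floor: bool = True
) -> pd.DataFrame:
    """Reconstruct the abundance trajectory of one county backwards in time.

    ``harvest`` needs columns year and kills covering a contiguous span;
    the anchor year must lie inside (or at the end of) that span.  Returns
    one row per year from the first harvest year minus one up to the anchor
    year, with columns ``year``, ``abundance``, ``feasibility_flag``
    (True where the harvest floor raised the raw recurrence value).
    """
    kills = _harvest_map(harvest)
    y_first, y_last = min(kills), max(kills)
    if not y_first <= params.anchor_year <= y_last:
        raise ValueError(
            f"anchor year {params.anchor_year} outside harvest span "
            f"[{y_first}, {y_last}]"
        )

    abundance = {params.anchor_year: float(params.anchor_abundance)}
    flags = {params.anchor_year: False}
    for t in range(params.anchor_year, y_first - 1, -1):
        raw = (abundance[t] + kills[t]) / params.lam
        prev_kill = kills.get(t - 1, 0.0)
        if floor and raw < prev_kill:
            abundance[t - 1] = prev_kill
            flags[t - 1] = True
        else:
            abundance[t - 1] = raw
            flags[t - 1] = False

    years = sorted(abundance)
    return pd.DataFrame(
        {
            "year": years,
            "abundance": [abundance[y] for y in years],
            "feasibility_flag": [flags[y] for y in years],
        }
    )


def carnivore_biomass_density(
    result: pd.DataFrame,
    params: CarnivoreModelParams,
    layout: AdminLayout,
    unit_id: str,
) -> pd.DataFrame:
    """Convert a reconstructed trajectory to biomass density for one county.

    density_t = N_t x mean body mass / county rangeland area.  Output is a
    biomass surface slice (trophic_level carnivore, slice = species name).
    """
    area = layout.county_rangeland_area(unit_id)
    if area <= 0:
        raise ValueError(f"county {unit_id} has no rangeland area")
    out = result.copy()
    out["trophic_level"] = "carnivore"
    out["slice"] = params.species
    out["unit_id"] = unit_id
    out["biomass_kg"] = out["abundance"] * params.mean_body_mass
    out["density_kg_km2"] = out["biomass_kg"] / area
    return out[
        [
            "trophic_level",
            "slice",
            "unit_id",
            "year",
            "abundance",
            "feasibility_flag",
            "density_kg_km2",
            "biomass_kg",
        ]
    ]


def national_carnivore_series(
    surfaces: pd.DataFrame, layout: AdminLayout
) -> pd.DataFrame:
    """Area-weighted national carnivore density per year and slice.

    Guild totals (slice ``total``) are appended: the per-year sum of all
    species' biomass over the national rangeland area.
    """
    counties = layout.county_table().set_index("county_id")
    total_area = float(counties["rangeland_area_km2"].sum())
    per_slice = (
        surfaces.groupby(["slice", "year"], sort=False)["biomass_kg"]
        .sum()
        .reset_index()
    )
    per_slice["density_kg_km2"] = per_slice["biomass_kg"] / total_area
    guild = (
        per_slice.groupby("year", sort=False)[["biomass_kg"]].sum().reset_index()
    )
    guild["slice"] = "total"
    guild["density_kg_km2"] = guild["biomass_kg"] / total_area
    out = pd.concat([per_slice, guild], ignore_index=True)
    out.insert(0, "trophic_level", "carnivore")
    return out[["trophic_level", "slice", "year", "density_kg_km2", "biomass_kg"]]


def decadal_snapshot(series: pd.DataFrame, census_years) -> pd.DataFrame:
    """Extract the rows of the annual series at the census years (no averaging)."""
    years = set(series["year"])
    outside = [y for y in census_years if y not in years]
    if outside:
        raise ValueError(f"census years {outside} outside the series span")
    snap = series[series["year"].isin(set(census_years))]
    return snap.reset_index(drop=True)


def sensitivity_scan(
    harvest: pd.DataFrame,
    params: CarnivoreModelParams,
    lambda_grid,
    anchor_grid,
) -> pd.DataFrame:
    """Backcast over a grid of (lambda, anchor) values.

    For each combination the full reconstruction is summarised by the
    earliest-year abundance, the series minimum, and the count of
    feasibility-floored years — a cheap diagnostic for how strongly the
    reconstruction depends on the assumed growth rate and modern anchor.
    """
    lambda_grid = list(lambda_grid)
    anchor_grid = list(anchor_grid)
    if not lambda_grid or not anchor_grid:
        raise ValueError("grids must be non-empty")
    rows = []
    for lam in lambda_grid:
        for anchor in anchor_grid:
            p = CarnivoreModelParams(
                species=params.species,
                lam=lam,
                anchor_year=params.anchor_year,
                anchor_abundance=anchor,
                mean_body_mass=params.mean_body_mass,
            )
            res = backcast_population(harvest, p)
            rows.append(
                {
                    "lambda": lam,
                    "anchor_abundance": anchor,
                    "earliest_year": int(res["year"].min()),
                    "earliest_abundance": float(
                        res.loc[res["year"].idxmin(), "abundance"]
                    ),
                    "min_abundance": float(res["abundance"].min()),
                    "n_floored": int(res["feasibility_flag"].sum()),
                }
            )
    return pd.DataFrame(rows)
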