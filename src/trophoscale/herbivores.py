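"""Herbivore biomass assembly.

Livestock headcounts and wild-herbivore densities become per-municipality
biomass densities (kg per km^2 of rangeland) at the census years.  Livestock
biomass is seasonally standardised: a flock on the rangeland for three
months of the year contributes 25% of its full-year biomass.  Raw (not
metabolic) biomass is used throughout.

Biomass surfaces are tidy DataFrames with columns
``trophic_level, slice, unit_id, year, density_kg_km2, biomass_kg`` where
slice is one of total/livestock/wild (guild split) or forest/alpine
(ecosystem partition).
"""

from __future__ import annotations

import pandas as pd

from .admin import AdminLayout
from .config import SpeciesProfile

__all__ = [
    "seasonal_standardise",
    "assemble_herbivore_density",
    "national_summary",
    "guild_share",
    "ecosystem_partition",
]

SURFACE_COLUMNS = [
    "trophic_level",
    "slice",
    "unit_id",
    "year",
    "density_kg_km2",
    "biomass_kg",
]


def seasonal_standardise(headcount: float, profile: SpeciesProfile) -> float:
    """Rangeland-standardised population biomass in kg.

    biomass = headcount x mean body mass x fraction of the year on
    rangeland.  1000 sheep of 45 kg ranging three months (fraction 0.25)
    contribute 11 250 kg.
    """
    if headcount < 0:
        raise ValueError("headcount must be >= 0")
    return headcount * profile.mean_body_mass * profile.rangeland_fraction


def _check_species(table: pd.DataFrame, profiles: dict[str, SpeciesProfile]) -> None:
    unknown = sorted(set(table["species"]) - set(profiles))
    if unknown:
        raise KeyError(f"species without profiles: {unknown}")


def assemble_herbivore_density(
    livestock: pd.DataFrame,
    wild_densities: pd.DataFrame,
    profiles: dict[str, SpeciesProfile],
    layout: AdminLayout,
    year: int,
) -> pd.DataFrame:
    """Per-municipality herbivore biomass surface for one census year.

    The livestock slice sums seasonally standardised biomass over livestock
    and semi-domestic species and divides by rangeland area; the wild slice
    sums the supplied wild densities; total = livestock + wild.  Every
    municipality in the layout is reported (zero slices where no records).
    """
    _check_species(livestock, profiles)
    _check_species(wild_densities, profiles)

    live = livestock[livestock["year"] == year]
    wild = wild_densities[wild_densities["year"] == year]

    rows = []
    for _, unit in layout.units.iterrows():
        uid = unit["unit_id"]
        area = float(unit["rangeland_area_km2"])
        if area <= 0:
            raise ValueError(f"unit {uid} has no rangeland area")
        live_kg = sum(
            seasonal_standardise(rec["headcount"], profiles[rec["species"]])
            for _, rec in live[live["municipality_id"] == uid].iterrows()
        )
        wild_dens = float(
            wild.loc[wild["municipality_id"] == uid, "density_kg_km2"].sum()
        )
        live_dens = live_kg / area
        for slc, dens, kg in [
            ("livestock", live_dens, live_kg),
            ("wild", wild_dens, wild_dens * area),
            ("total", live_dens + wild_dens, live_kg + wild_dens * area),
        ]:
            rows.append(
                {
                    "trophic_level": "herbivore",
                    "slice": slc,
                    "unit_id": uid,
                    "year": year,
                    "density_kg_km2": dens,
                    "biomass_kg": kg,
                }
            )
    return pd.DataFrame(rows, columns=SURFACE_COLUMNS)


def national_summary(surface: pd.DataFrame, layout: AdminLayout) -> pd.DataFrame:
    """Rangeland-area-weighted national mean density per slice and year.

    Equivalent to summing absolute biomass and dividing by total rangeland
    area, so municipal absolute biomass is conserved exactly.
    """
    total_area = float(layout.units["rangeland_area_km2"].sum())
    out = (
        surface.groupby(["trophic_level", "slice", "year"], sort=False)["biomass_kg"]
        .sum()
        .reset_index()
    )
    out["density_kg_km2"] = out["biomass_kg"] / total_area
    return out[["trophic_level", "slice", "year", "density_kg_km2", "biomass_kg"]]


def guild_share(surface: pd.DataFrame, year: int) -> float:
    """Livestock share of total herbivore biomass in one year, in [0, 1].

    NaN when the total is zero (undefined share).
    """
    sub = surface[surface["year"] == year]
    total = float(sub.loc[sub["slice"] == "total", "biomass_kg"].sum())
    if total <= 0:
        return float("nan")
    livestock = float(sub.loc[sub["slice"] == "livestock", "biomass_kg"].sum())
    return livestock / total


def ecosystem_partition(
    livestock: pd.DataFrame,
    wild_densities: pd.DataFrame,
    profiles: dict[str, SpeciesProfile],
    layout: AdminLayout,
    year: int,
) -> pd.DataFrame:
    """Forest and alpine herbivore biomass surfaces for one census year.

    Forest species (moose, red deer, roe deer, cattle) sum into the forest
    slice, alpine species (wild and semi-domestic reindeer, sheep, goats)
    into the alpine slice; species assigned to neither (horses) are
    excluded from both.  Densities are expressed against the
    ecosystem-specific area (forest cells / open cells), so a unit with no
    open cells reports an alpine density of NaN while its absolute biomass
    is still conserved.
    """
    _check_species(livestock, profiles)
    _check_species(wild_densities, profiles)
    live = livestock[livestock["year"] == year]
    wild = wild_densities[wild_densities["year"] == year]

    rows = []
    for _, unit in layout.units.iterrows():
        uid = unit["unit_id"]
        rangeland = float(unit["rangeland_area_km2"])
        for eco in ("forest", "alpine"):
            eco_area = layout.ecosystem_area(uid, eco)
            kg = 0.0
            for _, rec in live[live["municipality_id"] == uid].iterrows():
                prof = profiles[rec["species"]]
                if prof.ecosystem == eco:
                    kg += seasonal_standardise(rec["headcount"], prof)
            for _, rec in wild[wild["municipality_id"] == uid].iterrows():
                prof = profiles[rec["species"]]
                if prof.ecosystem == eco:
                    # wild input is a density over rangeland; recover kg first
                    kg += rec["density_kg_km2"] * rangeland
            rows.append(
                {
                    "trophic_level": "herbivore",
                    "slice": eco,
                    "unit_id": uid,
                    "year": year,
                    "density_kg_km2": kg / eco_area if eco_area > 0 else float("nan"),
                    "biomass_kg": kg,
                }
            )
    return pd.DataFrame(rows, columns=SURFACE_COLUMNS)
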