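"""Synthetic study system with known ground truth.

The real analysis rests on national archives (harvest records, agricultural
censuses) and satellite productivity that cannot ship with a package.  This
module forward-simulates a complete stand-in: a gridded geography with
nested municipalities and counties, annual NPP fields, livestock and
wild-herbivore censuses, and carnivore populations governed by the same
growth-harvest recurrence the backcaster inverts.  Every generated quantity
is recorded as ground truth, so each downstream stage can be validated
exactly.

Randomness: one root :class:`numpy.random.SeedSequence` is spawned into four
child streams, in fixed order (land cover, NPP noise, carnivore harvests,
herbivore censuses).  A fixed seed therefore reproduces every artefact
byte-for-byte regardless of which subset of generators is invoked.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .admin import AdminLayout, county_id, municipality_id
from .config import (
    DEFAULT_PROFILES,
    FOREST,
    LAND_COVER_CLASSES,
    OPEN,
    CarnivoreParams,
    SpeciesProfile,
    SyntheticConfig,
)
from .npp import NPPRaster, write_raster_csv

__all__ = [
    "GroundTruth",
    "generate_admin_layout",
    "generate_npp_series",
    "simulate_carnivore_history",
    "simulate_herbivore_census",
    "generate_world",
]

# fixed spawn order of the child RNG streams
_STREAMS = ("land_cover", "npp", "carnivores", "herbivores")


def _rng(seed: int, stream: str) -> np.random.Generator:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS.index(stream)])


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover.

    true_population:
        species, unit_id (county), year, abundance — the simulated carnivore
        trajectories.
    true_herbivore_density:
        unit_id, year, slice (livestock/wild/total), density_kg_km2,
        biomass_kg — computed from the emitted censuses with the same
        species profiles the assembly stage uses.
    true_carnivore_density:
        species, unit_id (county), year, density_kg_km2.
    true_npp:
        unit_id, year, mean_npp over rangeland cells.
    true_params:
        the generating CarnivoreParams plus per-species anchors.
    """

    true_population: pd.DataFrame
    true_herbivore_density: pd.DataFrame
    true_carnivore_density: pd.DataFrame
    true_npp: pd.DataFrame
    true_params: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "true_params": self.true_params,
            "true_population": self.true_population.to_dict(orient="list"),
            "true_herbivore_density": self.true_herbivore_density.to_dict(
                orient="list"
            ),
            "true_carnivore_density": self.true_carnivore_density.to_dict(
                orient="list"
            ),
            "true_npp": self.true_npp.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


# ---------------------------------------------------------------------------
# geography


def generate_admin_layout(config: SyntheticConfig) -> AdminLayout:
    """Partition the grid into municipalities nested in counties.

    Assignment rule (documented so tests can enumerate it): cells are
    numbered row-major; ``numpy.array_split`` divides the cell sequence into
    ``n_counties`` contiguous runs, and each county run is again split into
    ``municipalities_per_county`` contiguous runs.  Land cover is drawn
    i.i.d. per cell from ``land_cover_fractions`` using the land-cover RNG
    stream, so fractions (1, 0, 0) give an all-forest map deterministically.
    """
    rows, cols = config.grid_shape
    n_cells = rows * cols
    n_units = config.n_counties * config.municipalities_per_county
    if n_cells < n_units:
        raise ValueError(
            f"cannot partition {n_cells} cells into {n_units} municipalities"
        )

    mun_index = np.empty(n_cells, dtype=int)
    cty_index = np.empty(n_cells, dtype=int)
    cell_ids = np.arange(n_cells)
    ordinal = 0
    unit_rows = []
    for ci, county_cells in enumerate(np.array_split(cell_ids, config.n_counties)):
        for mi, mun_cells in enumerate(
            np.array_split(county_cells, config.municipalities_per_county)
        ):
            mun_index[mun_cells] = ordinal
            cty_index[mun_cells] = ci
            unit_rows.append(
                {"unit_id": municipality_id(ci, mi), "county_id": county_id(ci)}
            )
            ordinal += 1

    rng = _rng(config.seed, "land_cover")
    land_cover = rng.choice(
        len(LAND_COVER_CLASSES), size=n_cells, p=config.land_cover_fractions
    )

    mun_index = mun_index.reshape(rows, cols)
    cty_index = cty_index.reshape(rows, cols)
    land_cover = land_cover.reshape(rows, cols)

    forest_code = LAND_COVER_CLASSES.index(FOREST)
    open_code = LAND_COVER_CLASSES.index(OPEN)
    units = pd.DataFrame(unit_rows)
    units["n_cells"] = [int((mun_index == i).sum()) for i in range(n_units)]
    units["forest_cells"] = [
        int(((mun_index == i) & (land_cover == forest_code)).sum())
        for i in range(n_units)
    ]
    units["open_cells"] = [
        int(((mun_index == i) & (land_cover == open_code)).sum())
        for i in range(n_units)
    ]
    units["rangeland_area_km2"] = (
        units["forest_cells"] + units["open_cells"]
    ) * config.cell_area

    return AdminLayout(
        grid_shape=(rows, cols),
        cell_area=config.cell_area,
        municipality_index=mun_index,
        county_index=cty_index,
        land_cover=land_cover,
        units=units,
    )


# ---------------------------------------------------------------------------
# productivity


def generate_npp_series(
    layout: AdminLayout, config: SyntheticConfig
) -> list[NPPRaster]:
    """One NPP raster per configured year, in kg C km^-2 yr^-1.

    Cell value = base x class multiplier x (1 + gradient x column) x
    lognormal(0, sd) noise.  Forest and open cells take their configured
    multipliers; ``other`` cells take 1.  Deterministic mode (or sd = 0)
    drops the noise term.
    """
    p = config.npp_params
    rows, cols = layout.grid_shape
    mult = np.ones(layout.grid_shape)
    mult[layout.land_cover == LAND_COVER_CLASSES.index(FOREST)] = p.forest_multiplier
    mult[layout.land_cover == LAND_COVER_CLASSES.index(OPEN)] = p.open_multiplier
    gradient = 1.0 + p.gradient * np.arange(cols)[None, :]
    deterministic_part = p.base * mult * gradient

    rng = _rng(config.seed, "npp")
    y0, y1 = config.years
    rasters = []
    for year in range(y0, y1 + 1):
        if config.deterministic or p.noise_sd == 0:
            values = deterministic_part.copy()
        else:
            noise = rng.lognormal(mean=0.0, sigma=p.noise_sd, size=(rows, cols))
            values = deterministic_part * noise
        rasters.append(
            NPPRaster(year=year, values=values, cell_area=layout.cell_area)
        )
    return rasters


# ---------------------------------------------------------------------------
# carnivores (forward model — the twin the backcaster inverts)


def simulate_carnivore_history(
    params: CarnivoreParams,
    layout: AdminLayout,
    seed: int,
    years: tuple[int, int],
    deterministic: bool = True,
    round_harvest: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Forward growth-then-harvest simulation per county.

    For each year t (growth first, harvest after):

        G_t = lambda * N_{t-1}
        H_t = round(h * G_t)            (deterministic mode)
              Binomial(round(G_t), h)   (stochastic mode)

    ``round_harvest=False`` keeps deterministic harvests real-valued, which
    makes the backcast inverse exact to floating-point precision.
        N_t = G_t - H_t

    Returns ``(truth, harvest)``: truth rows are (species, unit_id, year,
    abundance) with a leading row at the year before the span carrying the
    initial abundance; harvest rows are (species, county_id, year, kills).
    The abundance at ``params.anchor_year`` (default: final year) is the
    anchor later handed to the backcaster.
    """
    if not params.lam > 0:
        raise ValueError("lambda must be > 0")
    if not 0.0 <= params.harvest_rate < 1.0:
        raise ValueError("harvest rate must lie in [0, 1)")
    if params.initial_abundance < 0:
        raise ValueError("initial abundance must be >= 0")

    rng = np.random.default_rng(seed)
    y0, y1 = years
    truth_rows, harvest_rows = [], []
    for cid in layout.county_ids:
        n = float(params.initial_abundance)
        truth_rows.append(
            {"species": params.species, "unit_id": cid, "year": y0 - 1, "abundance": n}
        )
        for year in range(y0, y1 + 1):
            g = params.lam * n
            if deterministic:
                h = params.harvest_rate * g
                if round_harvest:
                    h = float(np.round(h))
            else:
                h = float(rng.binomial(int(np.round(g)), params.harvest_rate))
            h = min(h, g)  # harvest can never exceed the post-growth population
            n = g - h
            truth_rows.append(
                {
                    "species": params.species,
                    "unit_id": cid,
                    "year": year,
                    "abundance": n,
                }
            )
            harvest_rows.append(
                {
                    "species": params.species,
                    "county_id": cid,
                    "year": year,
                    "kills": int(h) if round_harvest else h,
                }
            )
    return pd.DataFrame(truth_rows), pd.DataFrame(harvest_rows)


# ---------------------------------------------------------------------------
# herbivores


def simulate_herbivore_census(
    config: SyntheticConfig,
    layout: AdminLayout,
    seed: int,
    profiles: dict[str, SpeciesProfile] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Livestock headcounts and wild densities at the census years.

    Headcounts are exact configured means in deterministic mode, Poisson
    draws otherwise.  Wild herbivore densities are the configured constant
    trajectories (they stand in for the cohort-model outputs that are
    pipeline inputs, not pipeline products).  Returns ``(livestock, wild,
    truth)`` where truth holds per-unit ground-truth biomass densities
    computed with the same species profiles the assembly stage uses.
    """
    profiles = profiles or DEFAULT_PROFILES
    unknown = [
        s
        for s in list(config.livestock_means) + list(config.wild_density_means)
        if s not in profiles
    ]
    if unknown:
        raise KeyError(f"species without profiles: {unknown}")

    rng = np.random.default_rng(seed)
    livestock_rows, wild_rows, truth_rows = [], [], []
    for _, unit in layout.units.iterrows():
        uid = unit["unit_id"]
        area = float(unit["rangeland_area_km2"])
        for year in config.census_years:
            live_kg = 0.0
            for species, mean in config.livestock_means.items():
                if config.deterministic:
                    count = int(round(mean))
                else:
                    count = int(rng.poisson(mean))
                livestock_rows.append(
                    {
                        "species": species,
                        "municipality_id": uid,
                        "year": year,
                        "headcount": count,
                    }
                )
                prof = profiles[species]
                live_kg += count * prof.mean_body_mass * prof.rangeland_fraction
            wild_density = 0.0
            for species, dens in config.wild_density_means.items():
                wild_rows.append(
                    {
                        "species": species,
                        "municipality_id": uid,
                        "year": year,
                        "density_kg_km2": float(dens),
                    }
                )
                wild_density += float(dens)
            live_density = live_kg / area if area > 0 else float("nan")
            truth_rows.append(
                {
                    "unit_id": uid,
                    "year": year,
                    "livestock_density": live_density,
                    "wild_density": wild_density,
                    "total_density": live_density + wild_density,
                    "livestock_biomass_kg": live_kg,
                    "wild_biomass_kg": wild_density * area,
                }
            )
    return (
        pd.DataFrame(livestock_rows),
        pd.DataFrame(wild_rows),
        pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# whole-world convenience


def generate_world(
    config: SyntheticConfig,
    out_dir: str | Path | None = None,
    profiles: dict[str, SpeciesProfile] | None = None,
):
    """Generate every synthetic input and the ground truth.

    Returns a dict with layout, rasters, livestock/wild/harvest tables and
    the :class:`GroundTruth`.  When ``out_dir`` is given, all artefacts are
    written there as the plain-text formats the pipeline reads (CSV tables,
    per-year raster CSVs, GeoJSON geometry, ground-truth JSON).
    """
    profiles = profiles or DEFAULT_PROFILES
    layout = generate_admin_layout(config)
    rasters = generate_npp_series(layout, config)

    carn_seed_root = np.random.SeedSequence(config.seed).spawn(len(_STREAMS))[
        _STREAMS.index("carnivores")
    ]
    carn_seeds = [s.generate_state(1)[0] % 2**31 for s in carn_seed_root.spawn(
        len(config.carnivore_params)
    )]
    truth_pop, harvests, carn_density = [], [], []
    anchors: dict[str, dict[str, float]] = {}
    for params, cseed in zip(config.carnivore_params, carn_seeds):
        truth, harvest = simulate_carnivore_history(
            params,
            layout,
            seed=int(cseed),
            years=config.years,
            deterministic=config.deterministic,
        )
        truth_pop.append(truth)
        harvests.append(harvest)
        anchor_year = params.anchor_year or config.years[1]
        anchors[params.species] = {
            cid: float(
                truth.loc[
                    (truth["unit_id"] == cid) & (truth["year"] == anchor_year),
                    "abundance",
                ].iloc[0]
            )
            for cid in layout.county_ids
        }
        mass = profiles[params.species].mean_body_mass
        dens = truth[truth["year"] >= config.years[0]].copy()
        dens["density_kg_km2"] = [
            row["abundance"] * mass / layout.county_rangeland_area(row["unit_id"])
            for _, row in dens.iterrows()
        ]
        carn_density.append(
            dens[["species", "unit_id", "year", "density_kg_km2"]]
        )
    truth_pop = pd.concat(truth_pop, ignore_index=True)
    harvests = pd.concat(harvests, ignore_index=True)
    carn_density = pd.concat(carn_density, ignore_index=True)

    herb_seed = np.random.SeedSequence(config.seed).spawn(len(_STREAMS))[
        _STREAMS.index("herbivores")
    ].generate_state(1)[0] % 2**31
    livestock, wild, herb_truth = simulate_herbivore_census(
        config, layout, seed=int(herb_seed), profiles=profiles
    )

    rangeland = layout.ecosystem_mask("all")
    true_npp = pd.DataFrame(
        [
            {
                "unit_id": uid,
                "year": r.year,
                "mean_npp": float(
                    r.values[rangeland & (layout.municipality_index == i)].mean()
                ),
            }
            for r in rasters
            for i, uid in enumerate(layout.municipality_ids)
            if (rangeland & (layout.municipality_index == i)).any()
        ]
    )

    truth = GroundTruth(
        true_population=truth_pop,
        true_herbivore_density=herb_truth,
        true_carnivore_density=carn_density,
        true_npp=true_npp,
        true_params={
            "carnivores": {
                p.species: {
                    "lambda": p.lam,
                    "harvest_rate": p.harvest_rate,
                    "initial_abundance": p.initial_abundance,
                    "anchor_year": p.anchor_year or config.years[1],
                }
                for p in config.carnivore_params
            },
            "anchors": anchors,
            "seed": config.seed,
        },
    )

    world = {
        "layout": layout,
        "rasters": rasters,
        "livestock": livestock,
        "wild": wild,
        "harvest": harvests,
        "truth": truth,
        "anchors": anchors,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        layout.to_geojson(out / "units.geojson")
        np.savetxt(out / "land_cover.csv", layout.land_cover, fmt="%d", delimiter=",")
        raster_dir = out / "npp"
        raster_dir.mkdir(exist_ok=True)
        for r in rasters:
            write_raster_csv(r, raster_dir / f"npp_{r.year}.csv")
        livestock.to_csv(out / "livestock.csv", index=False)
        wild.to_csv(out / "wild_density.csv", index=False)
        harvests.to_csv(out / "harvest.csv", index=False)
        truth.to_json(out / "ground_truth.json")
        with open(out / "anchors.json", "w") as fh:
            json.dump(anchors, fh, indent=1)

    return world
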