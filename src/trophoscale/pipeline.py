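"""End-to-end orchestration: simulate -> NPP -> herbivores -> backcast -> deviations.

The pipeline runs the whole workflow from one config and seed, writes every
intermediate artefact as plain-text CSV/GeoJSON/JSON, and emits a run
manifest (config hash, seed, per-stage row counts, warnings) so two runs
with the same config are byte-identical and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import backcast as bc
from . import herbivores as hb
from . import npp as npp_mod
from . import scaling
from .admin import AdminLayout
from .config import DEFAULT_PROFILES, SpeciesProfile, SyntheticConfig
from .synthetic import generate_world

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "national_trend_report"]


@dataclass(frozen=True)
class PipelineConfig:
    """Declarative description of one full run.

    The synthetic config doubles as the input source; deviation years must
    be census years, and the ecosystem modes select which deviation
    surfaces are produced.
    """

    out_dir: str
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    deviation_years: tuple[int, ...] | None = None  # default: all census years
    ecosystems: tuple[str, ...] = ("all", "forest", "alpine")
    tolerance_band: float = 0.1

    def resolved_deviation_years(self) -> tuple[int, ...]:
        years = self.deviation_years or self.synthetic.census_years
        bad = [y for y in years if y not in self.synthetic.census_years]
        if bad:
            raise ValueError(f"deviation years {bad} are not census years")
        return tuple(years)

    def config_hash(self) -> str:
        # hash the scientific configuration only; the output location must
        # not change the manifest identity
        payload = asdict(self)
        payload.pop("out_dir", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    row_counts: dict[str, int]
    warnings: list[str]
    scaling_models: dict[str, dict]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


def _write_csv(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, index=False, float_format="%.10g")
    return len(df)


def run_pipeline(
    config: PipelineConfig,
    profiles: dict[str, SpeciesProfile] | None = None,
) -> RunManifest:
    """Execute all stages and write artefacts under ``config.out_dir``.

    Layout: ``inputs/`` holds the simulated archives (the stand-ins for
    harvest records, censuses and rasters), top level holds the derived
    products (zonal NPP, biomass surfaces, backcasts, deviations, trend
    report, manifest).
    """
    profiles = profiles or DEFAULT_PROFILES
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    syn = config.synthetic
    warnings: list[str] = []
    counts: dict[str, int] = {}

    # stage 1: simulate ------------------------------------------------
    world = generate_world(syn, out / "inputs", profiles=profiles)
    layout: AdminLayout = world["layout"]
    rasters = world["rasters"]
    counts["harvest"] = len(world["harvest"])
    counts["livestock"] = len(world["livestock"])
    counts["wild"] = len(world["wild"])

    # stage 2: NPP aggregation ----------------------------------------
    zonal = pd.concat(
        [
            npp_mod.zonal_mean_npp(r, layout, ecosystem=eco)
            for r in rasters
            for eco in config.ecosystems
        ],
        ignore_index=True,
    )
    year_range = (rasters[0].year, rasters[-1].year)
    zonal_means = pd.concat(
        [
            npp_mod.multi_year_mean_npp(rasters, layout, year_range, ecosystem=eco)
            for eco in config.ecosystems
        ],
        ignore_index=True,
    )
    zonal_all = pd.concat([zonal, zonal_means], ignore_index=True)
    counts["zonal_npp"] = _write_csv(zonal_all, out / "zonal_npp.csv")
    n_empty = int((zonal_all["n_cells"] == 0).sum())
    if n_empty:
        warnings.append(f"{n_empty} unit/ecosystem zonal means had no eligible cells")

    # stage 3: herbivore assembly -------------------------------------
    herb_parts = []
    for year in syn.census_years:
        herb_parts.append(
            hb.assemble_herbivore_density(
                world["livestock"], world["wild"], profiles, layout, year
            )
        )
        herb_parts.append(
            hb.ecosystem_partition(
                world["livestock"], world["wild"], profiles, layout, year
            )
        )
    herb_surface = pd.concat(herb_parts, ignore_index=True)
    counts["herbivore_surface"] = _write_csv(
        herb_surface, out / "herbivore_biomass.csv"
    )

    # stage 4: carnivore backcast -------------------------------------
    carn_parts = []
    n_floored = 0
    true_params = world["truth"].true_params["carnivores"]
    for species, sp_params in true_params.items():
        mass = profiles[species].mean_body_mass
        for cid in layout.county_ids:
            harvest = world["harvest"]
            series = harvest[
                (harvest["species"] == species) & (harvest["county_id"] == cid)
            ]
            params = bc.CarnivoreModelParams(
                species=species,
                lam=sp_params["lambda"],
                anchor_year=sp_params["anchor_year"],
                anchor_abundance=world["anchors"][species][cid],
                mean_body_mass=mass,
            )
            result = bc.backcast_population(series, params)
            n_floored += int(result["feasibility_flag"].sum())
            carn_parts.append(
                bc.carnivore_biomass_density(result, params, layout, cid)
            )
    carn_surface = pd.concat(carn_parts, ignore_index=True)
    counts["carnivore_surface"] = _write_csv(
        carn_surface, out / "carnivore_biomass.csv"
    )
    if n_floored:
        warnings.append(f"feasibility floor raised {n_floored} reconstructed years")

    # stage 5: deviations ---------------------------------------------
    dev_years = config.resolved_deviation_years()
    dev_parts = []
    for eco in config.ecosystems:
        dev_parts.append(
            scaling.deviation_surfaces(
                herb_surface,
                carn_surface,
                zonal_all[zonal_all["ecosystem"] == eco],
                layout,
                profiles,
                dev_years,
                ecosystem=eco,
                tolerance_band=config.tolerance_band,
            )
        )
    deviations = pd.concat(dev_parts, ignore_index=True)
    counts["deviations"] = _write_csv(deviations, out / "deviations.csv")

    # choropleth join for the latest deviation year, herbivore level
    latest = max(dev_years)
    attrs = deviations[
        (deviations["year"] == latest)
        & (deviations["level"] == "herbivore")
        & (deviations["ecosystem"] == "all")
    ][["unit_id", "observed", "expected", "deviation", "sign_class"]]
    fc = layout.join_geojson(attrs)
    with open(out / "deviations.geojson", "w") as fh:
        json.dump(fc, fh)

    # stage 6: trend report -------------------------------------------
    report = national_trend_report(
        herb_surface,
        carn_surface,
        rasters,
        layout,
        world["livestock"],
        world["wild"],
        profiles,
        syn.census_years,
    )
    counts["trend_report"] = _write_csv(report, out / "national_trends.csv")

    registry = scaling.default_registry()
    manifest = RunManifest(
        config_hash=config.config_hash(),
        seed=syn.seed,
        row_counts=counts,
        warnings=warnings,
        scaling_models={
            name: {"coefficient": m.coefficient, "exponent": m.exponent}
            for name, m in registry.items()
        },
    )
    for name, m in registry.items():
        logger.info(
            "scaling model %s: coefficient=%g exponent=%g",
            name, m.coefficient, m.exponent,
        )
    manifest.to_json(out / "manifest.json")
    return manifest


def national_trend_report(
    herb_surface: pd.DataFrame,
    carn_surface: pd.DataFrame,
    rasters,
    layout: AdminLayout,
    livestock: pd.DataFrame,
    wild: pd.DataFrame,
    profiles: dict[str, SpeciesProfile],
    census_years,
) -> pd.DataFrame:
    """National biomass trends per census year.

    Columns: year; rangeland-masked national mean NPP; herbivore
    total/livestock/wild densities; livestock share of herbivore biomass;
    carnivore total density; per-species biomass shares within the
    livestock, wild-herbivore and carnivore guilds (``share_<species>``,
    summing to 1 within each guild wherever the guild biomass is nonzero).
    """
    npp_by_year = {
        r.year: npp_mod.national_mean_npp(r, layout, masked=True) for r in rasters
    }
    herb_nat = hb.national_summary(herb_surface, layout)
    carn_nat = bc.national_carnivore_series(carn_surface, layout)

    rows = []
    for year in census_years:
        row: dict = {"year": year, "national_npp": npp_by_year.get(year, float("nan"))}
        for slc in ("total", "livestock", "wild"):
            sel = herb_nat[(herb_nat["year"] == year) & (herb_nat["slice"] == slc)]
            row[f"herbivore_{slc}_density"] = (
                float(sel["density_kg_km2"].iloc[0]) if len(sel) else float("nan")
            )
        total = row["herbivore_total_density"]
        row["livestock_share"] = (
            row["herbivore_livestock_density"] / total if total > 0 else float("nan")
        )
        sel = carn_nat[(carn_nat["year"] == year) & (carn_nat["slice"] == "total")]
        row["carnivore_total_density"] = (
            float(sel["density_kg_km2"].iloc[0]) if len(sel) else float("nan")
        )

        # species shares within guilds
        live_y = livestock[livestock["year"] == year]
        live_kg = {
            sp: float(
                (grp["headcount"] * profiles[sp].mean_body_mass
                 * profiles[sp].rangeland_fraction).sum()
            )
            for sp, grp in live_y.groupby("species")
        }
        live_total = sum(live_kg.values())
        areas = dict(zip(layout.units["unit_id"], layout.units["rangeland_area_km2"]))
        wild_y = wild[wild["year"] == year]
        wild_kg = {
            sp: float(
                sum(
                    rec["density_kg_km2"] * areas[rec["municipality_id"]]
                    for _, rec in grp.iterrows()
                )
            )
            for sp, grp in wild_y.groupby("species")
        }
        wild_total = sum(wild_kg.values())
        carn_y = carn_surface[
            (carn_surface["year"] == year) & (carn_surface["slice"] != "total")
        ]
        carn_kg = carn_y.groupby("slice")["biomass_kg"].sum().to_dict()
        carn_total = sum(carn_kg.values())
        for sp, kg in live_kg.items():
            row[f"share_{sp}"] = kg / live_total if live_total > 0 else float("nan")
        for sp, kg in wild_kg.items():
            row[f"share_{sp}"] = kg / wild_total if wild_total > 0 else float("nan")
        for sp, kg in carn_kg.items():
            row[f"share_{sp}"] = kg / carn_total if carn_total > 0 else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
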