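"""Trophic scaling laws and observed-vs-expected deviation surfaces.

Expected consumer biomass follows published power laws between adjacent
trophic levels:

    expected herbivore biomass  = 0.643 x NPP^0.47        (from productivity)
    expected carnivore biomass  = 0.094 x HB^0.73         (from herbivores)

with two derived forms: the carnivore expectation applied to wild herbivore
biomass only, and the composition of both laws giving carnivores straight
from NPP.  Inputs and outputs are densities in kg km^-2 (NPP in
kg C km^-2 yr^-1).

Deviations are scored as log10(observed / expected), classified
below / in-line / above against a configurable tolerance band (default
+/- 0.1, i.e. within ~26% of expectation either way).  The absolute
difference observed - expected is carried along for completeness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .admin import AdminLayout
from .config import SpeciesProfile

__all__ = [
    "ScalingModel",
    "HERBIVORE_FROM_NPP",
    "CARNIVORE_FROM_HERBIVORE",
    "default_registry",
    "expected_herbivore_biomass",
    "expected_carnivore_biomass",
    "expected_carnivore_from_wild",
    "expected_carnivore_from_npp",
    "deviation",
    "deviation_surfaces",
]


@dataclass(frozen=True)
class ScalingModel:
    """A power-law trophic expectation: expected = coefficient x input^exponent.

    Strictly increasing on [0, inf); concave whenever exponent < 1.  The
    registry mechanism lets alternative coefficients (e.g. the wolf-prey
    exponent 0.72) be swapped in without touching the pipeline.
    """

    name: str
    coefficient: float
    exponent: float
    input_level: str
    output_level: str

    def __post_init__(self) -> None:
        if not self.coefficient > 0:
            raise ValueError("coefficient must be > 0")
        if not 0 < self.exponent <= 1:
            raise ValueError("exponent must lie in (0, 1]")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        if (x < 0).any():
            raise ValueError(f"{self.input_level} input must be >= 0")
        out = self.coefficient * np.power(x, self.exponent)
        return float(out) if out.ndim == 0 else out


HERBIVORE_FROM_NPP = ScalingModel(
    "herbivore_from_npp", 0.643, 0.47, "npp", "herbivore"
)
CARNIVORE_FROM_HERBIVORE = ScalingModel(
    "carnivore_from_herbivore", 0.094, 0.73, "herbivore", "carnivore"
)


def default_registry() -> dict[str, ScalingModel]:
    return {
        "herbivore_from_npp": HERBIVORE_FROM_NPP,
        "carnivore_from_herbivore": CARNIVORE_FROM_HERBIVORE,
    }


def expected_herbivore_biomass(npp, model: ScalingModel = HERBIVORE_FROM_NPP):
    """Expected herbivore biomass (kg km^-2) from NPP (kg C km^-2 yr^-1)."""
    return model(npp)


def expected_carnivore_biomass(hb, model: ScalingModel = CARNIVORE_FROM_HERBIVORE):
    """Expected carnivore biomass (kg km^-2) from observed herbivore biomass."""
    return model(hb)


def expected_carnivore_from_wild(whb, model: ScalingModel = CARNIVORE_FROM_HERBIVORE):
    """Expected carnivore biomass from wild (non-livestock) herbivores only."""
    return model(whb)


def expected_carnivore_from_npp(
    npp,
    herbivore_model: ScalingModel = HERBIVORE_FROM_NPP,
    carnivore_model: ScalingModel = CARNIVORE_FROM_HERBIVORE,
):
    """Expected carnivore biomass straight from NPP.

    Exact composition of the two laws:
    0.094 x (0.643 x NPP^0.47)^0.73.
    """
    return carnivore_model(herbivore_model(npp))


def deviation(observed: float, expected: float, tolerance_band: float = 0.1) -> dict:
    """Score one observed-vs-expected pair.

    Returns a dict with ``deviation`` = log10(observed/expected),
    ``difference`` = observed - expected, ``sign_class`` in
    {below, in-line, above, missing} and ``zero_observed``.  observed = 0
    yields -inf with the flag set; expected <= 0 makes the record missing.
    """
    if observed < 0:
        raise ValueError("observed must be >= 0")
    if not expected > 0 or not math.isfinite(expected):
        return {
            "deviation": float("nan"),
            "difference": float("nan"),
            "sign_class": "missing",
            "zero_observed": observed == 0,
        }
    if observed == 0:
        return {
            "deviation": float("-inf"),
            "difference": -expected,
            "sign_class": "below",
            "zero_observed": True,
        }
    dev = math.log10(observed / expected)
    if abs(dev) <= tolerance_band:
        cls = "in-line"
    else:
        cls = "above" if dev > 0 else "below"
    return {
        "deviation": dev,
        "difference": observed - expected,
        "sign_class": cls,
        "zero_observed": False,
    }


# ---------------------------------------------------------------------------
# surface-level scoring


def _npp_lookup(zonal_npp: pd.DataFrame):
    """Split zonal NPP rows into annual {year: {unit: mean}} and range means."""
    annual: dict[int, dict[str, float]] = {}
    ranged: dict[str, float] = {}
    for _, rec in zonal_npp.iterrows():
        year = rec["year"]
        if isinstance(year, str) and "-" in year:
            ranged[rec["unit_id"]] = rec["mean_npp"]
        else:
            annual.setdefault(int(year), {})[rec["unit_id"]] = rec["mean_npp"]
    return annual, ranged


# the observed herbivore year whose expectation is evaluated on a different
# NPP year (the productivity record starts in 2000)
NPP_YEAR_PAIRING = {1999: 2000}


def _match_npp(
    unit: str, year: int, annual: dict, ranged: dict
) -> float:
    target = NPP_YEAR_PAIRING.get(year, year)
    if target in annual and unit in annual[target]:
        return annual[target][unit]
    if unit in ranged:
        return ranged[unit]
    return float("nan")


def deviation_surfaces(
    herbivore_surface: pd.DataFrame,
    carnivore_surface: pd.DataFrame,
    zonal_npp: pd.DataFrame,
    layout: AdminLayout,
    profiles: dict[str, SpeciesProfile],
    years,
    ecosystem: str = "all",
    tolerance_band: float = 0.1,
    registry: dict[str, ScalingModel] | None = None,
) -> pd.DataFrame:
    """Score observed-vs-expected biomass per unit, level and basis.

    Herbivores are assessed per municipality against the NPP law on
    year-matched zonal NPP (an observation year absent from the NPP record
    falls back to the supplied multi-year mean row; the 1999 census is
    paired with year-2000 NPP).  Carnivores are assessed per county: the
    herbivore-basis expectation aggregates municipal absolute biomass to the
    county *before* the power law is applied (the law is nonlinear, so
    aggregation must precede it), the wild basis uses the wild slice only
    (all-species runs), and the NPP basis composes both laws on county-level
    NPP.  Ecosystem runs use the partitioned slices, ecosystem-assigned
    carnivore species and class-filtered NPP.
    """
    registry = registry or default_registry()
    herb_model = registry["herbivore_from_npp"]
    carn_model = registry["carnivore_from_herbivore"]

    herb_slice = "total" if ecosystem == "all" else ecosystem
    annual_npp, ranged_npp = _npp_lookup(zonal_npp)
    unit_to_county = dict(zip(layout.units["unit_id"], layout.units["county_id"]))

    missing_units = set(herbivore_surface["unit_id"]) - set(unit_to_county)
    if missing_units:
        raise KeyError(f"surface units not in layout: {sorted(missing_units)}")

    carn_species = [
        s
        for s, p in profiles.items()
        if p.guild == "carnivore" and (ecosystem == "all" or p.ecosystem == ecosystem)
    ]

    records = []

    def add(unit, year, level, basis, observed, expected):
        rec = deviation(observed, expected, tolerance_band)
        records.append(
            {
                "unit_id": unit,
                "year": year,
                "level": level,
                "ecosystem": ecosystem,
                "basis": basis,
                "observed": observed,
                "expected": expected,
                **rec,
            }
        )

    for year in years:
        herb = herbivore_surface[
            (herbivore_surface["year"] == year)
            & (herbivore_surface["slice"] == herb_slice)
        ]
        # herbivore level, per municipality, NPP basis
        for _, rec in herb.iterrows():
            npp = _match_npp(rec["unit_id"], year, annual_npp, ranged_npp)
            expected = herb_model(npp) if math.isfinite(npp) else float("nan")
            add(rec["unit_id"], year, "herbivore", "npp", rec["density_kg_km2"],
                expected)

        # carnivore level, per county
        county_tab = layout.county_table().set_index("county_id")
        herb_by_county = (
            herb.assign(county_id=herb["unit_id"].map(unit_to_county))
            .groupby("county_id")["biomass_kg"]
            .sum()
        )
        wild = herbivore_surface[
            (herbivore_surface["year"] == year)
            & (herbivore_surface["slice"] == "wild")
        ]
        wild_by_county = (
            wild.assign(county_id=wild["unit_id"].map(unit_to_county))
            .groupby("county_id")["biomass_kg"]
            .sum()
        )
        carn = carnivore_surface[
            (carnivore_surface["year"] == year)
            & (carnivore_surface["slice"].isin(carn_species))
        ]
        carn_by_county = carn.groupby("unit_id")["biomass_kg"].sum()

        for cid in layout.county_ids:
            if ecosystem == "all":
                area = float(county_tab.loc[cid, "forest_cells"]
                             + county_tab.loc[cid, "open_cells"]) * layout.cell_area
            elif ecosystem == "forest":
                area = float(county_tab.loc[cid, "forest_cells"]) * layout.cell_area
            else:
                area = float(county_tab.loc[cid, "open_cells"]) * layout.cell_area
            if area <= 0:
                continue
            observed_carn = float(carn_by_county.get(cid, 0.0)) / area

            hb = float(herb_by_county.get(cid, 0.0)) / area
            add(cid, year, "carnivore", "observed_herbivore", observed_carn,
                carn_model(hb))

            if ecosystem == "all":
                whb = float(wild_by_county.get(cid, 0.0)) / area
                add(cid, year, "carnivore", "wild_herbivore", observed_carn,
                    carn_model(whb))

            mun_ids = layout.units.loc[
                layout.units["county_id"] == cid, "unit_id"
            ]
            vals = [
                _match_npp(u, year, annual_npp, ranged_npp) for u in mun_ids
            ]
            vals = [v for v in vals if math.isfinite(v)]
            if vals:
                npp_c = float(np.mean(vals))
                add(cid, year, "carnivore", "expected_herbivore", observed_carn,
                    carn_model(herb_model(npp_c)))

    return pd.DataFrame(records)
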