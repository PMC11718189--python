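"""Herbivore biomass assembly: standardisation, guild split, ecosystem partition."""

import numpy as np
import pandas as pd
import pytest

from trophoscale.config import DEFAULT_PROFILES, SpeciesProfile
from trophoscale.herbivores import (
    assemble_herbivore_density,
    ecosystem_partition,
    guild_share,
    national_summary,
    seasonal_standardise,
)
from trophoscale.synthetic import simulate_herbivore_census
from helpers import one_unit_layout

SHEEP = DEFAULT_PROFILES["sheep"]


class TestSeasonalStandardise:
    def test_three_months_is_quarter_of_full_year_biomass(self):
        # 1000 head x 45 kg x 0.25 = 11250 kg
        assert seasonal_standardise(1000, SHEEP) == pytest.approx(11_250.0)
        full_year = SpeciesProfile("sheep", "herbivore", "livestock", 45.0, 1.0)
        assert seasonal_standardise(1000, full_year) == pytest.approx(45_000.0)
        assert seasonal_standardise(1000, SHEEP) == pytest.approx(
            0.25 * seasonal_standardise(1000, full_year)
        )

    def test_zero_headcount(self):
        assert seasonal_standardise(0, SHEEP) == 0.0

    def test_negative_headcount_rejected(self):
        with pytest.raises(ValueError):
            seasonal_standardise(-1, SHEEP)

    def test_fraction_outside_unit_interval_rejected_at_profile(self):
        with pytest.raises(ValueError):
            SpeciesProfile("x", "herbivore", "livestock", 45.0, 1.5)


class TestAssembly:
    def test_single_species_density_from_stated_area(self, small_layout):
        livestock = pd.DataFrame(
            [{"species": "sheep", "municipality_id": "m0000", "year": 2009,
              "headcount": 1000}]
        )
        wild = pd.DataFrame(columns=["species", "municipality_id", "year",
                                     "density_kg_km2"])
        surface = assemble_herbivore_density(
            livestock, wild, DEFAULT_PROFILES, small_layout, 2009
        )
        area = small_layout.rangeland_area("m0000")
        row = surface[(surface["unit_id"] == "m0000") & (surface["slice"] == "livestock")]
        assert row["density_kg_km2"].iloc[0] == pytest.approx(11_250.0 / area)
        total = surface[(surface["unit_id"] == "m0000") & (surface["slice"] == "total")]
        assert total["density_kg_km2"].iloc[0] == pytest.approx(11_250.0 / area)

    def test_equal_densities_give_same_national_density(self, small_layout):
        # national value is area-weighted, so equal unit densities pass through
        rows = []
        for uid in small_layout.municipality_ids:
            area = small_layout.rangeland_area(uid)
            rows.append({"trophic_level": "herbivore", "slice": "total",
                         "unit_id": uid, "year": 2009,
                         "density_kg_km2": 42.0, "biomass_kg": 42.0 * area})
        nat = national_summary(pd.DataFrame(rows), small_layout)
        assert nat["density_kg_km2"].iloc[0] == pytest.approx(42.0)

    def test_round_trip_against_generator_truth(self, small_config, small_layout):
        livestock, wild, truth = simulate_herbivore_census(
            small_config, small_layout, seed=0
        )
        for year in small_config.census_years:
            surface = assemble_herbivore_density(
                livestock, wild, DEFAULT_PROFILES, small_layout, year
            )
            for _, t in truth[truth["year"] == year].iterrows():
                got = surface[(surface["unit_id"] == t["unit_id"])]
                for slc, col in [("livestock", "livestock_density"),
                                 ("wild", "wild_density"),
                                 ("total", "total_density")]:
                    val = got.loc[got["slice"] == slc, "density_kg_km2"].iloc[0]
                    assert val == pytest.approx(t[col], rel=1e-12)

    def test_conservation_municipal_sum_equals_national(self, small_world, small_layout):
        surface = assemble_herbivore_density(
            small_world["livestock"], small_world["wild"], DEFAULT_PROFILES,
            small_layout, 2009,
        )
        nat = national_summary(surface, small_layout)
        for slc in ("livestock", "wild", "total"):
            total_kg = surface.loc[surface["slice"] == slc, "biomass_kg"].sum()
            assert nat.loc[nat["slice"] == slc, "biomass_kg"].iloc[0] == pytest.approx(
                total_kg, rel=1e-12
            )

    def test_density_scales_inversely_with_area(self):
        livestock = pd.DataFrame(
            [{"species": "sheep", "municipality_id": "m0000", "year": 2009,
              "headcount": 1000}]
        )
        wild = pd.DataFrame(columns=["species", "municipality_id", "year",
                                     "density_kg_km2"])
        small = one_unit_layout([0] * 4)    # 1 km^2 rangeland
        big = one_unit_layout([0] * 8)      # 2 km^2 rangeland
        d_small = assemble_herbivore_density(
            livestock, wild, DEFAULT_PROFILES, small, 2009
        )
        d_big = assemble_herbivore_density(
            livestock, wild, DEFAULT_PROFILES, big, 2009
        )
        rs = d_small.loc[d_small["slice"] == "livestock", "density_kg_km2"].iloc[0]
        rb = d_big.loc[d_big["slice"] == "livestock", "density_kg_km2"].iloc[0]
        assert rs == pytest.approx(2 * rb)

    def test_unknown_species_raises(self, small_layout):
        livestock = pd.DataFrame(
            [{"species": "unicorn", "municipality_id": "m0000", "year": 2009,
              "headcount": 1}]
        )
        wild = pd.DataFrame(columns=["species", "municipality_id", "year",
                                     "density_kg_km2"])
        with pytest.raises(KeyError):
            assemble_herbivore_density(
                livestock, wild, DEFAULT_PROFILES, small_layout, 2009
            )


class TestGuildShare:
    def test_wild_absent_gives_share_one(self, small_layout):
        livestock = pd.DataFrame(
            [{"species": "sheep", "municipality_id": "m0000", "year": 2009,
              "headcount": 10}]
        )
        wild = pd.DataFrame(columns=["species", "municipality_id", "year",
                                     "density_kg_km2"])
        surface = assemble_herbivore_density(
            livestock, wild, DEFAULT_PROFILES, small_layout, 2009
        )
        assert guild_share(surface, 2009) == pytest.approx(1.0)

    def test_direct_ratio(self, small_layout):
        area = small_layout.rangeland_area("m0000")
        surface = pd.DataFrame(
            [
                {"trophic_level": "herbivore", "slice": "livestock",
                 "unit_id": "m0000", "year": 2009, "density_kg_km2": 97 / area,
                 "biomass_kg": 97.0},
                {"trophic_level": "herbivore", "slice": "wild",
                 "unit_id": "m0000", "year": 2009, "density_kg_km2": 3 / area,
                 "biomass_kg": 3.0},
                {"trophic_level": "herbivore", "slice": "total",
                 "unit_id": "m0000", "year": 2009, "density_kg_km2": 100 / area,
                 "biomass_kg": 100.0},
            ]
        )
        assert guild_share(surface, 2009) == pytest.approx(0.97)

    def test_shares_complement_for_synthetic_draws(self, small_world):
        surface = assemble_herbivore_density(
            small_world["livestock"], small_world["wild"], DEFAULT_PROFILES,
            small_world["layout"], 2015,
        )
        live = guild_share(surface, 2015)
        sub = surface[surface["year"] == 2015]
        wild_share = (
            sub.loc[sub["slice"] == "wild", "biomass_kg"].sum()
            / sub.loc[sub["slice"] == "total", "biomass_kg"].sum()
        )
        assert 0.0 <= live <= 1.0
        assert live + wild_share == pytest.approx(1.0, rel=1e-12)

    def test_zero_total_is_missing(self, small_layout):
        surface = pd.DataFrame(
            [{"trophic_level": "herbivore", "slice": "total", "unit_id": "m0000",
              "year": 2009, "density_kg_km2": 0.0, "biomass_kg": 0.0}]
        )
        assert np.isnan(guild_share(surface, 2009))


class TestEcosystemPartition:
    def test_only_sheep_all_alpine(self, small_layout):
        livestock = pd.DataFrame(
            [{"species": "sheep", "municipality_id": "m0000", "year": 2009,
              "headcount": 1000}]
        )
        wild = pd.DataFrame(columns=["species", "municipality_id", "year",
                                     "density_kg_km2"])
        parts = ecosystem_partition(
            livestock, wild, DEFAULT_PROFILES, small_layout, 2009
        )
        forest = parts[(parts["unit_id"] == "m0000") & (parts["slice"] == "forest")]
        alpine = parts[(parts["unit_id"] == "m0000") & (parts["slice"] == "alpine")]
        assert forest["biomass_kg"].iloc[0] == 0.0
        open_area = small_layout.ecosystem_area("m0000", "alpine")
        assert alpine["density_kg_km2"].iloc[0] == pytest.approx(11_250.0 / open_area)

    def test_partition_conserves_total_with_horses_excluded(self, small_layout):
        livestock = pd.DataFrame(
            [
                {"species": "sheep", "municipality_id": "m0000", "year": 2009,
                 "headcount": 100},
                {"species": "cattle", "municipality_id": "m0000", "year": 2009,
                 "headcount": 10},
                {"species": "horse", "municipality_id": "m0000", "year": 2009,
                 "headcount": 4},
            ]
        )
        wild = pd.DataFrame(
            [{"species": "moose", "municipality_id": "m0000", "year": 2009,
              "density_kg_km2": 20.0}]
        )
        total = assemble_herbivore_density(
            livestock, wild, DEFAULT_PROFILES, small_layout, 2009
        )
        parts = ecosystem_partition(
            livestock, wild, DEFAULT_PROFILES, small_layout, 2009
        )
        horse_kg = seasonal_standardise(4, DEFAULT_PROFILES["horse"])
        for uid in small_layout.municipality_ids:
            eco_kg = parts.loc[parts["unit_id"] == uid, "biomass_kg"].sum()
            tot_kg = total.loc[
                (total["unit_id"] == uid) & (total["slice"] == "total"), "biomass_kg"
            ].iloc[0]
            excluded = horse_kg if uid == "m0000" else 0.0
            assert eco_kg + excluded == pytest.approx(tot_kg, rel=1e-12)

    def test_two_species_hand_sum(self, small_layout):
        # moose (forest, wild density 30 kg/km2) + sheep (alpine, 200 head)
        livestock = pd.DataFrame(
            [{"species": "sheep", "municipality_id": "m0000", "year": 2009,
              "headcount": 200}]
        )
        wild = pd.DataFrame(
            [{"species": "moose", "municipality_id": "m0000", "year": 2009,
              "density_kg_km2": 30.0}]
        )
        parts = ecosystem_partition(
            livestock, wild, DEFAULT_PROFILES, small_layout, 2009
        )
        rangeland = small_layout.rangeland_area("m0000")
        forest_area = small_layout.ecosystem_area("m0000", "forest")
        open_area = small_layout.ecosystem_area("m0000", "alpine")
        forest = parts[(parts["unit_id"] == "m0000") & (parts["slice"] == "forest")]
        alpine = parts[(parts["unit_id"] == "m0000") & (parts["slice"] == "alpine")]
        assert forest["biomass_kg"].iloc[0] == pytest.approx(30.0 * rangeland)
        assert forest["density_kg_km2"].iloc[0] == pytest.approx(
            30.0 * rangeland / forest_area
        )
        sheep_kg = seasonal_standardise(200, SHEEP)
        assert alpine["biomass_kg"].iloc[0] == pytest.approx(sheep_kg)
        assert alpine["density_kg_km2"].iloc[0] == pytest.approx(sheep_kg / open_area)
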