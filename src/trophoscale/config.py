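"""Configuration objects and shipped species defaults.

Species profiles carry the life-history constants that turn head counts and
harvest records into biomass: mean body mass, the fraction of the year the
species spends on rangeland, and an ecosystem assignment (forest / alpine /
none) used when deviations are computed per ecosystem.

The shipped default masses and rangeland fractions are documented
assumptions, editable via a YAML profile file; see ``docs/methods.md``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import yaml

FOREST = "forest"
OPEN = "open"
OTHER = "other"
LAND_COVER_CLASSES = (FOREST, OPEN, OTHER)

ECOSYSTEMS = ("all", "forest", "alpine")


@dataclass(frozen=True)
class SpeciesProfile:
    """Constants for one species of large (>10 kg) consumer.

    Parameters
    ----------
    species:
        Canonical lower-case name, e.g. ``"sheep"``.
    guild:
        ``"herbivore"`` or ``"carnivore"``.
    status:
        ``"livestock"``, ``"wild"`` or ``"semi-domestic"``.  Semi-domestic
        reindeer count on the livestock side of the guild split.
    mean_body_mass:
        Average individual mass in kg (> 0).
    rangeland_fraction:
        Fraction of the year spent on rangeland, in [0, 1]; livestock biomass
        is standardised by this fraction.
    ecosystem:
        ``"forest"``, ``"alpine"`` or ``"none"`` (excluded from both
        ecosystem partitions, e.g. horses).
    """

    species: str
    guild: str
    status: str
    mean_body_mass: float
    rangeland_fraction: float = 1.0
    ecosystem: str = "none"

    def __post_init__(self) -> None:
        if self.guild not in ("herbivore", "carnivore"):
            raise ValueError(f"unknown guild {self.guild!r}")
        if self.status not in ("livestock", "wild", "semi-domestic"):
            raise ValueError(f"unknown status {self.status!r}")
        if not self.mean_body_mass > 0:
            raise ValueError("mean_body_mass must be > 0")
        if not 0.0 <= self.rangeland_fraction <= 1.0:
            raise ValueError("rangeland_fraction must lie in [0, 1]")
        if self.ecosystem not in ("forest", "alpine", "none"):
            raise ValueError(f"unknown ecosystem {self.ecosystem!r}")

    @property
    def is_livestock(self) -> bool:
        """True for the livestock side of the guild split (incl. semi-domestic)."""
        return self.status in ("livestock", "semi-domestic")


# Default profiles.  Masses and rangeland fractions are package assumptions
# (round figures typical of Nordic rangeland stock and game); the ecosystem
# assignments follow the standard forest/alpine habitat classification of
# these species.  Override any entry via a YAML profile file.
DEFAULT_PROFILES: dict[str, SpeciesProfile] = {
    p.species: p
    for p in [
        # livestock
        SpeciesProfile("cattle", "herbivore", "livestock", 400.0, 0.25, "forest"),
        SpeciesProfile("sheep", "herbivore", "livestock", 45.0, 0.25, "alpine"),
        SpeciesProfile("goat", "herbivore", "livestock", 35.0, 0.25, "alpine"),
        SpeciesProfile("horse", "herbivore", "livestock", 450.0, 0.25, "none"),
        SpeciesProfile(
            "semi-domestic reindeer", "herbivore", "semi-domestic", 60.0, 1.0, "alpine"
        ),
        # wild herbivores
        SpeciesProfile("moose", "herbivore", "wild", 300.0, 1.0, "forest"),
        SpeciesProfile("red deer", "herbivore", "wild", 120.0, 1.0, "forest"),
        SpeciesProfile("roe deer", "herbivore", "wild", 25.0, 1.0, "forest"),
        SpeciesProfile("wild reindeer", "herbivore", "wild", 60.0, 1.0, "alpine"),
        # large carnivores
        SpeciesProfile("wolf", "carnivore", "wild", 40.0, 1.0, "forest"),
        SpeciesProfile("bear", "carnivore", "wild", 130.0, 1.0, "forest"),
        SpeciesProfile("lynx", "carnivore", "wild", 18.0, 1.0, "forest"),
        SpeciesProfile("wolverine", "carnivore", "wild", 12.0, 1.0, "alpine"),
    ]
}


def load_profiles(path) -> dict[str, SpeciesProfile]:
    """Load species profiles from YAML, overlaying the shipped defaults.

    The file maps species name to any subset of the profile fields; species
    not present in the defaults must provide all of guild/status/mass.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    profiles = dict(DEFAULT_PROFILES)
    for name, fields in raw.items():
        fields = dict(fields or {})
        fields.pop("species", None)
        if name in profiles:
            profiles[name] = replace(profiles[name], **fields)
        else:
            profiles[name] = SpeciesProfile(species=name, **fields)
    return profiles


@dataclass(frozen=True)
class NPPParams:
    """Parameters of the synthetic productivity field.

    base:
        Baseline NPP in kg C km^-2 yr^-1 (MODIS-era Norwegian means sit
        around 3e5).
    gradient:
        Linear east-west ramp per column: a cell in column c is multiplied
        by ``1 + gradient * c``.
    forest_multiplier / open_multiplier:
        Class-specific productivity multipliers (forest richer than open
        tundra).
    noise_sd:
        Standard deviation of multiplicative lognormal noise on the log
        scale; 0 disables noise.
    """

    base: float = 300_000.0
    gradient: float = 0.0
    forest_multiplier: float = 1.2
    open_multiplier: float = 0.6
    noise_sd: float = 0.15

    def __post_init__(self) -> None:
        if not self.base > 0:
            raise ValueError("base NPP must be positive")
        if self.forest_multiplier <= 0 or self.open_multiplier <= 0:
            raise ValueError("class multipliers must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class CarnivoreParams:
    """Growth-harvest model parameters for one carnivore species.

    lam:
        Annual multiplicative growth rate (lambda > 0).
    harvest_rate:
        Fraction of the post-growth population removed each year, in [0, 1).
    initial_abundance:
        Per-county starting abundance at the first simulated year.
    anchor_year:
        Year whose simulated abundance is handed to the backcaster as the
        modern monitoring anchor (defaults to the final year).
    """

    species: str
    lam: float
    harvest_rate: float
    initial_abundance: float
    anchor_year: int | None = None

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ValueError("lambda must be > 0")
        if not 0.0 <= self.harvest_rate < 1.0:
            raise ValueError("harvest rate must lie in [0, 1)")
        if self.initial_abundance < 0:
            raise ValueError("initial abundance must be >= 0")


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of a synthetic study system.

    A fixed seed makes every generated artefact byte-identical.  The grid
    partitions exactly into municipalities nested in counties, so zonal
    aggregation can be tested against exhaustive enumeration.
    """

    seed: int = 0
    n_counties: int = 3
    municipalities_per_county: int = 3
    # 120x120 cells of 0.25 km^2 give nine municipalities of ~360 km^2
    # rangeland each, near the ~418 km^2 median of real municipalities
    grid_shape: tuple[int, int] = (120, 120)
    cell_area: float = 0.25  # km^2, a 500 m cell
    years: tuple[int, int] = (1950, 2015)
    census_years: tuple[int, ...] = (1959, 1969, 1979, 1989, 1999, 2009, 2015)
    land_cover_fractions: tuple[float, float, float] = (0.55, 0.35, 0.10)
    npp_params: NPPParams = field(default_factory=NPPParams)
    # initial county abundances sized so total carnivore density sits around
    # 1-2 kg km^-2 on ~1000 km^2 synthetic counties
    carnivore_params: tuple[CarnivoreParams, ...] = (
        CarnivoreParams("wolf", 1.12, 0.10, 6.0),
        CarnivoreParams("bear", 1.08, 0.06, 12.0),
        CarnivoreParams("wolverine", 1.10, 0.08, 10.0),
        CarnivoreParams("lynx", 1.15, 0.12, 15.0),
    )
    deterministic: bool = False
    # per-species mean headcount per municipality at each census year
    livestock_means: dict[str, float] = field(
        default_factory=lambda: {
            "sheep": 4000.0,
            "cattle": 300.0,
            "goat": 150.0,
            "horse": 30.0,
            "semi-domestic reindeer": 500.0,
        }
    )
    # per-species wild herbivore density (kg km^-2) per municipality
    wild_density_means: dict[str, float] = field(
        default_factory=lambda: {
            "moose": 60.0,
            "red deer": 25.0,
            "roe deer": 8.0,
            "wild reindeer": 20.0,
        }
    )

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        n_units = self.n_counties * self.municipalities_per_county
        if rows * cols < n_units:
            raise ValueError(
                f"grid of {rows * cols} cells cannot hold {n_units} municipalities"
            )
        y0, y1 = self.years
        if y1 < y0:
            raise ValueError("year range must be increasing")
        bad = [y for y in self.census_years if not y0 <= y <= y1]
        if bad:
            raise ValueError(f"census years {bad} outside configured range {self.years}")
        if abs(sum(self.land_cover_fractions) - 1.0) > 1e-9:
            raise ValueError("land cover fractions must sum to 1")
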