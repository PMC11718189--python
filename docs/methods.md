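# Methods

This note documents the models implemented in `trophoscale`, the
assumptions behind them, the synthetic study system used for validation,
and the numerical choices that matter.

## Trophic levels and their resolutions

The pipeline treats three trophic levels at three native resolutions:
vegetation as annual net primary productivity (NPP, kg C km⁻² yr⁻¹) on a
raster of 500 m cells (0.25 km²); large herbivores (> 10 kg) as biomass
densities per municipality at decadal census years; large carnivores
(wolf, brown bear, wolverine, Eurasian lynx) as annually resolved county
series, snapshotted at the same decadal years. Densities are always
expressed per km² of *rangeland* — unimproved forest plus open
(tundra/heath) land; cultivated and urban cells ("other" class) are
excluded from both the NPP means and the density denominators. NPP is used
rather than standing plant biomass because annual production is what is
actually available to herbivores, much of the standing crop being wood.

## Carnivore backcasting

Forward model: within a year, growth happens first, harvest second,

    G_t = λ·N_{t−1},  H_t,  N_t = G_t − H_t,

with λ a constant per-species annual multiplicative growth rate. The
backcast inverts this exactly from a modern anchor abundance N(T):

    N_{t−1} = (N_t + H_t) / λ,

iterated backwards over the harvest span, followed by the feasibility
floor N_{t−1} := max(N_{t−1}, H_{t−1}) — a population cannot be smaller
than its own recorded kill. Floored years are flagged; at a flagged year
the reconstruction equals the kill exactly, and elsewhere the raw
recurrence holds exactly. The growth-then-harvest ordering was chosen so
that the forward simulator and the backcaster form a matched pair with an
exact algebraic inverse; the ordering convention is exposed in one place
and testable by round trip.

Abundances are kept real-valued through the recursion; rounding to whole
animals happens only at reporting. Over a ~170-year series, per-year
rounding would otherwise compound into a systematic bias.

Known limitations, by construction: λ is constant per species (optionally
overridable), so periods of rapid population change are reconstructed with
bias — underestimating during rapid increase and overestimating during
decline; unreported removals (vehicle kills, illegal hunting) are not
modelled; counties are closed (no dispersal). The `sensitivity_scan`
diagnostic quantifies how the earliest-year abundance responds to λ and
anchor choices; it is monotone in both (nonincreasing in λ, linear in the
anchor when harvests are zero).

## Herbivore assembly

Livestock biomass per municipality and census year is
Σ headcount × mean body mass × rangeland fraction, the last factor being
the seasonal standardisation (3 months on the range ⇒ 25%). Wild herbivore
biomass enters as a pre-estimated density table — the cohort-based
population models that produce such tables are a separate concern with
their own literature, and keeping them out makes the interface clean.
Raw (not metabolic) biomass is used throughout.

Species profiles (mass, rangeland fraction, guild, ecosystem) ship as
editable defaults. **The default masses and fractions are package
assumptions** — round figures typical of Nordic stock and game (sheep
45 kg at 0.25 of the year; cattle 400 kg at 0.25; moose 300 kg year-round;
etc.) — not authoritative values; any real analysis should override them
via `load_profiles`. Semi-domestic reindeer are counted on the livestock
side of the guild split, with rangeland fraction 1.0 (they range
year-round).

Ecosystem partition: forest species are moose, red deer, roe deer, cattle
(carnivores: wolf, bear, lynx); alpine species are wild and semi-domestic
reindeer, sheep, goats (carnivore: wolverine); horses belong to neither
and are excluded from the partition while remaining in the totals. The
"alpine" NPP class is operationalised as the open land-cover class, which
also contains lowland heaths — a labelling caveat, not a claim that all
open land is above the treeline. Ecosystem densities use the
ecosystem-specific cell areas as denominators, so the partition conserves
absolute biomass but not density sums.

## NPP aggregation

Unit conversion multiplies the raw grid by a scale factor and an area
factor (with the common satellite convention, raw × 10⁻⁴ kg C m⁻² × 10⁶
m² km⁻² = kg C km⁻²); declared fill codes and negative results map to
missing, negatives with a logged count. Zonal means are unweighted means
over the non-missing rangeland cells of the requested class set (all =
forest ∪ open; alpine = open), each cell belonging to exactly one
municipality. Units with no eligible cells are reported as missing with a
zero cell count rather than dropped. Multi-year means average the annual
zonal means. National summaries are offered both rangeland-masked
(default, consistent with the zonal logic) and unmasked.

## Scaling laws and deviations

Two shipped power laws: herbivores from NPP (coefficient 0.643, exponent
0.47) and carnivores from herbivore biomass (coefficient 0.094, exponent
0.73; the wolf–prey exponent 0.72 can be swapped in through the model
registry). Both are strictly increasing and concave; the composed
NPP→carnivore law is implemented as the exact composition and tested to
10⁻¹² relative against chaining the two calls.

The deviation metric is log₁₀(observed/expected) with a configurable
in-line band (default ±0.1, i.e. within ×1.26 either way); the absolute
difference is also emitted. The log-ratio was chosen because it is
scale-free, symmetric under swapping observed and expected (up to sign),
and additive across the composed laws. Zero observed biomass yields a −∞
sentinel with a flag rather than a dropped record, so "absent but
expected" stays visible in maps; a nonpositive expectation makes the
record missing.

Aggregation order matters because the laws are nonlinear: for
county-level carnivore assessment, municipal herbivore *absolute* biomass
is summed to the county first and the power law applied to the county
density, never the mean of per-municipality expectations. NPP-year
matching pairs each census year with the same-year NPP when available;
the 1999 census is paired with year-2000 NPP (the productivity record
starts in 2000), and any census year with no annual raster falls back to
the supplied multi-year mean. The wild-herbivore basis (carnivores vs wild
prey only) is produced in all-species runs; the ecosystem partition does
not split the wild/livestock axis, so ecosystem runs emit the observed-
herbivore and NPP bases only.

## Synthetic study system

The generator emulates the shape of the real inputs, not their content:

- **Geography** — a rectangular grid partitioned row-major by
  `numpy.array_split` into counties and nested municipalities (simplest
  layout that exercises nested zonal aggregation); land cover i.i.d. per
  cell from configured fractions. Defaults: 120×120 cells of 0.25 km²,
  3 counties × 3 municipalities ⇒ ~360 km² rangeland per municipality,
  near the ~418 km² median of the real municipal units.
- **NPP** — base level 300 000 kg C km⁻² yr⁻¹ with forest/open multipliers
  1.2/0.6 and multiplicative lognormal noise (sd 0.15 on the log scale);
  lognormal guarantees positivity and matches the right skew of real
  productivity fields. These defaults land national means near 290 000,
  inside the observed 272 000–357 000 range.
- **Livestock/wild censuses** — Poisson headcounts around configured
  means (exact means in deterministic mode); wild densities as configured
  constant trajectories. Default means give herbivore totals of
  ~400 kg km⁻² and a livestock share near 0.73.
- **Carnivores** — the forward twin of the backcast recurrence, with
  harvests either round(h·G_t) (deterministic) or Binomial(round(G_t), h)
  (stochastic). Default initial abundances put total carnivore density at
  a few kg km⁻².

All randomness flows from one root `SeedSequence` spawned into four
streams in fixed order (land cover, NPP, carnivores, herbivores), so a
fixed seed reproduces every artefact byte-for-byte regardless of which
generators run. Deterministic mode exists so that round-trip tests have
exact oracles: herbivore assembly reproduces the generator's recorded
densities exactly, and backcasting with the true λ and anchor reproduces
the true trajectory to floating-point precision (within ±1 animal when
forward harvests are integer-rounded).

What the generator does **not** emulate: real boundary geometries and
their merge history, spatial autocorrelation in land cover, density
dependence or environmental stochasticity in carnivore growth, livestock
trends over time, and observation error in the censuses. Passing tests
therefore demonstrate the correctness of the computational machinery under
known truth, not the fidelity of any particular historical reconstruction.

## Numerical choices

- Rasters travel as headerless plain-grid CSV (one file per year); unit
  geometries as GeoJSON built from shapely cell-box unions. All artefacts
  are plain text.
- CSV floats are written with `%.10g`, enough to round-trip the analysis
  while keeping byte-identical output across runs.
- Manifest hashing covers the scientific configuration only (not output
  paths), with SHA-256 over a canonical JSON encoding.
- The problem sizes used by the test suite and the acceptance script
  (10×10–120×120 grids, 50–170-year histories, ≤ 200 replicate
  simulations) were chosen as the smallest sizes at which every validated
  property is non-trivially exercised.
- Degenerate inputs: zero rangeland area raises a geometry error rather
  than producing infinities; empty zonal cell sets report missing; a
  harvest series with an unmarked gap is rejected rather than silently
  interpolated.
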