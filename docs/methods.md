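# Methods

`landmit` is a reduced-complexity, conservation-exact re-expression of the
carbon accounting used to weigh land-based mitigation options — BECCS,
afforestation/reforestation, avoided deforestation — against each other
under 1.5 °C and 2 °C warming pathways. Everything runs at an annual step
on a coarse land grid from synthetic inputs, so every result in the test
suite and analysis scripts is reproducible from a seed on one CPU in
seconds. This note records the model, its assumptions, the parameters
that matter, and what the synthetic setting can and cannot show.

## Grid, biomes and synthetic inputs

The native grid is a regular 2.5° × 3.75° latitude–longitude grid
(96 × 73); the default desk grid is 48 × 36 and tests use 24 × 18. Cells
are ranked by a smooth deterministic "continentality" score and selected
until the configured global land area (13 345.8 Mha) is met, which the
selection reaches to well within 5 %. Biomes are a latitude-band
caricature: eight bands from tropical forest to tundra, each carrying the
biome-mean vegetation carbon, its 10th–90th percentile envelope, an
equilibrium soil turnover time (C_soil/NPP) and a mean NPP. Initial
vegetation density is the biome equilibrium times a truncated-normal
heterogeneity factor clipped to the percentile envelope; soil pools start
at the exact discrete-step equilibrium of the cell's initial litter flux,
so an unforced run sits still from step one.

**Land use.** Global bioenergy area follows a piecewise cubic-Hermite
curve with zero end slopes through (2030, 0), (peak year, peak area),
(2100, end area). The ambitious preset (`im19_like`) peaks at 550 Mha in
2060 and declines to 430 Mha by 2100 with a mid/high-latitude weighting;
the moderate preset (`im26_like`) peaks at 325 Mha in 2085 with a
temperate weighting. Cells are assigned a conversion priority by weighted
sampling without replacement from a Gaussian latitude weight; the running
area target fills cells along that order (the marginal cell partially),
so the global trajectory is matched essentially exactly and abandonment
after the peak retreats last-in-first-out. Within a converted cell,
bioenergy occupies existing agriculture first — up to the preset's
`agri_displacement` share of local farmland (1.0 for the moderate preset,
whose real-world counterpart grows bioenergy predominantly on existing
and abandoned farmland; 0.25 for the ambitious preset, which clears
substantial mid/high-latitude forest) — and clears natural vegetation
only for the remainder. Food cropland (1 500 Mha) and pasture (3 300 Mha)
are static latitude-weighted backgrounds apart from that displacement.
These placement rules are caricatures: they reproduce the global
trajectories and the qualitative geography (farmland conversions in the
temperate belt, forest clearing poleward), not any particular map.

**Climate.** Warming profiles are exponential approaches
dT(t) = target − (target − 0.9) e^(−(t−2000)/30 yr), reaching within
0.05 K of target by 2100. The ensemble (default 34 in the generator; 8 in
the desk experiments) draws a climate feedback λ ~ U(0.7, 1.6) W m⁻² K⁻¹,
an ocean heat-uptake efficiency κ ~ U(0.5, 0.9) W m⁻² K⁻¹ and a
polar-amplification factor; temperature patterns are normalized to unit
area-weighted mean so pattern scaling preserves the global mean anomaly.

## Energy-balance inversion

A two-box energy-balance model (mixed layer C = 8 W yr m⁻² K⁻¹, deep
ocean C = 100, deep-ocean start at half the initial surface warming as a
stand-in for the historical transient) is run *backwards*: given dT(t),
the forcing is Q = C dT/dt + λ dT + κ (dT − dT_deep), discretized to
match the forward Euler integrator exactly, so re-running the model
forward with the inverted forcing reproduces the prescribed warming to
machine precision (the test budget allows 0.01 K). A fixed non-CO₂ share
(0.2) and the logarithmic law CO₂ = 285 ppm · 2^(Q_co2/3.7 W m⁻²) yield
each member's CO₂ path; less sensitive members (higher λ) get higher CO₂
for the same warming, which is what spreads the ensemble. Ocean carbon
uptake is a pulse-response convolution of atmospheric CO₂ increments
with an exponential kernel (fraction 0.7, e-folding 40 yr, normalized so
the discrete kernel mass equals the fraction); allowable fossil
emissions are diagnosed as atmospheric change (2.124 GtC ppm⁻¹) plus
ocean and land uptake, an identity that holds exactly by construction.
How non-CO₂ forcing behaved during the original inversion is not
something this package can know; the fixed share is a declared stand-in.

## Vegetation, soil and land-use bookkeeping

Each cell carries eight PFTs (broadleaf and needleleaf trees, shrub,
C3/C4 grass, food crop, pasture, bioenergy crop; the managed types use
grass parameters). The litter flux closes the vegetation balance,

    Λ = Π ν_{n−1} − (C_veg ν − C_veg,n−1 ν_{n−1}) ,

with all products of density × fraction expressed per unit cell area.
Growth is an exponential relaxation of density toward a per-PFT
equilibrium c_eq: ΔV = ν (c_eq − C) (1 − e^(−Π/c_eq)), which keeps Λ ≥ 0
whenever C ≤ c_eq and is unconditionally stable at the annual step; if a
forced state would still make Λ negative, Λ is floored at zero and the
density absorbs the shortfall so the balance never leaks. NPP is a
biome/PFT baseline scaled by (1 + β ln(CO₂/CO₂_ref)) with β = 0.5
(applied to c_eq as well, so fertilization raises standing biomass) and
a mild linear local-temperature factor (+2 %/K); CO₂_ref is each run's
starting CO₂ so initial fields begin in equilibrium. β is deliberately
exposed: the functional form is this package's own stand-in, not
something the accounting scheme prescribes. Crop/pasture PFTs carry a
per-biome suitability factor on productivity and standing biomass
(1.0 in the tropics down to 0.45/0.25 in boreal/tundra) reflecting the
short growing season a harvested grass crop can exploit where the native
vegetation is evergreen forest — without it, high-latitude conversion
would leave soil litter input nearly unchanged and the long-payback
mechanism would vanish. Half of pasture aboveground litter is respired
as grazing.

Agricultural PFT areas snap to the prescribed fractions; natural PFTs
relax toward a climate-dependent potential mix with e-folding times of
50 yr (trees), 20 yr (shrubs), 3 yr (grasses). The potential mix in
tundra/boreal blends toward a woodier composition once the local anomaly
crosses 1 K (width 1 K), a minimal tree-line advance.

Soil carbon sits in four pools with default turnovers 1/10/100/1000 yr
and litter split 0.6/0.3/0.09/0.01; decay scales as Q10^(ΔT_local/10),
Q10 = 2. The pipeline rescales all four turnovers per biome by one
factor so the equilibrium C_soil/NPP matches the biome table (tropical
forest 6 yr … tundra 87 yr); the local anomaly is measured relative to
the 2000 baseline the initial pools are equilibrated to.

Land-use transitions follow a fixed precedence: expanding classes draw
first from shrinking agricultural classes, then from natural vegetation;
leftover shrinkage is abandonment. Swaps between the grass-like managed
classes are *reclassifications* — the standing carbon moves with the
area, nothing is emitted — because converting cropland to a bioenergy
grass is a change of management, not a clearing event. Cleared natural
vegetation sheds its aboveground biomass into the wood-product pools
(woody sources 60/30/10 % fast/medium/slow; grass sources 100 % fast)
and its belowground biomass into the fast soil pool; the published
description of the product split ("10 %, 30–40 %, 60 %") cannot sum to
one, so the self-consistent 10/30/60 reading is used with the medium
share configurable. The aboveground split fraction is 0.5, shared with
the NPP allocation assumption. A config flag `initial_biomass_to_beccs`
instead credits the aboveground biomass of land cleared *for bioenergy*
to the geological reservoir — the integrated-assessment accounting
convention — and is what the comparison analysis toggles for its
"crosses" variant.

## Harvest, BECCS and the efficiency chain

H_i = ε_harv Λ_crop with ε_harv = 0.3 (the remaining 70 % of crop litter
reaches the soil); BECCS = H_i (ν_bio/ν_agric) ε_BECCS with
ε_BECCS = 0.6 covering all losses from field to repository; H = H_i −
BECCS enters the fast product pool, so the (1 − ε) losses are respired,
never dropped. The reservoir never decays. A capture multiplier (1, 1.5,
2, 3) scales the diverted flux for sensitivity sweeps, capped so no more
than the bioenergy share of the harvest can be stored (the cap binds
in-run above 1/ε_BECCS ≈ 1.67; the comparison sweep scales the captured
stock linearly instead, reading the multiplier as "more carbon per unit
land" from yields, residues or better capture). The standalone
efficiency-chain operation, captured = biomass × ccs_fraction ×
chain_efficiency, tabulates accounting conventions side by side: 0.5 GtC
of harvest through a 60 % chain stores 0.30 GtC, while 1 GtC of biomass
with 60–70 % of crops on CCS at 87 % net efficiency stores 0.52–0.61 GtC
— a factor 1.7–2 per unit cropland, which is the arithmetic core of why
different accounting frameworks disagree about BECCS. Dry-mass
conversion assumes 50 % carbon content and 10 % moisture (mass reported
*at* 10 % moisture, i.e. divide by 0.9).

## Experiments, attribution, payback

The matrix crosses two land-use presets with two warming targets plus
`2C_IM26_1.5CO2` (2 °C warming, 1.5 °C CO₂ path) to isolate CO₂
fertilization. Per member, the net difference in century carbon gain
between `1.5C_IM19` and `2C_IM26` is decomposed as: CO₂ effect from the
(2C_IM26_1.5CO2 − 2C_IM26) pair; climate effect from the IM1.9 warming
pair minus that CO₂ estimate; land-use effect from the 1.5 °C land-use
pair, split across food / bioenergy / afforestation drivers by the
attribution ledger (the bioenergy term also carries the reservoir
difference). The components cannot be exactly additive in a nonlinear
model, so the residual is reported as its own term rather than rescaled
away — on the default presets it is a few percent of the net.

The ledger tags each cell-year's change in C_veg + C_soil with the
standing land-use driver: when agricultural area expands, the year's
change is split across expanding classes in proportion to their area
increases and the categorization persists until a different kind of
change occurs; when it contracts, changes accrue to
afforestation/reforestation. The accumulation resets at the switch year
(the alternative — resetting the year after — is pinned down by the
toy-ledger test). Payback time is the accumulated bioenergy-category
deficit (including the conversion-year loss) divided by the cell's mean
annual capture flux, evaluated from the first bioenergy year to removal
or 2100; a deficit with no flux reports infinity. Conflict cells for the
forest-vs-BECCS comparison have bioenergy fraction > 0.05 in one run,
tree cover > 0.1 at 2100 in the other, and fractions differing by >
0.05 — thresholds this package had to choose, as no canonical values
exist.

## Numerical choices

Annual coupling step throughout (the litter equation is step-size
agnostic); exact `expm1`-based decay for soil and product pools so
conservation closes to machine precision; every run asserts that the
change in total stored carbon equals cumulative NPP minus respiration,
product decay and grazing to 1e-8 relative (measured residuals are
~1e-12). Divisions by areal fractions are guarded at zero with the
convention that an empty PFT has zero density. All randomness flows
through `numpy.random.default_rng` seeds carried in the study context.

## What the synthetic setting shows — and does not

The generators reproduce the *structure* of the study conditions: global
land-use trajectories, warming/CO₂ ensembles, biome-realistic stocks and
turnovers. They do not reproduce real maps, real meteorology, nitrogen
limitation, fire, or high-yield crop breeding; the full-physics
ensemble magnitudes (net +47 vs +102 GtC, a −85 GtC CO₂ term, 27→48 %
winning fractions) are therefore not quantitative targets here.
What the desk-scale pipeline does reproduce, and what the acceptance
tests check, are the directions and mechanisms: total land carbon gains
less under the ambitious land-use/1.5 °C combination than under the
moderate/2 °C one; payback is zero where bioenergy replaces existing
farmland and exceeds a century where it replaces boreal/tundra soils;
the forest-vs-BECCS winning fraction rises with the capture multiplier
and under the initial-biomass-to-storage accounting; and the worked
efficiency-chain arithmetic is exact. Problem sizes are chosen for a
single CPU: a 48 × 36 grid, 8-member ensembles, 101-year runs (~0.1 s
per run), with the 96 × 73 grid available behind a flag.
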