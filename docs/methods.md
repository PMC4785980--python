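# Methods

`sectorgap` simulates a forest stand as a set of individual trees on a
rectangular, toroidal plot rasterised at `pixel` = 0.1 m. Time advances
in annual steps; each year runs light competition, realized-crown
update, water competition, growth, mortality and recruitment, in that
order, and appends one row of stand summaries. A simulation starts from
an empty plot — the state following a stand-replacing disturbance — and
every random draw comes from a single seeded generator, so runs are
bit-reproducible.

## Above-ground competition

A crown is eight independent sectors (45° each, sector 0 starting due
east, counter-clockwise). Sector *i* with radius *rᵢ* and live-crown
ratio *βᵢ* claims, at stem distance *x* ≤ *rᵢ*, the elevation
*h*·(1 − *βᵢ*(x/rᵢ)^γ); γ = 0.5 for both species (a square-root crown
profile). Every pixel holds one unit of direct sunlight per year and
gives it to the highest claim; exact ties (which arise only between
identical-geometry trees) are resolved by a coin flip from the stand
RNG. Pixel membership is decided at pixel centres; stems sit at
continuous coordinates; all displacements wrap toroidally so edge trees
are not released from competition.

Two light ratios are recorded per tree:

- **S** (uptake/suppression ratio, drives mortality and is the value
  reported in tree tables): won pixels plus a 9% transparency credit on
  the rest of the *maximal* crown footprint, divided by that footprint.
  The maximal crown is the allometric disc of radius ρ·dbh — exactly
  the radius the incremental growth rule integrates to when no
  neighbour interferes — so S is a continuous measure of how far
  competition has restricted the crown: 1 for a never-restricted tree,
  0.09 for a fully overtopped one.
- **S_growth** (drives the growth modifier): the same quantity measured
  against the tree's *current* plastic crown — the fraction of the
  crown it actually carries that is lit. An uncrowded canopy tree keeps
  S_growth ≈ 1 and grows at full speed even while its crown is smaller
  than its allometric potential.

Using a single ratio for both roles fails in either direction: measured
against the plastic crown, S saturates at 1 for every canopy tree
(next year's potential is last year's realized crown) and all crowding
signal is lost; measured against the allometric crown, growth stalls
stand-wide and released trees can never re-expand. The two-ratio
design keeps both phrases of the model's definition — light captured
relative to "the potential light absent competition", and growth driven
by "the fraction of the realized to the potential crown" — each where
it is mechanistically coherent.

After allocation each sector radius is reduced to its **realized**
value: a fan of 9 equally spaced rays per sector is walked outward in
pixel steps, a sample point counts as unshaded when the tree wins its
pixel or no competing claim exceeds the tree's own potential elevation
there, and the sector radius becomes the mean over rays of the farthest
unshaded distance (configurable to the more biased min or max), capped
at the potential radius. An isolated tree keeps its full crown exactly.
Radii are floored at sapling scale (ρ·3 cm ≈ 0.3 m): a living tree
retains a minimal branch skeleton, so full overtopping suppresses a
crown without erasing it — otherwise zero radius is an absorbing state
and the advance-regeneration bank (the engine of gap succession) cannot
exist. Subsequent growth adds ρ·Δdbh to the realized radii, which is
what makes gap refill gradual instead of instantaneous.

## Below-ground competition

Root systems are discs of radius α·dbh. A tree claims pixel water with
strength *s* = 1 − *x_r*/*d_r* (1 at the stem, 0 at the edge); the
pixel's content *c* is divided among claimants in proportion to their
strengths, and a tree's uptake *u* sums its shares over its disc.
Several systems may overlap the same pixel. The aridity index maps
linearly to *c* ∈ [0, 6] units per pixel. The water uptake ratio is
W = u / demand, clipped to [0, 1], where demand is the uptake the same
tree would achieve alone at the base content of one unit per pixel —
i.e. its disc's pixel count. (Normalising demand by the summed claim
strengths instead would make an isolated tree at c = 0.5 report W = 1,
contradicting the definition of W as realized over potential uptake.)
An optional variant weights claims by trunk diameter
(`claim_variant="distance_diameter"`); the default is distance-only,
since larger trees already claim more through larger extents.

## Growth, mortality, recruitment

Potential growth is PRI(d) = b₁·(1 − d/b₂) cm/yr by default (b₂ the
asymptotic dbh; a constant-increment variant PRI = b₁ is available).
Realized growth multiplies PRI by λ = S_growth·W (multiplicative) or
min(S_growth, W) (Liebig's law); both mechanisms are first-class and
the stand-level patterns are insensitive to the choice. dbh never
shrinks; age always increments.

Mortality draws one uniform variate per tree per year (id order):

- light limitation: P_L·(1 − S)^q with q = 5. The convex shape confines
  shade mortality to strongly suppressed trees: a fully overtopped tree
  dies at 0.62·P_L per year (preserving the 20:1 contrast of the
  tabulated understory rates, 20% pine vs 1% hemlock), while a
  moderately crowded canopy tree (S ≈ 0.5) faces only ~1/32 of P_L.
  q is the one genuinely free shape parameter of the model; it was
  calibrated so that crowding thins young shade-intolerant cohorts on
  the century timescale of the classic succession narrative — small q
  extinguishes the pioneer cohort within decades, binary understory
  rules never thin it — and it doubles as the source of canopy
  turnover, so no extra background mortality is needed
  (`background_mortality` defaults to 0 and is kept as an optional
  floor).
- water limitation: P_W = P_max·(1 − W), species-independent;
  P_max = 0.20 by default, configurable (published analyses of this
  system quote both 10% and 20%; all non-zero values behave alike).
- combination: additive, 1 − (1 − P_L)(1 − P_W), or capped,
  max(P_L, P_W); additive ≥ capped always. Default: capped, paired with
  multiplicative growth.

Recruitment adds Poisson(ν·area) saplings per year (ν = 40 ha⁻¹yr⁻¹) at
uniform positions, species drawn 50/50 between the prototypes (or from
a caller-supplied sampler, e.g. the species-continuum draw), dbh
uniform on [3, 5] cm, full live crown, sector radii ρ·dbh.

## Species parameterization

Two prototype conifers with contrasting shade tolerance:

| parameter | white pine | eastern hemlock | units | provenance |
|---|---|---|---|---|
| b₁ (potential increment) | 0.77134 | 0.3498 | cm/yr | published calibration |
| P_L (understory mortality) | 0.20 | 0.01 | 1/yr | published calibration |
| γ (crown profile exponent) | 0.5 | 0.5 | — | published calibration |
| tolerance rank ρ_t | 0 | 1 | — | definition |
| b₂ (asymptotic dbh) | 150 | 120 | cm | assumed |
| ρ (crown radius per dbh) | 0.1 | 0.1 | m/cm | assumed |
| α (root extent per dbh) | 0.07 | 0.07 | m/cm | assumed, calibrated |
| h_max (asymptotic height) | 40 | 30 | m | assumed |
| k (allometry curvature) | 0.03 | 0.03 | 1/cm | assumed |
| c_t (crown transparency) | 0.09 | 0.09 | — | published calibration |

Height follows 1.35 + (h_max − 1.35)(1 − e^(−k·dbh)); strictly
increasing, bounded by h_max, equal to breast height at dbh → 0.

The "assumed" constants are not published for this system; they were
fixed once from three structural requirements: pine outgrows hemlock at
full resources, adult crowns span several metres, and the stand can
reach a closed canopy under modest water supply. α is the sensitive
one: it sets the root-to-crown area ratio (≈ 0.5 here). Much larger α
makes below-ground competition kill the mesic understory bank and
pushes canopy closure far up the aridity axis; much smaller α removes
the suppression of understory re-initiation on intermediate soils.
α = 0.07 m/cm is the regime in which closure near aridity 0.2, a
thriving mesic bank, and its suppression on drier soils coexist.

`interpolate_species(alpha)` returns the componentwise linear blend of
the two prototype vectors (α = 1 → pine, α = 0 → hemlock by default;
the opposite orientation is a flag, since both conventions appear in
the literature), and `sample_alpha` draws blend coordinates by
polynomial mutation (Deb's operator, distribution index η_m = 5,
centres 0.05 and 0.95, clipped to [0, 1]).

## Stand metrics

- shade tolerance index: Σρ_t·ω_t / Σω_t with basal-area weights by
  default (count and a dbh^2.5 biomass proxy are alternatives; the
  three are rank-correlated on simulated stands). Undefined (NaN) on an
  empty stand.
- basal area by stratum, the canopy/understory split using the
  won-direct-light flag; the tolerant/intolerant guild split cuts
  tolerance rank at 0.5 and partitions the total exactly.
- canopy cover: fraction of pixels under ≥ 1 *maximal* (allometric)
  crown projection. Realized crowns tile the canopy without overlap, so
  their union is capped near 0.8 by the interstitial pores of any disc
  packing; the potential projections overlap and close over the pores,
  which is what "closed canopy" (cover ≥ 0.95, configurable threshold)
  means here.
- crown symmetry: min/max sector radius per tree, basal-area-weighted
  over canopy trees (an operationalization choice; the ratio is 1 for
  an isolated tree and falls with one-sided crowding).
- equilibrium summaries: mean ± sd of each metric over the second half
  of a run, (T/2, T].

Succession timing is read from 25-year centred rolling means of the two
guild basal-area series (raw series flip sign spuriously while the
first sapling cohorts establish): the crossover year is the first
smoothed year the tolerant guild exceeds the intolerant one after the
latter has led, and the stabilization year is the year after the last
smoothed deficit.

## Experiment scale

Full-scale runs (0.25 ha, 1500 yr) are available through the CLI but
the shipped experiments, tests and the acceptance script use reduced
stands chosen to keep a full reproduction within minutes on one CPU:

- succession timing: 30 × 30 m × 750 yr × 5 seeds in
  `scripts/acceptance.py` (≈ 2 min per seed); 20 × 20 m × 600 yr in the
  test suite.
- aridity sweeps: 20 × 20 m × 400 yr per grid point (script);
  20 × 20 m × 300 yr (tests).
- mechanism-robustness grid: 15 × 15 m × 250 yr per cell.

Plot size mainly adds replication, not new mechanisms: stands of
20-30 m already hold several hundred trees at mesic equilibrium.
Reduced plots make the takeover timing noisier and slightly earlier
than the 0.25-ha narrative (~80-110 yr median versus ~150), because a
handful of large pioneer deaths suffices to tip the basal-area balance.

## What the model does and does not emulate

The simulator itself is the data generator: all experiments start from
a bare plot under constant climate (fixed aridity), constant
recruitment pressure and two (or a continuum of) species. It captures
size-asymmetric light competition, symmetric but depletable water
sharing, crown plasticity, gap dynamics and demographic trade-offs. It
does not include seed dispersal or density-dependent fecundity,
inter-annual climate variability, soil heterogeneity or water dynamics
(recharge/depletion), browsing or pathogens, age-related senescence, or
crown recession (live-crown ratios stay at 1 after emergence: no rule
for bole formation is defined in this model family's published form).
Passing tests therefore demonstrate the internal logic of spatial
resource competition, not predictive skill for any real inventory.

## Numerical choices and degenerate inputs

- Pixel-centre sampling throughout (claims, root discs, cover); no
  area-weighting of boundary pixels.
- Toroidal wrap in every distance computation; windows are clipped to
  the plot size so wrapped indices never duplicate.
- Ray sampling of realized radii walks from the sector radius inward in
  pixel-sized steps; a 1e-9 m elevation tolerance treats a tree's own
  claim as unshaded.
- Empty stands are legal everywhere: allocation returns an all-ground
  map, metrics report 0 or NaN as documented, `equilibrium_summary`
  refuses series shorter than the requested horizon.
- Trees with all-zero sector radii cannot arise through the public
  operations (the sapling floor); `crown_symmetry` rejects them.
- Mortality uses one uniform draw per tree in id order; light
  tie-breaks consume RNG draws only when ties occur. Identical seeds
  give identical trajectories to the last bit; different tie histories
  cannot desynchronise replicate configurations because all draws come
  from the single stand stream.

## Known limitations

- The canopy-cover ceiling of realized crowns (pore geometry) means
  cover statistics depend on the potential-projection convention
  documented above.
- Succession timing at reduced plot scale is systematically earlier
  than the full-scale narrative (see "Experiment scale").
- In this implementation the mesic takeover, once it happens, is
  monotone: the stabilization year coincides with the crossover year
  rather than following a centuries-long mixed phase. The replacement
  phase is more decisive here than in larger-plot accounts of this
  system.
- The polynomial-mutation sampler and the blend orientation follow one
  printed convention; the orientation flag exists because the two
  conventions conflict in the source literature.
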