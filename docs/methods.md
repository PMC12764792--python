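# Methods

## Model structure

One replicate simulates overlapping generations of hermaphroditic perennial
plants on a bounded lattice.  Each generation executes, in order:

1. a fresh global seasonal factor *SV* ~ N(1, σ=10⁻³), applied
   multiplicatively to the three bioclimatic layers of every patch (one
   draw per generation, shared by all patches), and a refresh of every
   plant's environmental fitness *E*;
2. survival — a flat 10 %/cycle hazard plus certain death when the
   incremented age exceeds the individual lifespan cap;
3. reproduction — each survivor draws Binomial(cap(age), *E*) ovules with
   cap 3/6/10 at age 1/2/≥3; each ovule independently picks a pathway
   (outcross / self / apomictic by the bearer cytotype's rates), a pollen
   donor where needed, and gametes; dosage sums outside {2x, 3x, 4x} and
   aneuploid gametes abort, and seeds that are triploid or have a triploid
   parent survive with probability `triploid_seed_viability`;
4. dispersal and *simultaneous* settlement: landing distance is truncated
   exponential (mean `lambda_seed` = 1.5 patches, cut at 20), direction
   uniform, edges absorbing; a seed establishes only on a free patch within
   its cytotype's tolerance of every variable, and among contenders for one
   patch the highest prospective *E* wins (ties uniform);
5. lineage censuses of the logged polyploidization events and the
   establishment check (50 living tetraploids sharing a lineage tag).

Mortality precedes reproduction so the two-seed contention rule is well
defined on the patches vacated that generation.  Plants store "completed
cycles": recruits (and founders) enter at age 0, are incremented to 1 at
the start of their first full cycle, and therefore first reproduce with
the age-1 cap of 3.

### Fitness and tolerance

Per variable, *E*ᵢ = 2^(−|IAᵢ − Vᵢ·SV| / Limitᵢ): 1 at the optimum, 0.5 at
one tolerance limit, 0.25 at two.  The five components are combined as a
geometric mean (configurable to product or minimum); the geometric mean
keeps the combined *E* on the single-variable scale.  Establishment
additionally requires *every* per-variable deviation to lie within the
cytotype's limit — the "limit of ecological tolerance" acts as a hard range
boundary, which is what confines diploids to a bounded region and lets
broader-tolerance tetraploids colonise its margins.  Tetraploid limits are
the diploid limits times `limit_multiplier_4x`; triploids use the diploid
limits.  The lifespan cap is ⌈10·*E*(at establishment)⌉, reproducing both
stated facts (10-cycle life expectancy and maximal life at *E* = 1) with
one formula.

### Gametes, events, lineages

Gamete classes by cytotype: 2x → reduced x or unreduced 2x (the swept
rate, zero before the onset generation 200); 3x → {x: 0.25, 2x: 0.25,
unreduced 3x: 0.05, aneuploid: 0.45}; 4x → reduced 2x (unreduced 4x rate
0 by default).  Apomictic ovules carry an unreduced female gamete and
clone the mother.

A polyploidization event is **counted when the neo-cytotype seed
establishes** as a plant, not when it is formed.  This reading is forced by
the magnitudes of the reported response variables: at a 0.6 %
unreduced-gamete rate a replicate logs ~10² events over 1000 generations,
which matches the establishment rate of 3x/4x recruits (≈ 0.5 per
generation) and is ~40-fold below the rate at which such seeds are merely
formed.  Events are bilateral (both gametes unreduced) or unilateral
(exactly one).  A new lineage tag is minted only when neither parent is
tetraploid; matings involving an existing tetraploid propagate its tag
(maternal tag, falling back to paternal), so a growing tetraploid
neighbourhood reads as one lineage rather than a dust of singletons.  SPE
requires 50 *living* tetraploids with one tag; pending events finalize to
UPE at the stop.  GPIP is taken from the earliest-established SPE of the
run: its establishment generation minus its formation generation.

### Triploid seed viability

The default `triploid_seed_viability = 0.1` was calibrated once against
the reported response-variable structure, as the configuration's own open
calibration knob: the printed bilateral:unilateral ratios are consistent
across treatment rows with a viability near 0.11, and with 0.1 the sweep
reproduces the qualitative pattern (no successful events at ≤ 5 %
unreduced gametes, rare successes at 10 %, fixation with SPE ≈ 9 at 20 %).
At 0.3 the triploid bridge is strong enough to drive near-fixation at 10 %,
contradicting the reported rarity.

## The synthetic landscape

The generator emulates the structure of the cropped real-world raster
stack the model is designed for: three near-uniform bioclimatic layers
(relative spatial sd < 1 %) and two soil layers whose heterogeneity bounds
the occupiable area.  Soil layers are the sum of (a) a smoothed Gaussian
random field (sd 5 and 3 units, correlation length 12 patches) giving
local patchiness, and (b) a fixed radial *basin* term rising as
`basin_amplitude·(r/50)²` from the grid center (amplitudes 40 and 24
units).  Purely stationary random fields proved structurally wrong here:
either the population surfs shallow gradients to the grid edge or the
landscape fragments into look-alike blobs far from the founder area — both
destroy the bounded central range on which the niche-shift experiments
rest.  The basin gives one connected central range (diploid maximum range
≈ 15 % of the grid, realized census ≈ 900–1400 at quasi-equilibrium,
matching the ~1000-plant scale of the reference comparison) with margins
where diploid suitability decays — which is where broader-tolerance or
shifted-optimum tetraploids establish.  The landscape is a fixed model
input: one environment seed (0, a package constant) is shared by all
replicates, as with a real raster stack; run-to-run stochasticity comes
from the demographic seed.

What the generator does **not** emulate: multimodal or anisotropic real
terrain, correlations between soil variables, and any geographic meaning
of the units.  Passing sweeps on this landscape show the model's dynamics
are right, not that any particular real landscape behaves identically.

## Experiment families

All sweeps share the baseline: 0.6 % unreduced gametes, outcrossing,
self-sterile plants, tolerance multiplier 1.  Treatments: the
unreduced-gamete rate; tetraploid selfing; tetraploid apomixis; mixed
mating (apomictic ovule fraction = level, the remainder selfing — the
reported flat response across levels with strong success already at 10 %
is only attainable when tetraploid bearers never depend on outcross
pollen); the tetraploid tolerance multiplier (all plants self-sterile);
and the shifted optimum — 30 patches at the configured distance (ring ± 2
patches around the founder centroid), each new tetraploid founder adopting
the V-values of one of them before settlement, with tetraploid selfing
assurance (a lone shifted founder could never mate otherwise; the low GPIP
and stable coexistence this family exhibits require it).

Statistics: per-level mean ± sd; one-way ANOVA and all-pairs Tukey HSD at
α = 0.01 (statsmodels), with a deterministic insert-and-absorb compact
letter display over the sorted means; first-SPE density maps as per-patch
count grids with the maximum-diploid-range contour (union of founder-area
suitabilities); establishment efficiency = mean final 4x proportion / mean
SPE, undefined at zero SPE.

## The deterministic baseline

The gametic recursion with inviable triploids: diploids contribute x
gametes (1−p) and 2x gametes (p), tetraploids 2x gametes weighted by
relative fertility f; random union; 3x offspring die; 4x offspring are
weighted by relative viability v.  The interior (mixed) fixed point solves
v·f²τ² + (2vfp − (1−p)²)τ + vp² = 0 for τ = t/d and exists only while the
discriminant is positive, giving closed-form exclusion thresholds
p* = 3 − 2√2 ≈ 17.16 % (f = v = 1) and p* = 9 − 4√5 ≈ 5.57 % (f = v = 2),
used as independent oracles for the bisection implementation.  The
`felber_config` preset runs the spatial model under equivalent conditions:
uniform environment (all layers flat, *E* = 1), triploid viability 0,
distance-free pollen donor choice, a 32 × 32 grid (≈ 1000 patches, the
census scale of the comparison), onset at generation 50 and a
500-generation post-onset horizon.  The agent-based threshold is the
smallest scanned rate at which diploids go extinct in a majority of
replicates.

## Numerical and implementation notes

- Population state is structure-of-arrays; every step is vectorized
  (~5 ms/generation at a 1000-plant census), so full sweeps run on one CPU.
- Pollen donors are drawn by kernel-proposal rejection (propose a
  displacement from the exponential kernel, accept if occupied) with an
  exact window-weighted fallback for sparse neighbourhoods after 8 rounds —
  the sampled law is exactly the truncated exponential over occupied
  patches in both branches; isolated mothers abort (pollen limitation).
- One RNG stream per replicate in fixed program order: identical (config,
  seed) pairs give bitwise-identical summaries and event logs.
- Settlement ties are broken uniformly at random *inside* the same stream;
  contention is resolved simultaneously after all seeds disperse.
- Raster input is deliberately plain: single-band TIFF or CSV layers, crop
  windows in pixel coordinates, node-based bilinear resampling
  (corner-preserving); nodata becomes NaN and forces *E* = 0 / unsuitable.
  No CRS handling or reprojection.
- Degenerate inputs: zero founders stop a run immediately with a zeroed
  summary ("extinct"); an all-occupied grid settles nothing; zero-variance
  treatment groups with equal means share one Tukey letter.

## Problem sizes

Test-suite sweep batches use 6–16 replicates per level and the acceptance
script 5–20 (vs 1000 in the full study); the agent-based exclusion scan
uses 0.5-percentage-point steps with 5 replicates per step.  These sizes
resolve the qualitative treatment structure and the threshold to the
precision claimed; means of strongly overdispersed responses (e.g. SPE at
a 10 % unreduced-gamete rate) carry correspondingly wide errors at this
scale.

## Known limitations

- No gene-level genetics: IA is a quantitative trait with midparent
  inheritance (segregation noise available but 0 by default), no drift,
  mutation, or inbreeding depression.
- The triploid block is a single scalar viability; no endosperm-dosage
  mechanism, no pollen competition beyond distance weighting, no seed bank
  or secondary dispersal.
- Cytotypes above 4x are treated as inviable.
- The homogeneous-environment mode (`uniform_e`) clamps *E* but keeps
  age-scaled fecundity; whether fertility should stay age-structured there
  is a modelling choice, made here for comparability with the
  heterogeneous runs.
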