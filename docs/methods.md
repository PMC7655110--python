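# Methods

## The residency model

The central object is a chromosome carrying `n` CARs (cohesin associated
regions) at positions `x_1 < … < x_n`, each with a latent occupancy
probability `p_i ∈ [0, 1]`: the chance that CAR *i* carries stably bound
cohesin in any one cell. The model's assumptions, stated explicitly:

- occupancy is independent across CARs and across cells;
- loop-extruding cohesin halts only at *occupied* CARs, so each cell's loops
  connect consecutive occupied CARs (the default "consecutive" mode);
- the looping pool and the CAR-bound pool are distinct — forming a loop does
  not deplete occupancy anywhere;
- one chromosome per simulation; multi-chromosome studies are loops over
  independent maps.

Under these rules, uniform occupancy `p` gives the span law
`P(span = k) ∝ (n − k) p² (1 − p)^(k−1)` (the `n − k` factor is the
finite-chain edge correction; the infinite-chain law is the truncated
geometric). The unit tests verify the simulator against exhaustive `2^12`
enumeration of occupancy patterns, and `enumerate_consecutive_spans` exposes
that enumeration for n ≤ 20.

The **extruder mode** makes the machinery explicit: each extruder loads at a
random position, grows symmetrically, halts per side at the first occupied
CAR (or chromosome end), and stops when the total extruded length reaches its
processivity budget. Anchors that halted at an occupied CAR are *positioned*;
others are *unpositioned*. Extruders neither collide nor stall at unoccupied
CARs. By default loading is uniform and every extruder gets the same budget
(50 kb), with one extruder per 30 kb of chromosome — an order-of-magnitude
choice that makes wild-type extruder looping adjacent-dominated, matching the
consecutive mode.

### Occupancy distribution

Default occupancies are drawn from a two-class "residency mixture": nine of
every ten CARs from a Beta-shaped bulk confined to [0.05, 0.8] (mean ≈ 0.44)
and exactly one in ten from a high-residency class uniform on [0.88, 0.98];
the overall mean is ≈ 0.5. The two classes mirror the heavy-tailed cohesin
ChIP peak-height distribution in which the top decile — the high-residency
CARs that act as barriers and domain boundaries — stands clearly apart from
the bulk. A plain `Beta(a, b)` remains available
(`occupancy_shape=(a, b)`); note that with a unimodal Beta the top decile is
*not* separated from the next decile, and boundary-precision properties that
depend on that separation degrade accordingly.

### Scenarios

| name | occupancy transform | extruder overrides |
|------|--------------------|--------------------|
| WT, BRN1 | identity | — |
| MCD1 | all 0 | — |
| WPL1 | × 0.5 | — |
| PDS5 | arms (> 30 kb from centromere) × 0.05; pericentric × 0.7; centromeric CAR unchanged | processivity × 10, exponential budgets, centromeric loading |

The PDS5 extruder overrides are the one place the base extruder defaults are
deliberately changed, because the phenotype demands it: with a *fixed*
budget, every unpositioned end lands at a constant distance from its halt
point and the "stripe" degenerates to a spot, so PDS5 budgets are drawn
exponentially (constant detachment rate) with mean 10× the wild-type
processivity; and with *uniform* loading the whole map fills with long loops
and the centromere row is not enriched over the map's own distance
expectation, so PDS5 extruders load Gaussian-distributed around the
centromere (σ = 5 kb), modeling extrusion emanating from the centromere.
Base-mode extrusion keeps fixed budgets and uniform loading.

Loop frequency is defined as the fraction of *cells* containing a given
anchor pair (duplicates within one cell count once), which keeps frequencies
in (0, 1] even when many centromere-loaded extruders form the same pair.

## The emulated ChIP track

Each CAR contributes a Gaussian bump with FWHM 1 kb (the observed mean peak
width) whose area equals `peak_gain × p_i`, on top of per-bin Poisson
background of mean `depth` (default 2 per 100 bp bin). Peak calling is a
smoothed threshold-and-local-maximum detector (3-bin moving average; greedy
acceptance from the highest summit with ≥ 2 kb separation; ties to the
leftmost; width = span above half height). `chip_calibration` computes the
expected smoothed peak height per unit occupancy for the exact binning and
smoothing used, so `estimate_occupancy` inverts peak heights back to
occupancy; the linear height↔occupancy mapping is a modeling assumption, not
an observed calibration. Round-trip recovery achieves RMSE < 0.01 noise-free
and < 0.05 at the default noise.

## Rendering contact maps

The expected matrix is

```
E(i,j) = B(i,j) · [1 + domain_weight · Σ_{loops ∋ (i,j)} f_loop]
         + focal_weight · Σ_loops f_loop · G2(i,j; anchors, σ)
```

with background `B ∝ (s + s0)^(−α)` (α = 1, s0 = 1 kb — a yeast-like decay;
the exponent is config-exposed, not fitted), `G2` a unit-mass 2-D Gaussian at
the loop's anchor pair with σ = 500 bp (≈ 91% of spot mass within ±1 kb, the
observed anchor confinement), and the domain term a multiplicative boost of
the background over the intra-loop square ("uniform boost" interpreted as a
uniform *fraction* of the local background, so domains keep a realistic decay
rather than a flat plateau). Unpositioned loops contribute focal mass at
their recorded coordinates with weight 1/n_cells. Counts are Poisson-sampled
on the upper triangle (total = `total_reads`, default 2×10⁷ — the intra
contact count a deeply sequenced nucleosome-resolution experiment would
allocate to a 750 kb chromosome) and mirrored; `noise=False` returns the
expected matrix for oracle tests.

`focal_weight` (0.002 reads-fraction per unit loop frequency) and
`domain_weight` (0.3) are free rendering parameters with no measured
counterpart; they were calibrated once against the package's qualitative
acceptance properties (planted-loop recovery, boundary/high-residency
correspondence) and then frozen.

## Matrix statistics

- **ICE balancing**: multiplicative per-bin weights equalizing row sums;
  bins with zero coverage or below the 0.02 quantile of nonzero coverage are
  blocked (NaN weight). Converges to row-sum CV < 1e−6 on dense matrices;
  non-convergence is recorded in `balance_info`, not raised.
- **O/E**: each entry over its diagonal mean; empty diagonals give NaN.
- **Decay curves**: distances binned into exponentially widening bins
  (100 bp – 1 Mb, 8 per decade); contacts under 100 bp are discarded. The
  curve stores both the mass fraction per bin (sums to 1) and the density
  (mass / bin width), whose log-log slope is the decay exponent; sliding
  5-bin least-squares slopes give the slope track. (The normalized-mass and
  density views are kept separate because "sums to one" and "divided by bin
  width" cannot hold for a single vector.)
- **Pile-ups (APA)**: mean of O/E sub-matrices at anchor pairs, ±5 kb at
  200 bp (51×51); pairs closer to the diagonal than the half-width, or whose
  window leaves the matrix, are dropped and counted. The enrichment ratio is
  the single center pixel over the mean of the four 14² corner blocks flush
  with the window corners (a 3×3 center mean is available, default off).
  Peak-pair operations cap separations at 100 kb.
- **Loop caller**: donut filter. Local expectation = ring mean of O/E
  (Chebyshev radii 2–5, same-row/column cross excluded) × diagonal
  expectation; Poisson tail p-values (continuous gamma form, so expected-value
  matrices work) are BH-corrected across all band pixels (5–100 kb) at
  FDR 0.1; calls additionally need fold ≥ 2, and connected clusters of
  significant pixels merge to their strongest pixel. Clusters below
  `min_cluster = 2` pixels are discarded: a genuine anchor spot (σ = 500 bp ≈
  2.5 bins) always spans several pixels, while Poisson speckle is almost
  always a single pixel — without this the BH step, whose threshold adapts to
  the thousands of true spot pixels, admits hundreds of one-pixel false calls.
- **Insulation**: sliding-diamond sum of balanced contacts at 2 kb bins; the
  15 kb search window is rounded to whole bins (8 bins = 16 kb, since 15 kb
  is not a multiple of 2 kb). Scores are log2 of the raw score over the
  genome-wide mean; boundaries are local minima with prominence ≥ 0.4 (log2
  units). The prominence default was calibrated together with the render
  weights: every CAR insulates somewhat in this model, so a permissive
  cutoff (e.g. 0.1) marks a dip at nearly every CAR, while 0.4 retains the
  deep minima, which sit at high-residency CARs ~9 times in 10.
- **ADA**: every contact with both loci inside a domain (plus 0.5
  domain-length flanks per side) maps to rescaled coordinates
  `N = (C − D_start)/(D_end − D_start)` on a pseudo grid (30 bins per domain
  length); a domain whose length equals the pseudo-size reproduces its
  sub-matrix exactly (flank 0).

## Study conditions and problem sizes

The standard desk scale is one 750 kb chromosome with 90 CARs (median
spacing 8 kb, log-normal σ = 0.45 clipped to [3, 40] kb), centromere at
375 kb, 3,000 cells, 200 bp bins and 2×10⁷ reads — matrices are 3,750²
dense arrays, chosen so the full study runs in minutes on one CPU. The
span-law checks use 200 CARs × 10,000 cells; occupancy-recovery checks use
5,000 cells. Loop-frequency-based occupancy recovery uses √(adjacent-pair
frequency), which identifies per-CAR occupancy exactly under homogeneous
occupancy (adjacent-pair frequency is `p_i p_{i+1}`); the recovery experiment
therefore runs on a uniform-occupancy chromosome.

## What the generator does and does not emulate

It emulates: CAR spacing statistics, occupancy-graded ChIP peaks, focal
anchor spots and loop-domain squares over a distance-decay background,
count noise, low-coverage masking, and depletion phenotypes. It does not
emulate: read-level artifacts (ligation orientation, mappability structure,
GC bias), replication/cohesion, condensin, the rDNA locus, cell-cycle
dynamics, trans contacts, or correlated occupancy between neighboring CARs.
Passing tests therefore validate the statistics' implementations and the
model's internal consistency — not agreement with any real dataset.

## Known limitations

- Under the PDS5 occupancy transform, pericentric CARs retain 0.7× occupancy
  and intercept most extruding sides within 30 kb of the centromere: ~95% of
  positioned anchors fall in the centromeric/pericentric *region*, but only
  ~65–75% at the single centromeric CAR, and the contiguous high-O/E stripe
  along the centromere row is tens of kilobases at the default read depth
  (the stripe also competes against its own contribution to the per-diagonal
  expected value, since in this scenario essentially all long-range signal is
  centromere-anchored).
- The caller detects every loop whose focal spot clears Poisson noise; at the
  default depth this includes +2…+5 CAR loops, so the distinct-call span
  median exceeds the adjacent-peak interval median even though the
  frequency-weighted population span distribution is adjacent-dominated.
- ICE is the only balancing method (no KR), and matrices are dense — fine at
  desk scale, not for whole genomes.
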