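# carloops

A generative model of cohesin-dependent loop organization on mitotic budding-yeast
chromosomes, with the Micro-C-style contact-map statistics needed to analyze it.

In mitotic yeast, cohesin accumulates at discrete loci called **CARs** (cohesin
associated regions), spaced ~8 kb apart, and holds together **positioned loops**
whose anchors coincide with CARs. The height of a cohesin ChIP-seq peak at a CAR
reflects the probability `p_i` that the CAR is stably occupied by cohesin in any
one cell. `carloops` turns that residency model into a testable simulator:

1. **Per-cell occupancy** — in each cell, CAR *i* is occupied independently with
   probability `p_i`.
2. **Loop formation** — loop-extruding cohesin stops only at occupied CARs, so a
   loop forms between every pair of *consecutive occupied* CARs. In cells where
   an intermediate CAR is cohesin-free, the loop expands past it. For uniform
   occupancy `p` this yields the geometric span law
   `P(span = k) ∝ p²(1-p)^(k-1)` in CAR intervals. An explicit extruder mode
   (finite processivity, per-side halting) adds the unpositioned anchors needed
   for centromeric stripes.
3. **Population contact map** — loops aggregate over thousands of cells into a
   loop→frequency table, rendered as a binned contact matrix: power-law
   distance-decay background, a focal Gaussian spot at each anchor pair
   (confined within ~1 kb), and a "loop domain" square inside each loop.

On top of the simulator sit the standard map statistics: ICE matrix balancing,
observed-over-expected normalization, contact-decay curves with sliding log-log
slopes, aggregate peak analysis (pile-ups with a center-over-corner enrichment
ratio), a donut-filter loop caller with Poisson/Benjamini–Hochberg statistics,
sliding-diamond insulation scores with boundary calling, and aggregate domain
analysis (ADA) with pseudo-size rescaling.

Named scenarios emulate protein depletions: `WT` and `BRN1` (condensin; loops
unaffected), `MCD1` (cohesin loss — no loops), `WPL1` (half occupancy — loop
expansion), `PDS5` (arm depletion with pericentric retention — centromeric
stripes).

## Worked example

```python
import carloops as cl

car_map = cl.build_car_map(n_cars=90, chrom_length=750_000,
                           centromere=375_000, seed=1)
pop = cl.simulate_population(car_map, n_cells=3_000, seed=2)
mat = cl.ice_balance(cl.render_map(pop, car_map, cl.RenderParams(seed=3)))
calls = cl.call_loops(mat)
print(calls.n_loops)
```

The numbered drivers under `analysis/` run the full study; on seed 1 they print:

```
built 90 CARs, median spacing 7309 bp (target 8 kb)
called 90 ChIP peaks, mean width 1062 bp (~1 kb)
occupancy recovered from peak heights with RMSE 0.008
WT   :  803 distinct loops, mean span 2.22 CAR intervals
WPL1 : 1696 distinct loops, mean span 4.37 CAR intervals
called loops:      WT 491  ->  WPL1 754 (more loops on Wpl1 depletion)
pile-up reach:     WT +7 -> WPL1 +10 CAR intervals (expansion)
anchor-CAR overlap (WT): 98.9%
barrier contrast:  across high-residency 1.17 vs 7.16 without
boundaries at high-residency CARs: 30/34 (88.2%)
```

Reading the numbers: ChIP peak heights invert back to the latent occupancies
(RMSE < 1%); halving occupancy (Wpl1 depletion) roughly doubles the mean loop
span and the number of called loops, and loop signal reaches +10 instead of +7
CAR intervals; +2-CAR loops that must cross a high-residency CAR are ~6× weaker
than those that do not (high-residency CARs are barriers); and insulation-score
domain boundaries sit at high-residency CARs almost 9 times out of 10.

A CLI mirrors the library (`carloops simulate|render|decay|pileup|
interval-series|barrier|call-loops|insulation|ada|run --scenario WT`).

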