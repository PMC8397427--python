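# capsidperc

Percolation analysis of icosahedral virus capsid bond networks:
fragmentation thresholds and fragment-size distributions for the
triangular, rhombic and kite capsid tilings.

## The problem

Virus-like particles (VLPs) are repurposed capsids used for cargo
delivery, storage, catalysis and vaccination.  "Breadboard" strategies
remove and replace protein subunits, so a VLP's usefulness is bounded by
how many subunits can be removed before the shell falls apart.  That
limit is set by the *topology* of the intersubunit bond network, which
depends on the capsid's tiling geometry.

An icosahedral capsid with Caspar–Klug triangulation number
`T = h² + hk + k²` is built from `60T` protein subunits.  Three
homogeneous tilings realise this stoichiometry: `20T` triangular tiles
(trivalent contacts, `30T` bonds), `30T` rhombic dimer tiles
(tetravalent, `60T` bonds), and — at `T = 3` only — 60 kite tiles
(tetravalent, 120 bonds).  The bond network is the dual tiling: one
vertex per tile, one edge per intertile interface.

`capsidperc` builds these networks combinatorially (exact integer
gluing of the icosahedral lattice, no floating point), perforates them
by uniform random removal of exactly `i` subunits (site percolation) or
breakage of exactly `j` bonds (bond percolation), and estimates

* `P_con(f)` — the probability that *all* surviving subunits remain one
  connected component after deleting a fraction `f` (a dissociated
  singlet counts as fragmentation), estimated by Monte Carlo with
  binomial standard errors;
* the **fragmentation threshold** `f_T` (subunits) or `f_T^e` (bonds) —
  the deleted fraction at which `P_con = 0.5`, located by isotonic
  regression and linear interpolation on the integer removal grid;
* **fragment-size distributions** (PDF/CDF of connected-component
  sizes) under fixed or normally distributed removal fractions;
* the exact expected surviving-bond fraction
  `p_E = R(R−1)/(V(V−1))`, `R = p_V·V`, valency-free for every simple
  graph.

Benchmark results: the three `T = 3` architectures fragment at
`f_T = (0.226, 0.331, 0.278)` for (triangular, kite, rhombic) — the
kite tiling is the most robust and the triangular the most fragile —
and the `T = 4` rhombic architecture (hepatitis B virus) fragments at
~26% subunit removal, matching charge-detection mass-spectrometry
disassembly experiments.  Thresholds fall as `T` grows within each
family.

## Worked example

```python
from capsidperc import PercolationModel

model = PercolationModel.from_tiling("rhombic", 2, 0)   # T=4, the HBV architecture
res = model.fit(replicates=100_000, seed=1)
print(res.summary())

dist = res.fragment_distribution(f=0.20, sd=0.02, replicates=100_000, seed=1)
print("mass in fragments of >= 90 subunits at 20% removal:",
      round(dist.mass_at_least(90), 4))
```

prints

```
Capsid percolation results
==========================
network:    rhombic T=4: 120 tiles, 240 contacts, valency 4
mode:       vertex removal
grid:       counts 25..37 of 120
replicates: 100000 per grid point
seed:       1
threshold:  f_T = 0.2598 +/- 0.0002 (bracket 31..32)

mass in fragments of >= 90 subunits at 20% removal: 0.8076
```

Reading: the 120-tile T=4 rhombic network stays connected until about
26% of its tiles are deleted (`P_con` crosses 0.5 between removal
counts 31 and 32), and at 20% removal — below the threshold — 81% of
fragment mass still sits in near-complete shells of ≥ 90 tiles.
`res.plot()` draws the sigmoidal `P_con` curve with the threshold
gridline.

The same analysis is available from the shell:

```sh
capsidperc build --family rhombic --h 2 --k 0 --out t4.edgelist
capsidperc threshold --family rhombic --h 2 --k 0 --mode vertex \
    --reps 100000 --seed 1 --out t4_threshold.json
capsidperc table1 --reps 100000 --seed 1 --out comparison.csv
```

`percolate` writes P_con curves as CSV, `fragments` writes
fragment-size PDFs/CDFs, and any subcommand accepts `--graph` to
analyse a user-supplied edge list or GraphML network instead of a
built-in tiling.

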