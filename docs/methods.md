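# Methods

## The model

An icosahedral capsid is modelled purely topologically, as the graph of
its tiling's intersubunit contacts.  For a Caspar–Klug triangulation
number `T = h² + hk + k²` the package builds the deltahedron — the
icosahedral triangulation with `10T + 2` vertices, `30T` edges and `20T`
triangular facets — and derives from it the bond networks of the three
homogeneous capsid tilings:

| family     | tiles              | valency k₀ | contacts | construction                      |
|------------|--------------------|------------|----------|-----------------------------------|
| triangular | 20T                | 3          | 30T      | facet-adjacency graph             |
| rhombic    | 30T                | 4          | 60T      | medial graph (tiles on edges)     |
| kite       | 60 (T = 3 only)    | 4          | 120      | vertex–facet incidences of the icosahedron |

Disassembly is random, uniform and memoryless: a perforated capsid
missing exactly `i` tiles is a uniform draw among all `C(V₀, i)` subsets
(site percolation); random bond breakage removes exactly `j` of the `E₀`
contacts while retaining every tile (bond percolation).  The observable
is `P_con`, the probability that *all* surviving tiles form a single
connected component — a dissociated singlet already counts as
fragmentation, which is what single-particle mass-spectrometry
disassembly experiments resolve.  The fragmentation threshold `f_T`
(subunit removal) or `f_T^e` (bond breakage) is the deleted fraction at
which `P_con = 0.5`.

Assumptions worth stating: no energetics, kinetics or conformer
specificity — all contacts are equivalent and removal is uncorrelated;
the networks are purely combinatorial (no 3-D geometry); the ensemble is
exact-count (hypergeometric), not Bernoulli thinning.

## Network construction

The deltahedron is built with integer arithmetic only.  Each of the 20
icosahedron faces is a chart in the triangular lattice, written in
Eisenstein coordinates `(u, v) ≡ u + vω`, `ω = e^{iπ/3}`, and scaled by
`h + kω`.  The charts are laid out as the classic planar net; the cut
edges of the net are glued by the exact lattice isometries (rotations by
multiples of 60° plus translations) determined by matching the shared
edge endpoints.  Chart-straddling lattice edges are developed from any
chart their segment overlaps in positive length — an exact rational
test — and lattice points are identified across charts by union-find.
Cone points (the twelve 5-fold vertices) need no special casing beyond
this rule, because a positive-length overlap licences a single-valued
development while a touch at a single point does not.  Facets are
recovered as the 3-cliques of the resulting skeleton.  Every build is
audited against the closed forms (`10T+2 / 30T / 20T`, twelve degree-5
vertices, two facets per edge, Euler characteristic 2), so a
construction defect cannot pass silently.  Chiral lattices (`h ≠ k`,
both nonzero) are handled identically; `(h, k)` and `(k, h)` produce
isomorphic networks and are canonicalised to `h ≥ k`.

The kite network is defined only at T = 3: its tiles are the 60
vertex–facet incidences of the icosahedron, adjacent within a facet and
around a shared 5-fold vertex.  The generalisation of kite tilings to
larger T belongs to a different (3.4.6.4-lattice) construction and is
out of scope; other T values are rejected explicitly.

## Monte Carlo protocol

`P_con` at each removal count is the fraction of independent replicates
whose surviving network is connected, with binomial standard error
`sqrt(p(1−p)/n)`.  Connectivity per replicate is incremental union-find
with path halving over the surviving edges, O(E·α(V)); the kernels are
numba-compiled and handle ~10⁵ replicates per second per hundred edges.
A deliberately independent traversal-based connectivity check
(networkx) backs the object-level API and is cross-checked against the
union-find route on a thousand random states in the test suite.

Randomness: one master seed; per-grid-point substream seeds are derived
through `numpy.random.SeedSequence`, so curves are reproducible
bit-for-bit and independent of evaluation order.

Threshold localisation is two-pass.  A coarse strided scan (3,000
replicates per point, stride `max(1, N/40)`) is isotonic-regressed and
interpolated to centre the fine window; the integer-complete
neighbourhood (±6 counts, widened automatically if the crossing escapes
it) is then re-estimated at the full replicate count (default 100,000),
isotonic-regressed (P_con is non-increasing through the transition), and
the crossing is linearly interpolated between the two bracketing integer
counts.  The interpolation error is below one count (`< 1/V₀`), smaller
than the Monte Carlo noise at 10⁵ replicates; the quoted standard error
propagates the bracket estimates' binomial errors by the delta method.
Exhaustive subset enumeration (`enumerate_pcon_exact`, capped at 2×10⁶
subsets) and a catalogue of closed forms on cycles, paths, stars and
complete graphs provide exact oracles for every stochastic path.

## Fragment-size distributions

Per replicate a deleted fraction is either fixed or drawn from
Normal(f, σ) truncated to [0, 1] — the spread a titrated-denaturant
disassembly produces — converted to an integer count by
round-half-to-even, and the sizes of all connected components are
accumulated into unit-width (integer) bins.  Vertex mode excludes the
removed subunits from the distribution; bond mode accounts for every
subunit, so singletons appear as size-1 fragments.  The default σ is
0.02 (configurable); the PDF is normalised over fragments, its CDF
reaches 1 at size V₀.

The exact expected surviving-bond fraction under subunit removal is
`p_E = R(R−1) / (V(V−1))` with `R = p_V · V` surviving subunits — the
probability that both endpoints of an edge survive a uniform
exact-count draw.  It is valency-free and graph-independent, and is
validated against empirical means on every network in the tests.

## Conventions and degenerate inputs

* States with ≤ 1 surviving vertex count as connected.  The thresholds
  sit at deleted fractions ≤ 0.35, far from this regime, so the
  convention is observationally irrelevant but fixed for determinism.
* Exact `P_con` is non-increasing only while a macroscopic survivor set
  remains; near full depletion it rebounds (tiny survivor sets are
  connected whenever contiguous).  The property tests therefore assert
  monotonicity for counts up to half the vertices, which contains every
  threshold.
* A curve that never crosses 0.5 (complete graphs; truncated grids)
  yields an explicit no-threshold outcome (`NoThresholdError`, CLI exit
  code 3), never a number.
* Planar-lattice reference thresholds `p_c ≈ (0.303, 0.378, 0.347)` and
  `p_c^e = (0.347, 0.475, 0.476)` for (triangular, kite, rhombic) are
  stored literature constants for comparison, never recomputed.

## Problem sizes and defaults

Default 100,000 replicates per grid point near the crossing (the
published protocol); fragment distributions default to 10⁶ replicates —
the published distributions used typically 10⁷, and the default is an
order of magnitude lighter for desk use while leaving the PDF noise well
below visual resolution; both are overridable.  The family comparison
spans T ∈ {1, 3, 4, 7, 9, 12, 27, 36} for triangular and rhombic
tilings (up to 1,080 tiles / 2,160 bonds at T = 36 rhombic) plus the
T = 3 kite tiling.

## Known limitations

* Correlated, targeted or energy-weighted removal is not modelled; only
  uniform random perforation.
* The kite family exists here only at T = 3.
* The simulator reproduces the published subunit thresholds and almost
  all published bond thresholds to a few thousandths.  The two published
  T = 3 bond-threshold sets disagree with each other — (0.228, 0.344,
  0.297) tabulated versus (0.208, 0.318, 0.288) in text for
  (triangular, kite, rhombic) — and this protocol reproduces the latter
  set essentially exactly, so the tabulated T = 3 bond values for the
  triangular and kite tilings are not reproducible under the stated
  definitions (see the acceptance tests for which cells agree).
* Finite-size scaling to infinite-lattice percolation thresholds, and
  sigmoid fitting of P_con curves, are out of scope (interpolation
  only).
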