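# Methods

## Model and procedure

The package treats each brain region's time course as a point in an
n-dimensional space and studies the shape of the resulting point cloud
through persistent homology. The per-subject procedure is:

**Correlation distance.** For time courses X, Y of equal length with
Pearson correlation r, the default distance is

    d(X, Y) = sqrt((1 − r) / 2).

This maps r ∈ [−1, 1] onto [0, 1] and is a true metric: it equals the
Euclidean distance between the z-scored signals scaled by 1/sqrt(2n), so
the triangle inequality holds exactly and the Vietoris–Rips construction
operates on a genuine metric space. The non-square-root variant
(1 − r)/2 is available (`form="half"`) for sensitivity analyses; it is
not a metric but induces the same filtration order of edges, hence the
same barcode up to the monotone rescaling ε ↦ ε². r is clamped to
[−1, 1] before the square root so floating-point round-off cannot
produce NaN. Pearson invariance makes the distance — and therefore the
entire analysis — invariant to affine rescaling of any signal (positive
gain), to global additive offsets, and to one shared permutation of time
points applied to all signals.

**Vietoris–Rips filtration.** Vertices enter at ε = 0, an edge {i, j} at
d(i, j), and a triangle at the value of its longest edge. The filtration
is built to dimension 2 with no ε cutoff by default: for n = 64 regions
that is C(64,3) = 41 664 triangles, well within interactive time, and
truncating the filtration could censor loop deaths. Simplices are
totally ordered by (value, dimension, lexicographic vertex tuple); the
fixed tie-break makes every downstream output deterministic.

**Persistence over GF(2).** The barcode is computed by the standard
left-to-right column reduction of the boundary matrix with coefficients
in the two-element field (columns stored as integer bitmasks; addition is
XOR). The boundary matrix is block-diagonal by dimension, so dimensions
are reduced independently in the global order. H0 yields n bars born at
0, of which exactly one is essential for a connected input; H1 bars pair
a creator edge (birth) with the triangle whose reduced column kills the
class (death). On a full filtration no H1 bar is essential, because at
ε = max d the complex is the complete 2-skeleton, which is simply
connected for n ≥ 3. Plain reduction with bitmask columns runs in well
under a second at n = 64, so no clearing/twist or cohomology
optimization is used.

**Representative cycles.** For each finite H1 bar the reduced column of
its death triangle is retained: a GF(2) cycle (every vertex has even
degree) containing the birth edge. This choice is well defined by the
fixed reduction order, but two caveats are documented deliberately:

* it is *not* guaranteed to be the shortest cycle in its class — an
  optional greedy pass (`tighten_cycle`, off by default) XORs in
  boundaries of triangles present before the death until the edge count
  stops shrinking;
* when several triangles share an entry value (structurally common:
  every triangle ties its own longest edge, and all cofacet triangles of
  an edge that enter at that edge's value tie each other), the reduced
  column depends on the lexicographic order, so under vertex relabeling
  the representative is reproducible only *up to homology at the death
  scale*. The test suite checks exactly that invariant with an
  independent GF(2) rank computation.

**Zero-persistence bars.** Bars with death = birth (a hole filled the
instant it forms, e.g. the three edges and the triangle of an
equilateral triple arriving together) are discarded from reported
barcodes but can be retained (`keep_zero_bars=True`); Betti-number
curves are computed from the retained set so that counts agree exactly
with rank–nullity of the sublevel complex at every ε.

**Longest-loop selection.** The subject-level feature is the finite H1
bar with the largest longitude (death − birth). Ties break to the
earlier birth, then to the lexicographically smallest representative
vertex tuple — a convention chosen for determinism; ties have measure
zero for empirical data. Subjects with no positive-persistence H1 bar
are recorded as *absent*, not errors, and stay in cohort denominators.

**Cohort aggregation.** Longitudes of the per-subject longest bars are
histogrammed with fixed-width bins on [0, 1] (default width 0.025; bin
edges are rounded to 10 decimals so they sit on the decimal grid).
Region frequency counts each region once per subject whose longest-loop
representative contains it; reported fractions divide by the *full*
cohort size, absent subjects included. All writers use shortest
round-trip float formatting and fixed sort keys, so identical inputs
give byte-identical files.

## Synthetic cohorts

The generator emulates the *shape* of a resting-state cohort acquisition
(defaults: 198 subjects, 64 labeled cortical regions, 255 time points)
and plants a circular synchronization structure whose ground truth is
known:

* loop members k = 0..K−1 receive
  `x_k(t) = cos(2π·c·t/T + 2πk/K) + σ·ε` with iid standard-normal ε,
  integer cycle count c (default 8) so that at σ = 0 correlations are
  exactly cos(2πΔk/K) and distances exactly |sin(πΔk/K)| — the planted
  1-hole is then solvable in closed form;
* background regions receive `sqrt(ρ)·g(t) + sqrt(1−ρ)·η` with a shared
  per-subject signal g and iid η, ρ = 0.1 by default, so the null model
  is weakly correlated rather than trivially distant from the loop.

Defaults: K = 12 loop regions, σ = 0.2, chosen as a clearly detectable
but non-trivial plant — at that strength the longest-bar representative
recovers the planted set essentially always, and recovery degrades
monotonically as σ grows through 0.5 and 1.0. Per-subject randomness
derives from `SeedSequence([root_seed, subject_index])`, so any subject
can be regenerated in isolation; cohort-level member-pool draws use
`SeedSequence([root_seed, subject_index, 1])`.

What the generator does **not** emulate: hemodynamics and BOLD spectral
content, head motion and scanner artifacts, spatial autocorrelation
between neighboring parcels, inter-subject anatomical variability, and
the preprocessing chain (segmentation, realignment, ICA denoising) that
real acquisitions require. Passing recovery tests therefore demonstrate
the correctness of the distance/filtration/reduction/selection chain and
its noise robustness on planted structure — not that any particular
anatomical finding would replicate on empirical data.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `distance.form` | `sqrt-half` | — | `sqrt((1−r)/2)` (metric) or `(1−r)/2` |
| `tda.eps_max` | ∞ | distance | filtration cutoff; default keeps all simplices |
| `tda.keep_zero_bars` | false | — | retain death = birth bars in outputs |
| `tda.tighten` | false | — | greedy representative shortening |
| `cohort.bin_width` | 0.025 | distance | loop-length histogram bin width on [0, 1] |
| `synth.n_regions` | 64 | count | regions per subject (Desikan–Killiany names) |
| `synth.n_timepoints` | 255 | samples | acquisition length |
| `synth.loop_size` | 12 | count | planted loop size K (≥ 4) |
| `synth.noise_sigma` | 0.2 | signal a.u. | additive noise on loop oscillators |
| `synth.cycles_in_window` | 8 | cycles | oscillator periods per acquisition |
| `synth.background_corr` | 0.1 | — | shared-signal variance fraction ρ in background |

## Numerical choices

* Exact symmetry of distance matrices is enforced by mirroring the upper
  triangle; the diagonal is exactly 0. The reduction refuses
  non-symmetric input rather than silently symmetrizing.
* Degenerate inputs: a zero-variance region raises an error naming the
  region (and the subject, in pipeline context); duplicated signals are
  legal and sit at distance 0. An ε cutoff can leave essential H1 bars;
  they serialize with empty death/longitude and `essential=true`.
* Floats serialize via `repr` (shortest round-trip); all writers sort
  with fixed keys, making outputs byte-stable across runs.
* Problem sizes in the test suite: oracle equivalence uses 50 random
  matrices with n ∈ {4..8} at 20 scales each; stability uses 20 planted
  16-region instances under δ = 0.01 sup-norm perturbations (valid when
  the dominant bar exceeds 4δ in length and gap, which the chosen plant
  strength guarantees); recovery sweeps σ ∈ {0, 0.2, 0.5, 1.0} × 50
  seeds at the full 64-region shape; the cohort dry run processes
  198 × 64 × 255 end to end.

## Limitations

* Homology stops at dimension 1; voids (H2) and higher cavities are out
  of scope, as are persistent cohomology, sparse/approximate Rips
  constructions and landmarking.
* Only the single most persistent loop per subject is analyzed; subjects
  whose dynamic contains several comparably persistent loops are
  summarized by one of them.
* The correlation distance captures co-occurrence only: it is blind to
  lagged or nonlinear dependence and to time-resolved (dynamic)
  connectivity.
* Representative cycles are homology-class witnesses, not unique
  anatomical claims: a different valid representative of the same class
  can pass through different regions, especially for short-lived bars.
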