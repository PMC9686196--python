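# Methods

This note records the models, algorithms, defaults and design choices behind
`nanofacet`, in the order the pipeline runs them.

## Wulff construction and mass matching

The equilibrium shape of an FCC crystal truncated along the {100} and {111}
families is fixed by the ratio γ = γ{111}/γ{100}: each family's plane sits at
a distance from the center proportional to its surface energy.  A lattice
atom at position **x** (atom at the origin; lattice constant a, gold default
a = 0.4078 nm) belongs to the polyhedron at scale s when

    max_i |x·n̂_100,i| ≤ s   and   max_j |x·n̂_111,j| ≤ γ s.

Every atom therefore has a critical scale at which it enters the shape, and
sorting those scales yields the complete staircase of achievable cluster
sizes; symmetry orbits enter together, so sizes jump in steps.  The builder
selects the plateau whose atom count is nearest the target mass — the number
of atoms whose volume N·a³/4 equals a sphere of the requested equivalent
diameter — with ties broken toward the smaller cluster.  This is an exact
version of the recursive scale bisection: it evaluates every plateau instead
of a convergent subsequence.  For γ = 0.96 and a 4.0 nm target the staircase
has no size between 1925 and the next orbit, so the builder returns the
1925-atom cluster (equivalent diameter 3.96 nm).

Facet classification is by first-shell coordination number (cutoff 0.34 nm
for gold, strictly between the a/√2 and a shells; scaled with a for other
lattice constants): CN 12 → bulk, CN 9 → {111} terrace, CN 8 → {100}
terrace, all other undercoordinated atoms → edge/vertex.  Ideal-lattice
coordination makes this rule exact; it would misclassify on relaxed or
reconstructed surfaces, which are out of scope.

## Oligomer model

PLGA is represented at formula level: LA ester residues C3H4O2, GA residues
C2H2O2, plus H and OH caps (one water equivalent) in the protonated state;
the deprotonated chain is short one acid hydrogen.  The reference 6 LA + 2 GA
protonated oligomer has 69 atoms and 566.5 g/mol (C 12.011, H 1.008,
O 15.999).  Spatially an oligomer is a rigid cloud of 69 point sites uniform
in a 0.5 nm-radius sphere — downstream analyses (clustering, SASA occlusion,
radial distributions) consume only positions, so no force-field topology is
carried.  The residue arrangement along the chain is configurable and does
not affect any composition-level quantity.

## Synthetic adsorption kinetics

The generator reproduces the statistical structure the analyses assume —
dispersion → self-aggregation → facet-biased adsorption — with full ground
truth.  Defaults mirror the reference study conditions: 60 oligomers
(45 mM) in a 13 nm periodic box around the 4 nm particle, 1000 frames of
100 ps (a 100 ns horizon).

* Free clusters random-walk with per-frame rms displacement
  `diffusion_step · m^(−1/3)` (default 0.25 nm for a monomer); merged
  clusters move rigidly with frozen internal geometry.
* Two free clusters merge irreversibly when their centers approach within
  `aggregation_radius` (default 1.0 nm, minimum image).
* A free cluster with any site within `adsorption_radius` (default 0.7 nm)
  of a surface atom is in contact.  It draws a candidate anchor uniformly
  from the particle's surface atoms and binds with probability
  `base_binding_prob` × α (anchor on {111}), × 1 ({100}), × (1+α)/2 (edge),
  where α is the planted facet affinity.  On success the cluster relocates
  onto its anchor (innermost site 0.25 nm above it along the outward normal)
  and freezes; binding is irreversible, matching the monotone coverage
  growth the analyses assume.

Drawing the anchor from the global surface-atom pool (rather than taking
the geometrically nearest atom) is deliberate: protruding edge atoms would
otherwise dominate every contact, and the anchor-facet distribution would
carry an uncontrolled geometric bias.  With the pool draw, the facet of
each binding is an exact multinomial sample over surface-atom counts
weighted by the acceptance factors, so parameter recovery has a closed-form
expectation: at α = 1 the {111} share of facet-anchored bindings is the
{111} share of surface atoms.  What the generator does *not* emulate:
solvent, hydrodynamics, cluster shape relaxation, reversible adsorption,
and any force-field energetics — passing its tests shows the analysis
stack recovers planted statistics, not that it reproduces MD.

## Umbrella sampling and WHAM

Umbrella windows are sampled from p(ξ) ∝ exp(−[U(ξ) + k/2 (ξ−c)²]/k_BT) by
a Metropolis chain that alternates tuned random-walk steps (step size
adapted to 30–50% acceptance during burn-in) with independence proposals
from the bias Gaussian N(c, √(k_BT/k)), accepted on the residual potential
alone — the bias cancels against the proposal density.  The mixture
decorrelates the chain when the stiff bias dominates.  Defaults follow the
umbrella protocol being emulated: k = 10,000 kJ mol⁻¹ nm⁻², T = 300 K,
10,000 samples per window (a 10 ns production run sampled every 1 ps), and
0.02 nm window spacing.  The spacing is ~1.3σ of the biased coordinate
(σ = √(k_BT/k) ≈ 0.016 nm), the standard choice that makes adjacent
histograms overlap; spacing several σ apart makes the stitched profile
drift by multiple k_BT regardless of estimator, which is why spacing is
tied to k rather than fixed in nm.

WHAM iterates the standard coupled equations on a ξ histogram.  Numerical
choices:

* bin width 0.005 nm — smaller than σ, so the biased density is resolved;
  the Boltzmann factor of each harmonic bias is integrated exactly over
  each bin (erf), removing midpoint discretization bias;
* the window free energies are first obtained by minimizing the convex
  WHAM likelihood (L-BFGS with analytic gradient), then polished by
  fixed-point iteration to a 1e-7 tolerance (max 1e5 iterations) — plain
  iteration alone converges too slowly when overlap is thin;
* adjacent windows must share an occupied bin, otherwise the offending gap
  is reported by center;
* bins with fewer than 25 total samples are excluded from the reported
  profile (the Poisson error of −k_BT ln P is ~k_BT/√n), and the PMF is
  anchored to zero at the largest reported ξ.

At the default budget the reconstruction error for a 20 kJ/mol Gaussian
well over a 1 nm range is RMSE ≈ 0.1–0.45 kJ/mol across seeds.

## SASA and facet attribution

Shrake–Rupley with a deterministic golden-spiral point set (default 960
points per atom, probe 0.14 nm, gold van der Waals radius 0.166 nm,
generic adsorbate site radius 0.17 nm).  A point on the probe-expanded
sphere is accessible when outside every other expanded sphere; neighbor
candidates come from a k-d tree.  Adsorbate sites act as occluders only.
Facet areas are sums of per-atom areas by label, so the facet partition is
conserved exactly.

Edge attribution: edge and vertex atoms border both plane families, and
their accessible area is large precisely because they protrude.  The
`facet_exposure` helper reports two conventions — `exclude` (edges dropped
from the denominator) and `split` (each edge atom's area apportioned
half/half) — with `split` the default: it tracks the geometric Wulff face
areas (for γ = 0.96 the polyhedron faces split 65.5 : 34.5, and split-SASA
gives 65.6 : 34.4), whereas exclusion overweights the {111} terraces.

Relative coverage divides each facet's accessible area by the same facet's
area on the bare particle (and the total by the bare total), so an
uncoated particle reads 100%.

## Clustering and radial profiles

Cluster counting delegates to HDBSCAN (scikit-learn) with
min_samples = 7, min_cluster_size = 60, manhattan metric and leaf cluster
selection; distances are minimum-image by default (precomputed matrix) so
clouds straddling the periodic boundary are not split.  Leaf selection
cannot return the hierarchy root, so a frame whose sites have all merged
into one dense cluster would read as pure noise; in that degenerate regime
the counter falls back to an excess-of-mass pass with
`allow_single_cluster`.  Noise points are excluded from counts.  A plain
fixed-radius DBSCAN (textbook definition, O(N²)) ships in the package as
the reference implementation used by the tests on planted partitions.

g(r) around a reference point is the shell histogram normalized by shell
volume and mean site density (→ 1 for an ideal gas); the unnormalized
site–site distribution g*(r) is shell-volume-normalized only, so its
short-range (< 0.3 nm) part is the frame-independent intramolecular
signature of the rigid clouds.  Both require r_max ≤ half the box edge.

## Lennard-Jones enthalpy and the ΔG = ΔH − TΔS split

The enthalpy proxy along the approach coordinate is the pairwise 12-6
energy 4ε[(σ/r)¹² − (σ/r)⁶] between particle atoms and adsorbate sites
within a 1.0 nm cutoff (optional Coulomb term when charges are supplied),
referenced to zero at the largest ξ.  ε and σ are configuration inputs with
geometric/arithmetic combining; no force-field values are hard-coded.
`decompose_thermo` interpolates ΔG and ΔH onto the PMF grid restricted to
their shared support, re-anchors both at the largest shared ξ, and sets
TΔS = ΔH − ΔG, so ΔG − ΔH + TΔS = 0 holds pointwise by construction; the
coordinate is reported as ξ* = ξ − R with R the particle's equivalent
radius.

## Problem sizes in the shipped analyses and tests

The analysis drivers run 400-frame (40 ns) trajectories, cluster every
5 ns, and evaluate coverage with 480 quadrature points at a 4 ns stride;
the test suite uses 50–300 frame runs, a ~2 nm particle for geometry-heavy
checks, and 8 replicas for statistical recovery.  These sizes put every
stage's statistical error well inside the asserted tolerances while keeping
a full run in minutes on one core; all sizes are parameters, and nothing
in the implementation assumes them.

## Known limitations

* Ideal rigid lattices only: no relaxation, reconstruction, or amorphous
  particles; facet classification relies on ideal coordination.
* The kinetic model's anchor draw is statistical, not geometric; it is the
  right tool for testing facet-rate estimators, not for studying contact
  geometry.
* WHAM only (no MBAR), 1D reaction coordinates, replica mean/std as the
  only error estimate.
* SASA is quadrature-based; exact-arc areas and solvent-excluded surfaces
  are out of scope.
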