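# Methods

## Model

A monomer is a hard disc of diameter σ (the length unit) carrying three
attractive patches at 120°. The pair energy between discs i and j is a
state-gated Kern–Frenkel square well: −ε_well when (i) σ ≤ r_ij < σ + δ,
(ii) a patch on each particle points at the other within the half-opening
angle θ_pw (classical Kern–Frenkel convention: angular deviation < θ_pw on
*both* sides), and (iii) both patches are in the closed state p = 1;
otherwise 0, with the hard core handled as move rejection. The binary patch
state represents the open/closed conformations of a DNA tile's stacking
interface; P_open is the stationary probability that a patch of an isolated
particle is open. Geometry guarantees a single bond per patch: construction
asserts 2·θ_pw < acos(1 − σ²/2(σ+δ)²), the worst-case angular separation of
two hard partners inside one interaction shell.

Defaults σ = 1, δ = 0.038, θ_pw = 0.44 rad; energies in k_BT (β ≡ 1).
The simulation is strictly two-dimensional: surface adhesion is modelled
as 2D confinement only, with no explicit substrate energy term (the pair
potential is isolated in one function should one be added).

### Interaction-strength convention

With the default `normalize_patch_entropy=True`, ε is the per-bond
interaction strength *at fixed association entropy*: the well depth is

    ε_well = ε + 2 ln(π / θ_pw),

compensating the angular phase-space window (θ_pw/π)² of a bond. Under
this convention the patch width tunes bond geometry and flexibility while
leaving the association constant of a single bond unchanged — which is the
only convention under which sweeping θ_pw at a fixed "interaction strength
of 6 k_BT" keeps assembly alive at θ_pw ≈ 0.15–0.2 rad, and under which the
two reference parameter sets below sit on the assembled side of the gas
boundary at area fraction 0.1. A raw square well of depth exactly ε
(`normalize_patch_entropy=False`) is kept for textbook comparisons; ε = 0
means no attraction in either convention.

## Monte Carlo sampler

Single-particle Metropolis translation and rotation, a patch-state flip,
and a rigid-cluster move, drawn per attempt with default fractions
0.4/0.2/0.3/0.1. One sweep = N attempts. Maximum step sizes are tuned
toward 30–50% acceptance in a short pre-production phase (12 rounds of 25
sweeps), logged, then frozen; the calibrated values are recorded in the
trajectory metadata, and the whole procedure is a deterministic function of
the seed.

* **State flip.** Acceptance min(1, [w(new)/w(old)]·e^(−ΔE)) with intrinsic
  weights w(open) = P_open, w(closed) = 1 − P_open, making P_open the exact
  stationary open probability of a non-interacting patch (verified against
  this prediction at ε = 0, and against a two-particle configurational
  integral at ε > 0). This is the minimal detailed-balance-respecting
  coupling between states and bonding; the alternative (state resampling
  that ignores bond energy) would not have a Boltzmann stationary state.
* **Cluster move.** A bonded connected component is collected from a random
  seed particle; the attempt survives with probability 1/size (mimicking
  size-dependent diffusivity and making the cluster-selection probability
  uniform); a rigid translation or rotation is proposed and rejected if it
  would create any new bond or overlap (annihilation-of-new-bonds rule).
  Rotations are additionally rejected for clusters whose unwrapped extent
  exceeds half the box: beyond that, rigid rotation alters minimum-image
  internal distances across the periodic boundary. Translations are
  image-safe at any size. Cluster moves accelerate collective relaxation
  without shifting equilibrium (tested against runs without them).
* **Deposition** (kinetics runs only). Poisson(rate) insertions per sweep
  at uniform non-overlapping positions, states Bernoulli; a kinetic device
  emulating continuous adsorption from solution, never used in
  phase-diagram runs.

Energies are tracked incrementally through a linked-cell list and verified
against a from-scratch recomputation at every recorded frame (tolerance
10⁻⁸·N; the run aborts on drift). One counter-based RNG stream per run;
identical seeds give byte-identical trajectory files.

## Morphology stack

**Bond graph.** From simulation frames, bonds are exactly the pair-potential
bonds. From point sets (detected centres), particles closer than a cutoff
are bonded — default 1.25× the modal nearest-neighbour distance, the mode
taken from a Gaussian-KDE of nearest-neighbour distances for robustness to
detection jitter; degree-4+ nodes are pruned by removing their longest
edges (the monomer is 3-valent). The image pipeline, which knows its
lattice constant a, instead uses 1.4·a: bonded neighbours sit at a,
second neighbours at √3·a ≈ 1.73·a, so 1.4·a splits them with margin.

**Islands.** Connected components, BFS-unwrapped across the periodic
boundary. Edges whose unwrapped endpoint distance disagrees with the
minimum-image distance (wrap-around cycles of a percolating cluster) are
excluded from the planar embedding and the island is flagged; size and
edge counts are unaffected.

**Faces.** Rotation-system traversal: neighbours angle-sorted around each
node, walks follow next-clockwise half-edges; the unique clockwise walk
(negative signed area) is the outer face. Simple cycles of 3–9 vertices are
the labelled polygons; larger or non-simple interior walks are voids.
Euler's relation V − E + F = 2 (counting the outer face) holds for every
traversal and is asserted in tests. Crossing edges — possible only in
noisy point-set data — are resolved by deleting the longer edge of each
crossing pair; when more than 5% of an island's edges cross, the embedding
is untrustworthy and the island raises an error.

**Network density.** ND = E / E_max(V): the island's bond count over the
maximum bond count of any V-vertex subgraph of the honeycomb lattice.
E_max is exact by exhaustive enumeration for V ≤ 12 and by a face-spiral
construction beyond (hexagonal faces laid ring by ring around a seed face),
validated against the exhaustive values and against the closed form
⌊3V/2 − √(3V/2)⌋ for all V ≤ 3000. ND = 1 exactly for maximally compact
islands; trees decay toward (V−1)/E_max(V) ≈ 2/3, so the metric has a
compressed dynamic range for small or sparse islands (see Classification).

**Face density.** A companion compactness metric with a wider dynamic
range: F / F_max(V), the number of labelled polygons over
F_max(V) = E_max(V) − V + 1, the interior-face count of the maximally
compact island. 1 for ideal crystals, exactly 0 for chains and trees.
It is sensitive to ring closure, which edge counting is not: an island can
be bond-rich yet polygon-poor when its bonds are spent on branches.

**Border ratio.** Fraction of an island's polygons with at least one vertex
on the outer-face boundary walk (the stricter, vertex-based reading of
"polygon on the border"); 0 by convention when the island has no polygons.
1 for pure border growth, strictly decreasing as rings of hexagons are
added around a compact core.

**Frame summaries.** Island statistics enter frame-level summaries only for
islands of ≥ 24 particles; the frame ND is the island-size-weighted mean
over eligible islands. Island density is the eligible-island count per box
area.

## Phase classification

Labels are derived from the last 20 recorded frames of a run (default
5×10⁵ sweeps recorded every 2.5×10³ — the window is the final 10%), as a
pure function of stored observables:

* **gas** — the largest island, averaged over the window, stays below 24
  particles (transient grazes of the threshold do not count as assembly);
* **dla** — essentially zero accepted bond breaking (rate < 10⁻⁶ per
  attempted move) together with a large ramified island (border ratio
  > 0.9 at ≥ 100 particles): the kinetic fingerprint of the
  infinite-interaction-strength limit;
* otherwise **short_like** when the window-mean eligible-island ND clears
  `nd_cut` = 0.75 *and* the window-mean largest-island size clears
  `short_min_island` = 42, else **long_like**.

ND is the principal metric and island size the secondary determinant.
The size criterion does real work: in this engine the two reference
conditions (P_open = 0.8 vs 0.9 at ε = 8, θ_pw = 0.44) produce islands
whose E/E_max values overlap within seed noise (≈ 0.81–0.86 both, because
E_max(V) is small for small islands and inflates their score), while their
island sizes separate robustly (typically 60–130 of 150 particles in one
network versus 25–40-particle assemblies). `short_min_island` was
calibrated once as the midpoint between the size distributions of those
two reference conditions, then frozen; all cutoffs are explicit
`ClassifyThresholds` fields recorded with every diagram.

Sweeps run one simulation per (grid point, replicate) with seeds derived by
stable hashing of (master seed, point indices, replicate); per-point labels
are the majority over replicates, ties resolved by the replicate with the
median classifier metric. Boundary locations are reported as bracketing
grid intervals with midpoints — never extrapolated or fitted.

## Synthetic data

The generator emulates the assembly classes seen on mica, with complete
ground truth (centres, bonds, island identities, planted polygon census):

* **Compact islands** grow face by face: regular k-gons (k = 5, 6, 7 with
  per-face defect probabilities) attach to boundary edges in ring sweeps;
  coincident corners merge, so zero-defect growth reproduces the exact
  honeycomb (2 rings = the 24-particle, 7-hexagon flower). Defective
  islands are spring-relaxed (unit bond springs, second-neighbour bracing,
  non-bonded repulsion past the bond cutoff) so every bond stays within
  10% of the lattice constant and no non-bonded pair enters the cutoff;
  infeasible insertions are skipped and logged. The final census is the
  actual set of interior faces of the planted geometry, including any ring
  that closed around a skipped insertion.
* **Elongated assemblies** are neighbour-avoiding walks on the honeycomb
  lattice (optionally branching): the planted graph is a tree, so chains
  carry no polygons and a cutoff graph recovers exactly the planted bonds.
* **Gas** fields are isolated monomers at ≥ 2 lattice constants spacing.
* **Rasterization**: each monomer is drawn as a three-armed Gaussian-ridge
  star along its actual bond directions (half a bond per arm, so bonded
  ridges join seamlessly; free arms complete the 120° geometry), heights
  combined by maximum. Defaults: 750 nm field, 256×256 px (2.93 nm/px),
  2 nm ridge height, ridge width a/4 = 4 nm (AFM tip convolution broadens
  ~2 nm DNA well beyond its physical width), pixel noise σ = 0.1 nm, and
  per-scan-line constant offsets σ = 0.2 nm — the dominant AFM artefact
  class. The lattice constant defaults to 16 nm, chosen so a 750 nm field
  holds islands at the scale seen in tile-assembly AFM imagery; it is a
  config knob.

What the generator does *not* emulate: tip-shape convolution beyond
isotropic broadening, multilayer crowding, inter-frame drift, or defect
*dynamics*. Detection scores on synthetic fields therefore bound performance
on real micrographs from above.

## AFM image pipeline

Flatten (per-scan-line polynomial background fit over pixels below a
robust threshold; order 0 or 1) → segment (Otsu threshold unless
overridden, opening with a radius-1 disc) → skeletonize → centres.
Monomer centres are skeleton branch points (≥ 3 skeleton neighbours — the
unique three-way junction of the 3PS), merged within 0.3 lattice
constants; monomers whose free-arm spur was thinned away are recovered as
distance-transform thickness maxima at least 0.85·a from any junction
centre; junction-free blobs contribute centroids. Candidates within 0.5·a
deduplicate (bonded monomers sit a full lattice constant apart).
Confidence: junction-neighbour count / 3, capped at 1; fallback detections
carry reduced confidence. On seeded synthetic fields at default noise the
detector recovers ≥ 95% of centres within 0.3·a with ≈ 1.0 precision, and
image-derived ND rank-correlates with ground truth above 0.9.

## Problem sizes and numerical choices

Production phase-diagram runs use N = 150 at area fraction 0.1 (box
≈ 34.3 σ), 5×10⁵ sweeps, 200 recorded frames. The package's own acceptance
rerun uses 4×10⁵ sweeps per scan point with three seeds, and the in-suite
checks run reduced grids or single replicates at 4–5×10⁵ sweeps; each
states its problem size in its output or docstring. Classification labels
are protocol-length dependent near phase boundaries (assembly is
nucleation-limited), so scan results always quote the sweep count used. The cell list uses cells ≥ σ + δ (falling
back to an all-pairs scan for boxes under 3 cells). Histories are float64;
the incremental-energy tolerance is 10⁻⁸·N. Angular comparisons use strict
inequality (deviation < θ_pw), consistent between the Python reference
implementation and the numba kernels.

## Known limitations

* The exact interface-flexibility Hamiltonian of the original engine
  (including any mica-adhesion term) is not public; the compensated-well
  convention is this package's reconstruction, chosen to make the printed
  phase boundaries mutually consistent, and the raw-well convention is one
  flag away.
* At strong wells (ε_well ≳ 10) bond breaking is rare, so assembled states
  within reachable run lengths retain kinetic imperfections (border ratios
  near 1 even for compact networks); annealed radial crystals with interior
  polygon cores require far longer trajectories than the classification
  protocol uses.
* E/E_max compresses differences between sparse assemblies; hence the
  face-density companion metric used by the classifier.
* The face traversal requires a near-planar embedding; heavily crossing
  point-set graphs raise rather than guess.
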