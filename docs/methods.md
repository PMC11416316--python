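# Methods

`npcbasket` implements a desk-scale integrative-modeling pipeline for the
nuclear basket of the nuclear pore complex (NPC): a coarse-grained
representation of one symmetry unit against a fixed double nuclear ring
(NR), a restraint set translating heterogeneous data into a score,
replica-exchange Gibbs Monte Carlo sampling, and ensemble validation.  A
synthetic generator with a known ground truth supplies every input the
pipeline consumes, so the whole chain is testable without any deposited
data.

## Representation

One C8 symmetry unit is modeled; the assumption (borne out by the basket's
anchoring on the fixed double NR) is that components of neighboring units
do not interpenetrate, so inter-unit interfaces need not be sampled.  The
interface checks remain available through the optional symmetry-image term
of the excluded-volume score.

Each subunit is a string of spherical beads.  The multiscale schedule puts
all represented segments at 10 residues/bead (the *coarse* layer used for
connectivity, excluded volume, density scoring, and RMSD); rigid segments
that come with source coordinates additionally carry a 1 residue/bead
*fine* layer used for residue-resolved restraints (crosslinks, positional
specs).  Fine beads belong to the rigid body of their segment and move with
it.  Bead radius is volume-proportional, `r = 3.0 * n_res^(1/3)` Å — about
the radius of a one-residue sphere at typical protein density.  FG-repeat
segments are annotated `excluded` and produce no beads.

The stoichiometry presets encode the published compositions: yeast — two
Mlp copies (Mlp1/Mlp2 stoichiometry is ambiguous; both use Mlp1's length
but remain distinct types), one Nup1, two each of Nup2 and Nup60, and two
copies of the heptameric Nup84 complex (21 subunits, 12 types); mouse —
two each of Tpr, Nup50, Nup153 plus two copies of the nonameric Nup107
complex (24 subunits, 12 types).

Frame convention: origin at the scaffold-ring center, z along the central
axis pointing cytoplasmic, units Å.  The scaffold is a fixed rigid body; it
never moves, which also fixes the global frame and makes RMSD superposition
unnecessary.

## Restraints

All data terms are one-sided harmonics, `0.5 k (excess)^2` with stiffness
`k` = 1 kT/Å² by default; the functional forms are package choices since
only the restraint *types* are published.

* **Crosslinks** — upper bound on the minimum bead-center distance over all
  copy assignments of the two residues, cutoff 35 Å (the common DSS
  Cα–Cα convention).  The minimum rule is exact and makes ambiguity
  monotone: adding a copy can never raise a penalty.  An optional flag also
  considers the rotational images of fixed-scaffold beads, for contacts
  across the symmetry interface.
* **Density** — `w (1 − CC)` where CC is the normalized analytic overlap of
  two isotropic Gaussian mixtures (model: one Gaussian per coarse bead,
  σ = radius, weight ∝ residue count; map: from file or fit to an MRC grid
  by EM with k-means initialization on density-resampled voxels).  Because
  CC lives on a 0–1 scale while harmonic terms are in kT, `w` defaults to
  1000 so the map competes during sampling; the weight is exposed in
  `RestraintWeights`.
* **Positional** — immuno-EM style point targets with a tolerance (penalty
  on distance − tolerance) and membrane z-slabs (penalty on the excursion
  outside [z_min, z_max]); copy-ambiguous specs take the best copy.
* **Proximity** — upper bound on the minimum inter-domain bead distance
  (affinity co-purification contacts).
* **Connectivity** — upper bound `1.2 (r_i + r_j)` between consecutive
  beads of a chain; pairs inside one rigid body are constant and skipped.
  The 1.2 factor is the usual slack allowing beads to stay tangent without
  strain.
* **Excluded volume** — lower bound `r_i + r_j` over non-bonded coarse
  pairs, excluding pairs within one rigid body.
* **Structural equivalence** — for a residue alignment between two models,
  harmonic matching of all intra-model pairwise distances across aligned
  positions.  Being distance-based it is superposition-free and invariant
  under rigid motion of either model (used to transfer a yeast-like
  solution onto the mouse composition).

The weighted sum is reported with a per-term breakdown that sums to the
total; the density CC is reported alongside, not inside, the sum.
`ScoringFunction` compiles a bundle against a fixed topology into index
arrays for ~10⁴ evaluations/s on ~50 beads; it is cross-checked against the
reference `score_*` functions to 1e-9 in the tests.

## Sampling

Replica-exchange Gibbs Monte Carlo.  One MC step is a Gibbs sweep: a
Metropolis proposal per movable rigid body (random rotation about its
centroid, up to 8° by default, plus a random translation up to 4 Å) and per
flexible bead (translation up to 4 Å).  Replicas run at a geometric
temperature ladder from 1.0 to 2.5 (4 replicas by default); adjacent pairs
attempt configuration swaps every 10 steps with the standard
`min(1, exp((β_i − β_j)(E_i − E_j)))` rule.  Move magnitudes are annealed
with replica temperature (×√T).  Initial configurations place every movable
body and bead uniformly in a user-supplied box that encloses the scaffold
neighborhood; the scaffold itself is never randomized or moved.  Runs are
deterministic in the seed; independent runs use seeds spawned from the
configured seed.

The one-sided harmonic data terms form a long-range funnel (their gradient
grows with distance), which is what makes plain Metropolis sampling
converge from fully randomized starts at this problem size.

## Analysis

Good-scoring models are selected by total-score percentile and/or per-term
caps.  RMSD is computed over coarse beads in the fixed-scaffold frame (no
superposition); equivalent subunit copies are handled by exact
minimization over per-type permutations (types separate, so the joint
optimum is the sum of per-type optima; at ≤2 copies per type this is
trivial).  Clustering is greedy: the frame with the largest
within-threshold neighborhood seeds a cluster, repeat on the remainder.

Sampling precision follows the three-test exhaustiveness protocol on two
halves split by independent run: (a) two-sample Kolmogorov–Smirnov on the
score distributions; (b) per threshold, chi-square homogeneity and Cramér's
V of cluster populations between halves; (c) the precision is the smallest
grid threshold with p > 0.05, V < 0.10, and ≥ 80% of models in
non-singleton clusters.  Model precision is the average pairwise RMSD of a
cluster (primary) with the average RMSD to the centroid member also
reported.

Localization probability densities: each member contributes an indicator
envelope — voxels whose Gaussian-smoothed occupancy (σ = bead radius, i.e.
within one radius of a bead center) reaches exp(−1/2) — and the map value
is the fraction of members covering the voxel.  The map integral therefore
equals the mean member envelope volume, a normalization the tests check.

## Synthetic ground truth

The generator emulates the measured basket architecture: a fixed two-tier
scaffold arc (one C8 wedge of the double NR; 6 beads per tier, 50 Å tier
separation), straight strut rods tilted from the central axis terminating
in a distal blob, and flexible anchor chains near the scaffold.  Geometry
presets: yeast — 30° tilt, 540 Å distal offset, 760 Å distal ring diameter,
~100 Å strut thickness; mouse — 6°, 630 Å, ~1000 Å.  The scaffold ring
radius is derived from these by straight-rod geometry unless overridden.
The rod's topmost ~60 Å is left unrepresented so the first strut bead
clears the scaffold sterically; strut bead radii come from the strut
thickness (50 Å), not the volume rule, because the rod's cross-section is
the measured quantity.  Anchor chains are seeded random walks at bonded
step length with steric clearance against everything already placed; the
first bead sits just clear of a scaffold bead but inside DSS range, so an
anchor–scaffold crosslink is always possible.  The truth state scores
exactly zero on its own noiseless restraint bundle — it is the global
optimum by construction.

Simulated inputs: DSS-style crosslinks are residue pairs drawn uniformly
from distinct-bead pairs within the 35 Å cutoff, plus
`floor(n_true · fp/(1 − fp))` decoys drawn exclusively from beyond-cutoff
pairs so violation counts are exact; the density is one Gaussian per truth
bead with optional mean jitter; terminal localizations are point targets at
the true strut termini with stated uncertainty (20 Å default); membrane
slabs keep anchor N-termini in the scaffold z-band.  The effective noise
level of the real crosslink set at the modeling stage is not published, so
`fp_rate` defaults to 0 and is a parameter.

What the generator does **not** emulate: coiled-coil supercoiling and
flexibility within struts (rods are straight and rigid), FG repeats, the
curved nuclear envelope, map anisotropy and missing-wedge artifacts, and
crosslink assignment errors that correlate with abundance.  Passing the
recovery test therefore demonstrates the correctness of the machinery —
restraint math, sampling, and validation logic — not the attainable
accuracy on real cryo-ET and CX-MS data.

## Ground-truth recovery experiment

The integration benchmark (`workflows.ground_truth_recovery`): yeast
preset, 120 noiseless crosslinks (~2.4 per bead; dense enough that every
qualifying contact class is covered with high probability), jitter-free
density, terminal localizations at 20 Å, membrane slabs; sampling at 4
replicas × 20 000 steps × 2 independent runs (a desk-scale budget of a few
minutes on one CPU; production integrative modeling uses orders of
magnitude more).  Analysis selects the best 20% of frames, estimates the
sampling precision on the run split, clusters at that precision, and
compares the top-cluster centroid to the truth with copy-permutation RMSD.
Expected behavior: centroid RMSD well below twice the mean bead radius
(~66 Å), ≥ 90% ensemble-level crosslink satisfaction at 35 Å, and strut
localization density ≈ 1 at the true strut positions.

## Radial distribution function

NPC positions per tomogram are treated as a 3-D point pattern in the
tomogram box.  Per tomogram, g(r) is the observed pair count per distance
shell divided by the CSR expectation for the same intensity in the same
box; the final curve is the unweighted mean over tomograms (never pooled
pairs).  The CSR expectation uses the exact distance distribution of two
uniform points in the box, computed by numerically convolving the per-axis
squared-difference distributions — this is the translational edge
correction, deterministic and unbiased at the box boundary.  Particles
actually lie near the curved nuclear envelope (a quasi-2-D pattern in 3-D);
the 3-D treatment is an approximation and short-range values inherit it.
Defaults: 25 nm bins, r_max half the shortest box edge.

## Numerical choices and degenerate inputs

Zero-length moves are accepted (ΔE = 0); equal-temperature replicas always
swap.  Singleton clusters report zero precision with a note.  A chi-square
table with a single cluster is perfectly homogeneous (p = 1, V = 0).
Empty crosslink selections and empty good-scoring selections are explicit
outcomes, never silent.  GMM cross-correlation raises on zero-norm
mixtures.  mmCIF bead models round-trip centers to 1e-3 Å (writer
precision); MRC maps round-trip to float32 precision with origin and voxel
size preserved.

## Known limitations

Rigid straight struts and a single-wedge scaffold are idealizations; the
sampler's Gibbs sweeps evaluate the full energy per proposal (simple and
exact, but O(DOF · cost) per step — adequate at ~50 beads, not at
thousands); localization densities use indicator envelopes rather than
fractional occupancies; the exhaustiveness protocol's chi-square is
asymptotic and can be anticonservative for very small clusters (Cramér's V
is the primary gate there).
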