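# Methods

This note documents the models implemented in `voxgraph`, the knobs
that matter, what the synthetic phantoms do and do not emulate, and the
numerical choices made where the design was genuinely open.

## Graph construction

Nodes are the voxels inside the brain mask (GM, WM and CSF all
included); edges follow a Moore neighborhood scheme:

- **3-connectivity**: the 26 nonzero offsets with components in
  {−1, 0, 1};
- **5-connectivity**: those 26 plus the 5×5×5 outer shell, minus the 26
  outer offsets that are positive scalar multiples (2×) of an inner
  offset — they duplicate a direction already encoded — leaving 98.

"Parallel" is read as *positive scalar multiple*; this is the only
reading that yields 98 directions from the 124-offset shell. Each
direction is assigned an equal solid angle, 4π/26 or 4π/98 steradians.
Unit direction vectors are computed in physical mm (offset × voxel
size, normalized), so anisotropic voxels skew the angular geometry
correctly; lattice adjacency itself ignores voxel size.

### Directional diffusion profiles

**Tensor route.** p(i, **r**) is the trivariate Gaussian with the
voxel's tensor as covariance, evaluated at the neighbor's physical
displacement. The displacement enters at its true length, so the
outer-shell neighbors of the 5-connectivity scheme (up to 2√3 voxels
away) are damped by distance as the model dictates. A discretization
that matches a continuous Gaussian to FIR filter coefficients would be
an alternative; direct evaluation was chosen because the β
normalization in the edge weights removes any global scale, leaving
only relative direction weighting, and direct evaluation keeps the
value hand-checkable. Tensors are validated SPD by Cholesky before
use; failures are reported with voxel coordinates.

**ODF route.** ODF samples are raised to a power n (default n = 2,
configurable) and averaged over the spherical cap around each neighbor
direction. The cap half-angle solves the exact cap-area equation
2π(1−cos θ) = Ω rather than partitioning the sphere by nearest
neighbor: the model defines a per-direction solid angle, not a
partition, so caps of nearby directions may overlap. The power factor
sharpens peaks (diffusion ODFs discriminate fiber orientations only
weakly); n = 2 keeps hand oracles tractable while clearly sharpening.

Cap coverage constrains the ODF sample count N_o: the 26 caps need
N_o ≥ 60; the 98 finer caps need N_o ≳ 200 (the pipeline defaults to
120 and 320 respectively). An empty cap raises an error naming the
direction rather than silently producing an undefined profile.

### Edge weights

a_ij = [P(v_i)P(v_j)/α²]·(p(i,**r**ᵢⱼ)/βᵢ + p(j,**r**ⱼᵢ)/βⱼ), with α
the anisotropy maximum over the whole mask and β_k twice the maximum of
p over voxel k's own in-mask neighbors. Both factors are bounded to
[0, 1] by construction. Numerical detail: the orientation term divides
by β directly instead of multiplying by a precomputed reciprocal,
because x/(2x) rounds to exactly 0.5 in IEEE arithmetic — the fully
saturated edge weight is exactly 1, not 1 − ulp.

Edges to voxels outside the mask simply do not exist (no padding).
Voxels whose profile is all zero (β = 0) are dropped, then the largest
connected component is kept and the dropped count logged; the spectral
machinery assumes a single-connected graph. Node order is lexicographic
in (z, y, x) scan order and recorded on disk, fixing the mapping
between 4D signal volumes and node vectors.

## Spectral analysis

The symmetric normalized Laplacian is diagonalized for its C smallest
eigenpairs (default C = 50 at desk scale; the reference analysis uses
C = 1000 at brain scale). Problems with N ≤ 600 or C > N/2 go to dense
LAPACK; larger ones use shift-invert Lanczos about σ = −0.01 — the
spectrum near 0 is dense for these lattice graphs and plain Lanczos
converges poorly there, while L − σI is safely positive definite for
any σ < 0. The starting vector is seeded. Every returned pair is
verified against the residual bound ‖Lu − λu‖ ≤ 1e−8; violation is an
error, not a warning.

Eigenvector signs are fixed by making each column's largest-magnitude
entry positive (first such entry on ties). Repeated eigenvalues leave
the eigenspace basis arbitrary; tests that touch potentially degenerate
pairs compare projectors or subspaces, not individual vectors.

Mode variability is quantified two ways: total variation xᵀLx (equal to
λᵢ for a unit eigenvector, the basis of the graph-frequency reading)
and edge-weighted zero-crossings, where an endpoint value of exactly
zero counts as no crossing (strict sign opposition; a measure-zero
event in floating point).

## Graph signal processing

Each frame is processed independently (no temporal filtering): the
component along u₁ is regressed out and the residual normalized, which
guarantees zero energy at the first spectral index and unit total
energy. The ensemble energy spectral density is the mean of *squared*
GFT coefficients across frames — the energy reading of the ensemble
average; an unsquared sum could be negative and would not be an energy.
Frames parallel to u₁ (zero residual) are excluded and counted.

Null models: node-wise shuffling (per-frame independent permutations;
preserves each frame's value distribution, destroys spatial order) and
white Gaussian frames. For isotropic Gaussian signals, exchangeability
under any orthonormal basis puts a 1/(N−1) fraction of energy on every
mode once u₁ is regressed out — the flat reference line the structured
signals are compared against.

## Eigenmode matching

Aligning two subjects' first K eigenmodes uses the orthogonal
Procrustes rotation R (SVD of X_mᵀX_ref) followed by exact linear
assignment on |R|, producing a strict signed column permutation — the
group algorithm reorders columns, it does not apply dense rotations, so
the nearest signed permutation to R is extracted rather than R itself.
Translation is omitted: Laplacian eigenvectors beyond the first are
near zero-mean, leaving nothing for a translation to absorb. Group
matching initializes the average at subject 1 and sweeps
reorder-then-average until a full pass changes nothing (capped at 20
sweeps; the count is recorded) — a fixed sweep count can leave the
average biased toward its initialization. Averaged columns are not
re-orthonormalized; cosine-based matching is norm-invariant.

The Procrustes error E(K) is computed by zeroing the diagonal of the
cosine matrix before summing squares; subtracting the diagonal sum from
the total cancels catastrophically when matched cosines are near 1.
E(K) is symmetric, zero iff cross-modes are orthogonal, and
nondecreasing in K. Bootstrap validation samples subject pairs without
replacement within a draw, with replacement across draws, seeded.

Signed permutations cannot undo *mixing* within near-degenerate
eigenspaces — by design, that residual shows up in E(K). Consequence:
the cohort-versus-null comparison is only meaningful when inter-subject
perturbations are small relative to the eigenvalue gaps (see below).

## Synthetic phantoms

`make_tissue_phantom` builds a labeled box: a one-voxel outside layer,
a CSF rim, GM interior, and a straight cylindrical WM bundle along a
chosen axis. Anisotropy is ≈0.8 in the bundle, 0.12 in GM, 0.05 in CSF
(plus N(0, 0.015) noise, clipped to [0.01, 1] in-mask) — values in the
range of typical FA contrasts. Tensor fields are prolate, axially
symmetric, trace-normalized (unit mean diffusivity — the edge weights
normalize scale out), with the bundle's axial/radial eigenvalue ratio
as a parameter (default 5, FA ≈ 0.77) and background ratios derived
from the anisotropy map; per-voxel orientation jitter is ~0.03 rad. ODF
fields use a Watson-type kernel exp(κ((û·μ)² − 1)) (default κ = 8) on
an antipodally symmetric Fibonacci direction table, constant ODFs in
the background.

What the phantoms do **not** emulate: scanner noise and artifacts,
crossing or fanning fibers, partial-volume mixtures, gyral geometry,
and registration error (cohorts share one grid by construction, so
alignment is the identity and matching is isolated from registration).
Passing tests therefore demonstrate the correctness and the qualitative
behavior of the machinery — tissue-contrasted degrees, spectral trends,
energy orderings — not quantitative claims about real acquisitions.

Graph signals are synthesized as random eigenmode combinations with
coefficient variance ∝ (mode index)^(−γ) for indices ≥ 2 (default
γ = 2, mimicking the power-law energy decay fMRI shows on brain
graphs), plus optional white node-space noise. Cohorts perturb the base
anisotropy and bundle directions with smooth (2-voxel correlation
length) Gaussian fields of a chosen scale; zero scale reproduces the
base subject exactly.

## Study conditions and problem sizes

The package's own validation runs at desk scale, chosen so every check
completes in seconds on one CPU:

- spectral and tissue-contrast checks: 18³ phantom → 4096-node DTI-3
  graph, C = 50; dense cross-check on a ~200-node subgraph;
- GSP checks: 100-node full-spectrum toy (S = 500 Gaussian frames) and
  the 4096-node phantom graph for smooth-versus-null orderings;
- matching: 5-subject ODF-3 cohorts on a fixed template anatomy, grid
  (16, 14, 11) with a radius-3 bundle (1512 nodes), K ∈ {5, 10, 20},
  20 bootstrap draws.

The matching template is fixed deliberately: its first 21 eigenvalues
are separated by more than 1e−3, and the cohort perturbation scale
(5e−4) is kept below that gap so the planted mode correspondence is
recoverable — the regime in which comparing cohort error to the
random-orthonormal null is informative. Re-drawing the anatomy at
random occasionally produces near-degenerate pairs (gaps ~1e−5) whose
mixing is unfixable by any signed permutation; that failure mode is a
property of degenerate spectra, not of the matching algorithm.

## Known limitations

- The DTI profile uses direct Gaussian evaluation; a moment-matched FIR
  discretization could weight directions slightly differently.
- Whether spherical caps should overlap or partition the sphere is a
  modeling choice; overlap was chosen (per-direction solid angles), and
  profiles from the two conventions differ most for sparse ODF tables.
- Procrustes matching handles sign flips and swaps only; subspace
  mixing within close eigenvalues is reported, not corrected.
- Graphs at full brain scale (~8×10⁵ nodes) are out of scope for the
  test suite; the implementation is sparse throughout and the Lanczos
  path is the one intended for such sizes.
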