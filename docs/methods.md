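# Methods

This note records the models implemented in `implantsim`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
test surfaces do and do not establish about real data.

## Smooth cortical envelope

Subdural arrays rest on the inner dural sheet, not in the sulci, so
ground-truth grid coordinates live on a *smooth cortical envelope* (SCE): a
watertight surface that encloses the pial surface and bridges its
concavities. Construction: voxelize the pial surface (default pitch 1 mm)
and fill it to a solid; morphologically close with a spherical structuring
element of radius 30 mm, implemented with two Euclidean distance transforms
(dilate = distance-to-solid ≤ r, erode = distance-to-background > r), which
bridges any concavity narrower than twice the radius; dilate one voxel so
the extracted 0.5-isosurface strictly encloses the input; run marching
cubes; smooth.

Smoothing is the Taubin λ|μ low-pass filter (λ = α = 0.5, μ = −1.02 α,
100 iterations). A plain Laplacian filter at these settings visibly shrinks
closed surfaces and would pull the envelope inside the pial mesh it is
supposed to contain; the λ|μ pair removes the same high-frequency
protuberances with negligible shrinkage, which is what the containment
invariant (every pial vertex at non-positive signed distance) requires.
Tests build envelopes at 1.5–2 mm pitch to keep runtimes short; pitch only
sets the discretization tolerance of the envelope, not the algorithm.

Curvature is the cotangent Laplace–Beltrami mean-curvature magnitude with
mixed Voronoi vertex areas (the barycentric weight misestimates
irregular-valence vertices — on an icosphere the twelve valence-5 vertices
are off by ~15%, the mixed area is near-exact). A configurable pre-smoothing
(default 20 low-pass iterations) stabilizes the estimate on marching-cubes
output. Seed points are chosen automatically: curvature terciles define
Low/Medium/High classes, and seeds are drawn round-robin across classes
under a 15 mm minimum spacing, all from a named RNG stream.

## Grid and strip fitting

The fit minimizes E = Et + K·Ed over electrode coordinates, with Et the
summed squared displacement from the initial tangential placement and Ed the
summed squared rest-length error of the first/diagonal/second neighbor
springs, subject to every electrode lying within ε of the envelope
(K = 1000, ε = 0.1 mm; K = 100, ε = 0.5 mm for 16×16 grids). The three
spring classes control stretch, shear, and bending respectively; only
single-step diagonals are used.

The constraint is enforced by an escalating quadratic penalty
μ·Σ max(0, ‖xᵢ − sᵢ‖ − ε)² on the exact mesh distance (closest point sᵢ
recomputed at every function evaluation), minimized with L-BFGS and followed
by exact projection of any electrode still marginally out of tolerance.
A projected-alternation scheme (fully minimizing E, then projecting) was
tried first and rejected: the unconstrained minimum is the flat placement,
so the iteration ping-pongs and converges orders of magnitude too slowly on
the stiff spring system. The penalty solver reaches the same optima as an
exact-sphere-parametrized reference on spherical test envelopes and is
deterministic.

Two consequences of the sphere test geometry are worth stating. First, a
flat lattice cannot wrap a sphere isometrically (Gaussian curvature), so
deformations on a radius-70 sphere have a geometric floor that grows with
the array footprint: large 10 mm IED grids genuinely cannot fit, and the 5%
QC rule rejects them — on a real, locally much flatter envelope the same
arrays pass. Second, the per-electrode PCA normal at corner electrodes
reflects the tangent plane of the corner *neighborhood*, so corner normals
tilt by (patch size)/(2R) radians; this is a property of the estimator, not
a bug.

Quality control follows the implantation-realism rule: any fitted neighbor
distance deviating more than 5% of the IED rejects the scenario. Campaign
deformation statistics are reported per neighbor class as medians over all
edges of all accepted fits, pooling the 3/5/10 mm IED catalog — deformation
scales with the square of footprint/curvature-radius, so small-IED scenarios
dominate the pooled medians exactly as large campaigns dominated by small
arrays do.

## Depth arrays

Trajectories run along the inward envelope normal from an entry seed
(orthogonal drilling minimizes slippage and bone damage). The chord is the
farthest ray–envelope intersection. Arrays shorter than the chord get a
target depth drawn uniformly from [array length, chord]; longer arrays are
anchored at the chord end and trimmed to floor(chord/IED) + 1 contacts.
Contacts are indexed tip-first (index 0 = deepest, serialized as contact 1).

Bending displaces contacts orthogonally to the first–last axis, inside a
plane through the axis at a uniform random roll, following the symmetric
Lanczos window w(t) = sinc(2t − 1) scaled to a 1% of-length peak (default).
Bending does not re-equalize arc length; at ≤1% deflection the induced
arc-length error is below 0.01% of the IED. Real arrays bend slightly
asymmetrically (peak toward the deep end); the symmetric window is retained
deliberately as the published model.

## Overlapping arrays

A quadratic height field z = f(PC1, PC2) is fitted to the background
electrodes in their principal-component frame (the lowest-order surface
capturing local envelope curvature). The overlay lattice is placed flat in
that plane at a uniform random orientation and slid along a random direction
toward the background centroid; because the overlap count (overlay
electrodes inside the background's 2D convex hull — a deterministic reading
of "overlapping") is monotone along the approach, the translation realizing
round(fraction × N) overlaps is found by bisection, with a strictly-inside
nudge so the marginal electrode is not left exactly on the hull boundary.
Lifting through f preserves overlay IEDs well where the footprint is gently
curved; far outside the background footprint the quadratic extrapolates and
stretches distances, which is why the IED-preservation guarantee is limited
to QC-passing backgrounds. Overlay normals are inverse-distance averages of
the 4 nearest background normals (exact at coincidence, surface normal
beyond 3 IED). The overlay sits on the same fitted surface — the vertical
offset between stacked silicone sheets is not modeled.

## CT artifacts and noise

Voxels are sampled on one lattice per scenario (0.5 mm spacing, uniform
random rotation from quaternion sampling, origin uniform in one voxel) —
the patient's head pose in the scanner — inside a 10 mm cube per electrode.
Intensity is 1 − r with r the scaled radial distance in the electrode frame;
the semi-axis catalog is keyed by (type, IED): grids/strips 2.2/2.2/1.5 mm
(10 and 5 mm IED) or 1.1/1.1/1.0 mm (3 mm); depths 1.25/1.25/1.75 mm (10/5)
or 1.1/1.1/1.5 mm (3). Off-catalog IEDs map to the nearest entry with a
warning. Clean artifacts keep the open ellipsoid r < 1.

Noise is added over the whole cube (clean intensity 1 − r, negative outside
the ellipsoid) *before* the final pruning of negative voxels, so high noise
both erodes the core and scatters detached voxels around it. The correlated
component is white noise convolved with an isotropic Gaussian kernel
(FWHM 1 mm = 2 voxels; periodic boundaries preserve stationarity) and
rescaled to its exact target pointwise variance — the cited construction
specifies convolved white noise but not the kernel, and exact rescaling
makes the 20:1 correlated:uncorrelated variance split hold by construction.
Twelve total-variance levels run geometrically from 0.2 to 2.2. Duplicate
lattice sites across electrodes keep the maximum intensity when merged
(partial-volume brightening).

The depth ellipsoid's aspect ratio is only 1.4, so the orientation of a
single noisy depth artifact is not recoverable from its second moments; the
alignment contract of the generator is therefore verified on clean
artifacts.

## Noise fingerprint

Entropy estimation: per electrode, voxels are centred at the
intensity-weighted centroid and rotated so the electrode axis (PCA normal
for grids, first-to-last direction for depths) is +z; an intensity–radius
histogram (radius 0–5 mm in 0.25 mm bins × intensity 0–1 in 0.05 bins,
2.5–97.5 intensity percentile band per artifact) fingerprints each
electrode; all within-array histogram pairs are cross-correlated in full 2D
and the Shannon entropy (natural log — the base cancels in every
comparison) of each normalized cross-correlation image is averaged.
Consistent artifacts give peaky cross-correlations (low entropy), noisy
ones flat images (high entropy). Pairwise entropies are FFT-accelerated
(the circular correlation on the padded grid is the linear one up to a cell
permutation, which entropy ignores). Entropy depends on artifact size, so
estimates are normalized by subtracting the (type, IED) group mean. Grids
with fewer than 12 electrodes are excluded: edge-heavy layouts degrade the
PCA normals.

Best-fit matching scores a candidate noise level by the mean Pearson
correlation between all (target, candidate) histogram pairs, normalized by
the mean of the full within-target correlation matrix (diagonal included,
so exact copies score exactly 1) and returns the argmax level.

## Localization benchmark

Artifacts are merged, thresholded (linear schedule from 0.6 at level 1 to
0.25 at level 12 — lower thresholds at high noise keep the eroded cores),
and clustered with k set to the known contact count. k-means is the
scikit-learn implementation (10 seeded restarts); k-medoids is an
alternating Voronoi implementation (k-means++-style init, medoid update to
the within-cluster distance minimizer, 10 restarts, best total cost;
single-precision distances, double-precision centroids). Both report
intensity-weighted cluster centroids. Matching is optimal assignment
(Hungarian), so errors are invariant to cluster relabeling; methods are
compared with two-sided Wilcoxon signed-rank tests (normal approximation,
r = |z|/√n, r > 0.5 large) under Benjamini–Hochberg FDR across noise
levels.

Two properties of this benchmark on the synthetic envelope deserve note.
For 10 mm IED grids the artifacts are well separated and the *median* error
stays near 4–5% of the IED across all twelve noise levels — noise shows up
in the error tail (occasional cluster failures), not the median. The
noise-driven median degradation appears at 3 mm IED, where sampling cubes
overlap and clusters merge. Desk-scale campaign sizes: the localization
acceptance run uses 60 scenarios of the smallest catalog grid (2×4, 10 mm
IED) × 12 levels — per-electrode artifact and noise statistics depend on
(type, IED), not on grid size, so the smallest grid is representative while
keeping the voxel load modest.

## Synthetic envelopes vs. real data

The sphere/ellipsoid/bumpy generators provide watertight, curvature-graded
surfaces with closed-form oracles; the campaign conditions follow the
published study design (array catalog, 30 mm closing, K/ε, 5% QC, 12-level
noise ladder, 20:1 split, 1% bending). They do not reproduce: sulcal
anatomy and the interhemispheric gap (only the bumpy surface has
curvature classes at all), brain shift (electrodes are placed on the
undeformed envelope), beam hardening, streaks, cables, clips, Poisson
photon statistics, or Hounsfield calibration. Passing tests therefore
establish the internal correctness and calibration of the simulator and
the relative behavior of localization baselines — not absolute error rates
on patient CTs. The regression operator for comparing real against
simulated entropy ships, but no patient data do.

## Numerical choices

- Exact geometry kernels (closest point with conservative KD-tree pruning,
  Möller–Trumbore ray casting, generalized winding numbers) back every
  surface query; closest-point ties resolve to the lowest triangle index.
- All randomness flows from named, independently derived RNG streams
  (CRC32-keyed children of the master seed), so campaigns are byte-
  reproducible and adding a stage never perturbs another stage's draws.
- Fit convergence: relative objective tolerance 1e-6, penalty escalation
  ×10 from 100·K, L-BFGS with analytic gradients; feasibility is enforced
  exactly at the solution (post-projection), and monitored during iterations.
- Histograms use numpy's half-open binning with the last bin closed; the
  single-voxel artifact survives the degenerate percentile band.
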