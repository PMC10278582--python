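# Methods

This note records the model, the numerical choices, and the limits of
what the synthetic validation can show.  It is the package's own
account of its design; empirical numbers quoted here are the ones the
test suite and `scripts/acceptance.py` themselves compute.

## Signal model and multi-tensor fitting

Each voxel's diffusion-weighted signal is modeled as a mixture of
non-exchanging Gaussian compartments

S(b, g) = S0 · Σᵢ fᵢ · exp(−b · gᵀ Dᵢ g),  Σᵢ fᵢ = 1,

with 1–3 compartments per voxel.  Compartments are **axially
symmetric** (λ₂ = λ₃ = λ⊥): at three shells and 90 directions, full
6-dof tensors per compartment are not identifiable once three
compartments are allowed, and the downstream analysis consumes only
FA/MD per compartment, which the (λ∥, λ⊥) pair determines.

Fitting proceeds per candidate compartment count N:

* **Seeding.**  A two-resolution discrete search over subdivided
  icosahedral hemispheres (321 coarse / 1,281 fine axes).  For N=2 the
  coarse pair search solves the 2×2 linear system for the pair weights
  in closed form over the pairs of the 48 best single-axis matches;
  the winning pair is locally refined on the fine grid.  A second,
  geometric seed (axes split ±12° around the DTI principal axis in the
  e₁/e₂ plane) guards against shallow-crossing local minima; the
  better refined result is kept.  For N=3 a third axis is added
  greedily.  λ∥/λ⊥ are initialized from the single-tensor fit's AD/RD.
* **Refinement.**  Projected Levenberg–Marquardt on signal amplitudes
  (Gaussian-noise least squares; Rician bias is *not* corrected),
  batched across all voxels of a slice — residuals, Jacobians and
  normal equations are evaluated as stacked arrays, which is what
  makes 37-subject studies tractable on one core.  Eigenvalue bounds
  [1e−5, 4e−3] mm²/s; weights are non-negative with fractions
  normalized afterwards (so Σf = 1 holds by construction).
* **Merging.**  Compartments whose principal axes lie closer than the
  merge angle (default 20°) are merged greedily from the closest pair
  (fractions summed, axis = fraction-weighted mean), then
  re-optimized.  A separation numerically *at* the threshold (within
  1e−3°) counts as distinct, so a noiseless crossing at exactly the
  merge angle is reported as two tensors.  Compartments with fraction
  < 0.01 are dropped as spurious.
* **Selection.**  Nested F-test between successive candidate counts:
  F = ((SSE_N − SSE_{N+1})/Δp) / (SSE_{N+1}/(M − p_{N+1})) with 5
  parameters per compartment and M volumes; N+1 is accepted when
  p < 0.05.  Selection stops early when the simpler candidate already
  explains the data to numerical precision (SSE < 1e−16 · ‖y‖²) or
  when the richer candidate collapsed to the same effective count
  after merging.  The α and the nested-pair form are this package's
  choices; only "an F-test per voxel" is prescribed by the workflow it
  implements.

The DTI baseline is a weighted linear least-squares fit of the
log-signal (one reweighting pass with weights = squared predicted
signal), eigenvalues clamped at zero.

## Cortical coordinate system

The labeled mask (0 background, 1 ribbon interior, 2 pial boundary,
3 gray/white boundary) defines a Dirichlet problem ψ=0 on the pial and
ψ=1 on the gray/white label, solved with the 5-point stencil and a
sparse direct solve; ribbon pixels bordering the background get
homogeneous Neumann treatment.  Polarity (pial = 0) and the
superficial-first depth ordering are conventions.

Grid-lines start at 50 origins equally spaced by arc length along the
pial boundary (ordered by nearest-neighbor chaining, adequate for the
simple open boundary of a single-slice ribbon) and follow the
normalized gradient of ψ with fixed-step Euler integration at 88 µm
(half a pixel).  RK4 was considered and rejected: at this step and
curvature the reparameterization-stability test (halving the step
moves vertices by < half a step) already passes with Euler.  The final
vertex is clipped to the exact ψ=1 level crossing so traced lengths do
not depend on the integration step.  Each streamline is resampled to
10 vertices at equal arc length; vertex tangents use central
differences (one-sided at the ends).

Scalar maps are sampled bilinearly at the 500 vertices; a vertex whose
interpolation neighborhood touches non-finite data (or falls outside
the map) is *missing*, never zero-filled.  Multi-tensor fixels cannot
be interpolated across voxels, so each vertex uses the fit of the
voxel containing it and the labeling is done against the vertex
tangent.

## Parallel / perpendicular labeling

Scores are |e₁ · t| with the full 3D principal axis against the
in-plane tangent: an out-of-plane axis component lowers the score, so
strongly through-plane compartments fall into the perpendicular class
rather than being excluded.  Ties break toward the larger signal
fraction, then storage order (determinism).  A single-compartment
voxel joins the parallel class iff its score ≥ cos 45°; the other
class is missing there.  This 45° rule is a package decision — the
workflow being implemented does not specify how one-tensor voxels
enter the orientation-resolved sheets — and only affects voxels where
model selection kept one tensor (none, on the two-population phantom).

## Group statistics

The point statistic is the difference of group means (control −
experimental, matching the sign convention of the Cohen's d maps).
P-values use the add-one estimator p = (1 + #{|T*| ≥ |T|})/(R+1),
which is valid (super-uniform under exchangeability) at any finite R;
ties within float round-off of the observed statistic count as
exceedances.  One relabeling ensemble, drawn once per seed, is shared
across all grid points.

Cluster inference thresholds the point-wise p map at 0.05 and labels
4-connected components.  The null distribution tallies, for each of
the R relabelings, the maximum cluster size of that permuted grid,
with each permuted grid's point-wise p-values ranked against the same
shared ensemble — this reuse is what keeps the nested construction at
O(R) instead of O(R²).  The max-size statistic gives familywise
control; pooled tallying of all null cluster sizes is available behind
`null_statistic="pooled"`.  Two-sided throughout; no correction across
the four metrics (each metric's map is reported separately).  Missing
points never join clusters.

## Synthetic phantoms

The generator emulates the study conditions end to end: a cortical
ribbon (straight slab 8.75 × 1.75 mm, or quarter annulus) at 0.175 mm
in-plane pixels; radial and tangential fiber populations at every
ribbon voxel (defaults: radial λ∥/λ⊥ = 1.7/0.3 ×10⁻³ mm²/s, FA ≈ 0.80;
tangential 1.2/0.4 ×10⁻³, FA ≈ 0.60 — plausible in-vivo values for
coherent intracortical fibers, equal fractions); the 90-direction ×
3-shell (b = 670/1,270/2,010 s/mm²) + 15-b0 protocol with directions
on a deterministic spherical Fibonacci spiral shared across shells;
Rician magnitude noise at b0 SNR 30.  Group studies draw per-subject
multiplicative eigenvalue jitter (CV 5%) and independent noise;
lesions multiply the eigenvalues of one population inside a block
specified in grid coordinates (the emulated focal malformation).

What the phantom does **not** emulate: preprocessing artifacts (EPI
distortion, Gibbs ringing, motion — out of pipeline scope), partial
volume with white matter or CSF, spatially varying fiber dispersion,
realistic rodent neuroanatomy, and through-plane fibers (a
`through_plane` population exists but is off by default).  Passing
tests therefore demonstrate correctness of the *machinery* under the
stated generative model, not robustness to everything real tissue
does.

## Structure-tensor histology module

J = G_σ ∗ (∇I ∇Iᵀ) with central-difference gradients after 0.5 px
pre-smoothing (inner scale; the window itself is specified physically,
default 15 µm, converted through the pixel pitch and clamped to ≥1 px
with a warning).  Orientation is the eigenvector of the *smaller*
eigenvalue of J — i.e. along the local structures, the convention of
the standard orientation-analysis tools — equal to
½·atan2(2J_xy, J_xx − J_yy) + 90°.  Coherency C = (λmax − λmin)/(λmax
+ λmin), set to 0 where the energy E = trace(J) falls below 1e−12 of
its maximum.  E scales with the squared intensity; C and θ are
intensity-invariant.

## Analysis scales and determinism

The shipped analysis scripts and the group-level tests run the phantom
at 0.35 mm pixels (175 ribbon voxels) with 1000 permutations and
19 vs 18 subjects — the half-resolution scale keeps a full 37-subject
chain in the minutes range while preserving the 50 × 10 grid geometry;
null-calibration replicates use 10 vs 10 subjects.  Single-voxel and
oracle tests use the full 0.175 mm scale.  Every stochastic step takes
an explicit seed (numpy `default_rng`); identical seeds reproduce
studies, permutation ensembles and fits bit-identically.

## Known limitations

* Fractions are signal fractions, not volume fractions; no Rician
  bias correction in the fit (the noise-floor bias is real and is
  exercised by the tests, not removed).
* The F-test assumes Gaussian residuals; at very low SNR its effective
  α drifts.
* Tensors labeled perpendicular conflate in-plane tangential and
  through-plane fibers; the 2D grid cannot distinguish them.
* The Laplace solver and grid are 2D single-slice by design;
  equivolumetric (as opposed to equidistant) depth sampling is not
  implemented.
* Nearest-neighbor boundary chaining assumes a simple open pial curve;
  strongly folded boundaries would need a topological ordering.
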