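# Methods

This note documents the models, conventions and numerical choices
behind `amygshape`, what the synthetic cohorts emulate, and what
passing tests do and do not establish.

## The analysis model

The pipeline tests, at every vertex of a per-side template surface,
whether a signed displacement metric between subject and template is
linearly associated with a continuous trait score. The statistic is the
Pearson correlation's t-transform, t = r√((n−2)/(1−r²)) with n−2
degrees of freedom. This t is symmetric in the two variables, so it is
irrelevant which of metric and score is treated as the dependent
variable — the test suite asserts this equivalence numerically against
OLS fits in both directions.

Cluster-level inference thresholds |t| at the value whose two-sided
tail probability equals the cluster-forming p (default 0.001),
extracts suprathreshold connected components per sign on the template
triangulation, and assigns each cluster the standard 2D t-field
expected-cluster approximation: with R = area/FWHM² resels,
E[m] = R·ρ₂(t_c) + χ·ρ₀(t_c) (χ = 2 for a closed surface, ρ₂ the
Worsley EC density), E[N] = R·P(T > t_c), extent tail
P(S ≥ s) = exp(−βs) with β = E[m]/E[N] and s in resels, and corrected
p = 1 − exp(−E[m]·exp(−βs)); both tails double E[m] and E[N]. Resels
use the *applied* smoothing FWHM, which this pipeline knows exactly,
rather than residual-based smoothness estimation; when the data carry
additional intrinsic smoothness this is mildly conservative (more
resels than effective), which the null calibration study quantifies.
A max-cluster-extent permutation test over subjects (p = (1 + #{null
max ≥ observed})/(1 + n_perm)) serves as the distribution-free oracle;
under the null generator both methods hold the family-wise error at
α = 0.05 within the [0.01, 0.10] band over 200 simulated cohorts.

Within a significant cluster, the area-weighted mean of the smoothed
metric is partially correlated with the trait score controlling the
depression score: both are residualized on the confound and the
residuals correlated, with n−3 df — the two-stage construction equals
the correlation-matrix recursion, which the tests use as the oracle.

## Surface modeling conventions

**Spherical harmonics.** Real, orthonormal, without the
Condon–Shortley phase: Y_{l,0} = N_{l0}P_l⁰, Y_{l,±m} =
√2·N_{lm}P_l^m·{cos, sin}(mφ), so Y₀⁰ = 1/√(4π), Y₁⁰ = √(3/4π)cosθ,
and the degree-1 triple is √(3/4π)(y, z, x) on the unit sphere.
Coefficients are least-squares fits of the x/y/z coordinate channels;
the default expansion degree is L = 15 (the conventional choice for
subcortical structures — the sensitivity to L above ~10 is negligible
at amygdala scale), with the shared correspondence sampling an
icosphere at subdivision level 4 (2562 vertices; level 3, 642
vertices, for the desk-scale simulation studies).

**Parameterization.** The initial spherical map solves two uniform-
weight Laplace problems: a latitude field between extremal-z pole
vertices, remapped through the cumulative object-area distribution so
latitude bands carry equal area (this makes the map the identity for
spherical inputs), and a longitude field on the mesh cut along a
shortest pole-to-pole path, with the handedness fixed so the map
preserves orientation. Local Jacobi untangling sweeps remove any
flipped spherical triangle; alternative pole axes are tried if needed.
CALD optimization then sweeps vertices with area-imbalance-weighted
tangent averaging and step halving, accepting a move only if the local
area-distortion cost falls, no incident triangle flips, and the
vertex's length-distortion cost stays within the cap (default 8,
relaxed with a warning if the initial map already exceeds it);
ADC is thus non-increasing and bijectivity is preserved at every
accepted state. Distortion definitions: for face k with object-area
fraction o_k and spherical-area fraction s_k (solid angles / 4π),
ADC = meanₖ max(s_k/o_k, o_k/s_k); LDC is the worst over vertices of
the mean over incident edges of max(r_e, 1/r_e) with r_e the
normalized spherical/object edge-length ratio.

**Correspondence.** The longitude origin of the initial map is set by
a mesh-dependent date line and is therefore arbitrary per subject. The
parameter net is canonicalized from the degree-1 coefficients: writing
the degree-1 map as center + M·u with M = U·S·Vᵀ (axes sign-fixed
deterministically: largest component positive, det +1), the parameter
sphere is rotated by V so the map becomes U·S·u. After this, "same
parameter location" is a consistent anatomical correspondence across
subjects, which the FOE object-space alignment (translate center to
origin, rotate sorted axes onto +x,+y,+z) completes. Near-degenerate
FOEs (two semi-axes within 2%) skip the rotation with a warning and
rely on the ICP refinement.

**Registration.** Rigid only — closed-form Kabsch/Procrustes on the
index-wise correspondence, optionally alternated with a discrete
search over the 60 icosahedral rotations of the parameter sphere, each
candidate evaluated at its own Procrustes optimum so the search can
escape ICP local minima. No scaling or shear: displacement metrics
keep mm units and registered volumes are bit-identical to their
inputs. The template is the vertex-wise mean of FOE-aligned surfaces,
re-estimated once after registration (one round by default).

**Displacement and smoothing.** Direct displacement is the Euclidean
distance signed by the side of the template tangent plane
(sign((p−a)·N), with sign(0) = +); normal displacement is the
projection (p−a)·N. The unsigned literal reading of "direct distance"
cannot carry an outward/inward interpretation, so the sign rule is
part of this package's contract. Smoothing integrates the heat
equation with the cotangent Laplace–Beltrami stiffness and lumped
(barycentric) vertex masses, total time t = FWHM²/(16·ln 2), 20
implicit Euler sub-steps by default; implicit stepping is
unconditionally stable and conserves the lumped-mass integral exactly
(zero row sums), and variance never increases. Validation compares a
smoothed impulse against the Legendre series of the spherical heat
kernel (within 5% of the kernel peak out to twice the FWHM) and
eigenfunction decay factors exp(−l(l+1)t) for l ≤ 6 within 2%.

## The synthetic cohort generator

The generator defines the study conditions: n = 24 subjects; STAI-T ~
Normal(40, 7.56²); SDS built from the same latent normal with
population correlation 0.5 (the source design reports only that the
correlation is significant, so 0.5 is a configurable stand-in); left /
right mean volumes 1895 / 1937 mm³ with a common between-subject SD of
168 mm³ (midpoint of the per-side values 176 and 159); 1 mm isotropic
voxels. The base shape is an ellipsoid with semi-axis ratios
1.4:1.1:1 (mirrored in x between sides) perturbed by a random radial
field of spherical harmonics of degree 2–4 at 4% relative amplitude —
a stand-in for individual anatomy with the right topology and scale,
not an anatomical atlas. Ground truth is an outward normal
displacement a·G + ε with a = bump_gain·(STAI-T − mean)/SD,
G a Gaussian in angular distance from the bump center truncated at the
bump radius (σ = radius/2.5; defaults: 0.6 mm/SD, radius 0.8 rad on
the right side), and ε smooth noise built by heat-smoothing white
noise at 5 mm FWHM and rescaling to SD 0.25 mm — the same diffusion
operator the metrics stage uses. bump_gain was chosen for
detectability at n = 24, since the source design reports no effect
size for the shape–trait association; it is a generator default, not
an estimate. Masks come from a parity scanline voxelizer (ray
crossings per voxel column, with a deterministic sub-voxel irrational
grid offset so rays never graze edges); mask volumes agree with mesh
volumes to within 2% at 1 mm voxels.

Two cohort routes exist on purpose. The *surface route*
(`simulate_surface_cohort`) deforms a single per-cohort base shape on
the shared sampling, so correspondence is exact and the configured
noise is the only noise; the calibration (200 null cohorts) and
parameter-recovery (50 cohorts) studies use it at sampling level 3.
The *mask route* (`generate_cohort` → full pipeline) additionally
draws per-subject anatomy (individual radial perturbation and volume),
then voxelizes, repairs, re-parameterizes and registers each subject.
That route carries genuine between-subject shape variance of the same
order as the injected effect, so a single cohort at the default gain
sits near the detection threshold — the end-to-end tests therefore
assert reproducibility and the correct effect *direction* (elevated t
in the injected region), while power claims rest on the surface-route
studies. Neither route simulates MRI intensities, scanner bias fields,
rater variability, or anatomically faithful nucleus geometry, so
passing tests establish correctness and calibration of the analysis
machinery, not segmentation robustness on real images.

## Numerical and degenerate-input choices

- Topology repair order: largest 6-connected foreground component →
  fill background components not reaching the padded border (26-
  connected) → minimal binary closing, at most 5 iterations, until the
  iso-surface Euler characteristic is 2; every change is reported and
  the repair is idempotent. Foreground 6 / background 26 connectivity
  is the standard complementary pair.
- Iso-surfacing at level 0.5 with marching cubes on the padded grid;
  optional volume-preserving Laplacian pre-smoothing (≤ 5 iterations,
  λ = 0.3) is off by default and logged when used.
- Poles for the initial map: extremal-z vertices, ties broken by
  lowest index; pole axes z, x, y are tried in order until the map is
  flip-free.
- Constant metric at a vertex: t = 0, p = 1, flagged. Constant
  confound: partial correlation falls back to the simple correlation
  with a warning. FWHM = 0: smoothing is the identity; RFT refuses to
  run (resels undefined).
- Cluster-forming threshold p = 0.001 (two-sided) by default —
  convention of the surface-statistics packages this follows;
  configurable.
- Determinism: every stochastic stage draws from seeds derived from a
  single seed sequence recorded in the run manifest; identical
  configurations are bit-identical end-to-end.

## Problem sizes used by the studies

Calibration and recovery studies run 24-subject cohorts on level-3
sampling (642 vertices, ~770 mm² surfaces) with 500 permutations per
cohort: 200 cohorts for the null FWER, 50 for bump recovery. The
worked example and pipeline tests use the same scale; the full-route
default (level-4 sampling, L = 15) processes a 24-subject bilateral
cohort in minutes on one CPU.

## Known limitations

- CALD here is single-resolution local descent: it guarantees monotone
  ADC and bijectivity, not global optimality; strongly elongated or
  high-genus-risk shapes may keep visible distortion.
- RFT resels from the applied FWHM ignore intrinsic data smoothness;
  the permutation oracle is the reference when the two disagree.
- Rigid-only registration deliberately confounds residual size
  differences with displacement (volume is analyzed separately); a
  scale-normalized variant would change the metrics' meaning.
- The FOE canonicalization fails softly (warning, ICP-only) for
  near-spherical shapes where ellipsoid axes are ill-defined.
- The permutation oracle permutes the trait score only; it assumes
  exchangeable subjects under the null, which the generator satisfies.
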