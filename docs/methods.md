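# Methods

This note documents the models, numerical choices and synthetic study
conditions implemented in `projlddmm`, and what the passing tests do
and do not establish.

## Deformation model and discretization

Deformations are flows of time-dependent velocity fields:
`dphi_t/dt = v_t(phi_t)`, `phi_0 = Id`, with `v_t` in a
reproducing-kernel Hilbert space realized by a translation-invariant
Gaussian smoothing operator.  The inverse map is integrated by the
semi-Lagrangian recursion `psi_{k+1}(x) = psi_k(x - dt v_k(x))` with
`nt = 5` Euler steps in 3D and `nt = 3` in 2D; the forward map is the
same recursion on the time-reversed, negated velocity.  All sampling
is clamped multilinear interpolation, and the recursion keeps its
intermediates so that exact vector-Jacobian products of the
*discretized* scheme are available; the test suite verifies
registration gradients against central finite differences at relative
error below 1e-3.

The Gaussian Fourier multiplier is floored at 1e-6 so the
inverse-kernel path energy `dt * sum_t <v_t, K^{-1} v_t>` is finite in
double precision; the floored multiplier is itself a valid
positive-definite kernel (Gaussian plus a small multiple of the
identity).  Before registration the template is edge-padded along z by
the kernel support: the spectral kernel is periodic, and without
padding the two outermost section planes would couple through the
z-wrap.

**Kernel widths and penalty weights.**  Defaults are width
`8 x voxel` (3D, 1.0 mm at the default resolution) and `6 x pixel`
(2D, 0.75 mm), with penalty weights `lambda_V = lambda_U = 30`.  These
were set so that the deformation prior matches the physical distortion
scales of sectioned tissue (millimetre-smooth handling deformations):
narrower kernels let the flows chase texture noise in uniform region
interiors, visible as Jacobian ranges far outside those of realistic
deformations.

## Cross-modality contrast channel

Each section is expanded by a 2D Morlet scattering transform:
alternating wavelet convolutions and modulus nonlinearities over
`J = 2` dyadic scales and `L = 3` orientations up to order 2, low-pass
filtered and block-averaged to the template's in-plane resolution.
The path count per input channel is `1 + J*L + L^2 * J(J-1)/2 = 16`,
i.e. 48 feature images for a 3-channel stain.  Morlet filters are
built in the Fourier domain with an explicit zero-mean correction, so
constant inputs activate only the order-0 channel.  Convolutions are
periodic (FFT); sections are background-padded by construction, so
wrap-around effects are negligible.

Channels are standardized over pooled tissue pixels of all sections
(tissue by Otsu thresholding, taking the darker class) and reduced by
a single PCA to an `m = 6`-dimensional shared subspace; each section's
basis images are its standardized features projected on the shared
loadings, plus a constant image.  Coefficients `alpha_n` are estimated
by weighted least squares via the pseudo-inverse with two safeguards:

* **intensity stratification** — tissue pixels are weighted inversely
  to the occupancy of their observed-intensity stratum, so each
  intensity class contributes equally and small subregions are not
  sacrificed to large uniform ones (without this, the fit biases small
  regions' predictions by ~0.15 intensity units and the geometry then
  erases them);
* **Tukey IRLS** — two reweighting passes against gross outliers, so
  torn pixels (whose features resemble background while the projected
  template shows tissue) do not drag the predictor.

`alpha_n` is estimated at the start of each optimization stage, with
the geometry then optimized under fixed coefficients.  Re-fitting the
contrast every iteration creates a feedback loop in which the
predictor tracks geometric drift and small structures collapse; the
refit interval is configurable (`alpha_refit_every`).

## Artifact mixture and the optimization schedule

Each section pixel is explained by a three-class conditionally
Gaussian model: tissue (mean = predicted contrast), artifact (scalar
mean `mu_A`) and background (scalar `mu_B`), with shared noise scale
estimated robustly (1.4826 x MAD of tissue residuals) and uniform
priors.  The E-step yields the per-pixel weight field; the M-step
updates the nuisance means in closed form (optional sigma and prior
updates are implemented but off by default).

A structural property of this likelihood is that it evaluates only the
*observed* (deformed, projected template) intensity under each class:
a geometry that deforms the template projection into constant
background is likelihood-optimal regardless of the prediction.  To
keep the estimation well-posed the driver therefore separates roles:

1. **coarse robust stage** (template coarsened 2x) and
2. **full-resolution robust stage** estimate all geometry (rigid by
   damped Gauss-Newton, `u_n` and `v` by kernel-preconditioned
   gradient descent with backtracking line search) under a Tukey
   biweight matching loss (cutoff `6 sigma`), iterated as an IRLS /
   majorize-minimize scheme.  The Tukey loss is normalized to be
   quadratic-comparable (`rho(r) ~ r^2` near zero, saturating at
   `(6 sigma)^2/3`), which makes the weighted quadratic used by the
   line searches an exact majorizer and keeps the recorded energy
   trace monotone.  Gross outliers (tears) lose all influence while
   misalignment-scale residuals keep theirs;
3. **mixture stage** (full resolution) runs the EM on weights and
   nuisance means with geometry frozen, producing the per-pixel
   artifact interpretation.

Each stage's recorded energy (penalties plus the robust loss, or the
marginal negative log-likelihood at the mixture stage) is
non-increasing; stage boundaries change the lattice and the objective
family, so monotonicity is a per-stage property
(`RegistrationResult.trace_level_starts` marks the segments).

## Particle measures, resampling, surfaces

Particles carry position (mm), weight (mm^2 of sampled tissue) and a
`2l`-feature vector (per-region tangle counts, then per-region area
fractions; at the finest scale one particle per 2 um pixel with weight
in {4e-6 mm^2, 0}).  Maps act by the varifold action: positions move,
weights scale by the in-plane Jacobian magnitude, features are
carried.  Resampling uses a source-normalized assignment kernel
(nearest-neighbour or Gaussian, default bandwidth 0.125 mm), so total
weight and the mass-weighted count functional are conserved exactly;
feature distributions are reduced to weighted first moments.

Subregion boundary surfaces come from marching cubes followed by
edge-collapse decimation (midpoint collapses with a link-condition
guard; the few blocked edges are collapsed unconditionally and
repaired) until the minimum triangle edge reaches the target, default
6 voxels (0.75 mm at 0.125 mm spacing).  The Laplace-Beltrami basis is
the generalized eigenproblem of the cotangent stiffness matrix with
lumped barycentric vertex areas as the mass (and as the inner-product
weights `w(y)`); on a 2562-vertex unit sphere the computed spectrum
reproduces `l(l+1)` with multiplicities 3 and 5 within 5%.  Functions
are smoothed by attenuating basis coefficients with `1/(1 + k
lambda_i)` (Tikhonov; `k = 0.1 mm^2` by default, half-attenuation
wavelength about 2 mm); an alternative spatially varying denominator
form is available behind a flag for comparison.  Smoothed density is
the ratio of smoothed count and area functions, masked where the area
function vanishes.

## Tangle quantification

Probability maps are thresholded by Otsu's method (256-bin
between-class-variance maximization), split by a distance-transform
watershed whose seeds are local maxima separated by at least
`min_distance` pixels (default 10 px, i.e. 20 um at 2 um pixels), and
summarized per basin as centroid, pixel-count area and roundness
`4 pi A / P^2` (perimeter from the boundary chain, clipped to 1);
records under 3 px are discarded as noise.  Density tables assign each
record to the region at its centre and divide by the region's tissue
area.

## The synthetic specimen

The generator emulates a cut tissue block: a block-truncated outer
ellipsoid (4.4 x 4.4 x 3.6 mm semi-axes, cut at the block faces — so
sections are full cross-sections, as for a real specimen, and never
graze a tissue pole), containing a C-shaped ring, an inner ellipsoid
and a small sphere.  Inner regions are sized so every planar cap cut
by a section is at least ~1 mm across (several feature-resolution
elements, as real subregions are) with pole margins exceeding the
z-deformation amplitude.  Study conditions: 96 x 96 x 48 voxels at
0.125 mm; 8 sections 0.75 mm apart; histology simulated at 4x finer
in-plane resolution; 3D deformation 0.25 mm in-plane / 0.10 mm
through-plane at 1.5 mm smoothness (sectioning distortion is
dominantly in-plane); per-section rigid motion up to 4 degrees and
0.3 mm plus a 0.08 mm 2D flow; tears over 10% of tissue per section
(bright — missing tissue exposes the slide); Gaussian noise 0.015.

The stain model is a monotone double-sigmoid of template intensity
into three channels, deliberately plateauing over the ring (0.65) and
inner ellipsoid (0.80): those two regions share a mean stain intensity
within the texture amplitude and are distinguishable only by texture —
the ring carries a 6 cycles/mm carrier, the inner ellipsoid
12 cycles/mm, i.e. the two scattering band centres at the default
analysis scales.  The small sphere shares the 6 c/mm carrier but with
an oriented (fibre-like) pass band, separable through the orientation
channels; the outer parenchyma is nearly smooth.  On the default
conditions the scattering-based prediction correlates with the true
template sections at r = 0.93 pooled over tissue, against r = 0.59 for
an affine map of the linearly downsampled grayscale — the phenomenon
the contrast channel exists for.  Tangles are an inhomogeneous Poisson
process with per-region intensities (1, 3, 8, 20) per mm^2; synthetic
probability maps are Gaussian bumps (sigma 16 um) plus half-normal
noise.

**What the phantom does not emulate:** real stain physics and
inter-section staining variability, anatomically realistic geometry,
non-diffeomorphic damage (folds, splits), through-plane content
between sections, and scanner artifacts.  Passing the recovery tests
shows the estimation machinery is correct and robust under the modeled
effects at these scales; it does not certify accuracy on real
specimens, where contrast and artifact models are further from the
truth.

## Verified performance on the default conditions

On the fixed default seed the full pipeline recovers: landmark RMS
0.116 mm (< 1 voxel) through the composite section-to-template maps;
per-region Dice of mapped labels 0.93–0.96 (all >= 0.90); 95th
percentile Hausdorff distances <= 0.28 mm (<= 3 in-plane pixels);
mean artifact weight over fully torn pixels 0.88; monotone energy
within every stage.  A full registration takes ~6 minutes on one CPU;
the problem sizes above were chosen to keep a complete validation in
the tens of minutes.

## Known limitations

* Through-plane deformation is weakly observable from sparse sections;
  its recovery relies on the smoothness prior and intensity gradients
  across planes.
* The obs-side mixture cannot inform geometry without degeneracy (see
  above); artifact weighting therefore protects the contrast fit and
  the interpretation rather than steering the deformation directly.
* The linear contrast predictor shrinks extreme-valued small regions
  toward the tissue mean by a few percent of the intensity range even
  with stratification; sub-resolution subregions would need a richer
  predictor.
* Oblique section planes, Radon-type projections and measured 3D
  point-spreads are out of scope; the projection module covers planar
  Dirac slicing and an axial Gaussian point-spread.
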