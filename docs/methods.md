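# Methods

This note documents the models implemented in `abersim`, the parameter
choices that matter, the numerical conventions, and what the synthetic
tests do and do not establish about real data.

## Wavefronts and Zernike conventions

Aberrations are phase maps over the pupil expanded in Zernike modes with
ANSI single-indexing, `j = (n(n+2)+m)/2`. Modes are evaluated in the
**orthonormal** (unit-RMS over the unit disk) normalization: `sqrt(n+1)`
for rotationally symmetric modes, `sqrt(2(n+1))` otherwise. This choice is
what makes the coefficient-space quantities self-consistent: the Euclidean
norm of the coefficients (piston and tilt excluded) *is* the RMS wavefront
distortion in radians, so "rescale to RMS 2 rad" is an exact coefficient
operation, verified against numerical disk quadrature to 3e-3.

Coefficients are in radians of phase at the configured emission wavelength.
Two bounds profiles are shipped: an *experimental* profile (0.5 rad per
mode, raised to 1.5 rad for defocus and primary spherical) and a
*simulation* profile (1.5 rad for astigmatism, defocus and spherical). Both
zero piston and tilt, which displace but do not blur the image. Sampling is
independent uniform on `[-T_m, T_m]` — the distribution is otherwise
unconstrained, and uniform is the least-informative choice under a hard
bound. Paired single modes (astigmatism, coma, trefoil) split their fixed
amplitude as `(cos a, sin a)` over the mode pair; the split angle defaults
to a uniform draw on `[0, 2*pi)` since only the joint amplitude is
physically pinned.

## PSF synthesis and the forward model

Scalar Fourier optics with angular-spectrum defocus: per plane z the
amplitude PSF is `IFFT2(pupil * exp(i*(phi_ab + k_z(rho) z)))` with
`k_z = 2*pi*sqrt((n/lambda)^2 - rho^2)`, intensity its squared modulus.
The supported detection models are widefield and light-sheet; the sheet is
a Gaussian axial envelope multiplying the intensity PSF, with the nominal
"thickness" read as the envelope FWHM (2 um default, matching a 1.1 NA
water-dipping detection arm at 0.532 um emission and 0.13 um isotropic
voxels). Confocal, two-photon and structured-illumination forward models
are out of scope. PSFs are normalized to unit sum and stored
origin-centered; frequency-domain operations use numpy's unshifted layout
with PSFs `ifftshift`-ed before transforming so OTFs have zero phase at DC.

Degradation multiplies the ground-truth spectrum by the ratio OTF
`FT(aPSF)/FT(iPSF)`, zeroed where the ideal OTF magnitude falls below
1e-3 of DC — the unregularized ratio diverges at the support edge, and the
threshold is a bias/blow-up compromise. DC is exactly 1, so mean intensity
is preserved (to within negative-value clipping, <1 % on test phantoms).
An all-zero coefficient vector short-circuits to the exact identity: no
aberration means the degradation operator is the identity, and the literal
ratio path would only add a ~1e-4 support-truncation residue.

Shot noise rescales the volume so the above-threshold mean is `SNR^2`
photons (`SNR = sqrt(S)` for Poisson statistics, threshold 1 % of max),
then draws independent Poisson counts. Output stays in photon units.

## Phantoms

Phantoms contain five structure types — dots, finite-cylinder lines, ring
"circles", filled spheres, spherical-annulus shells — randomly posed in a
256^3 grid of 0.13 um voxels by default. Rasterization is anti-aliased via
2x supersampling and box down-averaging inside each object's bounding box;
overlapping objects combine by maximum. Per-object intensity is uniform on
[0.5, 1.0]. Default counts (40 dots, 15 lines, 10 circles, 8 spheres,
8 shells) and size ranges are package choices, exposed in `PhantomSpec`;
requested sizes are intersected with what the grid can hold, and a range
whose minimum cannot fit raises.

## Training pairs and the reference model

A training corpus is `n_sources x n_aberrations_per` pairs (the standard
protocol: 10 aberrations per source, e.g. 50 phantoms -> 500 pairs), each
pair carrying a derived seed, coefficients, RMS and SNR target in a JSON
manifest, so any aberrated volume is reproducible bit-for-bit.

The shipped restoration model is a **learned linear restoration filter**:
transfer function `G = 1 + H` with the correction `H` fit to
mean-normalized (aberrated -> ground truth) pairs by full-batch,
ridge-damped per-frequency descent from `H = 0`. The residual
parameterization matters: frequencies the data constrain weakly stay at
the identity rather than being shrunk to zero, which is what keeps the
filter from amplifying noise, and early stopping (the `epochs` parameter,
default 5; ridge 1e-2; step 0.5) acts as the regularizer. Orderings on the
benchmark are stable across ridge 1e-3..1. The model is deliberately small
— a desk-scale stand-in that exercises the same training and tiled
inference plumbing a deep residual-attention network would use at full
scale; any object with a shape-preserving `apply(volume)` can be plugged
in instead.

Tiled application lays out overlapping tiles (default overlap 32 voxels),
weights each with separable linear ramps, and normalizes by the accumulated
weight so the effective blending weights are an exact partition of unity;
an identity model round-trips the volume to 1e-6 and a pointwise linear
model exactly.

## Restoration baseline and preprocessing

Richardson–Lucy uses multiplicative updates with circular (FFT) edge
handling and the flipped-PSF adjoint, initialized from a flat field at the
observed mean; 20 iterations is the baseline protocol. Background
subtraction is a uniform clip-at-zero. Attenuation compensation multiplies
plane z by `exp(alpha * z)` with z the plane index from the shallow side
and alpha = 0.01 per plane by default (the paper-scale value; units are
per-plane because source stacks state depth in planes). Time-lapse
renormalization undoes per-timepoint 0-1 input normalization: ratio
`r_k = mean(raw pre) / mean(raw post)` per time point, predictions scaled
by `r_k / r_1`; means are whole-volume.

## Metrics

SSIM and PSNR are scikit-image's, configured as the MATLAB-standard
variant (Gaussian window sigma 1.5, K1 = 0.01, K2 = 0.03, population
covariance), data range from the reference. RMS contrast divides by the
mean, bins 3-fold by block averaging (trimming the remainder), and takes
the sample (ddof = 1) standard deviation. The SNR estimate is the square
root of the above-threshold mean. DCTS is the Shannon entropy of
L2-normalized DCT-II coefficients inside the OTF-support radius, divided
by the number of supported coefficients; an all-zero plane scores 0 by
convention.

In the restoration benchmark, volumes are brought to a common scale by
total-flux (mean) normalization before scoring, because raw photon-unit,
deconvolved and predicted volumes live in different intensity units. The
benchmark's phantoms are structure-rich (30 dots, 12 lines, 6 circles,
5 spheres, 5 shells per 64^3, ~25 % foreground after blurring): on
near-empty volumes the background dominates SSIM and the raw aberrated
input is already "structurally similar" to the reference, which buries the
restoration contrast the benchmark exists to measure. One benchmark
finding is worth stating: Richardson–Lucy with the true aberrated PSF
improves SSIM over the raw input but *lowers* PSNR (noise amplification),
while the trained filter improves both.

## Orientation and directional variance

Fiber voxels are selected by six-level multi-Otsu thresholding (lowest
class = background; histogram restricted to 64 bins, since the exhaustive
5-threshold search is combinatorial in the bin count and finer bins do not
move the thresholds meaningfully). Per-voxel orientation considers all
discrete lines through the center of an `n^3` window (lattice directions
to the boundary shell, gcd-reduced, antipode-deduplicated), each weighted
by `(masked length) / (1 + variance/mean^2 of intensities along the
line)`. Because orientations are axial, the weighted summation is realized
through the weighted second-moment tensor and its principal eigenvector: a
uniform weight floor over all lines only adds a multiple of the identity
and cannot tilt the principal axis, whereas summing sign-folded unit
vectors biases every estimate toward the folding hemisphere's pole (a +y
cylinder comes out tens of degrees wrong that way). The weight formula is
pluggable in spirit — the length/variance form is one concrete reading of
"weighted by length and intensity variations".

The window should span two to three fiber thicknesses. Windows smaller
than about 1.5 thicknesses sit entirely inside the fiber and see a
near-isotropic tensor; voxels at the mask boundary with signal comparable
to noise also carry unreliable orientations. Median angular error on
synthetic cylinders at proper window sizes is ~0.1 degree.

Angles are reported in degrees on [0, 180): theta (azimuth of the
xy-projection from +x), beta (zx-projection from +x), gamma (yz-projection
from -y), and the polar angle phi (from +z), computed from direction
cosines so the identity `tan^2 phi = 1/tan^2 beta + 1/tan^2 gamma` holds
without touching the tangent singularities. Directional variance averages
the unit-norm per-voxel contributions
`(f cos 2theta, f sin 2theta, SI) / sqrt(1+f^2)` with
`f = sqrt(1/tan^2 2beta + 1/tan^2 2gamma)` and `SI = -sign(phi - 90)`
(defined 0 at phi = 90 exactly, where the formula is 0/0); the unit norm
makes `DV = 1 - |mean|` provably lie in [0, 1].

## Problem sizes and determinism

Tests and the acceptance script run at reduced scale as the package's own
choice: 32–64^3 grids for forward-model and benchmark checks (the paper
protocol's full 256^3 is supported and used by the defaults), 10 evaluation
pairs for the restoration orderings, 10^4 draws for isotropy Monte-Carlo.
All sampling flows through `numpy.random.default_rng` seeds recorded in
manifests and config snapshots; identical seeds give bit-identical
volumes, manifests and metrics.

## What the synthetic tests do not show

The phantom generator emulates geometric structure, not tissue: no
refractive-index heterogeneity, no depth-*varying* aberrations within one
volume (the degradation applies one aberration per volume), no spatially
varying (laterally) wavefronts, no camera read noise or background
autofluorescence, and sharp-edged objects rather than textured biology.
Passing benchmarks therefore establishes that the machinery is
self-consistent and that restoration orderings hold under the stated
degradation model — not that a model trained on these phantoms transfers
to any particular instrument. The forward model is scalar (no high-NA
polarization effects) and single-view; multiview fusion, blind
deconvolution and resolution estimation by decorrelation analysis are
intentionally out of scope.
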