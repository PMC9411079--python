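# Methods

## Peak model and profile isolation

The package models a resolved high-resolution mass peak profile as a
Gaussian in m/z, which is the usual working assumption for Orbitrap
profiles (they can also be apodized towards a Lorentzian; a strongly
non-Gaussian profile then simply earns a low score rather than a wrong
"clean" centroid). Profiles are cut out of a spectrum between exact-zero
intensities — Orbitrap converters surround each resolved profile with true
zeros, so zeros act as predefined boundaries. Only `intensity == 0` counts;
there is no epsilon threshold.

Two refinements:

* **Valley splitting.** Inside a nonzero run, every strict local minimum
  splits the run, and the valley point belongs to *both* neighbouring
  profiles. A flat run of equal minimal values between two higher
  neighbours is treated as a single valley at its leftmost index — a
  deterministic convention, since plateaus are otherwise ambiguous.
  Deconvolution of overlapping profiles is deliberately out of scope: it
  would turn a linear per-profile fit into a slow non-linear joint fit.
* **Implicit zeros.** Some converters omit zero points instead of storing
  them. A run is therefore also broken wherever the m/z step exceeds
  `gap_factor` (default 4) times the run's median grid step. The default is
  chosen to be inert on fully zero-padded data.

## Weighted log-parabola regression

Taking logs turns the Gaussian into a parabola
`ln I = b0 + b1 x + b2 x^2`, fitted by weighted linear least squares with
weights `w_i = (I_i / sum I)^2` computed within each profile. The squared
relative-intensity weights counteract the log transform's amplification of
noise in the low-intensity tails; the exponent is exposed
(`weight_power`, default 2) because other instruments may prefer a
different damping. Weights are used exactly as defined (not renormalized),
and the mean square error uses `dof = n - 3`.

Numerics: each profile's m/z axis is centered on its most intense point
(leftmost on ties) before building the Vandermonde matrix. Raw m/z of order
1e2–1e3 against widths of order 1e-3 would otherwise make the normal
equations ill-conditioned by ~20 orders of magnitude. The centroid is
un-shifted on output; width, height and all propagated uncertainties are
shift-invariant (verified by equivariance tests).

Two solver paths exist and are tested to agree to 1e-9 relative: an
independent 3×3 normal-equation solve per profile (default) and a blocked
sparse solve that stacks all profiles of a spectrum into one block-diagonal
system — the layout that makes large spectra cheap in languages where loop
overhead dominates.

Acceptance filters, applied in order and always reported with a reason:
`min_points` (fewer than 4 points leaves no residual degree of freedom),
`beta2_nonneg` (an upward-opening log-parabola has no real Gaussian width),
and a defensive `nonfinite`. There is no positional sanity filter beyond
these two criteria; instead the output carries an `apex_inside` flag
(fitted centroid within the profile's m/z span) so users can filter
themselves without the pipeline silently changing behaviour.

## Error propagation and the score

The coefficient covariance is `MSE * (X^T W X)^-1`. The height error uses
the full covariance, `dI0^2 = g^T C g` with
`g = I0 * (1, x0', x0'^2)` in centered coordinates, because the height
depends on all three coefficients; the width error is
`dsigma = |1/(4 sigma b2^2)| * sqrt(C[2,2])`. The area error combines the
two *without* a height–width cross term:
`dA = sqrt(2 pi) * sqrt(sigma^2 dI0^2 + I0^2 dsigma^2)`. Whether a cross
term belongs there is a genuine design choice; the variance-only form is
used and isolated in one function (`regression.backtransform`) so the
alternative is a one-line change.

`DQS = 1 - erf(dA/A)`, clamped to [0, 1] against floating-point underflow.
Categories I–IV are bounded at relative area errors of 1%, 5% and 33% —
the familiar significance-testing levels — with thresholds computed from
those three numbers at import time, never hard-coded as DQS decimals. The
boundary convention is half-open with the better category claiming the
boundary (a relative error of exactly 1% is still category I).

`nrmse` is `sqrt(MSE)` divided by the profile's mean log intensity. It is a
fit-quality diagnostic on the regression scale, complementary to the DQS
(which is about parameter confidence, not residual size alone).

## Derived quantities

FWHM = 2·sqrt(2 ln 2)·sigma; mass resolution R = m/FWHM; mass accuracy in
signed ppm. The resolution–m/z relationship is summarized by fitting
`R = a * m^b` with non-linear least squares (initialized from the log–log
linear fit, which is exact on noiseless power-law data). Cross-scan m/z
precision chains centroids over consecutive scans: a centroid joins the
open chain whose running mean m/z lies within `ppm_tol` (default 3 ppm, a
typical Orbitrap extraction window; running mean rather than last member,
which would drift), tolerating at most `max_gap = 2` consecutive missing
scans, and keeping chains of at least `min_size = 10`. "Missing scans" is
the chosen reading of an interruption; both readings are expressible
through `max_gap`. Scan numbering uses the trailing integer of the scan id
when available so that genuinely missing scans count as gaps.

## Synthetic data

The generator emulates the features of Orbitrap MS1 data that the method
actually depends on, at desk scale:

* **Widths** follow `R(m) = 70000 * (200/m)^0.5` (nominal resolution
  70,000 at m/z 200), converted to Gaussian sigma via the FWHM relation.
* **Points per profile**: drawn as `4 + Poisson(2.9)` capped at 20, giving
  the 4–20 range with mean ≈ 6.9 observed for real Orbitrap profiles; each
  peak is sampled on a uniform grid over ±3σ (beyond which Orbitrap
  profiles are zero-filled; the generator zero-fills each peak's
  contribution beyond its own window, plus half a grid step so edge samples
  survive). Explicit peak lists instead use a grid of step
  `FWHM / points_per_fwhm` (default 2.5).
* **Heights** log-uniform in 1e4–1e7; a detector floor of 1 count truncates
  small model values to zero and thereby defines the zero boundaries.
* **Noise** is multiplicative log-normal, `I * exp(eps)`,
  `eps ~ N(0, noise_cv)` — consistent with the log-domain regression and
  with Orbitrap intensity behaviour. This is the generator's strongest
  assumption and is isolated in one place; an additive option exists for
  stress tests. Randomness comes from numpy's seeded PCG64, so spectra are
  bit-reproducible across platforms.

What the generator does **not** emulate: isotopic patterns, chromatographic
elution, centroid drift across scans, heteroscedastic detector noise, or
non-Gaussian (Lorentzian/Bi-Gaussian) peak shapes. Green tests on synthetic
data therefore demonstrate correctness of the algorithmic chain and its
error propagation, not instrument-grade performance on real files.

## The overlap experiment

`overlap_experiment` generates pairs of equal-height Gaussians at
controlled center separations (in multiples of sigma), runs the full
pipeline, and reports mean and standard deviation of the DQS per
separation (default 200 replicates, 1% noise, a random grid phase per
replicate so results are not tied to one sampling alignment).

Measured behaviour is **U-shaped**, not monotone: the mean DQS falls from
≈ 0.98 at 6σ to ≈ 0.87 around 3σ, where valley-split half-profiles are most
contaminated by the neighbour's tail — and then *rises again* towards
≈ 0.97 at 1.5σ. Below the separation at which a valley can still be
sampled, the two peaks merge into a single symmetric, near-Gaussian blob
that the regression fits confidently. This is a real and instructive
limitation of the score: DQS flags *asymmetric* or *partially split*
interference strongly, but a symmetric equal-height merge largely evades
it (the merged centroid sits between the true peaks, with an inflated
width — the `sigma` column and the resolution law are the way to catch
such cases). The merged pair still scores below an isolated peak under
identical noise, and the resolved→split branch (6σ→3σ) is strictly
decreasing; both properties are asserted in the test suite.

## Problem sizes and tolerances

The test suite works at desk scale chosen to keep the full run around ten
seconds while still exercising every claim: 1000 peaks for exact-recovery
and oracle-agreement checks, 100 spectra for solver equivalence, 200
replicates per separation for the overlap study. Exactness claims use
1e-9 relative (noiseless recovery, solver equivalence), which is the level
float64 supports through the covariance chain for 4–20-point profiles;
agreement with the iterative non-linear oracle is required within
0.1 fitted sigma for at least 99% of noisy profiles.
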