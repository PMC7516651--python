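# Methods

## The quality measure

`enmiqa` scores a 2-D magnitude MR image without any reference image. The
idea: isolated single-pixel intensity impulses — pixels strictly brighter or
darker than their whole neighborhood by more than a margin `t` — are the
footprint of acquisition noise and reconstruction artifacts. A clean image
contains a few such extrema, and only at small margins; a degraded image keeps
producing them as the margin grows.

Formally, for a threshold `t` a pixel at `(a, b)` passes the extremum test
when

    I(a,b) > I(a+i, b+j) + t   for every neighbor offset (i, j),  or
    I(a,b) < I(a+i, b+j) - t   for every neighbor offset (i, j),

with strict inequalities (plateaus are never extrema). The count of passing
pixels is `I(t)`, and sweeping `t = 1..S` gives the extrema profile
`I(1), ..., I(S)`. The profile is renormalized to a probability distribution
`k_t = I(t) / sum_u I(u)` and the score is its Shannon entropy

    h = - sum_t k_t ln k_t ,    0 <= h <= ln S .

Low entropy means the extrema die out quickly (mass concentrated at small
`t`): a clean image. High entropy means extrema persist across thresholds: a
distorted image. The score is *higher for worse images*; the evaluation
protocol's monotone mapping absorbs the polarity, so no sign convention is
imposed on the raw score.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `S` | 30 | largest threshold, in intensity units; the profile has S cells. The measure is stable for S roughly between 20 and 60 on 8-bit data; for 16-bit dynamic ranges S should be scaled by the user. |
| neighborhood | 8 | offsets used by the test. The full 3×3 neighborhood is the method's setting; the 4-neighborhood (axial offsets only) is exposed for sensitivity analyses and is markedly more permissive (diagonal equalities no longer veto an extremum). |
| log base | e | entropy units (nats). Correlation-based evaluation is invariant to the base; base 2 is available. |

### Numerical and boundary choices

- The test is evaluated only on pixels whose full neighborhood lies inside
  the image; the one-pixel border is skipped rather than padded. Another
  implementation that pads borders would differ by at most the border count.
- Intensities are kept in native integer units (DICOM rescale slope/intercept
  applied, then rounded). Thresholds are defined in those units, so no silent
  rescaling is done; an opt-in min–max rescale to 0–255 exists for
  cross-bit-depth comparisons.
- Profiles are computed in one pass from each pixel's extremum *margin*
  `max(center − max(neighbors), min(neighbors) − center)`: a pixel passes at
  threshold `t` iff its margin exceeds `t`, which makes the per-threshold
  counts a cumulative histogram of margins. This is exactly equivalent to
  running the test per threshold and is verified against a literal
  double-sum implementation in the tests.
- An all-zero profile (e.g. a constant image) has undefined entropy; the
  score is defined as 0, consistent with reading entropy as intensity
  disorder.
- Entropy is invariant to positive scaling of the counts, so dividing the
  profile by the image size M·N (kept available as `ExtremaProfile.normalized`)
  does not change the score.

## Evaluation protocol

Objective scores `Q` are compared against mean opinion scores (`MOS`, 1–5)
with the standard IQA methodology. A five-parameter monotone logistic
mapping

    Qp = b1 * (1/2 - 1/(1 + exp(b2 (Q - b3)))) + b4 Q + b5

is fitted by nonlinear least squares; PLCC and RMSE are computed on `Qp`,
while SRCC and KRCC are computed on raw `Q` (rank criteria are invariant to
any monotone mapping, so the choice is immaterial and raw scores avoid a
needless dependence on the fit).

- **Fit**: Levenberg–Marquardt from the data-spanning start
  `b = (range(MOS), 1/std(Q), mean(Q), 0, mean(MOS))`, plus a sign-flipped
  start and a start at the ordinary linear fit (the linear family is nested
  at `b1 = 0`); the lowest final SSE wins. The fit is deterministic and never
  worse than plain linear regression.
- **SRCC**: the classical closed form `1 - 6 Σd²/(m(m²-1))` on tie-free data;
  Pearson correlation of average ranks when ties are present.
- **KRCC**: tau-a by exhaustive pair enumeration, `(m_c - m_d)/(m(m-1)/2)`,
  with tied pairs counted in neither term — the printed formula taken
  literally.
- **Jarque–Bera**: `JB = n/6 (skew² + (kurt-3)²/4)` with biased sample
  moments. The χ²(2) asymptote is anti-conservative at moderate n, so below
  n = 2000 the 5% critical value is simulated (50,000 seeded Monte-Carlo
  replicates, cached per n).
- **Variance-ratio F-test**: a normal distribution is fitted to each
  measure's residual vector, 1000 samples are drawn from each (explicit
  seed, recorded in the result), and the ratio of the drawn sample variances
  is referred to F(999, 999). Both the two-sided decision (variances differ)
  and the one-sided decision (first variance smaller) are reported, since
  claims of *smaller* residual variance are one-sided. The test runs only
  after both residual vectors pass the Jarque–Bera gate.

**Known limitation of the resampling step.** Drawing from a *fitted* normal
adds plug-in variance of order `2/L` (L = residual length) per side on the
log variance ratio, on top of the `2/(n_draws - 1)` the F reference accounts
for. The test is therefore correctly sized only when `L` is large relative
to `n_draws`; for residual vectors of a few dozen images it can over-reject
substantially. The calibration test in this package uses L = 100,000 null
residual vectors, where the measured two-sided rejection rate at the 95%
level is ≈ 5%.

## Synthetic phantoms

The generator emulates the essential structure of magnitude MR slices:
bright, smoothly shaded anatomy (composited ellipses, optionally with a
linear radial intensity gradient) on a dark background, with optional
Gaussian blur and a noise model. The `rician` model

    out = round( sqrt( (A + n1)² + n2² ) ),   n1, n2 ~ N(0, σ)

is the physically motivated default: magnitude reconstruction of complex
Gaussian noise yields Rician intensities, reducing to a Rayleigh
distribution (mean σ√(π/2)) where the signal is zero — a closed form the
tests verify. The default phantom is a 160×160, 8-bit canvas with background
level 12 and four ellipses at intensities 60–240, two of them
gradient-shaded. Rendering is deterministic; noise is reproducible under an
explicit seed.

What the phantoms do **not** emulate: parallel-imaging (GRAPPA) artifacts,
k-space undersampling, motion, bias fields, or anatomical texture. Real MR
degradations from shortened acquisition share with Rician noise the property
the measure responds to — isolated local intensity extrema — but passing
tests on phantoms demonstrates correctness and monotone distortion response
of the implementation, not clinical-level agreement with radiologist
opinion. Validation against human scores requires a real dataset of images
with MOS, which the `batch` + `evaluate` commands accept directly
(images + `image_id,mos` CSV).

## Problem sizes in the test suite

Exact-equivalence checks run on hundreds of random images up to 16×16 (where
a literal double-sum oracle is affordable); distortion-response checks
average 20 phantom replicates per noise level at 160×160; F-test calibration
uses 500 Monte-Carlo replicates. These sizes give stable statistics for
every property asserted.
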