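# Methods

## Model and procedure

`undark` treats a low-lighting underwater image as the photometric inverse
of a hazy one. On the internal [0, 1] intensity scale the inversion is
`x̄ = 1 − x` (the 8-bit `255 − x` rule). The inverted image is modelled as

    I(x) = J(x) t(x) + A (1 − t(x)),

a linear mix of attenuated scene radiance `J` and atmospheric light `A`
weighted by the transmission `t(x)`, the fraction of scene light reaching
the camera unscattered. Dehazing the inverted image and inverting back
brightens the original's dark regions while leaving well-lit regions alone.

The pipeline stages, in fixed order:

1. **Invert** the input; compute the **grayscale** of the inverted image
   (BT.601 weights 0.299/0.587/0.114).
2. **Contrast code image (CCI).** For every pixel, the population standard
   deviation σ of the inverted grayscale is computed inside seven candidate
   square windows, 3×3 … 15×15, coded `c = 1..7` (side `2c + 1`). Codes
   start at 7; candidates are scanned 6 → 1 and candidate `c` displaces the
   accepted `c_best` iff `σ_c < σ_best (1 − t/100)^(c_best − c)` with
   tolerance `t` in percent. The exponent compounds per code step, so at
   `t = 5` a jump from 15×15 straight to 3×3 needs `0.95⁶ ≈ 73.51%` of the
   accepted σ. An earlier acceptance stands even if later candidates fail.
   At `t = 0` the rule degenerates to "smallest σ wins, ties to the larger
   window". σ is deliberately computed on the *inverted* image; since
   inversion is affine with slope −1, σ — and therefore the CCI — is
   identical either way.
3. **Dark channel** `min_window(min_channel I)` with the window side taken
   per pixel from the CCI.
4. **Atmospheric light.** `A_c` = per-channel mean of the inverted image at
   the `⌈0.002·H·W⌉` brightest dark-channel positions (minimum one).
5. **Transmission** `t(x) = 1 − ω · min_window(min_c I_c/A_c)`, window per
   pixel from the CCI, clamped to [0, 1].
6. **Refinement** with a fast guided filter (below), guided by the inverted
   grayscale, then re-clamped.
7. **Recovery** `J = (I − A)/max(t, t0) + A`, clamped to [0, 1], and a final
   inversion.

The result object carries every intermediate (CCI, dark channel, raw and
refined transmission, airlight) for inspection and dumping.

## Guided filter

Within each window of radius `r` the output is an affine function of the
guide: `a_k = cov(I, p)/(var(I) + ε)`, `b_k = mean(p) − a_k mean(I)`, and
each pixel averages the coefficients of all windows covering it. The fast
variant subsamples guide and source by ratio `s` (bilinear), computes the
coefficient maps at radius `max(1, round(r/s))`, upsamples the
window-averaged coefficients bilinearly, and applies the affine form at
full resolution. `r` is defined at full resolution, as in the fast
variant's source literature. With `s = 1` the fast path calls the exact
filter, bit-identically. Measured on band-limited smooth fields
(64×80, r = 8, s = 4) the fast/exact discrepancy peaks near 0.07 on the
[0, 1] scale; 0.1 is the documented bound asserted in tests. The guide is
the grayscale of the inverted input — the construction of the guided-filter
literature — so scene edges transfer into the refined map and halos shrink.

## Parameters

| name | default | units | role |
| --- | --- | --- | --- |
| `omega` | 0.9 | – | haze-removal strength; 0 keeps all haze (identity), 1 removes everything |
| `tolerance_pct` | 3 | % | per-code-step σ reduction required to pick a smaller window |
| `t0` | 0.1 | – | transmission floor in recovery; bounds noise amplification in dense regions |
| `airlight_fraction` | 0.002 | – | share of brightest dark-channel pixels averaged for A |
| `gf.radius` | 28 | px | guided-filter window radius at full resolution |
| `gf.eps` | 0.45 | – | guided-filter smoothing degree |
| `gf.subsample` | 4 | – | fast-variant subsampling ratio |

`omega`, `tolerance_pct` and the guided-filter triple are the operating
point used for the method's reference evaluation on 1280×720 footage; `t0 =
0.1` follows the original dark-channel-prior work (the value is otherwise
unstated), and 0.2% with ceiling and a one-pixel minimum makes the airlight
estimate well-defined down to tiny images.

## Numerical choices

- Intensities are float64 in [0, 1] throughout; clamping happens at stage
  exits, not mid-formula. File I/O is 8-bit with round-half-even rescaling.
- All windowed operators (σ, minima, box means) replicate edges so border
  pixels see full-size windows and the CCI is defined everywhere.
- σ uses the population (divisor N) form via running box means of `g` and
  `g²`. The cancellation `E[g²] − E[g]²` leaves O(1e−13) round-off where
  the true variance is zero, which would scramble code selection in flat
  regions; variances below 1e−10 are floored to exactly zero. The smallest
  variance a genuinely non-constant 8-bit window can have is ~6e−8 (one
  1/255 step in a 15×15 window), so the floor is three decades below any
  real structure and five above the round-off.
- Brightest-pixel selection for A breaks ties by row-major scan order
  (stable argsort), making runs bit-reproducible.
- Ties in code selection resolve to the larger window (strict inequality in
  the acceptance test), so a constant image is all code 7.
- Degenerate inputs: an all-black image inverts to all-white, giving
  A = (1,1,1) and flat transmission `1 − ω`; the pipeline proceeds and
  clamps. An all-white image makes the inverted image black and A zero;
  the transmission stage raises a degenerate-airlight error rather than
  dividing by zero.

## Synthetic scenes

The generator composes what archive deep-sea frames actually contain: a
flat dark background, flat patches, bright blocks (lights, specular
targets) and textured squares, under a known transmission field (constant,
ramp, radial, or random blockwise) and airlight, with
`lowlight(J) = invert(apply_haze(invert(J), t, A))` so the planted haze is
exactly what the dehazer sees. One seeded `default_rng` drives all
randomness.

Two texture primitives are provided because they probe opposite σ regimes:
a periodic checkerboard has nearly scale-independent σ, so code selection
correctly keeps large windows over it, while band-limited noise (uniform
noise smoothed over a stated length, rescaled to a stated amplitude) has σ
growing with window size, so small windows win over it — the behaviour
expected over rocks and instrument structure. The generator emulates
layout, lighting and texture statistics only; it does not model
wavelength-dependent attenuation, forward-scatter blur, sensor noise or
compression artifacts, so passing tests demonstrate correctness of the
algorithmic pipeline, not photorealistic performance on real footage.

The scale/halo study uses a 240×320 step-edge scene with a bright vertical
stripe and uniform darkening, downscaled to 50% and 25%. The measured
quantity is the peak-to-peak intensity in a corridor at a fixed *relative*
offset between edge and stripe: at full scale no 15×15 window reaches a
feature from inside the corridor (both approaches leave it flat); after
downscaling, fixed 15×15 windows reach the stripe and corrupt the corridor,
while the CCI drops to small codes there. That study uses tolerance 5 and a
proportionate guided filter (r = 4, ε = 0.01, s = 1), since a radius-28
filter on a 60×80 image would smooth away the very structure under study.

## Problem sizes

Tests run on images from 8×8 (brute-force oracle equivalence, 20 seeds) to
96×128 synthetic scenes, the scale study at 240×320, and one 1280×720 frame
for window-count accounting; the full suite completes in a few seconds.

## Known limitations

- Window sizes stop at 15×15; very large smooth gradients may still prefer
  even larger windows.
- A single global airlight; scenes with several light sources violate the
  model and get a compromise A.
- No chromatic correction: channels are dehazed jointly with one t, so
  colour casts survive enhancement.
- The e-/r-scores depend on the Canny/Sobel operators as implemented in
  scikit-image; absolute values are not comparable across toolchains,
  ratios and orderings are.
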