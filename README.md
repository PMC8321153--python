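# undark

Contrast-guided enhancement of low-lighting underwater images.

Deep-sea cameras depend on artificial lighting, so their footage pairs
well-lit structures with large poorly-lit regions in which animals and
instruments are barely visible — a problem for both human annotators and
automated marine image analysis. `undark` brightens exactly those regions:
darkness in a low-light image behaves like haze in its inverted version, so
the enhancer inverts the input, removes the "haze" with a dark-channel-prior
pipeline, and inverts back.

## Method

The inverted image is modelled as a hazy observation

```
I(x) = J(x) t(x) + A (1 − t(x))
```

with scene radiance `J`, per-channel atmospheric light `A`, and transmission
map `t ∈ [0, 1]`. The dark channel `min_window(min_channel I)` drives the
estimates: `A` is the per-channel mean of the image at the 0.2% brightest
dark-channel positions, the transmission is
`t(x) = 1 − ω · min_window(min_c I_c / A_c)`, and the radiance is recovered
as `J = (I − A) / max(t, t0) + A`.

The distinguishing step is the **contrast code image (CCI)**: instead of one
fixed window, every pixel gets a window side `2c + 1` with code `c ∈ 1..7`
(3×3 … 15×15) chosen from the local standard deviation σ of the inverted
grayscale. Large windows strengthen the dark-channel prior but create halos
around strong gradients; small windows avoid halos but oversaturate the
radiance. The selection starts at code 7 and lets a smaller window win only
if its σ beats the accepted one by a compounding tolerance margin,
`σ_c < σ_best (1 − t/100)^(c_best − c)` — at `t = 5%` a 3×3 window must reach
73.51% of the 15×15 σ. The raw transmission map is refined with a fast
guided filter (subsampled, locally affine in the guidance image) before
recovery.

The package also ships the blind evaluation scores used for such enhancers
(e-score: relative visible-edge increase via Canny; r-score: geometric-mean
gradient ratio at visible edges; GCF: multi-resolution global contrast
factor) and a deterministic synthetic scene generator with known
transmission ground truth, so the whole pipeline is testable without any
external dataset.

## Worked example

```python
import numpy as np
from undark import (default_scene_spec, make_scene, render_t_field,
                    make_lowlight, enhance, to_grayscale, compute_report,
                    code_histogram)

spec = default_scene_spec(seed=7)                  # 96x128 synthetic seabed
J, masks = make_scene(spec)                        # clean radiance + masks
t = render_t_field(spec.t_field, spec.height, spec.width)
low = make_lowlight(J, t, spec.airlight)           # low-light observation

res = enhance(low)                                 # default parameters
rep = compute_report(to_grayscale(low), to_grayscale(res.enhanced))
```

Output for this scene:

```
mean intensity (input):      0.296
mean intensity (enhanced):   0.560
dark-region mean in -> out:  0.235 -> 0.354
estimated airlight A:        [0.778 0.793 0.807]
CCI code histogram:          {1: 11540, 2: 12, 3: 3, 4: 0, 5: 0, 6: 4, 7: 729}
e-score: 0.027   r-score: 2.133   GCF 1.784 -> 5.475
```

The enhancement roughly doubles the overall brightness, lifts the darkened
corners (transmission < 0.5) from 0.235 to 0.354 mean intensity, and the
r-score of 2.13 and tripled GCF confirm the visibility and contrast gain.
The code histogram shows the CCI at work: code 1 (3×3) dominates where the
radial lighting gradient and textures demand fine windows, while the
homogeneous regions keep code 7 (15×15).

A command-line interface mirrors the library:

```
undark scene.png -o enhanced.png --tolerance 3 --metrics scores.json \
       --dump-intermediates debug/
```

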