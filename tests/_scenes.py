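"""Shared synthetic experiment scenes for cross-module tests."""

from __future__ import annotations

import numpy as np
from skimage.transform import resize

from undark.guided_filter import GuidedFilterParams
from undark.imagery import to_grayscale
from undark.pipeline import EnhancementParams, enhance
from undark.synthfix import make_lowlight

#: Experiment configuration for the scale/halo study: the tolerance used in
#: the scale experiment and a guided filter proportionate to the scene size.
SCALE_STUDY_PARAMS = EnhancementParams(
    omega=0.9,
    tolerance_pct=5.0,
    gf=GuidedFilterParams(radius=4, eps=0.01, subsample=1),
)


def step_stripe_scene(height: int = 240, width: int = 320) -> np.ndarray:
    """Low-light scene with a radiance step edge at mid-width and a bright
    vertical stripe at 3/4 width (a lit structure), under uniform darkening.

    The corridor between edge and stripe is perfectly flat, so any intensity
    variation the enhancer introduces there is a dehazing artifact (halo).
    """
    J = np.empty((height, width, 3))
    J[:, : width // 2] = 0.25
    J[:, width // 2 :] = 0.7
    s0 = int(0.75 * width)
    J[:, s0 : s0 + int(0.04 * width)] = 0.98
    t = np.full((height, width), 0.55)
    return make_lowlight(J, t, (0.9, 0.9, 0.9))


def corridor_flatness_violation(gray: np.ndarray) -> float:
    """Peak-to-peak intensity inside the flat corridor right of the edge.

    The corridor sits at a fixed *relative* offset (11%–16% of the width,
    right of centre): far enough from both features that full-resolution
    windows never reach it, but close enough that a fixed 15×15 window does
    reach the stripe once the image is downscaled.
    """
    w = gray.shape[1]
    lo = w // 2 + int(0.11 * w)
    hi = max(w // 2 + int(0.16 * w), lo + 2)
    return float(np.ptp(gray[:, lo:hi]))


def halo_growth_under_downscaling(patch_code: int | None) -> list[float]:
    """Corridor flatness violation at 100%/50%/25% scale for the CCI-guided
    (``patch_code=None``) or fixed-window enhancement."""
    base = step_stripe_scene()
    h, w = base.shape[:2]
    values = []
    for scale in (1.0, 0.5, 0.25):
        if scale == 1.0:
            img = base
        else:
            img = resize(
                base, (int(h * scale), int(w * scale), 3), order=1, anti_aliasing=True
            )
        res = enhance(img, SCALE_STUDY_PARAMS, patch_code=patch_code)
        values.append(corridor_flatness_violation(to_grayscale(res.enhanced)))
    return values
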