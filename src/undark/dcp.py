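"""Dark-channel-prior dehazing primitives.

The hazy image model is ``I(x) = J(x)·t(x) + A·(1 − t(x))`` with observed
image *I*, scene radiance *J*, global atmospheric light *A* (one scalar per
colour channel) and transmission map ``t ∈ [0, 1]``.  The dark channel of an
image is the windowed minimum, over space and colour channels, of its
intensities; the dark-channel prior says it is near zero for haze-free
natural content, which turns the model into estimators for *A* and *t* and
finally the recovery ``J = (I − A)/max(t, t0) + A``.

All windowed minima replicate edges so border pixels see full windows, and
the window side can be fixed or taken per pixel from a contrast code image
(see :mod:`undark.cci`).
"""

from __future__ import annotations

import math

import numpy as np
from scipy.ndimage import minimum_filter

from .cci import N_CODES, patch_size_from_code

__all__ = [
    "dark_channel_fixed",
    "dark_channel_cci",
    "estimate_atmospheric_light",
    "transmission_map",
    "recover_radiance",
]


def _check_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) array, got shape {img.shape}")
    return img


def dark_channel_fixed(img: np.ndarray, patch_size: int) -> np.ndarray:
    """Dark channel with one window size for every pixel.

    Per pixel: minimum over R, G, B, then minimum over the centred
    ``patch_size × patch_size`` window (edge-replicated).
    """
    img = _check_rgb(img)
    patch_size = int(patch_size)
    if patch_size < 1 or patch_size % 2 == 0:
        raise ValueError(f"patch_size must be odd and >= 1, got {patch_size}")
    return minimum_filter(img.min(axis=2), size=patch_size, mode="nearest")


def _windowed_min_by_code(chan_min: np.ndarray, cci: np.ndarray) -> np.ndarray:
    """Windowed minimum of a 2-D map with the window side taken per pixel
    from the contrast code image."""
    cci = np.asarray(cci)
    if cci.shape != chan_min.shape:
        raise ValueError(
            f"CCI shape {cci.shape} does not match image shape {chan_min.shape}"
        )
    if cci.size and (cci.min() < 1 or cci.max() > N_CODES):
        raise ValueError("CCI codes must lie in 1..7")
    out = np.empty_like(chan_min)
    for c in range(1, N_CODES + 1):
        mask = cci == c
        if mask.any():
            size = patch_size_from_code(c)
            out[mask] = minimum_filter(chan_min, size=size, mode="nearest")[mask]
    return out


def dark_channel_cci(img: np.ndarray, cci: np.ndarray) -> np.ndarray:
    """Contrast-guided dark channel: window side ``2·CCI(x) + 1`` per pixel.

    Pointwise sandwiched between the fixed 15×15 dark channel (below) and
    the fixed 3×3 one (above), since minima over nested windows can only
    decrease.
    """
    img = _check_rgb(img)
    return _windowed_min_by_code(img.min(axis=2), cci)


def estimate_atmospheric_light(
    img: np.ndarray, dark: np.ndarray, fraction: float = 0.002
) -> np.ndarray:
    """Per-channel atmospheric light from the brightest dark-channel pixels.

    Selects the ``ceil(fraction · H · W)`` highest dark-channel positions
    (default 0.2%, at least one pixel; ties broken by row-major scan order
    for determinism) and returns the per-channel mean of the image at those
    positions as ``A = (A_R, A_G, A_B)``.
    """
    img = _check_rgb(img)
    dark = np.asarray(dark, dtype=np.float64)
    if dark.shape != img.shape[:2]:
        raise ValueError(
            f"dark channel shape {dark.shape} does not match image {img.shape[:2]}"
        )
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    k = max(1, math.ceil(fraction * dark.size))
    order = np.argsort(-dark.ravel(), kind="stable")[:k]
    return img.reshape(-1, 3)[order].mean(axis=0)


def transmission_map(
    img: np.ndarray,
    airlight: np.ndarray,
    cci: np.ndarray,
    omega: float = 0.9,
) -> np.ndarray:
    """Contrast-guided transmission estimate
    ``t(x) = 1 − ω · min_window(min_channel I/A)``.

    ``omega ∈ [0, 1]`` sets how much haze is removed (``ω = 0`` keeps it all,
    ``t ≡ 1``); the window side comes from the CCI per pixel.  The result is
    clamped to ``[0, 1]``.
    """
    img = _check_rgb(img)
    airlight = np.asarray(airlight, dtype=np.float64).reshape(3)
    if np.any(airlight <= 0.0):
        raise ValueError(f"degenerate atmospheric light {airlight}: all components must be > 0")
    if not 0.0 <= omega <= 1.0:
        raise ValueError(f"omega must be in [0, 1], got {omega}")
    ratio_min = (img / airlight).min(axis=2)
    t = 1.0 - omega * _windowed_min_by_code(ratio_min, cci)
    return np.clip(t, 0.0, 1.0)


def recover_radiance(
    img: np.ndarray,
    t: np.ndarray,
    airlight: np.ndarray,
    t0: float = 0.1,
    clip: bool = True,
) -> np.ndarray:
    """Invert the hazy image model: ``J = (I − A)/max(t, t0) + A``.

    ``t0`` bounds the denominator away from zero so haze-dense regions do not
    blow up; it deliberately leaves some haze behind there.  With ``clip``
    (the default) the result is clamped to ``[0, 1]`` for display; pass
    ``clip=False`` for algebraic round-trip checks.
    """
    img = _check_rgb(img)
    t = np.asarray(t, dtype=np.float64)
    if t.shape != img.shape[:2]:
        raise ValueError(f"transmission shape {t.shape} does not match image {img.shape[:2]}")
    if not 0.0 < t0 <= 1.0:
        raise ValueError(f"t0 must be in (0, 1], got {t0}")
    airlight = np.asarray(airlight, dtype=np.float64).reshape(3)
    J = (img - airlight) / np.maximum(t, t0)[:, :, None] + airlight
    return np.clip(J, 0.0, 1.0) if clip else J
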