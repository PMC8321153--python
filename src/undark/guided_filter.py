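"""Guided filter and its subsampled fast variant.

The guided filter expresses the output as a locally affine function of a
guidance image: within each square window ``w_k`` of radius *r*,

    q_i = a_k I_i + b_k,
    a_k = cov_k(I, p) / (var_k(I) + ε),      b_k = mean_k(p) − a_k mean_k(I),

and each output pixel averages the coefficients of all windows covering it,
``q_i = ā_i I_i + b̄_i``.  ε > 0 sets the degree of smoothing (large ε drives
a → 0 and the output toward a double box mean of the source).

The fast variant subsamples guide and source by a ratio *s*, computes the
coefficient maps at the reduced scale with radius ``max(1, round(r/s))``,
upsamples the window-averaged coefficients bilinearly, and applies the affine
form at full resolution.  Here it refines raw transmission maps, with the
grayscale inverted input as the guide, so scene edges survive the smoothing
and dehazing halos shrink.

All box means use running-sum accumulation (cost independent of radius) and
replicate edges, consistent with the other windowed operators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter
from skimage.transform import resize

__all__ = ["GuidedFilterParams", "guided_filter", "fast_guided_filter"]


@dataclass(frozen=True)
class GuidedFilterParams:
    """Refinement parameters: full-resolution window radius, smoothing ε,
    and subsampling ratio (1 = plain guided filter)."""

    radius: int = 28
    eps: float = 0.45
    subsample: int = 4

    def __post_init__(self) -> None:
        if int(self.radius) < 1:
            raise ValueError(f"radius must be >= 1, got {self.radius}")
        if not self.eps > 0:
            raise ValueError(f"eps must be > 0, got {self.eps}")
        if int(self.subsample) < 1:
            raise ValueError(f"subsample ratio must be >= 1, got {self.subsample}")


def _box(x: np.ndarray, radius: int) -> np.ndarray:
    return uniform_filter(x, size=2 * radius + 1, mode="nearest")


def _check_pair(guide: np.ndarray, src: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    guide = np.asarray(guide, dtype=np.float64)
    src = np.asarray(src, dtype=np.float64)
    if guide.ndim != 2:
        raise ValueError(f"guide must be 2-D, got shape {guide.shape}")
    if guide.shape != src.shape:
        raise ValueError(f"guide shape {guide.shape} != source shape {src.shape}")
    return guide, src


def _coefficients(
    guide: np.ndarray, src: np.ndarray, radius: int, eps: float
) -> tuple[np.ndarray, np.ndarray]:
    mean_i = _box(guide, radius)
    mean_p = _box(src, radius)
    var_i = _box(guide * guide, radius) - mean_i * mean_i
    cov_ip = _box(guide * src, radius) - mean_i * mean_p
    a = cov_ip / (var_i + eps)
    b = mean_p - a * mean_i
    return a, b


def guided_filter(
    guide: np.ndarray, src: np.ndarray, radius: int = 28, eps: float = 0.45
) -> np.ndarray:
    """Edge-preserving filtering of *src* steered by *guide* (same shape)."""
    guide, src = _check_pair(guide, src)
    radius = int(radius)
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    if not eps > 0:
        raise ValueError(f"eps must be > 0, got {eps}")
    a, b = _coefficients(guide, src, radius, eps)
    return _box(a, radius) * guide + _box(b, radius)


def fast_guided_filter(
    guide: np.ndarray, src: np.ndarray, params: GuidedFilterParams | None = None
) -> np.ndarray:
    """Subsampled guided filter; bit-identical to :func:`guided_filter`
    when ``params.subsample == 1``."""
    if params is None:
        params = GuidedFilterParams()
    guide, src = _check_pair(guide, src)
    s = int(params.subsample)
    if s == 1:
        return guided_filter(guide, src, params.radius, params.eps)
    h, w = guide.shape
    if s > min(h, w) // 2:
        raise ValueError(
            f"subsample ratio {s} too large for a {h}x{w} image (max {min(h, w) // 2})"
        )
    hs, ws = max(2, round(h / s)), max(2, round(w / s))
    guide_s = resize(guide, (hs, ws), order=1, mode="edge", anti_aliasing=False)
    src_s = resize(src, (hs, ws), order=1, mode="edge", anti_aliasing=False)
    radius_s = max(1, round(params.radius / s))
    a, b = _coefficients(guide_s, src_s, radius_s, params.eps)
    a_up = resize(_box(a, radius_s), (h, w), order=1, mode="edge", anti_aliasing=False)
    b_up = resize(_box(b, radius_s), (h, w), order=1, mode="edge", anti_aliasing=False)
    return a_up * guide + b_up
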