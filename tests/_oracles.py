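"""Independent brute-force oracles for the windowed operators.

Everything here is written as directly as possible — explicit per-pixel
loops over edge-replicated padded arrays — and stays independent of the
implementations it checks.  Intended only for tiny images.
"""

from __future__ import annotations

import numpy as np


def _padded_window(padded: np.ndarray, y: int, x: int, size: int) -> np.ndarray:
    # padded has a border of size//2 replicated pixels; (y, x) indexes the
    # original image, so the window starts at (y, x) in padded coordinates.
    return padded[y : y + size, x : x + size]


def brute_local_sigma(gray: np.ndarray, size: int) -> np.ndarray:
    half = size // 2
    padded = np.pad(gray, half, mode="edge")
    out = np.empty_like(gray, dtype=np.float64)
    for y in range(gray.shape[0]):
        for x in range(gray.shape[1]):
            win = _padded_window(padded, y, x, size)
            out[y, x] = np.sqrt(np.mean((win - win.mean()) ** 2))
    return out


def brute_dark_channel(img: np.ndarray, size: int) -> np.ndarray:
    half = size // 2
    chan_min = img.min(axis=2)
    padded = np.pad(chan_min, half, mode="edge")
    out = np.empty_like(chan_min)
    for y in range(chan_min.shape[0]):
        for x in range(chan_min.shape[1]):
            out[y, x] = _padded_window(padded, y, x, size).min()
    return out


def brute_select_codes(sigmas: np.ndarray, tolerance_pct: float) -> np.ndarray:
    """Per-pixel Python re-derivation of the code-selection scan."""
    n, h, w = sigmas.shape
    shrink = 1.0 - tolerance_pct / 100.0
    codes = np.empty((h, w), dtype=np.int64)
    for y in range(h):
        for x in range(w):
            best_code = n
            best_sigma = sigmas[n - 1, y, x]
            for c in range(n - 1, 0, -1):
                if sigmas[c - 1, y, x] < best_sigma * shrink ** (best_code - c):
                    best_code = c
                    best_sigma = sigmas[c - 1, y, x]
            codes[y, x] = best_code
    return codes


def brute_box_mean(x: np.ndarray, radius: int) -> np.ndarray:
    size = 2 * radius + 1
    padded = np.pad(x, radius, mode="edge")
    out = np.empty_like(x, dtype=np.float64)
    for y in range(x.shape[0]):
        for xx in range(x.shape[1]):
            out[y, xx] = _padded_window(padded, y, xx, size).mean()
    return out


def brute_guided_filter_coefficients(
    guide: np.ndarray, src: np.ndarray, radius: int, eps: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window affine coefficients a_k, b_k from windowed moments."""
    mean_i = brute_box_mean(guide, radius)
    mean_p = brute_box_mean(src, radius)
    corr_ip = brute_box_mean(guide * src, radius)
    corr_ii = brute_box_mean(guide * guide, radius)
    a = (corr_ip - mean_i * mean_p) / (corr_ii - mean_i * mean_i + eps)
    b = mean_p - a * mean_i
    return a, b


def brute_guided_filter(
    guide: np.ndarray, src: np.ndarray, radius: int, eps: float
) -> np.ndarray:
    a, b = brute_guided_filter_coefficients(guide, src, radius, eps)
    return brute_box_mean(a, radius) * guide + brute_box_mean(b, radius)
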