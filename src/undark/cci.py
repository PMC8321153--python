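"""Contrast code image (CCI): per-pixel selection of dehazing patch sizes.

Dark-channel dehazing applies a windowed minimum whose window ("patch") size
trades off two failure modes: small patches weaken the dark-channel prior and
oversaturate the recovered radiance, large patches create halos around strong
gradients.  The CCI resolves this per pixel by examining the local standard
deviation σ of the (inverted, grayscale) image inside seven candidate square
windows, 3×3 through 15×15, coded ``c = 1..7`` with side ``2c + 1``.

Selection favours large windows: every pixel starts at code 7, candidates are
scanned downward, and a smaller window only displaces the currently accepted
one if its σ undercuts the accepted σ by a compounding tolerance margin —
candidate code ``c`` is accepted over the current best ``c_best`` iff

    σ_c  <  σ_best · (1 − t/100)^(c_best − c)

where ``t`` is the tolerance in percent.  At ``t = 5`` a 3×3 window must
therefore produce a σ of at most ``0.95⁶ ≈ 73.51 %`` of the accepted 15×15
value to be selected, and at ``t = 0`` the rule reduces to "smallest σ wins,
ties to the larger window".
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import uniform_filter

__all__ = [
    "N_CODES",
    "PATCH_SIZES",
    "patch_size_from_code",
    "local_sigma",
    "sigma_stack",
    "select_codes",
    "compute_cci",
    "tolerance_factor",
    "code_histogram",
]

#: Number of candidate window codes.
N_CODES = 7

#: Candidate square window sides, indexed by code − 1.
PATCH_SIZES = tuple(2 * c + 1 for c in range(1, N_CODES + 1))


def patch_size_from_code(c: int) -> int:
    """Window side for code *c*: ``2c + 1`` (code 1 → 3×3, code 7 → 15×15)."""
    c = int(c)
    if not 1 <= c <= N_CODES:
        raise ValueError(f"code must be in 1..{N_CODES}, got {c}")
    return 2 * c + 1


def _check_gray(gray: np.ndarray) -> np.ndarray:
    gray = np.asarray(gray, dtype=np.float64)
    if gray.ndim != 2 or gray.size == 0:
        raise ValueError(f"expected a non-empty (H, W) array, got shape {gray.shape}")
    return gray


def local_sigma(gray: np.ndarray, patch_size: int) -> np.ndarray:
    """Per-pixel population standard deviation inside a centred square window.

    Borders are handled by edge replication so every pixel sees a full-size
    window.  Computed from running box means of ``g`` and ``g²`` so the cost
    is independent of the window size.
    """
    gray = _check_gray(gray)
    patch_size = int(patch_size)
    if patch_size % 2 == 0 or not 3 <= patch_size <= 15:
        raise ValueError(f"patch_size must be odd and within 3..15, got {patch_size}")
    m = uniform_filter(gray, size=patch_size, mode="nearest")
    m2 = uniform_filter(gray * gray, size=patch_size, mode="nearest")
    var = np.clip(m2 - m * m, 0.0, None)
    # The two box means cancel catastrophically on (near-)constant windows,
    # leaving O(1e-13) round-off where the true variance is 0.  The smallest
    # variance a genuinely non-constant 8-bit window can have is ~6e-8
    # (a single 1/255 step in a 15x15 window), so flooring far below that
    # restores exact zeros without touching real structure.
    var[var < 1e-10] = 0.0
    return np.sqrt(var)


def sigma_stack(gray: np.ndarray) -> np.ndarray:
    """σ maps for all seven candidate sizes, stacked as ``(7, H, W)``.

    Layer ``k`` (0-based) holds :func:`local_sigma` at window side
    ``2(k+1) + 1``.
    """
    gray = _check_gray(gray)
    return np.stack([local_sigma(gray, size) for size in PATCH_SIZES])


def tolerance_factor(tolerance_pct: float, steps: int) -> float:
    """Compounded acceptance factor ``(1 − t/100)^steps`` for a code jump."""
    if tolerance_pct < 0 or tolerance_pct >= 100:
        raise ValueError(f"tolerance must be in [0, 100) percent, got {tolerance_pct}")
    if steps < 0:
        raise ValueError("steps must be non-negative")
    return (1.0 - tolerance_pct / 100.0) ** steps


def select_codes(sigmas: np.ndarray, tolerance_pct: float = 3.0) -> np.ndarray:
    """Per-pixel code selection from a ``(7, H, W)`` σ stack.

    Codes start at 7 and candidates are scanned 6 → 1; a candidate replaces
    the accepted code only if it beats the compounded tolerance threshold
    (see module docstring).  An earlier acceptance stands regardless of
    whether later (smaller) candidates fail.
    """
    sigmas = np.asarray(sigmas, dtype=np.float64)
    if sigmas.ndim != 3 or sigmas.shape[0] != N_CODES:
        raise ValueError(f"expected a (7, H, W) sigma stack, got shape {sigmas.shape}")
    shrink = 1.0 - float(tolerance_pct) / 100.0
    if not 0.0 < shrink <= 1.0:
        raise ValueError(f"tolerance must be in [0, 100) percent, got {tolerance_pct}")
    codes = np.full(sigmas.shape[1:], N_CODES, dtype=np.int64)
    best = sigmas[N_CODES - 1].copy()
    for c in range(N_CODES - 1, 0, -1):
        accept = sigmas[c - 1] < best * shrink ** (codes - c)
        codes[accept] = c
        best[accept] = sigmas[c - 1][accept]
    return codes


def compute_cci(gray: np.ndarray, tolerance_pct: float = 3.0) -> np.ndarray:
    """Contrast code image of a grayscale image: ``(H, W)`` ints in 1..7."""
    return select_codes(sigma_stack(gray), tolerance_pct)


def code_histogram(codes: np.ndarray) -> dict[int, int]:
    """Frequency of each code 1..7 (all keys present, zeros included)."""
    codes = np.asarray(codes)
    counts = np.bincount(codes.ravel(), minlength=N_CODES + 1)
    return {c: int(counts[c]) for c in range(1, N_CODES + 1)}
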