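"""Blind contrast-enhancement scores: e-score, r-score and GCF.

No ground-truth reference exists for archive footage, so enhancement is
judged by comparing each original/enhanced pair with blind measures:

e-score
    Relative increase in visible edges, ``(n_enh − n_orig) / n_orig``, with
    edges from Canny hysteresis detection (defaults: strong 0.2, weak 0.05).

r-score
    Visibility level: the geometric mean, over edge pixels visible in the
    enhanced image, of the Sobel gradient-magnitude ratio enhanced/original.
    Ratios with a zero denominator (or zero numerator, which would collapse
    the geometric mean) are excluded.  1.0 means unchanged visibility; an
    unclipped contrast doubling scores exactly 2.0.

GCF (global contrast factor)
    Mean absolute difference to the 4-neighbours of a perceptually
    linearised luminance (L = 100·√(v^2.2)), averaged per pixel, computed at
    nine progressively halved resolutions and combined with an empirical
    resolution-weighting polynomial (constants from the GCF publication).

Scores that are undefined (no edges to count) raise
:class:`UndefinedScoreError`; report assembly records them as missing rather
than 0.  Slots for third-party scores (SURF counts, BLIINDS-II, FADE) are
reserved in :class:`MetricReport` so externally computed values can be
merged, but they are never computed here.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np
from skimage.feature import canny
from skimage.filters import sobel

__all__ = [
    "UndefinedScoreError",
    "MetricReport",
    "edge_map",
    "e_score",
    "r_score",
    "gcf",
    "compute_report",
    "write_reports_json",
    "write_reports_csv",
]


class UndefinedScoreError(ValueError):
    """Raised when a score's denominator set is empty (e.g. no edges)."""


# Resolution-weighting polynomial of the GCF construction (nine levels,
# weight w_i = (-0.406385 i/9 + 0.334573) i/9 + 0.0877526).
_GCF_LEVELS = 9
_GCF_POLY = (-0.406385, 0.334573, 0.0877526)
_GCF_GAMMA = 2.2


def edge_map(gray: np.ndarray, strong: float = 0.2, weak: float = 0.05) -> np.ndarray:
    """Boolean visible-edge map by Canny hysteresis detection."""
    gray = np.asarray(gray, dtype=np.float64)
    if gray.ndim != 2:
        raise ValueError(f"expected an (H, W) gray image, got shape {gray.shape}")
    if not 0.0 < weak < strong < 1.0:
        raise ValueError(f"thresholds must satisfy 0 < weak < strong < 1, got {strong}/{weak}")
    return canny(gray, low_threshold=weak, high_threshold=strong)


def e_score(
    orig: np.ndarray, enh: np.ndarray, strong: float = 0.2, weak: float = 0.05
) -> float:
    """Relative increase in visible-edge count between original and enhanced."""
    orig = np.asarray(orig, dtype=np.float64)
    enh = np.asarray(enh, dtype=np.float64)
    if orig.shape != enh.shape:
        raise ValueError(f"image shapes differ: {orig.shape} vs {enh.shape}")
    n_orig = int(edge_map(orig, strong, weak).sum())
    n_enh = int(edge_map(enh, strong, weak).sum())
    if n_orig == 0:
        raise UndefinedScoreError("original image has no visible edges; e-score undefined")
    return (n_enh - n_orig) / n_orig


def r_score(
    orig: np.ndarray, enh: np.ndarray, strong: float = 0.2, weak: float = 0.05
) -> float:
    """Geometric-mean gradient ratio at edges visible in the enhanced image."""
    orig = np.asarray(orig, dtype=np.float64)
    enh = np.asarray(enh, dtype=np.float64)
    if orig.shape != enh.shape:
        raise ValueError(f"image shapes differ: {orig.shape} vs {enh.shape}")
    visible = edge_map(enh, strong, weak)
    g_orig = sobel(orig)
    g_enh = sobel(enh)
    mask = visible & (g_orig > 0) & (g_enh > 0)
    if not mask.any():
        raise UndefinedScoreError("no visible edges with nonzero gradients; r-score undefined")
    return float(np.exp(np.mean(np.log(g_enh[mask] / g_orig[mask]))))


def _local_contrast(L: np.ndarray) -> float:
    """Mean over pixels of the average absolute difference to 4-neighbours."""
    dv = np.abs(np.diff(L, axis=0))
    dh = np.abs(np.diff(L, axis=1))
    total = np.zeros_like(L)
    count = np.zeros_like(L)
    total[:-1, :] += dv
    total[1:, :] += dv
    total[:, :-1] += dh
    total[:, 1:] += dh
    count[:-1, :] += 1
    count[1:, :] += 1
    count[:, :-1] += 1
    count[:, 1:] += 1
    return float(np.mean(total / np.maximum(count, 1)))


def _halve(L: np.ndarray) -> np.ndarray:
    """2×2 block mean; odd trailing rows/columns are edge-replicated."""
    h, w = L.shape
    if h % 2:
        L = np.vstack([L, L[-1:, :]])
    if w % 2:
        L = np.hstack([L, L[:, -1:]])
    return 0.25 * (L[0::2, 0::2] + L[1::2, 0::2] + L[0::2, 1::2] + L[1::2, 1::2])


def gcf(gray: np.ndarray) -> float:
    """Global contrast factor of a grayscale image in [0, 1]."""
    gray = np.asarray(gray, dtype=np.float64)
    if gray.ndim != 2 or gray.size == 0:
        raise ValueError(f"expected a non-empty (H, W) image, got shape {gray.shape}")
    L = 100.0 * np.sqrt(np.clip(gray, 0.0, 1.0) ** _GCF_GAMMA)
    p2, p1, p0 = _GCF_POLY
    total = 0.0
    for i in range(1, _GCF_LEVELS + 1):
        if min(L.shape) < 2:
            break
        x = i / _GCF_LEVELS
        weight = (p2 * x + p1) * x + p0
        total += weight * _local_contrast(L)
        L = _halve(L)
    return total


@dataclass
class MetricReport:
    """One row of scores for an original/enhanced image pair.

    ``surf_features``, ``bliinds2`` and ``fade`` stay ``None`` unless merged
    from external tools.  Undefined scores are ``None`` as well.
    """

    filename: str = ""
    params_digest: str = ""
    e_score: Optional[float] = None
    r_score: Optional[float] = None
    gcf_before: Optional[float] = None
    gcf_after: Optional[float] = None
    edge_count_before: Optional[int] = None
    edge_count_after: Optional[int] = None
    surf_features: Optional[float] = None
    bliinds2: Optional[float] = None
    fade: Optional[float] = None


def compute_report(
    orig_gray: np.ndarray,
    enh_gray: np.ndarray,
    *,
    filename: str = "",
    params_digest: str = "",
    strong: float = 0.2,
    weak: float = 0.05,
) -> MetricReport:
    """Assemble all computable scores; undefined ones are left missing."""
    report = MetricReport(filename=filename, params_digest=params_digest)
    report.edge_count_before = int(edge_map(orig_gray, strong, weak).sum())
    report.edge_count_after = int(edge_map(enh_gray, strong, weak).sum())
    try:
        report.e_score = e_score(orig_gray, enh_gray, strong, weak)
    except UndefinedScoreError:
        pass
    try:
        report.r_score = r_score(orig_gray, enh_gray, strong, weak)
    except UndefinedScoreError:
        pass
    report.gcf_before = gcf(orig_gray)
    report.gcf_after = gcf(enh_gray)
    return report


def write_reports_json(reports: list[MetricReport], path) -> None:
    with open(path, "w") as fh:
        json.dump([asdict(r) for r in reports], fh, indent=2)


def write_reports_csv(reports: list[MetricReport], path) -> None:
    fields = list(asdict(MetricReport()).keys())
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        for r in reports:
            writer.writerow(asdict(r))
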