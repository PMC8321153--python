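"""Synthetic low-light / hazy scene generator with known ground truth.

Real deep-sea footage pairs dark homogeneous stretches of seabed with bright
textured structures (animals, rocks, instruments) lit by artificial sources.
This module composes such scenes programmatically — a flat background,
optional flat patches, textured squares (checkerboard or uniform noise) and
planted bright blocks — together with a known transmission field ``t(x)`` and
atmospheric light *A*, so every stage of the enhancement pipeline can be
tested against ground truth and no external dataset is needed.

Haze is applied with the forward model ``I = J·t + A·(1 − t)``; a low-light
scene is its inversion dual: ``lowlight(J) = invert(apply_haze(invert(J)))``,
so the darkness planted here is exactly the haze the (inverted) dehazer sees.

Everything is deterministic given ``SceneSpec.seed``; a single
``numpy.random.default_rng`` drives noise textures and blockwise fields.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .imagery import invert

__all__ = [
    "SceneSpecError",
    "FlatPatch",
    "TexturedPatch",
    "BrightBlock",
    "TransmissionField",
    "SceneSpec",
    "render_t_field",
    "make_scene",
    "apply_haze",
    "make_lowlight",
    "default_scene_spec",
]


class SceneSpecError(ValueError):
    """Raised for out-of-bounds or overlapping region layouts."""


@dataclass(frozen=True)
class FlatPatch:
    """Axis-aligned rectangle of constant radiance."""

    top: int
    left: int
    height: int
    width: int
    intensity: tuple[float, float, float] = (0.5, 0.5, 0.5)


@dataclass(frozen=True)
class TexturedPatch:
    """Rectangle carrying high-frequency texture around a base radiance.

    ``kind='checker'`` alternates ``base ± amplitude`` in blocks of
    ``period`` pixels — its local σ is nearly scale-independent, so the
    contrast-code selection keeps large windows over it.  ``kind='noise'``
    adds band-limited noise (uniform noise smoothed with a Gaussian of
    ``period`` pixels, rescaled to ``±amplitude``) — its σ grows with window
    size, so small windows are selected over it, emulating rocks and
    instrument structure.
    """

    top: int
    left: int
    height: int
    width: int
    base: float = 0.5
    amplitude: float = 0.25
    period: int = 1
    kind: Literal["checker", "noise"] = "checker"


@dataclass(frozen=True)
class BrightBlock:
    """Planted near-white block (an artificial light / specular target)."""

    top: int
    left: int
    height: int
    width: int
    intensity: tuple[float, float, float] = (1.0, 1.0, 1.0)


@dataclass(frozen=True)
class TransmissionField:
    """Named transmission pattern.

    kinds: ``constant`` (value=lo), ``ramp`` (lo→hi along ``axis``),
    ``radial`` (hi at centre, lo at corners), ``blocks`` (``rows × cols``
    grid of values drawn uniformly from [lo, hi] by the scene RNG).
    """

    kind: Literal["constant", "ramp", "radial", "blocks"] = "constant"
    lo: float = 0.7
    hi: float = 1.0
    axis: int = 1
    rows: int = 4
    cols: int = 4

    def __post_init__(self) -> None:
        if not (0.0 <= self.lo <= 1.0 and 0.0 <= self.hi <= 1.0):
            raise SceneSpecError("transmission values must lie in [0, 1]")


@dataclass(frozen=True)
class SceneSpec:
    """Full description of a synthetic scene; serialisable to JSON."""

    height: int = 96
    width: int = 128
    seed: int = 0
    background: tuple[float, float, float] = (0.4, 0.45, 0.5)
    regions: tuple = ()
    airlight: tuple[float, float, float] = (0.85, 0.9, 0.95)
    t_field: TransmissionField = field(default_factory=TransmissionField)

    def to_json(self) -> str:
        d = asdict(self)
        d["regions"] = [
            {"type": type(r).__name__, **asdict(r)} for r in self.regions
        ]
        return json.dumps(d, indent=2)


def render_t_field(
    t_field: TransmissionField, height: int, width: int, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Materialise a transmission pattern as an ``(H, W)`` array in [0, 1]."""
    lo, hi = t_field.lo, t_field.hi
    if t_field.kind == "constant":
        return np.full((height, width), lo)
    if t_field.kind == "ramp":
        ramp = np.linspace(lo, hi, width if t_field.axis == 1 else height)
        t = np.tile(ramp, (height, 1)) if t_field.axis == 1 else np.tile(ramp[:, None], (1, width))
        return t
    if t_field.kind == "radial":
        yy, xx = np.mgrid[0:height, 0:width]
        cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
        r = np.hypot((yy - cy) / max(cy, 1), (xx - cx) / max(cx, 1)) / np.sqrt(2)
        return hi - (hi - lo) * np.clip(r, 0.0, 1.0)
    if t_field.kind == "blocks":
        if rng is None:
            rng = np.random.default_rng(0)
        vals = rng.uniform(lo, hi, size=(t_field.rows, t_field.cols))
        ridx = np.minimum(np.arange(height) * t_field.rows // height, t_field.rows - 1)
        cidx = np.minimum(np.arange(width) * t_field.cols // width, t_field.cols - 1)
        return vals[np.ix_(ridx, cidx)]
    raise SceneSpecError(f"unknown transmission field kind {t_field.kind!r}")


def _region_slices(r, height: int, width: int) -> tuple[slice, slice]:
    if r.top < 0 or r.left < 0 or r.top + r.height > height or r.left + r.width > width:
        raise SceneSpecError(f"region {r} exceeds the {height}x{width} canvas")
    if r.height < 1 or r.width < 1:
        raise SceneSpecError(f"region {r} is empty")
    return slice(r.top, r.top + r.height), slice(r.left, r.left + r.width)


def make_scene(spec: SceneSpec) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Render the clean radiance *J* plus boolean region masks.

    Returns ``(J, masks)`` with ``masks['flat']`` covering flat patches and
    bright blocks and ``masks['textured']`` covering textured squares.
    Overlapping regions raise :class:`SceneSpecError`.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = int(spec.height), int(spec.width)
    if h < 1 or w < 1:
        raise SceneSpecError("scene must be at least 1x1")
    J = np.empty((h, w, 3))
    J[:] = np.asarray(spec.background, dtype=np.float64)
    occupied = np.zeros((h, w), dtype=bool)
    flat_mask = np.zeros((h, w), dtype=bool)
    tex_mask = np.zeros((h, w), dtype=bool)
    for r in spec.regions:
        ys, xs = _region_slices(r, h, w)
        if occupied[ys, xs].any():
            raise SceneSpecError(f"region {r} overlaps a previous region")
        occupied[ys, xs] = True
        if isinstance(r, TexturedPatch):
            yy, xx = np.mgrid[0 : r.height, 0 : r.width]
            if r.kind == "checker":
                parity = ((yy // r.period) + (xx // r.period)) % 2
                tex = r.base + r.amplitude * (2.0 * parity - 1.0)
            elif r.kind == "noise":
                raw = rng.uniform(-1.0, 1.0, size=(r.height, r.width))
                raw = gaussian_filter(raw, sigma=max(r.period, 1), mode="nearest")
                peak = np.abs(raw).max()
                tex = r.base + r.amplitude * raw / (peak if peak > 0 else 1.0)
            else:
                raise SceneSpecError(f"unknown texture kind {r.kind!r}")
            J[ys, xs] = np.clip(tex, 0.0, 1.0)[:, :, None]
            tex_mask[ys, xs] = True
        elif isinstance(r, (FlatPatch, BrightBlock)):
            J[ys, xs] = np.asarray(r.intensity, dtype=np.float64)
            flat_mask[ys, xs] = True
        else:
            raise SceneSpecError(f"unknown region type {type(r).__name__}")
    return np.clip(J, 0.0, 1.0), {"flat": flat_mask, "textured": tex_mask}


def apply_haze(J: np.ndarray, t_field: np.ndarray, airlight) -> np.ndarray:
    """Forward haze model ``I = J·t + A·(1 − t)`` (clamped to [0, 1])."""
    J = np.asarray(J, dtype=np.float64)
    t = np.asarray(t_field, dtype=np.float64)
    if J.ndim != 3 or J.shape[2] != 3:
        raise SceneSpecError(f"expected an (H, W, 3) radiance, got shape {J.shape}")
    if t.shape != J.shape[:2]:
        raise SceneSpecError(f"t-field shape {t.shape} does not match image {J.shape[:2]}")
    if t.min() < 0.0 or t.max() > 1.0:
        raise SceneSpecError("t-field values must lie in [0, 1]")
    A = np.asarray(airlight, dtype=np.float64).reshape(3)
    I = J * t[:, :, None] + A * (1.0 - t[:, :, None])
    return np.clip(I, 0.0, 1.0)


def make_lowlight(J: np.ndarray, t_field: np.ndarray, airlight) -> np.ndarray:
    """Low-light rendering of *J*: ``invert(apply_haze(invert(J), t, A))``.

    The inverted output carries exactly the planted haze, so recovering it
    with the true ``t`` and *A* reproduces *J* (up to clamping).
    """
    return invert(apply_haze(invert(np.asarray(J, dtype=np.float64)), t_field, airlight))


def default_scene_spec(seed: int = 0, height: int = 96, width: int = 128) -> SceneSpec:
    """A representative study scene: dark flat seabed, two textured squares,
    one planted bright block, radial darkening toward the corners."""
    sq = min(height, width) // 4
    return SceneSpec(
        height=height,
        width=width,
        seed=seed,
        background=(0.35, 0.4, 0.45),
        regions=(
            TexturedPatch(
                top=height // 8,
                left=width // 8,
                height=sq,
                width=sq,
                base=0.55,
                amplitude=0.25,
                period=1,
                kind="checker",
            ),
            TexturedPatch(
                top=height // 2,
                left=width // 2,
                height=sq,
                width=sq,
                base=0.5,
                amplitude=0.2,
                period=2,
                kind="noise",
            ),
            BrightBlock(
                top=height // 8,
                left=3 * width // 4,
                height=5,
                width=5,
                intensity=(0.98, 0.99, 1.0),
            ),
        ),
        airlight=(0.85, 0.9, 0.95),
        t_field=TransmissionField(kind="radial", lo=0.35, hi=0.95),
    )
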