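"""Synthetic dermoscopy-like images with exact ground-truth masks.

Lesions are star-convex regions whose boundary radius is a Fourier series

    r(theta) = r0 * (1 + sum_k a_k sin(k theta + phi_k)),   k = 2..6,

so edges become increasingly irregular as ``boundary_irregularity`` grows
while the rasterized mask remains exact.  Pigment interpolates from a dark
center toward the skin tone with radial position (``center_fade``), the two
properties that make real lesions hard to delineate.  Optional dark hair
strokes and Gaussian texture noise complete the scene.  No attempt at
photorealism is made: the generator supplies statistical structure, not
appearance fidelity.

Everything is reproducible from the integer seed alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Tuple

import numpy as np
from PIL import Image

__all__ = ["LesionParams", "generate", "export_isic_layout", "lesion_radius"]

_SKIN_TONES = np.array(
    [
        [0.91, 0.76, 0.65],
        [0.87, 0.70, 0.59],
        [0.80, 0.62, 0.50],
        [0.71, 0.53, 0.41],
    ]
)
_CENTER_TONES = np.array(
    [
        [0.32, 0.20, 0.14],
        [0.26, 0.17, 0.13],
        [0.40, 0.26, 0.17],
    ]
)

_N_HARMONICS = 5  # k = 2..6


@dataclass(frozen=True)
class LesionParams:
    seed: int = 0
    image_size: int = 256
    lesion_area_fraction: Tuple[float, float] = (0.05, 0.4)
    boundary_irregularity: float = 0.15
    center_fade: float = 0.6
    hair_density: int = 3
    noise_sd: float = 0.03

    def __post_init__(self):
        lo, hi = self.lesion_area_fraction
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("lesion_area_fraction must lie inside (0, 1)")
        if self.image_size * self.image_size * lo < 16:
            raise ValueError(
                "area fraction infeasible: fewer than 16 lesion pixels"
            )
        if self.boundary_irregularity < 0:
            raise ValueError("boundary_irregularity must be nonnegative")


def lesion_radius(theta: np.ndarray, r0: float, amp: np.ndarray,
                  phase: np.ndarray) -> np.ndarray:
    """Boundary radius r(theta) of the star-convex lesion."""
    k = np.arange(2, 2 + len(amp))
    series = (amp[:, None] * np.sin(k[:, None] * theta[None, :]
                                    + phase[:, None])).sum(axis=0)
    return r0 * (1.0 + series)


def _sample_boundary(rng: np.random.Generator, params: LesionParams,
                     frac: float) -> Tuple[float, np.ndarray, np.ndarray]:
    amp = rng.normal(0.0, 1.0, _N_HARMONICS)
    amp *= params.boundary_irregularity / np.arange(2, 2 + _N_HARMONICS)
    amp = np.clip(amp, -0.45, 0.45)
    phase = rng.uniform(0, 2 * math.pi, _N_HARMONICS)
    # E[r^2] = r0^2 (1 + sum a_k^2 / 2): rescale so the area hits the target
    target_area = frac * params.image_size ** 2
    r0 = math.sqrt(target_area / (math.pi * (1.0 + 0.5 * float(amp @ amp))))
    return r0, amp, phase


def _rasterize(size: int, cy: float, cx: float, r0: float,
               amp: np.ndarray, phase: np.ndarray):
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - cy, xx - cx
    rho = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    r_b = lesion_radius(theta.ravel(), r0, amp, phase).reshape(theta.shape)
    r_b = np.maximum(r_b, 1e-6)
    mask = rho <= r_b
    radial = np.clip(rho / r_b, 0.0, 1.0)  # 0 at center, 1 at boundary
    return mask, radial


def _draw_hairs(rng: np.random.Generator, img: np.ndarray, count: int) -> None:
    size = img.shape[0]
    for _ in range(count):
        p0 = rng.uniform(0, size, 2)
        p1 = rng.uniform(0, size, 2)
        ctrl = (p0 + p1) / 2 + rng.normal(0, size / 6, 2)
        t = np.linspace(0, 1, 4 * size)[:, None]
        pts = ((1 - t) ** 2 * p0 + 2 * t * (1 - t) * ctrl + t ** 2 * p1)
        pts = np.round(pts).astype(int)
        keep = ((pts >= 0) & (pts < size)).all(axis=1)
        pts = pts[keep]
        shade = rng.uniform(0.05, 0.25)
        for oy in (0, 1):
            y = np.clip(pts[:, 0] + oy, 0, size - 1)
            img[y, pts[:, 1]] = img[y, pts[:, 1]] * 0.25 + shade * 0.75


def _render(rng: np.random.Generator, params: LesionParams):
    size = params.image_size
    lo, hi = params.lesion_area_fraction
    mask = radial = None
    for _ in range(20):  # rejection loop on realized area
        frac = rng.uniform(lo, hi)
        r0, amp, phase = _sample_boundary(rng, params, frac)
        margin = r0 * (1 + float(np.abs(amp).sum()))
        c_lo = min(margin, size / 2)
        c_hi = max(size - margin, size / 2)
        cy, cx = rng.uniform(c_lo, c_hi, 2)
        mask, radial = _rasterize(size, cy, cx, r0, amp, phase)
        realized = mask.mean()
        if lo <= realized <= hi:
            break
    skin = _SKIN_TONES[rng.integers(len(_SKIN_TONES))]
    center = _CENTER_TONES[rng.integers(len(_CENTER_TONES))]
    img = np.empty((size, size, 3))
    img[:] = skin
    fade = params.center_fade * radial[..., None]  # 0 center .. fade at edge
    lesion_color = center[None, None] * (1 - fade) + skin[None, None] * fade
    img[mask] = lesion_color[mask]
    if params.hair_density > 0:
        _draw_hairs(rng, img, params.hair_density)
    if params.noise_sd > 0:
        img += rng.normal(0, params.noise_sd, img.shape)
    return np.clip(img, 0, 1), mask


def generate(params: LesionParams, n: int) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Return ``n`` (image, mask) pairs.

    Images are float64 (H, W, 3) in [0, 1]; masks boolean (H, W).  Sample i
    is a pure function of ``(params.seed, i)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out = []
    for i in range(n):
        rng = np.random.default_rng([params.seed, i])
        out.append(_render(rng, params))
    return out


def export_isic_layout(samples, directory, prefix: str = "SYNTH") -> List[str]:
    """Write image/mask pairs using the archive naming convention
    (``<stem>.png`` + ``<stem>_segmentation.png``); returns the stems."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stems = []
    for i, (img, mask) in enumerate(samples):
        stem = f"{prefix}_{i:07d}"
        Image.fromarray((img * 255).round().astype(np.uint8)).save(
            directory / f"{stem}.png"
        )
        Image.fromarray((mask.astype(np.uint8) * 255)).save(
            directory / f"{stem}_segmentation.png"
        )
        stems.append(stem)
    return stems
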