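"""Synthetic MR-like phantoms with controllable distortion.

Magnitude MR images show bright anatomy on a dark, noisy background.  The
generator emulates that structure with composited ellipses (optionally
carrying a radial intensity gradient, mimicking shading within tissue)
over a low uniform background, followed by optional Gaussian blur and a
configurable noise model.  Magnitude reconstruction of complex Gaussian
noise produces Rician-distributed intensities, which reduce to a Rayleigh
distribution where the underlying signal is zero, so the ``rician`` model
is the physically motivated default for grading distortion severity:

    out = round(sqrt((A + n1)^2 + n2^2)),  n1, n2 ~ N(0, sigma) i.i.d.

Everything is deterministic under (spec, seed).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence, Tuple

import numpy as np
from scipy import ndimage

from .nms_extrema import GrayscaleImage

__all__ = ["Ellipse", "PhantomSpec", "render_clean", "add_noise", "graded_series", "default_spec"]

NOISE_MODELS = ("none", "gaussian", "rician")


@dataclass(frozen=True)
class Ellipse:
    """One elliptical structure: center (row, col), semi-axes (pixels),
    rotation angle in degrees, peak intensity, and an optional edge
    intensity for a linear radial gradient."""

    center: Tuple[float, float]
    axes: Tuple[float, float]
    angle_deg: float = 0.0
    intensity: float = 200.0
    edge_intensity: float | None = None


@dataclass(frozen=True)
class PhantomSpec:
    height: int = 160
    width: int = 160
    background_level: int = 12
    structures: Tuple[Ellipse, ...] = ()
    noise_model: str = "rician"
    sigma: float = 0.0
    blur_sigma: float = 0.0
    seed: int = 0
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if self.noise_model not in NOISE_MODELS:
            raise ValueError(
                f"unknown noise model {self.noise_model!r}; valid: {NOISE_MODELS}"
            )
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        object.__setattr__(self, "structures", tuple(self.structures))

    @property
    def max_intensity(self) -> int:
        return 2**self.bit_depth - 1

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        d = json.loads(text)
        d["structures"] = tuple(
            Ellipse(
                center=tuple(e["center"]),
                axes=tuple(e["axes"]),
                angle_deg=e.get("angle_deg", 0.0),
                intensity=e.get("intensity", 200.0),
                edge_intensity=e.get("edge_intensity"),
            )
            for e in d.get("structures", ())
        )
        return cls(**d)


def default_spec(**overrides) -> PhantomSpec:
    """A canonical anatomy-like phantom: nested bright ellipses with a
    gradient-shaded interior on a dark background."""
    structures = (
        Ellipse(center=(80.0, 80.0), axes=(62.0, 50.0), angle_deg=10.0,
                intensity=150.0, edge_intensity=110.0),
        Ellipse(center=(70.0, 72.0), axes=(26.0, 18.0), angle_deg=-25.0,
                intensity=220.0, edge_intensity=180.0),
        Ellipse(center=(98.0, 96.0), axes=(16.0, 12.0), angle_deg=40.0,
                intensity=60.0),
        Ellipse(center=(56.0, 104.0), axes=(8.0, 8.0), angle_deg=0.0,
                intensity=240.0),
    )
    base = dict(height=160, width=160, background_level=12, structures=structures)
    base.update(overrides)
    return PhantomSpec(**base)


def render_clean(spec: PhantomSpec) -> GrayscaleImage:
    """Deterministic rasterization of the spec's ellipses; no randomness."""
    canvas = np.full((spec.height, spec.width), float(spec.background_level))
    rows, cols = np.mgrid[0 : spec.height, 0 : spec.width].astype(np.float64)
    for s in spec.structures:
        cr, cc = s.center
        ar, ac = s.axes
        if not (0 <= cr < spec.height and 0 <= cc < spec.width):
            warnings.warn(
                f"structure centered at {s.center} lies outside the "
                f"{spec.height}x{spec.width} canvas; it will be clipped",
                stacklevel=2,
            )
        theta = np.deg2rad(s.angle_deg)
        dr, dc = rows - cr, cols - cc
        u = dr * np.cos(theta) + dc * np.sin(theta)
        v = -dr * np.sin(theta) + dc * np.cos(theta)
        rho2 = (u / ar) ** 2 + (v / ac) ** 2
        inside = rho2 <= 1.0
        if s.edge_intensity is None:
            canvas[inside] = s.intensity
        else:
            rho = np.sqrt(rho2[inside])
            canvas[inside] = s.intensity + (s.edge_intensity - s.intensity) * rho
    if spec.blur_sigma > 0:
        canvas = ndimage.gaussian_filter(canvas, spec.blur_sigma)
    pixels = np.clip(np.round(canvas), 0, spec.max_intensity).astype(np.int64)
    return GrayscaleImage(pixels=pixels, source_id=f"phantom(seed={spec.seed})")


def add_noise(
    image: GrayscaleImage, model: str, sigma: float, seed: int, bit_depth: int = 8
) -> GrayscaleImage:
    """Apply the chosen noise model, then round and clip to the bit depth."""
    if model not in NOISE_MODELS:
        raise ValueError(f"unknown noise model {model!r}; valid: {NOISE_MODELS}")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    a = image.pixels.astype(np.float64)
    if model == "none" or sigma == 0.0:
        noisy = a
    else:
        rng = np.random.default_rng(seed)
        if model == "gaussian":
            noisy = a + rng.normal(0.0, sigma, size=a.shape)
        else:  # rician: magnitude of complex signal + Gaussian noise
            n1 = rng.normal(0.0, sigma, size=a.shape)
            n2 = rng.normal(0.0, sigma, size=a.shape)
            noisy = np.sqrt((a + n1) ** 2 + n2**2)
    pixels = np.clip(np.round(noisy), 0, 2**bit_depth - 1).astype(np.int64)
    return GrayscaleImage(
        pixels=pixels, source_id=f"{image.source_id}+{model}(sigma={sigma},seed={seed})"
    )


def render(spec: PhantomSpec) -> GrayscaleImage:
    """Clean render followed by the spec's own noise model."""
    clean = render_clean(spec)
    return add_noise(clean, spec.noise_model, spec.sigma, spec.seed, spec.bit_depth)


def graded_series(
    spec: PhantomSpec,
    sigmas: Sequence[float],
    seeds: Sequence[int] | None = None,
) -> list:
    """One clean render corrupted at each noise level, independently seeded.

    Returns a list of (sigma, GrayscaleImage) with the spec's noise model;
    used to grade distortion severity on a fixed geometry.
    """
    sigmas = list(sigmas)
    if not sigmas:
        raise ValueError("need at least one sigma")
    if seeds is None:
        seeds = [spec.seed + i for i in range(len(sigmas))]
    if len(seeds) != len(sigmas):
        raise ValueError("seeds and sigmas must have equal length")
    clean = render_clean(spec)
    model = spec.noise_model if spec.noise_model != "none" else "rician"
    out = []
    for sigma, seed in zip(sigmas, seeds):
        if sigma == 0:
            out.append((sigma, clean))
        else:
            out.append((sigma, add_noise(clean, model, sigma, seed, spec.bit_depth)))
    return out
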