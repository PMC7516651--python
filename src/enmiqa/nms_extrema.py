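"""Thresholded non-maximum suppression and extrema-count profiles.

A pixel is a *local extremum at threshold t* when its intensity strictly
exceeds every neighbor's intensity by more than ``t``, or falls strictly
below every neighbor's intensity by more than ``t``.  Counting such
extrema over a sequence of thresholds ``t = 1..S`` yields a profile whose
shape reflects how much isolated intensity disorder the image contains:
noisy or artifact-laden images keep producing extrema at large thresholds,
while clean images run out quickly.

The test is evaluated only on interior pixels, i.e. those whose full
neighborhood lies inside the image; the one-pixel border is skipped rather
than padded, so no intensity values are ever invented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np

__all__ = [
    "GrayscaleImage",
    "NeighborhoodSpec",
    "ThresholdSequence",
    "ExtremaProfile",
    "nms_test",
    "count_extrema",
    "extrema_profile",
]

_FOUR_OFFSETS: Tuple[Tuple[int, int], ...] = ((0, 1), (0, -1), (1, 0), (-1, 0))
_EIGHT_OFFSETS: Tuple[Tuple[int, int], ...] = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)


@dataclass(frozen=True)
class GrayscaleImage:
    """2-D grid of non-negative integer intensities.

    Parameters
    ----------
    pixels
        2-D array of integer intensities; copied and stored as ``int64``
        so neighbor differences never overflow narrow unsigned types.
    source_id
        Free-text provenance label (file path, phantom spec, ...).
    """

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError(f"image must be 2-D, got shape {arr.shape}")
        if arr.shape[0] < 3 or arr.shape[1] < 3:
            raise ValueError(
                f"image must be at least 3x3 so interior pixels exist, got {arr.shape}"
            )
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.round(arr)):
                raise ValueError("intensities must be integers")
        if np.any(arr < 0):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "pixels", arr.astype(np.int64, copy=True))

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def size(self) -> int:
        """Total pixel count M*N."""
        return self.height * self.width


@dataclass(frozen=True)
class NeighborhoodSpec:
    """The set of neighbor offsets used by the extremum test (4 or 8)."""

    offsets: Tuple[Tuple[int, int], ...]

    def __post_init__(self) -> None:
        offs = tuple(sorted(tuple(o) for o in self.offsets))
        if len(set(offs)) != len(offs):
            raise ValueError("duplicate neighbor offsets")
        for dr, dc in offs:
            if (dr, dc) == (0, 0) or dr not in (-1, 0, 1) or dc not in (-1, 0, 1):
                raise ValueError(f"offset {(dr, dc)} outside the 3x3 neighborhood")
        if len(offs) not in (4, 8):
            raise ValueError(f"neighborhood size must be 4 or 8, got {len(offs)}")
        if len(offs) == 4 and set(offs) != set(_FOUR_OFFSETS):
            raise ValueError("4-neighborhood must be the axial offsets")
        object.__setattr__(self, "offsets", offs)

    @property
    def size(self) -> int:
        return len(self.offsets)

    @classmethod
    def four(cls) -> "NeighborhoodSpec":
        """Axial (edge-connected) neighborhood."""
        return cls(_FOUR_OFFSETS)

    @classmethod
    def eight(cls) -> "NeighborhoodSpec":
        """Full 3x3 neighborhood (the method's default setting)."""
        return cls(_EIGHT_OFFSETS)

    @classmethod
    def of_size(cls, size: int) -> "NeighborhoodSpec":
        if size == 4:
            return cls.four()
        if size == 8:
            return cls.eight()
        raise ValueError(f"neighborhood size must be 4 or 8, got {size}")


@dataclass(frozen=True)
class ThresholdSequence:
    """Consecutive integer thresholds 1..S."""

    S: int

    def __post_init__(self) -> None:
        if self.S < 1:
            raise ValueError(f"S must be a positive integer, got {self.S}")

    @property
    def thresholds(self) -> np.ndarray:
        return np.arange(1, self.S + 1)


@dataclass(frozen=True)
class ExtremaProfile:
    """Extrema counts I(t) for t = 1..S, raw and normalized by image size."""

    counts: np.ndarray
    image_size: int
    S: int = field(default=0)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 1:
            raise ValueError("counts must be a 1-D sequence")
        if np.any(counts < 0):
            raise ValueError("extrema counts cannot be negative")
        if np.any(counts > self.image_size):
            raise ValueError("extrema count exceeds the number of pixels")
        if np.any(np.diff(counts) > 0):
            raise ValueError("extrema counts must be non-increasing in t")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "S", int(counts.shape[0]))

    @property
    def normalized(self) -> np.ndarray:
        """Counts divided by the image size M*N."""
        return self.counts / self.image_size


def _margins(image: GrayscaleImage, nbhd: NeighborhoodSpec) -> np.ndarray:
    """Per-interior-pixel extremum margin.

    For each interior pixel the margin is the largest integer ``g`` such
    that the pixel passes the extremum test for every threshold ``t < g``:
    ``g = max(center - max(neighbors), min(neighbors) - center)``.  A pixel
    is an extremum at threshold ``t`` iff ``margin > t``, which lets the
    whole profile be read off one array.
    """
    px = image.pixels
    center = px[1:-1, 1:-1]
    max_nb = np.full(center.shape, np.iinfo(np.int64).min, dtype=np.int64)
    min_nb = np.full(center.shape, np.iinfo(np.int64).max, dtype=np.int64)
    for dr, dc in nbhd.offsets:
        nb = px[1 + dr : px.shape[0] - 1 + dr, 1 + dc : px.shape[1] - 1 + dc]
        np.maximum(max_nb, nb, out=max_nb)
        np.minimum(min_nb, nb, out=min_nb)
    return np.maximum(center - max_nb, min_nb - center)


def nms_test(
    image: GrayscaleImage,
    row: int,
    col: int,
    t: int,
    nbhd: NeighborhoodSpec | None = None,
) -> int:
    """Thresholded extremum test at a single interior pixel.

    Returns 1 iff the pixel is strictly greater than every neighbor plus
    ``t`` or strictly less than every neighbor minus ``t``, else 0.
    """
    if nbhd is None:
        nbhd = NeighborhoodSpec.eight()
    if t < 1:
        raise ValueError(f"threshold must be >= 1, got {t}")
    if not (1 <= row <= image.height - 2):
        raise IndexError(f"row {row} is not interior (valid: 1..{image.height - 2})")
    if not (1 <= col <= image.width - 2):
        raise IndexError(f"col {col} is not interior (valid: 1..{image.width - 2})")
    px = image.pixels
    center = px[row, col]
    neighbors = [px[row + dr, col + dc] for dr, dc in nbhd.offsets]
    if all(center > nb + t for nb in neighbors):
        return 1
    if all(center < nb - t for nb in neighbors):
        return 1
    return 0


def count_extrema(
    image: GrayscaleImage, t: int, nbhd: NeighborhoodSpec | None = None
) -> int:
    """Number of interior pixels passing the extremum test at threshold t."""
    if nbhd is None:
        nbhd = NeighborhoodSpec.eight()
    if t < 1:
        raise ValueError(f"threshold must be >= 1, got {t}")
    return int(np.count_nonzero(_margins(image, nbhd) > t))


def extrema_profile(
    image: GrayscaleImage, S: int = 30, nbhd: NeighborhoodSpec | None = None
) -> ExtremaProfile:
    """Extrema-count profile I(t) for t = 1..S.

    Equivalent to calling :func:`count_extrema` per threshold, but computed
    in one pass from the per-pixel extremum margins.
    """
    if nbhd is None:
        nbhd = NeighborhoodSpec.eight()
    if S < 1:
        raise ValueError(f"S must be a positive integer, got {S}")
    margins = _margins(image, nbhd).ravel()
    # counts[t-1] = #{pixels with margin > t}; margins <= 1 never contribute
    positive = margins[margins > 1]
    if positive.size == 0:
        counts = np.zeros(S, dtype=np.int64)
    else:
        capped = np.minimum(positive - 1, S)  # margin g contributes to t = 1..g-1
        hist = np.bincount(capped, minlength=S + 1)
        counts = np.cumsum(hist[::-1])[::-1][1 : S + 1]
    return ExtremaProfile(counts=counts, image_size=image.size)
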