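"""ENMIQA: Shannon entropy of the extrema-count profile as a quality score.

The extrema counts ``I(1..S)`` are renormalized to a probability
distribution ``k_i = I(i) / sum(I)`` and scored by the Shannon entropy
``h = -sum k_i log k_i`` (natural log by default).  A clean image
concentrates its extrema at small thresholds, giving low entropy; a
distorted image keeps producing extrema at large thresholds, spreading
the distribution and raising the entropy.  The score therefore increases
with the amount of local intensity disorder.

Two conventions close the degenerate cases: the contribution of an empty
cell is ``s(0) = 0``, and a profile whose counts are all zero (a perfectly
flat image) scores 0.  Dividing the profile by the image size cancels in
the renormalization, so raw and normalized counts give identical scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .nms_extrema import ExtremaProfile, GrayscaleImage, NeighborhoodSpec, extrema_profile

__all__ = ["QualityScore", "entropy_of_profile", "enmiqa"]


@dataclass(frozen=True)
class QualityScore:
    """Entropy value with the parameters that produced it."""

    value: float
    S: int
    neighborhood_size: int
    image_id: str = ""
    log_base: float = math.e

    def __post_init__(self) -> None:
        upper = math.log(self.S, self.log_base) if self.S > 1 else 0.0
        if not (-1e-9 <= self.value <= upper + 1e-9):
            raise ValueError(
                f"score {self.value} outside [0, log_{self.log_base}({self.S})]"
            )


def entropy_of_profile(
    profile: ExtremaProfile,
    *,
    neighborhood_size: int = 8,
    image_id: str = "",
    log_base: float = math.e,
) -> QualityScore:
    """Shannon entropy of the renormalized extrema profile.

    Zero-count cells contribute nothing (``s(0) = 0``); an all-zero profile
    scores 0 by convention.
    """
    counts = np.asarray(profile.counts, dtype=np.float64)
    if np.any(counts < 0):
        raise ValueError("extrema counts cannot be negative")
    total = counts.sum()
    if total == 0:
        value = 0.0
    else:
        k = counts[counts > 0] / total
        value = float(-(k * np.log(k)).sum())
        if log_base != math.e:
            value /= math.log(log_base)
        value = max(value, 0.0) + 0.0  # clamp tiny negatives, drop -0.0
    return QualityScore(
        value=value,
        S=profile.S,
        neighborhood_size=neighborhood_size,
        image_id=image_id,
        log_base=log_base,
    )


def enmiqa(
    image: GrayscaleImage,
    S: int = 30,
    nbhd: NeighborhoodSpec | None = None,
    *,
    log_base: float = math.e,
) -> QualityScore:
    """Score an image: extrema profile over t = 1..S, then entropy.

    Defaults (S=30, full 8-neighborhood, natural log) are the method's
    reference setting.  Deterministic for fixed image bytes and parameters.
    """
    if nbhd is None:
        nbhd = NeighborhoodSpec.eight()
    profile = extrema_profile(image, S=S, nbhd=nbhd)
    return entropy_of_profile(
        profile,
        neighborhood_size=nbhd.size,
        image_id=image.source_id,
        log_base=log_base,
    )
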