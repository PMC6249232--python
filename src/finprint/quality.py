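"""Image-quality gating: Laplacian sharpness and the admission filter.

Blurred fin photographs produce unstable keypoint descriptors, so images are
scored by the standard deviation of the Laplacian response over the fin
region (low = blurred) and admitted to identification only if they meet
minimum size, feature-count and (optionally) sharpness thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .segmentation import FinImage, FinMask, rgb_to_lab

#: 4-neighbour Laplacian.
LAPLACIAN_KERNEL = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=np.float64)


@dataclass(frozen=True)
class SharpnessScore:
    """Standard deviation of the Laplacian response on the 8-bit grey scale."""

    value: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("sharpness is non-negative")

    def __float__(self) -> float:
        return self.value


@dataclass(frozen=True)
class QualityConfig:
    """Admission thresholds. All are inclusive (>=); a threshold of 0 disables
    the corresponding rule.

    ``sharpness_threshold`` is the sigma_s gate; 0 (the default) admits every
    sharpness. ``whole_image_sharpness`` scores the full frame instead of the
    fin region only.
    """

    min_width_px: int = 200
    min_height_px: int = 200
    min_features: int = 5
    sharpness_threshold: float = 0.0
    whole_image_sharpness: bool = False

    def __post_init__(self) -> None:
        for name in ("min_width_px", "min_height_px", "min_features", "sharpness_threshold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def greyscale(image: FinImage) -> np.ndarray:
    """Intensity plane used throughout: CIE-Lab L* rescaled to [0, 255]."""
    return rgb_to_lab(image).L * (255.0 / 100.0)


def laplacian_sharpness(grey: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Population std of the Laplacian response of a grey plane, optionally
    restricted to a boolean mask.  Reflect padding at the frame boundary;
    pixels touching the mask border are included."""
    response = ndimage.convolve(np.asarray(grey, float), LAPLACIAN_KERNEL, mode="reflect")
    values = response.ravel() if mask is None else response[mask]
    return float(values.std())


def sharpness(
    image: FinImage, mask: FinMask | None = None, *, whole_image: bool = False
) -> SharpnessScore:
    """Sharpness = population std of the Laplacian-filtered greyscale image
    over the fin foreground (or the whole frame with ``whole_image=True``)."""
    grey = greyscale(image)
    if whole_image or mask is None:
        return SharpnessScore(value=laplacian_sharpness(grey))
    if mask.area_px == 0:
        raise ValueError("empty fin mask")
    return SharpnessScore(value=laplacian_sharpness(grey, mask.mask))


#: Tags used in filter-failure reasons.
REASON_WIDTH = "width"
REASON_HEIGHT = "height"
REASON_FEATURES = "feature_count"
REASON_SHARPNESS = "sharpness"


def passes_filter(
    image: FinImage,
    mask: FinMask,
    n_features: int,
    config: QualityConfig | None = None,
) -> tuple[bool, list[str]]:
    """Admission filter: width >= min_width_px AND height >= min_height_px AND
    n_features >= min_features AND sharpness >= sigma_s.

    Returns ``(pass, reasons)`` where ``reasons`` lists every violated rule.
    The sharpness statistic is only computed when the sigma_s gate is active.
    """
    if n_features < 0:
        raise ValueError("n_features must be >= 0")
    config = config or QualityConfig()
    reasons: list[str] = []
    if image.width < config.min_width_px:
        reasons.append(REASON_WIDTH)
    if image.height < config.min_height_px:
        reasons.append(REASON_HEIGHT)
    if n_features < config.min_features:
        reasons.append(REASON_FEATURES)
    if config.sharpness_threshold > 0:
        score = sharpness(image, mask, whole_image=config.whole_image_sharpness)
        if score.value < config.sharpness_threshold:
            reasons.append(REASON_SHARPNESS)
    return (not reasons), reasons
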