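"""Fin segmentation: CIE-Lab conversion, Otsu thresholding, morphological cleaning.

A cropped dorsal-fin photograph shows a grey fin against blue sea water.  The
two classes are nearly linearly separable in the opponent (a*, b*) plane of
CIE-Lab, so a single Otsu cut on the better-separating opponent channel,
followed by morphological noise removal and largest-component selection,
recovers the fin mask without any learned model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color, measure, morphology


class DegenerateInputError(ValueError):
    """Raised when an input carries no usable signal (e.g. a constant channel)."""


class SegmentationError(RuntimeError):
    """Raised when no fin foreground survives thresholding and cleaning."""


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunables for :func:`extract_fin_mask`.

    Parameters
    ----------
    channel:
        Opponent channel fed to Otsu: ``"auto"`` picks whichever of a*/b*
        attains the larger between-class variance at its own Otsu optimum,
        ``"a"``/``"b"`` force one.
    morph_radius:
        Disk radius (px) for opening/closing.  ``None`` uses
        ``max(1, round(0.005 * min(H, W)))``.
    """

    channel: str = "auto"
    morph_radius: int | None = None

    def __post_init__(self) -> None:
        if self.channel not in ("auto", "a", "b"):
            raise ValueError(f"channel must be auto|a|b, got {self.channel!r}")
        if self.morph_radius is not None and self.morph_radius < 1:
            raise ValueError("morph_radius must be >= 1")


@dataclass
class FinImage:
    """An 8-bit RGB photograph of (one side of) a dorsal fin."""

    pixels: np.ndarray
    source: str = "synthetic"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"expected HxWx3 RGB array, got shape {px.shape}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class LabImage:
    """CIE-Lab planes of an image: lightness L* and opponents a* (green-red), b* (blue-yellow)."""

    L: np.ndarray
    a: np.ndarray
    b: np.ndarray


@dataclass
class FinMask:
    """Binary foreground mask of the fin within an image."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    def to_png_array(self) -> np.ndarray:
        """0/255 uint8 rendering, for writing inspection PNGs."""
        return (self.mask.astype(np.uint8)) * 255


def rgb_to_lab(image: FinImage) -> LabImage:
    """Convert sRGB (D65) to CIE-Lab; L* in [0, 100]."""
    lab = color.rgb2lab(image.pixels)
    return LabImage(L=lab[..., 0], a=lab[..., 1], b=lab[..., 2])


_N_BINS = 256


def _otsu_cut(channel: np.ndarray) -> tuple[int, float, np.ndarray, np.ndarray]:
    """Otsu split of a real channel over a 256-bin histogram.

    Returns ``(best_bin, best_variance, bin_index_image, bin_edges)`` where the
    foreground-candidate class is every bin strictly above ``best_bin``.
    Between-class variance sigma_b^2 = w0*w1*(mu0-mu1)^2 is maximised over all
    255 cuts (equivalent to minimising intra-class variance); the first
    maximum wins on ties.
    """
    vmin = float(channel.min())
    vmax = float(channel.max())
    idx = np.floor((channel - vmin) / (vmax - vmin) * _N_BINS).astype(np.int64)
    np.clip(idx, 0, _N_BINS - 1, out=idx)
    counts = np.bincount(idx.ravel(), minlength=_N_BINS).astype(np.float64)
    centers = vmin + (np.arange(_N_BINS) + 0.5) * (vmax - vmin) / _N_BINS

    w0 = np.cumsum(counts)[:-1]
    w1 = counts.sum() - w0
    cum_mean = np.cumsum(counts * centers)[:-1]
    total_mean = (counts * centers).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = cum_mean / w0
        mu1 = (total_mean - cum_mean) / w1
        sigma_b2 = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b2 = np.where((w0 > 0) & (w1 > 0), sigma_b2, -np.inf)
    best = int(np.argmax(sigma_b2))
    edges = vmin + np.arange(_N_BINS + 1) * (vmax - vmin) / _N_BINS
    return best, float(sigma_b2[best]), idx, edges


def otsu_threshold(channel: np.ndarray) -> tuple[float, np.ndarray]:
    """Binarise a 2-D channel at the Otsu optimum.

    The threshold maximises the between-class variance of a 256-bin histogram.
    The returned mask is oriented so that the foreground is the class in the
    *minority* on the 1-px image border: cropped fin photographs have sea, not
    fin, at their edges.

    Raises
    ------
    DegenerateInputError
        If the channel is constant (no split exists).
    """
    channel = np.asarray(channel, dtype=np.float64)
    if channel.ndim != 2:
        raise ValueError("channel must be a 2-D array")
    if channel.min() == channel.max():
        raise DegenerateInputError("constant channel: Otsu split undefined")
    best, _, idx, edges = _otsu_cut(channel)
    threshold = float(edges[best + 1])
    mask = idx > best
    border = np.concatenate(
        [mask[0, :], mask[-1, :], mask[1:-1, 0], mask[1:-1, -1]]
    )
    if border.size and border.mean() > 0.5:
        mask = ~mask
    return threshold, mask


def morphological_clean(mask: np.ndarray, radius: int) -> np.ndarray:
    """Binary opening then closing with a disk of the given radius.

    Opening removes specks smaller than the structuring element; closing then
    fills comparably small holes.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    footprint = morphology.disk(radius)
    cleaned = morphology.opening(np.asarray(mask, bool), footprint)
    return morphology.closing(cleaned, footprint)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep the largest 8-connected component; size ties go to the component
    whose smallest (row, col) foreground pixel is lexicographically first."""
    labels = measure.label(mask, connectivity=2)
    n = labels.max()
    if n == 0:
        raise SegmentationError("empty mask after cleaning")
    if n == 1:
        return labels == 1
    sizes = np.bincount(labels.ravel())[1:]
    biggest = np.flatnonzero(sizes == sizes.max()) + 1
    if len(biggest) > 1:
        rows, cols = np.nonzero(np.isin(labels, biggest))
        order = np.lexsort((cols, rows))
        winner = labels[rows[order[0]], cols[order[0]]]
    else:
        winner = biggest[0]
    return labels == winner


def default_morph_radius(height: int, width: int) -> int:
    return max(1, round(0.005 * min(height, width)))


def extract_fin_mask(
    image: FinImage, config: SegmentationConfig | None = None
) -> FinMask:
    """Segment the fin: Lab conversion, Otsu on the better opponent channel,
    morphological cleaning, largest-component selection.

    With ``channel="auto"`` the a* and b* channels are each thresholded and
    the one achieving the larger Otsu between-class variance is used — per
    image, whichever opponent axis best separates grey fin from blue water.

    Raises
    ------
    DegenerateInputError
        Constant image (both opponent channels flat).
    SegmentationError
        No foreground survives cleaning.
    """
    config = config or SegmentationConfig()
    lab = rgb_to_lab(image)
    channels = {"a": lab.a, "b": lab.b}
    if config.channel == "auto":
        best_mask = None
        best_var = -np.inf
        any_valid = False
        for ch in ("a", "b"):
            arr = channels[ch]
            if arr.min() == arr.max():
                continue
            any_valid = True
            cut, var, idx, _ = _otsu_cut(arr)
            if var > best_var:
                best_var = var
                best_mask = idx > cut
        if not any_valid:
            raise DegenerateInputError("constant opponent channels: no fin/sea contrast")
        raw = best_mask
    else:
        arr = channels[config.channel]
        if arr.min() == arr.max():
            raise DegenerateInputError(f"constant {config.channel}* channel")
        cut, _, idx, _ = _otsu_cut(arr)
        raw = idx > cut

    border = np.concatenate([raw[0, :], raw[-1, :], raw[1:-1, 0], raw[1:-1, -1]])
    if border.size and border.mean() > 0.5:
        raw = ~raw

    radius = config.morph_radius or default_morph_radius(image.height, image.width)
    cleaned = morphological_clean(raw, radius)
    if not cleaned.any():
        raise SegmentationError("no foreground after morphological cleaning")
    return FinMask(mask=_largest_component(cleaned))
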