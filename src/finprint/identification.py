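"""Identity assignment for dorsal-fin photographs.

The core pipeline: detect scale/rotation-invariant keypoints restricted to
the fin, match descriptors one-to-one against every enrolled fin model,
summarise each comparison by the number of equally-oriented matches k* and
the trimmed median descriptor distance d*, and predict the model maximising
k* (ties broken by minimum d*).  Predictions with weak support (k* <= 4) or
unresolved ties carry explicit reliability warnings.

Scar patterns on a Risso's dolphin fin are stable, high-contrast marks, so a
generic interest-point detector finds repeatable features on them; the
backend is pluggable behind :class:`FeatureBackend` and defaults to
scikit-image's SIFT (scale- and rotation-invariant, deterministic).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from skimage.feature import SIFT

from .quality import QualityConfig, passes_filter, greyscale, sharpness
from .segmentation import (
    FinImage,
    FinMask,
    SegmentationConfig,
    SegmentationError,
    DegenerateInputError,
    extract_fin_mask,
)

# --------------------------------------------------------------------------
# Feature detection
# --------------------------------------------------------------------------


class FeatureBackend(Protocol):
    """A keypoint detector/descriptor with scale and orientation estimates."""

    name: str
    descriptor_length: int

    def detect(
        self, grey: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Return ``(xy, scales, orientations_deg, descriptors)`` for a float
        greyscale image: positions as an (n, 2) array of (x, y) pixel
        coordinates, orientations in degrees in [0, 360), descriptors as an
        (n, d) float array."""
        ...


class SiftBackend:
    """scikit-image SIFT detector (128-d descriptors, deterministic)."""

    name = "sift"
    descriptor_length = 128

    def __init__(self, **params):
        self._params = params

    def detect(self, grey):
        det = SIFT(**self._params)
        try:
            det.detect_and_extract(np.ascontiguousarray(grey, dtype=np.float64))
        except RuntimeError:  # no features found
            return (
                np.empty((0, 2), float),
                np.empty(0, float),
                np.empty(0, float),
                np.empty((0, self.descriptor_length), float),
            )
        rc = det.keypoints
        xy = np.stack([rc[:, 1], rc[:, 0]], axis=1).astype(np.float64)
        orientations = np.degrees(det.orientations) % 360.0
        return xy, det.scales.astype(float), orientations, det.descriptors.astype(np.float64)


_BACKENDS = {"sift": SiftBackend}


def get_backend(name: str = "sift", **params) -> FeatureBackend:
    try:
        return _BACKENDS[name](**params)
    except KeyError:
        raise ValueError(f"unknown backend {name!r}; available: {sorted(_BACKENDS)}") from None


@dataclass(frozen=True)
class Keypoint:
    """One interest point: position, scale, orientation (degrees, [0, 360))
    and its descriptor vector."""

    x: float
    y: float
    scale: float
    orientation: float
    descriptor: np.ndarray


@dataclass
class FeatureSet:
    """Keypoints with descriptors, restricted to the fin region of one image."""

    xy: np.ndarray           # (n, 2) of (x, y)
    scales: np.ndarray       # (n,)
    orientations: np.ndarray  # (n,) degrees in [0, 360)
    descriptors: np.ndarray  # (n, d)
    image_ref: str = ""

    def __len__(self) -> int:
        return self.xy.shape[0]

    def __getitem__(self, j: int) -> Keypoint:
        return Keypoint(
            x=float(self.xy[j, 0]),
            y=float(self.xy[j, 1]),
            scale=float(self.scales[j]),
            orientation=float(self.orientations[j]),
            descriptor=self.descriptors[j],
        )


def detect_features(
    image: FinImage, mask: FinMask, backend: FeatureBackend | None = None
) -> FeatureSet:
    """Detect keypoints on the full image, then delete every keypoint whose
    (x, y) position falls outside the fin mask.

    An empty result is valid — admission is the quality filter's job.
    """
    if mask.area_px == 0:
        raise ValueError("empty fin mask")
    backend = backend or get_backend()
    xy, scales, orientations, descriptors = backend.detect(greyscale(image))
    if len(xy):
        cols = np.clip(np.round(xy[:, 0]).astype(int), 0, mask.mask.shape[1] - 1)
        rows = np.clip(np.round(xy[:, 1]).astype(int), 0, mask.mask.shape[0] - 1)
        inside = mask.mask[rows, cols]
        xy, scales, orientations, descriptors = (
            xy[inside], scales[inside], orientations[inside], descriptors[inside],
        )
    return FeatureSet(
        xy=xy, scales=scales, orientations=orientations,
        descriptors=descriptors, image_ref=image.source,
    )


# --------------------------------------------------------------------------
# Matching and per-model scoring
# --------------------------------------------------------------------------


@dataclass
class MatchSet:
    """One-to-one descriptor matches between a query and a model feature set.

    ``query_xy``/``model_xy`` are the matched positions (the P array),
    ``distances`` the descriptor L2 distances (the D array), ``orientations``
    the (query, model) orientation pairs in degrees (the O array).
    """

    query_xy: np.ndarray
    model_xy: np.ndarray
    distances: np.ndarray
    orientations: np.ndarray  # (k, 2)
    image_distances: np.ndarray | None = None  # optional diagnostic: |p_query - p_model|

    @property
    def k(self) -> int:
        return self.distances.shape[0]

    def __len__(self) -> int:
        return self.k


def match_features(
    query: FeatureSet, model: FeatureSet, *, ratio_threshold: float | None = None
) -> MatchSet:
    """Mutual-nearest-neighbour matching under descriptor L2 distance.

    A pair (i, j) is kept iff j is i's nearest model descriptor AND i is j's
    nearest query descriptor, which makes the matching one-to-one.  An
    optional Lowe ratio test (``ratio_threshold``, default off) additionally
    requires d1/d2 <= threshold on the query side.
    """
    if len(query) == 0 or len(model) == 0:
        raise ValueError("both feature sets must be non-empty")
    D = cdist(query.descriptors, model.descriptors)
    nn_q = D.argmin(axis=1)
    nn_m = D.argmin(axis=0)
    qi = np.arange(len(query))
    mutual = nn_m[nn_q] == qi
    if ratio_threshold is not None and D.shape[1] >= 2:
        part = np.partition(D, 1, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = part[:, 0] / part[:, 1]
        mutual &= (ratio <= ratio_threshold) | ~np.isfinite(ratio)
    qsel = qi[mutual]
    msel = nn_q[mutual]
    image_d = np.linalg.norm(query.xy[qsel] - model.xy[msel], axis=1)
    return MatchSet(
        query_xy=query.xy[qsel],
        model_xy=model.xy[msel],
        distances=D[qsel, msel],
        orientations=np.stack(
            [query.orientations[qsel], model.orientations[msel]], axis=1
        ) if len(qsel) else np.empty((0, 2)),
        image_distances=image_d,
    )


def median_distance_iqr(distances: Sequence[float]) -> float:
    """Trimmed median d*: median of the distances lying inside the closed
    [25th, 75th] percentile interval (linear-interpolation percentiles).

    With very short lists the closed interval can contain no sample (e.g. two
    distinct values); the plain median is returned then.
    """
    d = np.asarray(distances, dtype=np.float64)
    if d.size == 0:
        raise ValueError("empty distance list")
    q25, q75 = np.percentile(d, [25, 75])
    kept = d[(d >= q25) & (d <= q75)]
    if kept.size == 0:
        kept = d
    return float(np.median(kept))


def filter_equal_orientation(matches: MatchSet, *, unit: str = "rad") -> MatchSet:
    """Keep only the matched pairs whose orientations agree: those with
    omega = round(o_query - o_model) == 0.

    The orientation difference is wrapped to the half-open symmetric interval
    ((-pi, pi] radians or (-180, 180] degrees) and rounded half-to-even.  The
    unit the difference is expressed in before rounding sets the width of the
    agreement window: ``"rad"`` (the default used by the pipeline) keeps
    pairs aligned within +/-0.5 radian, ``"deg"`` within +/-0.5 degree.
    """
    if unit not in ("rad", "deg"):
        raise ValueError("unit must be 'rad' or 'deg'")
    if matches.k == 0:
        return matches
    diff_deg = matches.orientations[:, 0] - matches.orientations[:, 1]
    wrapped = -((-diff_deg + 180.0) % 360.0 - 180.0)  # wrap to (-180, 180]
    if unit == "rad":
        omega = np.round(np.deg2rad(wrapped))
    else:
        omega = np.round(wrapped)
    keep = omega == 0
    return MatchSet(
        query_xy=matches.query_xy[keep],
        model_xy=matches.model_xy[keep],
        distances=matches.distances[keep],
        orientations=matches.orientations[keep],
        image_distances=None if matches.image_distances is None
        else matches.image_distances[keep],
    )


@dataclass
class FinModel:
    """An enrolled reference: one side of one dolphin's fin with its features."""

    dolphin_name: str
    side: str
    image: FinImage
    features: FeatureSet
    sharpness: float = 0.0

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if len(self.features) == 0:
            raise ValueError("a fin model requires a non-empty feature set")


@dataclass
class ModelScore:
    """Evidence for one query-vs-model comparison."""

    model: FinModel
    k: int
    k_star: int
    d_star: float | None
    matches: MatchSet | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.k_star <= self.k:
            raise ValueError("0 <= k_star <= k violated")


WARN_LOW_SUPPORT = "low_support"
WARN_AMBIGUOUS_TIE = "ambiguous_tie"


@dataclass
class Prediction:
    """The identity decision with its match evidence and reliability warnings."""

    dolphin_name: str
    side: str
    winning_score: ModelScore
    warnings: frozenset[str]
    scores: list[ModelScore] = field(default_factory=list)
    sharpness: float | None = None


@dataclass
class Rejection:
    """A query refused by the admission filter (or by segmentation failure)."""

    reasons: tuple[str, ...]
    sharpness: float | None = None
    n_features: int | None = None


def compare_to_models(
    query_features: FeatureSet,
    models: Sequence[FinModel],
    *,
    omega_unit: str = "rad",
    ratio_threshold: float | None = None,
) -> list[ModelScore]:
    """Score the query against every model, preserving model order.

    Per model: mutual-NN matching, trimmed median distance d* over all k
    matches, then the equal-orientation filter giving k*.
    """
    if not models:
        raise ValueError("model collection is empty")
    scores: list[ModelScore] = []
    for model in models:
        ms = match_features(query_features, model.features, ratio_threshold=ratio_threshold)
        d_star = median_distance_iqr(ms.distances) if ms.k else None
        filtered = filter_equal_orientation(ms, unit=omega_unit)
        scores.append(
            ModelScore(model=model, k=ms.k, k_star=filtered.k, d_star=d_star, matches=ms)
        )
    return scores


def predict_identity(scores: Sequence[ModelScore]) -> Prediction:
    """Decision rule: winner = argmax k*; k* ties are broken by minimum d*;
    a residual tie keeps the first model in enrollment order and raises the
    ``ambiguous_tie`` warning.  A winner with k* <= 4 raises ``low_support``.
    """
    if not scores:
        raise ValueError("no scores to decide on")
    k_max = max(s.k_star for s in scores)
    tied = [s for s in scores if s.k_star == k_max]
    warnings: set[str] = set()
    if len(tied) == 1:
        winner = tied[0]
    else:
        d_min = min(np.inf if s.d_star is None else s.d_star for s in tied)
        tied_d = [s for s in tied
                  if (np.inf if s.d_star is None else s.d_star) == d_min]
        winner = tied_d[0]
        if len(tied_d) > 1:
            warnings.add(WARN_AMBIGUOUS_TIE)
    if winner.k_star <= 4:
        warnings.add(WARN_LOW_SUPPORT)
    return Prediction(
        dolphin_name=winner.model.dolphin_name,
        side=winner.model.side,
        winning_score=winner,
        warnings=frozenset(warnings),
        scores=list(scores),
    )


def identify(
    image: FinImage,
    models: Sequence[FinModel],
    config: QualityConfig | None = None,
    backend: FeatureBackend | None = None,
    *,
    segmentation_config: SegmentationConfig | None = None,
    omega_unit: str = "rad",
    ratio_threshold: float | None = None,
) -> Prediction | Rejection:
    """Full pipeline on one query image: segmentation, sharpness, feature
    detection, admission filter, model comparison, identity decision.

    Returns a :class:`Rejection` (never a forced guess) when segmentation
    fails, when the admission filter refuses the image, or when no model
    yields a single raw match.
    """
    if not models:
        raise ValueError("no enrolled models")
    config = config or QualityConfig()
    backend = backend or get_backend()
    try:
        mask = extract_fin_mask(image, segmentation_config)
    except (SegmentationError, DegenerateInputError):
        return Rejection(reasons=("segmentation",))
    features = detect_features(image, mask, backend)
    score = sharpness(image, mask, whole_image=config.whole_image_sharpness)
    ok, reasons = passes_filter(image, mask, len(features), config)
    if not ok:
        return Rejection(reasons=tuple(reasons), sharpness=score.value,
                         n_features=len(features))
    scores = compare_to_models(
        features, models, omega_unit=omega_unit, ratio_threshold=ratio_threshold
    )
    if all(s.k == 0 for s in scores):
        # no model produced a single raw match: refuse rather than guess
        return Rejection(reasons=(WARN_LOW_SUPPORT,), sharpness=score.value,
                         n_features=len(features))
    prediction = predict_identity(scores)
    prediction.sharpness = score.value
    return prediction


# --------------------------------------------------------------------------
# Gallery persistence
# --------------------------------------------------------------------------


def save_gallery(models: Sequence[FinModel], directory: str | Path) -> None:
    """Persist enrolled models: a models.json manifest plus one NPZ of
    keypoint arrays per model."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for idx, m in enumerate(models):
        stem = f"model_{idx:04d}"
        np.savez(
            directory / f"{stem}.npz",
            xy=m.features.xy,
            scales=m.features.scales,
            orientations=m.features.orientations,
            descriptors=m.features.descriptors,
            pixels=m.image.pixels,
        )
        manifest.append(
            {
                "dolphin_name": m.dolphin_name,
                "side": m.side,
                "image_ref": m.features.image_ref,
                "sharpness": m.sharpness,
                "arrays": f"{stem}.npz",
                "descriptor_length": int(m.features.descriptors.shape[1]),
            }
        )
    (directory / "models.json").write_text(
        json.dumps({"backend": "sift", "models": manifest}, indent=2)
    )


def load_gallery(directory: str | Path) -> list[FinModel]:
    directory = Path(directory)
    manifest_path = directory / "models.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no gallery manifest at {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    models = []
    for entry in manifest["models"]:
        data = np.load(directory / entry["arrays"])
        features = FeatureSet(
            xy=data["xy"],
            scales=data["scales"],
            orientations=data["orientations"],
            descriptors=data["descriptors"],
            image_ref=entry["image_ref"],
        )
        models.append(
            FinModel(
                dolphin_name=entry["dolphin_name"],
                side=entry["side"],
                image=FinImage(pixels=data["pixels"], source=entry["image_ref"]),
                features=features,
                sharpness=entry.get("sharpness", 0.0),
            )
        )
    return models
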