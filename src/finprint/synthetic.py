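"""Synthetic fin imagery and sighting schedules with known ground truth.

Field photographs of Risso's dolphin fins are not openly distributed, so the
test bed is synthetic: a grey, dorsal-fin-shaped polygon on blue sea water,
carrying a per-identity pattern of near-white scar strokes (Risso's dolphins
accumulate long-lasting white scarring that photo-ID relies on).  Every
render returns the exact foreground polygon as a ground-truth mask, and all
randomness flows from explicit seeds, so renders are bit-reproducible.

The same module fabricates catalogues and multi-date sighting schedules
across two depth strata for the analytics code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date as Date, timedelta
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import disk, polygon

from .catalogue import Catalogue, CatalogueEntry, SightingRecord
from .segmentation import FinImage, FinMask

DEFAULT_SEA = (20, 60, 140)
DEFAULT_FIN = (128, 128, 128)

#: Dorsal-fin-like silhouette in normalized [0,1]^2 coordinates (x, y with y
#: downward): broad base, curved leading edge, falcate tip, trailing notch.
_FIN_TEMPLATE = np.array(
    [
        (0.05, 0.95), (0.10, 0.62), (0.17, 0.40), (0.27, 0.22), (0.40, 0.10),
        (0.50, 0.07), (0.54, 0.14), (0.50, 0.30), (0.52, 0.45), (0.58, 0.60),
        (0.68, 0.74), (0.80, 0.85), (0.90, 0.92), (0.92, 0.97), (0.05, 0.97),
    ]
)


@dataclass(frozen=True)
class ScarStroke:
    """One scar: an anti-aliased near-white line on the fin surface, in
    normalized fin coordinates."""

    start: tuple[float, float]
    end: tuple[float, float]
    width: float        # normalized; ~0.004-0.010 of the canvas
    brightness: int     # 8-bit grey value, near-white


@dataclass(frozen=True)
class IdentitySpec:
    """A synthetic individual: silhouette plus its fixed scar pattern."""

    name: str
    fin_polygon: np.ndarray
    scar_pattern: tuple[ScarStroke, ...]

    def __post_init__(self) -> None:
        if len(self.scar_pattern) < 3:
            raise ValueError("an identity needs >= 3 scar strokes")


@dataclass(frozen=True)
class RenderParams:
    """Rendering conditions for one photograph."""

    width: int = 400
    height: int = 400
    rotation_deg: float = 0.0
    scale: float = 1.0
    blur_sigma: float = 0.0
    sea_color: tuple[int, int, int] = DEFAULT_SEA
    fin_color: tuple[int, int, int] = DEFAULT_FIN
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("canvas must be at least 1x1")
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        if self.blur_sigma < 0 or self.noise_sd < 0:
            raise ValueError("blur_sigma and noise_sd must be >= 0")


def make_identity(name: str, seed: int, n_scars: int = 8) -> IdentitySpec:
    """Create a reproducible identity: the template silhouette with small
    per-identity vertex jitter, plus ``n_scars`` pseudo-random scar strokes
    drawn from the identity's own seed (independent of any render)."""
    rng = np.random.default_rng(seed)
    poly = _FIN_TEMPLATE + rng.normal(0.0, 0.01, _FIN_TEMPLATE.shape)
    strokes = []
    for _ in range(max(3, n_scars)):
        a = rng.uniform([0.20, 0.30], [0.72, 0.82])
        angle = rng.uniform(0.0, 2.0 * np.pi)
        length = rng.uniform(0.05, 0.22)
        b = a + length * np.array([np.cos(angle), np.sin(angle)])
        strokes.append(
            ScarStroke(
                start=(float(a[0]), float(a[1])),
                end=(float(b[0]), float(b[1])),
                width=float(rng.uniform(0.004, 0.009)),
                brightness=int(rng.integers(225, 256)),
            )
        )
    return IdentitySpec(name=name, fin_polygon=poly, scar_pattern=tuple(strokes))


def _transform(points: np.ndarray, params: RenderParams) -> np.ndarray:
    """Map normalized fin coordinates to pixel coordinates: centre, rotate,
    scale to 0.6 * scale * min(W, H)."""
    theta = np.deg2rad(params.rotation_deg)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    extent = 0.6 * params.scale * min(params.width, params.height)
    centre = np.array([params.width / 2.0, params.height / 2.0])
    return (np.atleast_2d(points) - 0.5) @ rot.T * extent + centre


def generate_fin_image(
    identity: IdentitySpec, params: RenderParams
) -> tuple[FinImage, FinMask]:
    """Render one photograph of an identity and its exact ground-truth mask.

    The polygon is rotated/scaled onto the canvas, filled with the fin
    colour, overlaid with the identity's scar strokes (clipped to the fin),
    Gaussian-blurred by ``blur_sigma`` and perturbed by i.i.d. Gaussian pixel
    noise.  The returned mask is the un-degraded polygon support.

    Raises if the transformed fin exceeds the canvas.
    """
    verts = _transform(identity.fin_polygon, params)
    if (verts[:, 0].min() < 0 or verts[:, 1].min() < 0
            or verts[:, 0].max() > params.width - 1
            or verts[:, 1].max() > params.height - 1):
        raise ValueError(
            f"fin exceeds the {params.width}x{params.height} canvas at "
            f"scale {params.scale}, rotation {params.rotation_deg} deg"
        )
    shape = (params.height, params.width)
    mask = np.zeros(shape, dtype=bool)
    rr, cc = polygon(verts[:, 1], verts[:, 0], shape)
    mask[rr, cc] = True

    img = np.empty((*shape, 3), dtype=np.float64)
    img[:] = params.sea_color
    img[mask] = params.fin_color

    extent = 0.6 * params.scale * min(params.width, params.height)
    for stroke in identity.scar_pattern:
        a = _transform(np.array(stroke.start), params)[0]
        b = _transform(np.array(stroke.end), params)[0]
        radius = max(0.7, stroke.width * extent)
        n_steps = int(np.hypot(*(b - a)) / max(radius, 0.5)) * 2 + 2
        for t in np.linspace(0.0, 1.0, n_steps):
            c = a + t * (b - a)
            rr, cc = disk((c[1], c[0]), radius, shape=shape)
            keep = mask[rr, cc]
            img[rr[keep], cc[keep]] = stroke.brightness

    if params.blur_sigma > 0:
        img = gaussian_filter(img, sigma=(params.blur_sigma, params.blur_sigma, 0))
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        img = img + rng.normal(0.0, params.noise_sd, img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return (
        FinImage(pixels=pixels, source=f"synthetic:{identity.name}:seed{params.seed}"),
        FinMask(mask=mask),
    )


# --------------------------------------------------------------------------
# Gallery simulation (model/query split)
# --------------------------------------------------------------------------


@dataclass
class LabelledRender:
    """One rendered photograph with its provenance."""

    name: str
    image: FinImage
    mask: FinMask
    params: RenderParams


@dataclass
class GallerySim:
    """A simulated study: clean model renders plus perturbed, labelled
    query renders of the same identities."""

    identities: list[IdentitySpec]
    models: list[LabelledRender]
    queries: list[LabelledRender]


def generate_gallery(
    n_identities: int,
    params: RenderParams | None = None,
    seed: int = 0,
    *,
    n_queries: int = 3,
    rotation_max_deg: float = 15.0,
    scale_range: tuple[float, float] = (0.9, 1.1),
    blur_choices: Sequence[float] = (0.0,),
) -> GallerySim:
    """Render one clean model image per identity plus ``n_queries`` perturbed
    queries per identity (rotation uniform in +/-``rotation_max_deg``, scale
    uniform in ``scale_range``, blur drawn from ``blur_choices``).

    Model and query renders never share parameters: models are rendered
    unrotated at scale 1 with zero blur, queries always carry fresh noise
    seeds and continuous perturbations.
    """
    if n_identities < 2:
        raise ValueError("need at least 2 identities")
    base = params or RenderParams()
    rng = np.random.default_rng(seed)
    identities = [
        make_identity(f"synth-{i:03d}", seed=int(rng.integers(1 << 30)))
        for i in range(n_identities)
    ]
    models = []
    queries = []
    for ident in identities:
        mp = replace(base, rotation_deg=0.0, scale=1.0, blur_sigma=0.0,
                     seed=int(rng.integers(1 << 30)))
        image, mask = generate_fin_image(ident, mp)
        models.append(LabelledRender(name=ident.name, image=image, mask=mask, params=mp))
        for _ in range(n_queries):
            qp = replace(
                base,
                rotation_deg=float(rng.uniform(-rotation_max_deg, rotation_max_deg)),
                scale=float(rng.uniform(*scale_range)),
                blur_sigma=float(rng.choice(np.asarray(blur_choices, dtype=float))),
                seed=int(rng.integers(1 << 30)),
            )
            image, mask = generate_fin_image(ident, qp)
            queries.append(LabelledRender(name=ident.name, image=image, mask=mask, params=qp))
    return GallerySim(identities=identities, models=models, queries=queries)


# --------------------------------------------------------------------------
# Catalogue / sighting schedule simulation
# --------------------------------------------------------------------------

#: Survey bounding box (decimal degrees): Gulf of Taranto, Northern Ionian Sea.
_BBOX = {"lat": (39.9, 40.5), "lon": (16.9, 17.5)}


def generate_catalogue(
    n_dolphins: int,
    n_dates: int = 11,
    p_resight: float = 0.3,
    depth_mix: float = 0.5,
    seed: int = 0,
    *,
    start_date: Date = Date(2013, 7, 1),
) -> Catalogue:
    """Simulate a photo-ID catalogue with sighting records.

    Each survey date is assigned a depth stratum (deep with probability
    ``depth_mix``: depth uniform in [800, 1000] m, else [436, 799] m,
    mirroring a continental-slope survey area).  Each dolphin is present on
    each date independently with probability ``p_resight``; a dolphin seen
    nowhere is assigned one random date so every catalogued individual has at
    least one sighting.  One catalogue entry (photograph) is created per
    (dolphin, date) presence.  Deterministic per seed.
    """
    if n_dolphins < 1 or n_dates < 1:
        raise ValueError("need at least one dolphin and one date")
    if not (0 <= p_resight <= 1 and 0 <= depth_mix <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    dates = [start_date + timedelta(days=int(d))
             for d in sorted(rng.choice(4 * 365, size=n_dates, replace=False))]
    names = [f"dolphin-{i:03d}" for i in range(n_dolphins)]
    present = rng.random((n_dolphins, n_dates)) < p_resight
    for i in range(n_dolphins):
        if not present[i].any():
            present[i, int(rng.integers(n_dates))] = True

    deep = rng.random(n_dates) < depth_mix
    depths = np.where(deep, rng.uniform(800.0, 1000.0, n_dates),
                      rng.uniform(436.0, 799.0, n_dates))
    gps = np.stack(
        [rng.uniform(*_BBOX["lat"], n_dates), rng.uniform(*_BBOX["lon"], n_dates)],
        axis=1,
    )
    sightings = []
    entries = []
    for j, d in enumerate(dates):
        dolphins = frozenset(names[i] for i in range(n_dolphins) if present[i, j])
        if not dolphins:
            continue
        group = len(dolphins) + int(rng.integers(0, 4))
        sightings.append(
            SightingRecord(date=d, gps=(float(gps[j, 0]), float(gps[j, 1])),
                           depth_m=float(depths[j]), group_size=group,
                           dolphins=dolphins)
        )
        for name in sorted(dolphins):
            stem = f"images/{name}_{d.isoformat()}"
            entries.append(
                CatalogueEntry(
                    dolphin_name=name,
                    input_image=f"{stem}_full.png",
                    cropped_fin=f"{stem}_fin.png",
                    observation_date=d,
                    gps=(float(gps[j, 0]), float(gps[j, 1])),
                    codename=f"campaign-{d.year}",
                )
            )
    return Catalogue(entries=entries, sightings=sightings)
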