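"""Catalogue data model: dolphins, images, observation dates, GPS, sightings.

Each catalogue row links one cropped fin photograph to a named individual,
an observation date and a GPS position; companion sighting records add the
depth stratum and group size needed by the sighting analytics.  Catalogues
round-trip through flat JSON or CSV files.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from datetime import date as Date
from pathlib import Path
from typing import Callable, Mapping, Sequence

from .identification import FeatureBackend, FinModel, detect_features, get_backend
from .quality import QualityConfig, passes_filter, sharpness
from .segmentation import (
    DegenerateInputError,
    FinImage,
    SegmentationConfig,
    SegmentationError,
    extract_fin_mask,
)


class SchemaError(ValueError):
    """A required attribute is missing from a catalogue file."""


class ValidationError(ValueError):
    """A catalogue value violates its invariant (bad date, GPS range, ...)."""


ENTRY_FIELDS = (
    "dolphin_name", "input_image", "cropped_fin",
    "observation_date", "gps_lat", "gps_lon", "codename",
)
SIGHTING_FIELDS = ("date", "gps_lat", "gps_lon", "depth_m", "group_size", "dolphins")


def _parse_date(value, context: str) -> Date:
    if isinstance(value, Date):
        return value
    try:
        return Date.fromisoformat(str(value))
    except ValueError as exc:
        raise ValidationError(f"{context}: invalid date {value!r}") from exc


@dataclass
class CatalogueEntry:
    """One catalogued photograph of a named dolphin."""

    dolphin_name: str
    input_image: str
    cropped_fin: str
    observation_date: Date
    gps: tuple[float, float]
    codename: str = ""
    side: str = "right"

    def __post_init__(self) -> None:
        if not self.dolphin_name:
            raise ValidationError("dolphin_name must be non-empty")
        self.observation_date = _parse_date(self.observation_date, self.dolphin_name)
        lat, lon = float(self.gps[0]), float(self.gps[1])
        if not -90 <= lat <= 90:
            raise ValidationError(f"{self.dolphin_name}: latitude {lat} outside [-90, 90]")
        if not -180 <= lon <= 180:
            raise ValidationError(f"{self.dolphin_name}: longitude {lon} outside [-180, 180]")
        self.gps = (lat, lon)
        if self.side not in ("left", "right"):
            raise ValidationError(f"{self.dolphin_name}: side must be left|right")


@dataclass
class SightingRecord:
    """One survey sighting: date, position, depth stratum data, group."""

    date: Date
    gps: tuple[float, float]
    depth_m: float
    group_size: int
    dolphins: frozenset[str]

    def __post_init__(self) -> None:
        self.date = _parse_date(self.date, "sighting")
        if self.depth_m <= 0:
            raise ValidationError(f"sighting {self.date}: depth_m must be > 0")
        self.dolphins = frozenset(self.dolphins)
        if self.group_size < len(self.dolphins):
            raise ValidationError(
                f"sighting {self.date}: group_size {self.group_size} < "
                f"{len(self.dolphins)} identified dolphins"
            )


@dataclass
class Catalogue:
    """Ordered catalogue entries plus optional sighting records."""

    entries: list[CatalogueEntry] = field(default_factory=list)
    sightings: list[SightingRecord] | None = None

    def __post_init__(self) -> None:
        seen = set()
        for e in self.entries:
            key = (e.dolphin_name, e.cropped_fin)
            if key in seen:
                raise ValidationError(f"duplicate (dolphin, cropped_fin) pair {key}")
            seen.add(key)
        if self.sightings is not None:
            dates = {s.date for s in self.sightings}
            for e in self.entries:
                if e.observation_date not in dates:
                    raise ValidationError(
                        f"{e.dolphin_name}: observation date {e.observation_date} "
                        "has no sighting record"
                    )

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def dolphin_names(self) -> list[str]:
        return sorted({e.dolphin_name for e in self.entries})

    @property
    def observation_dates(self) -> list[Date]:
        return sorted({e.observation_date for e in self.entries})


# --------------------------------------------------------------------------
# File I/O
# --------------------------------------------------------------------------


def _entry_from_record(record: Mapping, row: int) -> CatalogueEntry:
    for name in ENTRY_FIELDS:
        if name not in record or record[name] in (None, ""):
            if name == "codename" and "codename" in record:
                continue
            raise SchemaError(f"row {row}: missing required attribute {name!r}")
    try:
        return CatalogueEntry(
            dolphin_name=str(record["dolphin_name"]),
            input_image=str(record["input_image"]),
            cropped_fin=str(record["cropped_fin"]),
            observation_date=record["observation_date"],
            gps=(float(record["gps_lat"]), float(record["gps_lon"])),
            codename=str(record.get("codename", "")),
            side=str(record.get("side", "right")),
        )
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ValidationError):
            raise
        raise ValidationError(f"row {row}: {exc}") from exc


def _sighting_from_record(record: Mapping, row: int) -> SightingRecord:
    for name in SIGHTING_FIELDS:
        if name not in record:
            raise SchemaError(f"sighting row {row}: missing attribute {name!r}")
    dolphins = record["dolphins"]
    if isinstance(dolphins, str):
        dolphins = [d for d in dolphins.split(";") if d]
    return SightingRecord(
        date=record["date"],
        gps=(float(record["gps_lat"]), float(record["gps_lon"])),
        depth_m=float(record["depth_m"]),
        group_size=int(record["group_size"]),
        dolphins=frozenset(dolphins),
    )


def load_catalogue(
    path: str | Path, format: str | None = None,
    sightings_path: str | Path | None = None,
) -> Catalogue:
    """Read a catalogue from JSON (list of flat objects) or CSV (UTF-8,
    comma-separated, header row).  ``format`` defaults to the file suffix.
    Row order is preserved.  An optional companion sightings file is loaded
    alongside.
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt not in ("json", "csv"):
        raise ValueError(f"format must be json or csv, got {fmt!r}")
    if fmt == "json":
        records = json.loads(path.read_text(encoding="utf-8"))
    else:
        with path.open(newline="", encoding="utf-8") as fh:
            records = list(csv.DictReader(fh))
    entries = [_entry_from_record(rec, row) for row, rec in enumerate(records)]
    sightings = load_sightings(sightings_path) if sightings_path else None
    return Catalogue(entries=entries, sightings=sightings)


def load_sightings(path: str | Path, format: str | None = None) -> list[SightingRecord]:
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "json":
        records = json.loads(path.read_text(encoding="utf-8"))
    elif fmt == "csv":
        with path.open(newline="", encoding="utf-8") as fh:
            records = list(csv.DictReader(fh))
    else:
        raise ValueError(f"format must be json or csv, got {fmt!r}")
    return [_sighting_from_record(rec, row) for row, rec in enumerate(records)]


def _entry_record(e: CatalogueEntry) -> dict:
    return {
        "dolphin_name": e.dolphin_name,
        "input_image": e.input_image,
        "cropped_fin": e.cropped_fin,
        "observation_date": e.observation_date.isoformat(),
        "gps_lat": repr(e.gps[0]),
        "gps_lon": repr(e.gps[1]),
        "codename": e.codename,
        "side": e.side,
    }


def save_catalogue(catalogue: Catalogue, path: str | Path, format: str | None = None) -> None:
    """Write the catalogue so that :func:`load_catalogue` reproduces it
    field-for-field.  GPS is serialised via ``repr`` (full float precision,
    well beyond 6 decimal places)."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt not in ("json", "csv"):
        raise ValueError(f"format must be json or csv, got {fmt!r}")
    records = [_entry_record(e) for e in catalogue.entries]
    if fmt == "json":
        for rec in records:  # JSON keeps numbers as numbers
            rec["gps_lat"] = float(rec["gps_lat"])
            rec["gps_lon"] = float(rec["gps_lon"])
        path.write_text(json.dumps(records, indent=2), encoding="utf-8")
    else:
        header = ("dolphin_name", "input_image", "cropped_fin", "observation_date",
                  "gps_lat", "gps_lon", "codename", "side")
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=header)
            writer.writeheader()
            writer.writerows(records)


def save_sightings(sightings: Sequence[SightingRecord], path: str | Path,
                   format: str | None = None) -> None:
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    records = [
        {
            "date": s.date.isoformat(),
            "gps_lat": s.gps[0],
            "gps_lon": s.gps[1],
            "depth_m": s.depth_m,
            "group_size": s.group_size,
            "dolphins": ";".join(sorted(s.dolphins)),
        }
        for s in sightings
    ]
    if fmt == "json":
        path.write_text(json.dumps(records, indent=2), encoding="utf-8")
    elif fmt == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=SIGHTING_FIELDS)
            writer.writeheader()
            writer.writerows(records)
    else:
        raise ValueError(f"format must be json or csv, got {fmt!r}")


# --------------------------------------------------------------------------
# Model enrollment
# --------------------------------------------------------------------------


@dataclass
class EnrollmentResult:
    """Models built from a catalogue plus the dolphins that could not be
    enrolled (every candidate image failed the admission gate)."""

    models: list[FinModel]
    unenrollable: dict[str, list[str]]

    @property
    def m(self) -> int:
        """Total model count: one per (dolphin, side) pair with a passing image."""
        return len(self.models)


def _default_loader(base_dir: Path) -> Callable[[str], FinImage]:
    import imageio.v3 as iio

    def load(rel_path: str) -> FinImage:
        arr = iio.imread(base_dir / rel_path)
        if arr.ndim == 2:
            arr = arr[..., None].repeat(3, axis=2)
        return FinImage(pixels=arr[..., :3], source=rel_path)

    return load


def build_fin_models(
    catalogue: Catalogue,
    side_labels: Mapping[str, str] | None = None,
    quality_config: QualityConfig | None = None,
    *,
    backend: FeatureBackend | None = None,
    segmentation_config: SegmentationConfig | None = None,
    base_dir: str | Path = ".",
    image_loader: Callable[[str], FinImage] | None = None,
) -> EnrollmentResult:
    """Enroll exactly one fin model per (dolphin, side) pair with at least one
    image passing the admission gate.

    Among passing candidates the image with the highest sharpness is
    enrolled; sharpness ties break on the lexicographically smallest cropped
    image path, so enrollment is deterministic.  Dolphins whose images all
    fail are reported in ``unenrollable`` with their failure reasons, never
    silently dropped.  ``side_labels`` (cropped_fin path -> left|right)
    overrides the entries' own side column.
    """
    quality_config = quality_config or QualityConfig()
    backend = backend or get_backend()
    loader = image_loader or _default_loader(Path(base_dir))

    best: dict[tuple[str, str], tuple[float, str, FinModel]] = {}
    failures: dict[str, list[str]] = {}
    enrolled_dolphins: set[str] = set()
    for e in catalogue.entries:
        side = (side_labels or {}).get(e.cropped_fin, e.side)
        image = loader(e.cropped_fin)
        try:
            mask = extract_fin_mask(image, segmentation_config)
        except (SegmentationError, DegenerateInputError):
            failures.setdefault(e.dolphin_name, []).append(
                f"{e.cropped_fin}: segmentation")
            continue
        features = detect_features(image, mask, backend)
        ok, reasons = passes_filter(image, mask, len(features), quality_config)
        if not ok:
            failures.setdefault(e.dolphin_name, []).append(
                f"{e.cropped_fin}: {','.join(reasons)}")
            continue
        score = sharpness(image, mask,
                          whole_image=quality_config.whole_image_sharpness).value
        key = (e.dolphin_name, side)
        cand = (score, e.cropped_fin)
        incumbent = best.get(key)
        # highest sharpness wins; ties -> lexicographically smallest path
        if (incumbent is None
                or cand[0] > incumbent[0]
                or (cand[0] == incumbent[0] and cand[1] < incumbent[1])):
            best[key] = (
                score, e.cropped_fin,
                FinModel(dolphin_name=e.dolphin_name, side=side, image=image,
                         features=features, sharpness=score),
            )
        enrolled_dolphins.add(e.dolphin_name)

    models = [v[2] for _, v in sorted(best.items())]
    unenrollable = {name: reasons for name, reasons in failures.items()
                    if name not in enrolled_dolphins}
    return EnrollmentResult(models=models, unenrollable=unenrollable)
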