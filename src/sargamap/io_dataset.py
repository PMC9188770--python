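"""Dataset plumbing: images, 3-class masks, geotags, manifests, and splits.

The segmentation works with three land-cover classes — Sargassum (the
stranded brown macroalgae), Sand, and Other (sky, sea, vegetation,
people, ...). Masks are stored as palette-colored PNGs; the canonical
palette is brown / yellow / gray and can be overridden wherever a
``palette`` argument is accepted, as long as it stays a bijection
between the three labels and three distinct RGB colors.
"""

from __future__ import annotations

import csv
import enum
import logging
import math
from dataclasses import dataclass, field
from datetime import datetime
from fractions import Fraction
from pathlib import Path

import numpy as np
from PIL import Image, ExifTags, UnidentifiedImageError

logger = logging.getLogger("sargamap")

__all__ = [
    "Label",
    "DEFAULT_PALETTE",
    "CLASS_ORDER",
    "LabelMask",
    "ImagePair",
    "GeoPhotoRecord",
    "DatasetSplit",
    "MISSING",
    "DimensionMismatchError",
    "PaletteError",
    "GeotagParseError",
    "read_pair",
    "read_pair_concat",
    "read_geotag",
    "write_geotag",
    "read_sidecar",
    "split_dataset",
    "write_manifest",
    "read_manifest",
    "save_mask",
    "load_mask",
    "save_rgb",
    "load_rgb",
]


class Label(enum.IntEnum):
    """Pixel classes of the beach-scene segmentation."""

    SARGASSUM = 0
    SAND = 1
    OTHER = 2


#: Canonical mask palette: brown Sargassum, yellow sand, gray everything else.
DEFAULT_PALETTE: dict[Label, tuple[int, int, int]] = {
    Label.SARGASSUM: (123, 63, 0),
    Label.SAND: (255, 221, 0),
    Label.OTHER: (128, 128, 128),
}

#: Row order used by metric reports (matches the evaluation-table layout).
CLASS_ORDER: tuple[Label, ...] = (Label.SARGASSUM, Label.OTHER, Label.SAND)


class DimensionMismatchError(ValueError):
    """Image and mask (or truth and prediction) dimensions disagree."""


class PaletteError(ValueError):
    """A mask contains colors not attributable to any palette entry."""


class GeotagParseError(ValueError):
    """EXIF is present but its GPS block cannot be decoded."""


#: Sentinel distinguishing "no GPS block" from a decoding failure.
MISSING = None


def _validate_palette(palette: dict[Label, tuple[int, int, int]]) -> None:
    if set(palette) != set(Label):
        raise PaletteError("palette must map exactly the three labels")
    colors = list(palette.values())
    if len({tuple(c) for c in colors}) != 3:
        raise PaletteError("palette colors must be distinct")


@dataclass
class LabelMask:
    """A 2-D grid of class labels plus the palette that renders it.

    ``labels`` is an ``(H, W)`` uint8 array of :class:`Label` values.
    """

    labels: np.ndarray
    palette: dict[Label, tuple[int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_PALETTE)
    )

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D grid")
        if self.labels.size and self.labels.max() > max(Label):
            raise ValueError("labels contain values outside the three classes")
        _validate_palette(self.palette)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def counts(self) -> dict[Label, int]:
        binc = np.bincount(self.labels.ravel(), minlength=3)
        return {lab: int(binc[lab]) for lab in Label}

    def fractions(self) -> dict[Label, float]:
        n = self.labels.size
        return {lab: c / n for lab, c in self.counts().items()}

    def to_rgb(self) -> np.ndarray:
        """Render the mask as its palette-colored RGB image (H, W, 3 uint8)."""
        lut = np.zeros((3, 3), dtype=np.uint8)
        for lab, color in self.palette.items():
            lut[lab] = color
        return lut[self.labels]

    @classmethod
    def from_rgb(
        cls,
        rgb: np.ndarray,
        palette: dict[Label, tuple[int, int, int]] | None = None,
        tolerance: int = 8,
    ) -> "LabelMask":
        """Map an RGB rendering back to labels by nearest palette color.

        A pixel whose per-channel max distance to *every* palette color
        exceeds ``tolerance`` is unmappable and raises :class:`PaletteError`
        naming the most frequent offending color.
        """
        palette = dict(DEFAULT_PALETTE) if palette is None else dict(palette)
        _validate_palette(palette)
        rgb = np.asarray(rgb)
        if rgb.ndim != 3 or rgb.shape[2] != 3:
            raise ValueError("expected an (H, W, 3) RGB array")
        pix = rgb.reshape(-1, 3).astype(np.int32)
        labs = sorted(palette)
        colors = np.array([palette[lab] for lab in labs], dtype=np.int32)
        diff = pix[:, None, :] - colors[None, :, :]          # (N, 3, 3)
        cheby = np.abs(diff).max(axis=2)
        sq = (diff * diff).sum(axis=2)
        nearest = sq.argmin(axis=1)
        bad = cheby.min(axis=1) > tolerance
        if bad.any():
            bad_colors, counts = np.unique(pix[bad], axis=0, return_counts=True)
            worst = bad_colors[counts.argmax()]
            raise PaletteError(
                f"{int(bad.sum())} mask pixel(s) not within tolerance {tolerance} "
                f"of any palette color; most frequent offender RGB{tuple(int(v) for v in worst)}"
            )
        labels = np.array([int(labs[i]) for i in range(len(labs))], dtype=np.uint8)[
            nearest
        ].reshape(rgb.shape[:2])
        return cls(labels=labels, palette=palette)


@dataclass
class ImagePair:
    """An RGB beach photograph aligned with its ground-truth mask."""

    image_id: str
    rgb: np.ndarray
    mask: LabelMask
    source_path: Path | None = None

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb, dtype=np.uint8)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError("rgb must be (H, W, 3)")
        if self.rgb.shape[:2] != self.mask.shape:
            raise DimensionMismatchError(
                f"rgb {self.rgb.shape[:2]} vs mask {self.mask.shape}"
            )
        h, w = self.mask.shape
        if h < 8 or w < 8:
            raise ValueError("images must be at least 8x8")


@dataclass
class GeoPhotoRecord:
    """One geotagged photograph with its estimated Sargassum coverage.

    ``coverage_pct`` is a percentage in [0, 100] or ``None`` when the
    photograph gives no usable beach pixels (the undefined case).
    """

    image_id: str
    latitude: float
    longitude: float
    timestamp: datetime | None = None
    coverage_pct: float | None = None

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude} outside [-180, 180]")
        if self.coverage_pct is not None and not 0.0 <= self.coverage_pct <= 100.0:
            raise ValueError(f"coverage_pct {self.coverage_pct} outside [0, 100]")


@dataclass
class DatasetSplit:
    """A random train/validation partition of image ids."""

    train_ids: list[str]
    validation_ids: list[str]
    seed: int


# ---------------------------------------------------------------------------
# Paired-image IO


def load_rgb(path: Path | str) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def save_rgb(rgb: np.ndarray, path: Path | str) -> Path:
    path = Path(path)
    Image.fromarray(np.asarray(rgb, dtype=np.uint8), "RGB").save(path)
    return path


def save_mask(mask: LabelMask, path: Path | str) -> Path:
    """Write a mask as a lossless palette-colored PNG."""
    path = Path(path)
    if path.suffix.lower() != ".png":
        raise ValueError("masks are always written as PNG (lossless)")
    Image.fromarray(mask.to_rgb(), "RGB").save(path, format="PNG")
    return path


def load_mask(
    path: Path | str,
    palette: dict[Label, tuple[int, int, int]] | None = None,
    tolerance: int = 8,
) -> LabelMask:
    return LabelMask.from_rgb(load_rgb(path), palette=palette, tolerance=tolerance)


def read_pair(
    rgb_path: Path | str,
    mask_path: Path | str,
    palette: dict[Label, tuple[int, int, int]] | None = None,
    tolerance: int = 8,
) -> ImagePair:
    """Read a photograph and its mask from the parallel-directory layout."""
    rgb = load_rgb(rgb_path)
    mask_rgb = load_rgb(mask_path)
    if rgb.shape[:2] != mask_rgb.shape[:2]:
        raise DimensionMismatchError(
            f"image {rgb.shape[:2]} vs mask {mask_rgb.shape[:2]}"
        )
    mask = LabelMask.from_rgb(mask_rgb, palette=palette, tolerance=tolerance)
    return ImagePair(
        image_id=Path(rgb_path).stem, rgb=rgb, mask=mask, source_path=Path(rgb_path)
    )


def read_pair_concat(
    path: Path | str,
    palette: dict[Label, tuple[int, int, int]] | None = None,
    tolerance: int = 8,
) -> ImagePair:
    """Read a side-by-side concatenated pair (RGB | mask in one file)."""
    both = load_rgb(path)
    h, w = both.shape[:2]
    if w % 2:
        raise DimensionMismatchError(f"concatenated width {w} is odd")
    rgb, mask_rgb = both[:, : w // 2], both[:, w // 2 :]
    mask = LabelMask.from_rgb(mask_rgb, palette=palette, tolerance=tolerance)
    return ImagePair(
        image_id=Path(path).stem, rgb=rgb, mask=mask, source_path=Path(path)
    )


# ---------------------------------------------------------------------------
# Geotags

_EXIF_DT = "%Y:%m:%d %H:%M:%S"


def _dms_to_degrees(dms, ref: str) -> float:
    deg, minute, sec = (float(v) for v in dms)
    val = deg + minute / 60.0 + sec / 3600.0
    if ref in ("S", "W"):
        val = -val
    return val


def _degrees_to_dms(value: float) -> tuple[Fraction, Fraction, Fraction]:
    value = abs(value)
    deg = math.floor(value)
    rem = (value - deg) * 60
    minute = math.floor(rem)
    sec = (rem - minute) * 60
    return (
        Fraction(deg),
        Fraction(minute),
        Fraction(round(sec * 1_000_000), 1_000_000),
    )


def read_geotag(
    image_path: Path | str,
) -> tuple[float, float, datetime | None] | None:
    """Decode EXIF GPS to WGS84 decimal degrees.

    Returns ``(latitude, longitude, timestamp-or-None)`` or :data:`MISSING`
    when the file carries no GPS block. A GPS block that is present but
    undecodable raises :class:`GeotagParseError` — a distinct condition.
    """
    try:
        with Image.open(image_path) as im:
            exif = im.getexif()
    except (UnidentifiedImageError, OSError) as exc:
        raise GeotagParseError(f"cannot open {image_path}: {exc}") from exc
    gps = exif.get_ifd(ExifTags.IFD.GPSInfo)
    if not gps:
        return MISSING
    try:
        lat = _dms_to_degrees(gps[2], gps.get(1, "N"))
        lon = _dms_to_degrees(gps[4], gps.get(3, "E"))
    except (KeyError, TypeError, ValueError, ZeroDivisionError) as exc:
        raise GeotagParseError(f"corrupt GPS block in {image_path}: {exc}") from exc
    ts_raw = exif.get(ExifTags.Base.DateTimeOriginal) or exif.get_ifd(
        ExifTags.IFD.Exif
    ).get(ExifTags.Base.DateTimeOriginal)
    ts = None
    if ts_raw:
        try:
            ts = datetime.strptime(str(ts_raw), _EXIF_DT)
        except ValueError:
            ts = None
    return lat, lon, ts


def write_geotag(
    rgb: np.ndarray,
    path: Path | str,
    latitude: float,
    longitude: float,
    timestamp: datetime | None = None,
) -> Path:
    """Save an RGB image with an EXIF GPS block (used by the scene generator)."""
    path = Path(path)
    exif = Image.Exif()
    exif[ExifTags.IFD.GPSInfo] = {
        1: "N" if latitude >= 0 else "S",
        2: _degrees_to_dms(latitude),
        3: "E" if longitude >= 0 else "W",
        4: _degrees_to_dms(longitude),
    }
    if timestamp is not None:
        exif[ExifTags.Base.DateTimeOriginal] = timestamp.strftime(_EXIF_DT)
    Image.fromarray(np.asarray(rgb, dtype=np.uint8), "RGB").save(path, exif=exif)
    return path


def read_sidecar(path: Path | str) -> dict[str, tuple[float, float, datetime | None]]:
    """Read a sidecar CSV of geotags keyed by image_id.

    Columns: ``image_id, latitude, longitude[, timestamp]``. EXIF wins over
    the sidecar on conflict (the caller handles precedence; a warning is
    logged there).
    """
    out: dict[str, tuple[float, float, datetime | None]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            ts = None
            if row.get("timestamp"):
                ts = datetime.fromisoformat(row["timestamp"])
            out[row["image_id"]] = (
                float(row["latitude"]),
                float(row["longitude"]),
                ts,
            )
    return out


# ---------------------------------------------------------------------------
# Splits and manifests


def split_dataset(ids: list[str], n_train: int, seed: int) -> DatasetSplit:
    """Uniform random train/validation split without replacement.

    Deterministic for a fixed seed; the remainder after drawing ``n_train``
    ids becomes the validation set.
    """
    if n_train > len(ids):
        raise ValueError(f"n_train={n_train} exceeds dataset size {len(ids)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    train = [ids[i] for i in sorted(perm[:n_train])]
    val = [ids[i] for i in sorted(perm[n_train:])]
    return DatasetSplit(train_ids=train, validation_ids=val, seed=seed)


_MANIFEST_COLUMNS = ["image_id", "latitude", "longitude", "timestamp", "coverage_pct"]


def write_manifest(records: list[GeoPhotoRecord], path: Path | str) -> Path:
    """Write the photo manifest CSV (undefined coverage → empty cell)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_MANIFEST_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.image_id,
                    repr(r.latitude),
                    repr(r.longitude),
                    r.timestamp.isoformat() if r.timestamp else "",
                    "" if r.coverage_pct is None else repr(float(r.coverage_pct)),
                ]
            )
    return path


def read_manifest(path: Path | str) -> list[GeoPhotoRecord]:
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(
                GeoPhotoRecord(
                    image_id=row["image_id"],
                    latitude=float(row["latitude"]),
                    longitude=float(row["longitude"]),
                    timestamp=(
                        datetime.fromisoformat(row["timestamp"])
                        if row.get("timestamp")
                        else None
                    ),
                    coverage_pct=(
                        float(row["coverage_pct"]) if row.get("coverage_pct") else None
                    ),
                )
            )
    return records
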