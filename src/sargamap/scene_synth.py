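"""Synthetic paired beach scenes and synthetic geotagged photo sets.

Real inputs are crowdsourced beach photographs with hand-painted
three-class masks. This module emulates their two essential features at
desk scale so the whole pipeline (training, evaluation, mapping) can run
without any download:

* scenes are horizontal bands — sky/sea (Other) on top, a Sargassum
  wrack line in the middle, Sand at the bottom — with smooth random band
  boundaries and band-limited color texture; the band composition gives
  the translator a learnable spatial prior, like the framing the real
  photo-selection protocol favored;
* photo sets are points scattered along a straight stretch of coast with
  a position-dependent mean coverage profile plus observation noise.

It makes no attempt at photorealism: no water transparency, shadows, or
mixed textures (the known failure modes of the real imagery).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Callable

import numpy as np
from scipy.ndimage import gaussian_filter1d, gaussian_filter

from .io_dataset import (
    DEFAULT_PALETTE,
    GeoPhotoRecord,
    ImagePair,
    Label,
    LabelMask,
    save_mask,
    write_geotag,
    write_manifest,
)

__all__ = ["SceneSpec", "CoastSpec", "make_scene", "make_coast", "emit_dataset"]

EARTH_RADIUS_M = 6_371_000.0


@dataclass
class SceneSpec:
    """Parameters of one synthetic beach scene.

    ``sargassum_fraction`` and ``sand_fraction`` are requested label
    proportions (the remainder is Other); the realized mask matches them
    to within 0.03. ``texture_scale`` controls the smoothness of band
    boundaries and of the color texture, in pixels. ``color_jitter_sd``
    is the texture-noise standard deviation in 8-bit units.
    """

    height: int = 256
    width: int = 256
    sargassum_fraction: float = 0.3
    sand_fraction: float = 0.3
    texture_scale: float = 16.0
    color_jitter_sd: float = 8.0
    seed: int = 0
    palette: dict[Label, tuple[int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_PALETTE)
    )

    def __post_init__(self) -> None:
        for frac in (self.sargassum_fraction, self.sand_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction {frac} outside [0, 1]")
        if self.sargassum_fraction + self.sand_fraction > 1.0 + 1e-12:
            raise ValueError("sargassum_fraction + sand_fraction exceeds 1")
        if self.height % 8 or self.width % 8:
            raise ValueError("height and width must be divisible by 8")


@dataclass
class CoastSpec:
    """Parameters of a synthetic geotagged photo set along a coastline.

    Photos are spread evenly along a ``length_m``-meter great-circle
    segment starting at (``origin_lat``, ``origin_lon``) with the given
    compass ``bearing``; ``coverage_profile`` maps the relative position
    in [0, 1] to a mean coverage percentage, to which Gaussian noise of
    ``noise_sd`` percentage points is added and clamped to [0, 100].
    """

    origin_lat: float = 18.715693
    origin_lon: float = -87.708009
    bearing: float = 0.0
    length_m: float = 600.0
    n_photos: int = 20
    coverage_profile: Callable[[float], float] = lambda t: 50.0
    noise_sd: float = 5.0
    lateral_jitter_m: float = 3.0
    seed: int = 0
    start_time: datetime | None = None
    end_time: datetime | None = None

    def __post_init__(self) -> None:
        if self.n_photos < 1:
            raise ValueError("n_photos must be >= 1")
        if self.length_m <= 0:
            raise ValueError("length_m must be positive")


def _smooth_boundary(rng, width: int, scale: float, amplitude: float) -> np.ndarray:
    """Zero-mean smooth random curve: Gaussian noise low-passed at `scale`."""
    raw = rng.standard_normal(width)
    sm = gaussian_filter1d(raw, sigma=max(scale, 1.0), mode="wrap")
    sd = sm.std()
    if sd < 1e-12:
        return np.zeros(width)
    sm = sm / sd * amplitude
    return sm - sm.mean()


def make_scene(spec: SceneSpec) -> ImagePair:
    """Generate one paired scene (RGB photograph + ground-truth mask).

    Deterministic per ``spec.seed``. With ``color_jitter_sd`` = 0 every
    RGB pixel is exactly its label's palette color.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    f_sarg, f_sand = spec.sargassum_fraction, spec.sand_fraction
    f_other = 1.0 - f_sarg - f_sand

    # Band boundaries measured in rows from the top; zero-mean wiggles keep
    # column-averaged fractions equal to the request, so only clipping and
    # per-column rounding can move realized fractions. Shrink the wiggle
    # amplitude until the 0.03 contract holds (extreme fractions leave no
    # headroom for wiggles).
    amplitude = min(spec.texture_scale, h / 8)
    for _ in range(8):
        b1 = f_other * h + _smooth_boundary(rng, w, spec.texture_scale, amplitude)
        b2 = (f_other + f_sarg) * h + _smooth_boundary(
            rng, w, spec.texture_scale, amplitude
        )
        # absent bands get exact boundaries, not wiggled ones
        if f_other == 0:
            b1[:] = 0.0
        if f_sand == 0:
            b2[:] = h
        b1 = np.clip(b1, 0, h)
        b2 = np.clip(np.maximum(b2, b1), 0, h)
        if f_sarg == 0:
            b1 = b2.copy()
        rows = np.arange(h)[:, None]
        labels = np.full((h, w), int(Label.OTHER), dtype=np.uint8)
        labels[(rows >= np.round(b1)[None, :]) & (rows < np.round(b2)[None, :])] = int(
            Label.SARGASSUM
        )
        labels[rows >= np.round(b2)[None, :]] = int(Label.SAND)
        binc = np.bincount(labels.ravel(), minlength=3) / (h * w)
        if (
            abs(binc[Label.SARGASSUM] - f_sarg) <= 0.03
            and abs(binc[Label.SAND] - f_sand) <= 0.03
        ):
            break
        amplitude /= 2.0
    mask = LabelMask(labels=labels, palette=dict(spec.palette))

    rgb = mask.to_rgb().astype(np.float64)
    if spec.color_jitter_sd > 0:
        noise = rng.standard_normal((h, w, 3))
        noise = gaussian_filter(
            noise, sigma=(spec.texture_scale / 4, spec.texture_scale / 4, 0)
        )
        sd = noise.std(axis=(0, 1), keepdims=True)
        sd[sd < 1e-12] = 1.0
        rgb = rgb + noise / sd * spec.color_jitter_sd
    rgb = np.clip(np.round(rgb), 0, 255).astype(np.uint8)

    return ImagePair(image_id=f"scene_{spec.seed:06d}", rgb=rgb, mask=mask)


def _destination(
    lat: float, lon: float, bearing_deg: float, distance_m: float
) -> tuple[float, float]:
    """Great-circle destination point (spherical direct problem)."""
    phi1 = np.radians(lat)
    lam1 = np.radians(lon)
    theta = np.radians(bearing_deg)
    delta = distance_m / EARTH_RADIUS_M
    phi2 = np.arcsin(
        np.sin(phi1) * np.cos(delta) + np.cos(phi1) * np.sin(delta) * np.cos(theta)
    )
    lam2 = lam1 + np.arctan2(
        np.sin(theta) * np.sin(delta) * np.cos(phi1),
        np.cos(delta) - np.sin(phi1) * np.sin(phi2),
    )
    return float(np.degrees(phi2)), float(np.degrees(lam2))


def make_coast(spec: CoastSpec) -> list[GeoPhotoRecord]:
    """Scatter ``n_photos`` geotagged records along the coast segment.

    Positions are evenly spaced over [0, 1] (a single photo sits at the
    origin); deterministic per ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_photos
    positions = np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.0])
    records = []
    for i, t in enumerate(positions):
        lat, lon = _destination(
            spec.origin_lat, spec.origin_lon, spec.bearing, t * spec.length_m
        )
        if spec.lateral_jitter_m > 0:
            lat, lon = _destination(
                lat,
                lon,
                spec.bearing + 90.0,
                float(rng.normal(0.0, spec.lateral_jitter_m)),
            )
        cov = spec.coverage_profile(float(t)) + float(rng.normal(0.0, spec.noise_sd))
        ts = None
        if spec.start_time is not None:
            if spec.end_time is not None and n > 1:
                ts = spec.start_time + timedelta(
                    seconds=t * (spec.end_time - spec.start_time).total_seconds()
                )
            else:
                ts = spec.start_time
        records.append(
            GeoPhotoRecord(
                image_id=f"photo_{i:04d}",
                latitude=lat,
                longitude=lon,
                timestamp=ts,
                coverage_pct=float(np.clip(cov, 0.0, 100.0)),
            )
        )
    return records


def emit_dataset(
    out_dir: Path | str,
    n_pairs: int,
    scene: SceneSpec | None = None,
    coast: CoastSpec | None = None,
    seed: int = 0,
) -> Path:
    """Write a complete synthetic project: images/, masks/, manifest.csv.

    Each pair reuses ``scene`` with per-pair seeds derived from ``seed``
    and randomized class fractions; geotags come from ``coast`` (resized
    to ``n_pairs`` photos) and are embedded as EXIF in the JPEG images.
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    scene = scene or SceneSpec()
    coast = coast or CoastSpec()
    master = np.random.default_rng(seed)
    records = make_coast(
        CoastSpec(
            origin_lat=coast.origin_lat,
            origin_lon=coast.origin_lon,
            bearing=coast.bearing,
            length_m=coast.length_m,
            n_photos=n_pairs,
            coverage_profile=coast.coverage_profile,
            noise_sd=coast.noise_sd,
            lateral_jitter_m=coast.lateral_jitter_m,
            seed=seed,
            start_time=coast.start_time,
            end_time=coast.end_time,
        )
    )
    out_records = []
    for i, rec in enumerate(records):
        f_sarg = float(master.uniform(0.05, 0.55))
        f_sand = float(master.uniform(0.05, min(0.55, 0.95 - f_sarg)))
        pair = make_scene(
            SceneSpec(
                height=scene.height,
                width=scene.width,
                sargassum_fraction=f_sarg,
                sand_fraction=f_sand,
                texture_scale=scene.texture_scale,
                color_jitter_sd=scene.color_jitter_sd,
                seed=int(master.integers(0, 2**31 - 1)),
                palette=dict(scene.palette),
            )
        )
        image_id = f"img_{i:04d}"
        write_geotag(
            pair.rgb,
            out_dir / "images" / f"{image_id}.jpg",
            rec.latitude,
            rec.longitude,
            rec.timestamp,
        )
        save_mask(pair.mask, out_dir / "masks" / f"{image_id}.png")
        out_records.append(
            GeoPhotoRecord(
                image_id=image_id,
                latitude=rec.latitude,
                longitude=rec.longitude,
                timestamp=rec.timestamp,
                coverage_pct=rec.coverage_pct,
            )
        )
    write_manifest(out_records, out_dir / "manifest.csv")
    return out_dir
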