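"""Green pixel intensity (GPI) extraction from annotated photographs.

The colorimetric response variable of the assay is the green pixel intensity

    GPI = G / (R + G + B)

of an 8-bit RGB pixel, a dimensionless fraction in (0, 1].  A culture
photographed against a white background is characterised by the mean GPI of
three culture pixels (at least one from the shadowed and one from the lit
part of the vessel) minus the mean GPI of six background pixels (three from
the white paper on each side of the vessel):

    GPI_sample = GPI_culture - GPI_background

Each sample is photographed in triplicate, and on every sampling day a
media-only baseline vessel is photographed the same way.  The final reading

    GPI_final = mean(GPI_sample over 3 photos) - mean(GPI_baseline over 3 photos)

is what enters the calibration curve.  Negative values are retained, not
clipped: blank-replicate distributions must stay unbiased for the limit of
blank to be meaningful.

Pixel selection is seeded, stratified random sampling from the annotated
regions (the lab protocol picks pixels by hand with a color picker; random
sampling with a recorded seed reproduces the 3 + 6 counts and the
shadow/lit stratification while staying deterministic).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image

from .errors import AnnotationError, GeometryError, InvalidPixelError, ValidationError

__all__ = [
    "PixelRGB",
    "PhotoAnnotation",
    "GpiReading",
    "SampleGpi",
    "green_pixel_intensity",
    "load_image",
    "region_coordinates",
    "sample_region_pixels",
    "gpi_of_photo",
    "gpi_final",
    "analyze_photoset",
]

# A region is either a half-open rectangle [row0, col0, row1, col1] or an
# explicit list of [row, col] pixels; coordinates are 0-based.
Region = Sequence


@dataclass(frozen=True)
class PixelRGB:
    """One 8-bit color triple, optionally tagged with its image coordinate."""

    r: int
    g: int
    b: int
    row: int | None = None
    col: int | None = None

    def __post_init__(self) -> None:
        for name in ("r", "g", "b"):
            v = getattr(self, name)
            if not (0 <= int(v) <= 255):
                raise ValidationError(f"channel {name}={v} outside [0, 255]")


def green_pixel_intensity(pixel: PixelRGB) -> float:
    """G / (R + G + B) for one pixel; in (0, 1].

    Achromatic pixels give exactly 1/3 and the ratio is invariant under
    uniform channel scaling.  A pure-black pixel carries no color
    information and is rejected.
    """
    total = int(pixel.r) + int(pixel.g) + int(pixel.b)
    if total == 0:
        where = (
            f" at (row={pixel.row}, col={pixel.col})"
            if pixel.row is not None
            else ""
        )
        raise InvalidPixelError(f"black pixel (R=G=B=0){where}: GPI undefined")
    return int(pixel.g) / total


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG photograph as an (H, W, 3) uint8 array.

    Alpha channels are composited over white (the assay photographs cultures
    against a white background); deeper-than-8-bit images are rescaled to
    8 bits.
    """
    with Image.open(path) as img:
        if img.mode in ("I", "I;16", "I;16B", "I;16L"):
            arr = np.asarray(img, dtype=np.float64)
            arr = np.clip(arr / 257.0, 0, 255).round().astype(np.uint8)
            img = Image.fromarray(arr)
        if img.mode == "P":
            img = img.convert("RGBA")
        if img.mode in ("RGBA", "LA"):
            white = Image.new("RGBA", img.size, (255, 255, 255, 255))
            img = Image.alpha_composite(white, img.convert("RGBA"))
        return np.asarray(img.convert("RGB"), dtype=np.uint8)


def region_coordinates(region: Region, shape: tuple[int, int]) -> np.ndarray:
    """Expand a region spec into an (k, 2) array of (row, col) coordinates."""
    region = list(region)
    if len(region) == 4 and all(np.isscalar(v) for v in region):
        r0, c0, r1, c1 = (int(v) for v in region)
        if r1 <= r0 or c1 <= c0:
            raise AnnotationError(f"empty rectangle {region}")
        if r0 < 0 or c0 < 0 or r1 > shape[0] or c1 > shape[1]:
            raise GeometryError(
                f"rectangle {region} outside image of shape {shape}"
            )
        rows, cols = np.mgrid[r0:r1, c0:c1]
        return np.column_stack([rows.ravel(), cols.ravel()])
    coords = np.asarray(region, dtype=int)
    if coords.ndim != 2 or coords.shape[1] != 2 or coords.shape[0] == 0:
        raise AnnotationError(f"region must be a rectangle or pixel list, got {region!r}")
    if (
        coords.min() < 0
        or coords[:, 0].max() >= shape[0]
        or coords[:, 1].max() >= shape[1]
    ):
        raise GeometryError(f"pixel list extends outside image of shape {shape}")
    return coords


@dataclass
class PhotoAnnotation:
    """Pixel-selection regions for one photograph.

    ``role`` is ``"sample"`` for culture vessels and ``"baseline"`` for the
    media-only vessel photographed each sampling day.  Regions are 0-based
    half-open rectangles ``[row0, col0, row1, col1]`` or explicit pixel
    lists, and must be pairwise disjoint.
    """

    image_path: str | Path | None
    culture_shadow_region: Region
    culture_lit_region: Region
    background_left_region: Region
    background_right_region: Region
    role: str = "sample"
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        if self.role not in ("sample", "baseline"):
            raise AnnotationError(f"role must be 'sample' or 'baseline', got {self.role!r}")

    def regions(self) -> dict[str, Region]:
        return {
            "culture_shadow": self.culture_shadow_region,
            "culture_lit": self.culture_lit_region,
            "background_left": self.background_left_region,
            "background_right": self.background_right_region,
        }

    def validate(self, shape: tuple[int, int]) -> dict[str, np.ndarray]:
        """Expand all regions, checking bounds and pairwise disjointness."""
        coords = {
            name: region_coordinates(region, shape)
            for name, region in self.regions().items()
        }
        seen: dict[tuple[int, int], str] = {}
        for name, arr in coords.items():
            for rc in map(tuple, arr):
                if rc in seen:
                    raise AnnotationError(
                        f"regions {seen[rc]!r} and {name!r} overlap at pixel {rc}"
                    )
                seen[rc] = name
        return coords

    def to_json(self, path: str | Path) -> None:
        doc = {
            "image": str(self.image_path),
            "role": self.role,
            "sample_id": self.sample_id,
            "regions": {k: list(map(_as_jsonable, v)) for k, v in self.regions().items()},
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PhotoAnnotation":
        try:
            doc = json.loads(Path(path).read_text())
            regions = doc["regions"]
            return cls(
                image_path=doc["image"],
                culture_shadow_region=regions["culture_shadow"],
                culture_lit_region=regions["culture_lit"],
                background_left_region=regions["background_left"],
                background_right_region=regions["background_right"],
                role=doc.get("role", "sample"),
                sample_id=str(doc.get("sample_id", "sample")),
            )
        except (KeyError, json.JSONDecodeError) as exc:
            raise AnnotationError(f"malformed annotation {path}: {exc}") from exc


def _as_jsonable(v):
    if np.isscalar(v):
        return int(v)
    return [int(x) for x in v]


@dataclass(frozen=True)
class GpiReading:
    """Background-corrected GPI of one photograph."""

    gpi_culture: float
    gpi_background: float
    gpi_sample: float
    photo_index: int = 1


@dataclass
class SampleGpi:
    """Triplicate-photo, baseline-corrected GPI of one sample."""

    sample_id: str
    gpi_final: float
    per_photo_gpi: list[GpiReading] = field(default_factory=list)
    baseline_mean: float = 0.0


def _draw(rng: np.random.Generator, coords: np.ndarray, k: int, name: str) -> np.ndarray:
    if len(coords) < k:
        raise AnnotationError(
            f"region {name!r} has {len(coords)} pixels; {k} required"
        )
    idx = rng.choice(len(coords), size=k, replace=False)
    return coords[idx]


def sample_region_pixels(
    image: np.ndarray,
    annotation: PhotoAnnotation,
    seed: int | np.random.Generator,
) -> tuple[list[PixelRGB], list[PixelRGB]]:
    """Draw 3 culture and 6 background pixels from the annotated regions.

    Culture pixels are stratified over the shadowed and lit regions (two
    from the larger region, one from the smaller; ties favor the lit
    region).  Background pixels are three from each side.  Selection is
    deterministic given the seed.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] < 3:
        raise ValidationError(f"expected an (H, W, 3) RGB image, got shape {image.shape}")
    coords = annotation.validate(image.shape[:2])
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    shadow, lit = coords["culture_shadow"], coords["culture_lit"]
    n_shadow = 2 if len(shadow) > len(lit) else 1
    picks = np.vstack(
        [
            _draw(rng, shadow, n_shadow, "culture_shadow"),
            _draw(rng, lit, 3 - n_shadow, "culture_lit"),
        ]
    )
    bg = np.vstack(
        [
            _draw(rng, coords["background_left"], 3, "background_left"),
            _draw(rng, coords["background_right"], 3, "background_right"),
        ]
    )

    def to_pixels(sel: np.ndarray) -> list[PixelRGB]:
        return [
            PixelRGB(*(int(c) for c in image[r, ccol, :3]), row=int(r), col=int(ccol))
            for r, ccol in sel
        ]

    return to_pixels(picks), to_pixels(bg)


def gpi_of_photo(
    culture_pixels: Sequence[PixelRGB],
    background_pixels: Sequence[PixelRGB],
    photo_index: int = 1,
) -> GpiReading:
    """Mean culture GPI minus mean background GPI for one photograph.

    Requires exactly 3 culture and 6 background pixels.  For a baseline
    photograph the "culture" pixels are drawn from the media region; the
    arithmetic is identical.
    """
    if len(culture_pixels) != 3:
        raise ValidationError(f"expected 3 culture pixels, got {len(culture_pixels)}")
    if len(background_pixels) != 6:
        raise ValidationError(f"expected 6 background pixels, got {len(background_pixels)}")
    gpi_culture = float(np.mean([green_pixel_intensity(p) for p in culture_pixels]))
    gpi_background = float(np.mean([green_pixel_intensity(p) for p in background_pixels]))
    return GpiReading(
        gpi_culture=gpi_culture,
        gpi_background=gpi_background,
        gpi_sample=gpi_culture - gpi_background,
        photo_index=photo_index,
    )


def gpi_final(
    sample_readings: Sequence[GpiReading],
    baseline_readings: Sequence[GpiReading],
    sample_id: str = "sample",
) -> SampleGpi:
    """Triplicate mean of GPI_sample minus triplicate mean of GPI_baseline."""
    if len(sample_readings) != 3:
        raise ValidationError(f"expected 3 sample photographs, got {len(sample_readings)}")
    if len(baseline_readings) != 3:
        raise ValidationError(f"expected 3 baseline photographs, got {len(baseline_readings)}")
    baseline_mean = float(np.mean([r.gpi_sample for r in baseline_readings]))
    mean_sample = float(np.mean([r.gpi_sample for r in sample_readings]))
    return SampleGpi(
        sample_id=sample_id,
        gpi_final=mean_sample - baseline_mean,
        per_photo_gpi=list(sample_readings),
        baseline_mean=baseline_mean,
    )


def _readings_for(
    annotations: Sequence[PhotoAnnotation],
    seeds: Iterable[np.random.SeedSequence],
    images: Sequence[np.ndarray] | None,
) -> list[GpiReading]:
    readings = []
    for i, (ann, ss) in enumerate(zip(annotations, seeds), start=1):
        image = images[i - 1] if images is not None else load_image(ann.image_path)
        culture, background = sample_region_pixels(
            image, ann, np.random.default_rng(ss)
        )
        readings.append(gpi_of_photo(culture, background, photo_index=i))
    return readings


def analyze_photoset(
    sample_annotations: Sequence[PhotoAnnotation],
    baseline_annotations: Sequence[PhotoAnnotation],
    seed: int,
    sample_id: str = "sample",
    sample_images: Sequence[np.ndarray] | None = None,
    baseline_images: Sequence[np.ndarray] | None = None,
) -> SampleGpi:
    """Run the full per-sample pipeline: 3 sample + 3 baseline photographs.

    Images are loaded from each annotation's ``image_path`` unless arrays
    are supplied directly.  Each photograph gets an independent child seed
    derived deterministically from ``seed``.
    """
    if len(sample_annotations) != 3 or len(baseline_annotations) != 3:
        raise ValidationError("exactly 3 sample and 3 baseline photographs are required")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    for ann in sample_annotations:
        if ann.role != "sample":
            raise AnnotationError(f"annotation for {ann.image_path} has role {ann.role!r}")
    for ann in baseline_annotations:
        if ann.role != "baseline":
            raise AnnotationError(f"annotation for {ann.image_path} has role {ann.role!r}")
    seeds = ss.spawn(6)
    sample_readings = _readings_for(sample_annotations, seeds[:3], sample_images)
    baseline_readings = _readings_for(baseline_annotations, seeds[3:], baseline_images)
    return gpi_final(sample_readings, baseline_readings, sample_id=sample_id)
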