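"""Reading, writing and basic conversion of section images and ROI polygons.

Conventions used throughout the package:

* pixel coordinates are 0-based ``(x, y)`` with *x* to the right and *y*
  down; a pixel ``(col, row)`` has its centre at ``(col + 0.5, row + 0.5)``;
* a rasterised polygon mask contains a pixel iff the pixel *centre* lies
  inside the polygon (even-odd rule), so an axis-aligned rectangle with
  integer vertices covers exactly ``width * height`` pixels;
* acquisition-range (16-bit) images are mapped to the 8-bit analysis range
  by fixed nominal-range scaling, not per-image min-max, so that preset
  thresholds stay comparable across sections.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import shapely
import tifffile
from shapely.geometry import Polygon

CHANNEL_ROLES = (
    "cci103f",
    "pimonidazole",
    "nuclei",
    "phospho_atm",
    "brightfield",
    "red_hypoxia",
)


class ImageIOError(ValueError):
    """Unreadable file or inconsistent channel layout."""


class ChannelMapError(ImageIOError):
    """A channel map references an unknown role or a missing page."""


class ShapeMismatchError(ImageIOError):
    """Channels of one section do not share a single shape."""


@dataclass
class SectionImage:
    """A registered multi-channel 2-D fluorescence image.

    ``channels`` maps a channel role (one of :data:`CHANNEL_ROLES`) to a 2-D
    intensity raster; all rasters share one shape.  ``bit_depth`` declares the
    acquisition range (8 or 16 bit).
    """

    channels: dict[str, np.ndarray]
    um_per_px: float = 1.0
    bit_depth: int = 16
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.channels:
            raise ImageIOError("a SectionImage needs at least one channel")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ShapeMismatchError(f"channels have differing shapes: {sorted(shapes)}")
        for role in self.channels:
            if role not in CHANNEL_ROLES:
                raise ChannelMapError(
                    f"unknown channel role {role!r}; expected one of {CHANNEL_ROLES}"
                )
        if self.bit_depth not in (8, 16):
            raise ImageIOError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        limit = 2**self.bit_depth - 1
        for role, ch in self.channels.items():
            if ch.min() < 0 or ch.max() > limit:
                raise ImageIOError(
                    f"channel {role!r} has intensities outside the "
                    f"{self.bit_depth}-bit range [0, {limit}]"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class RoiPolygon:
    """Closed simple polygon outlining the tumour-bearing region.

    Vertices are 0-based pixel coordinates ``(x, y)``; closure is implied.
    """

    vertices: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.vertices = [(float(x), float(y)) for x, y in self.vertices]
        if len(self.vertices) < 3:
            raise ValueError("an ROI polygon needs at least 3 vertices")
        poly = Polygon(self.vertices)
        if poly.area == 0 or not poly.is_valid:
            raise ValueError("degenerate or self-intersecting ROI polygon")

    def as_shapely(self) -> Polygon:
        return Polygon(self.vertices)

    @classmethod
    def rectangle(cls, x0: float, y0: float, x1: float, y1: float) -> "RoiPolygon":
        return cls([(x0, y0), (x1, y0), (x1, y1), (x0, y1)])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"vertices": self.vertices}))

    @classmethod
    def from_json(cls, path: str | Path) -> "RoiPolygon":
        data = json.loads(Path(path).read_text())
        return cls(vertices=[tuple(v) for v in data["vertices"]])


def read_section(
    path: str | Path,
    channel_map: Mapping[int, str] | None = None,
    um_per_px: float | None = None,
) -> SectionImage:
    """Read a multi-page TIFF into a :class:`SectionImage`.

    ``channel_map`` maps page index to channel role.  When omitted, the
    metadata sidecar written by :func:`write_section` (a JSON image
    description) is used instead.
    """
    path = Path(path)
    if not path.exists():
        raise ImageIOError(f"no such file: {path}")
    with tifffile.TiffFile(path) as tif:
        pages = [p.asarray() for p in tif.pages]
        desc = tif.pages[0].description or ""
    meta: dict = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    if channel_map is None:
        roles = meta.get("channel_roles")
        if roles is None:
            raise ChannelMapError(
                "no channel_map given and the file carries no embedded channel roles"
            )
        channel_map = {i: role for i, role in enumerate(roles)}
    channels: dict[str, np.ndarray] = {}
    for idx, role in channel_map.items():
        if role not in CHANNEL_ROLES:
            raise ChannelMapError(f"unknown channel role {role!r}")
        if idx < 0 or idx >= len(pages):
            raise ChannelMapError(
                f"channel map references page {idx} of a {len(pages)}-page file"
            )
        channels[role] = pages[idx]
    shapes = {c.shape for c in channels.values()}
    if len(shapes) != 1:
        raise ShapeMismatchError(f"pages mapped to channels differ in shape: {sorted(shapes)}")
    bit_depth = int(meta.get("bit_depth", 16 if next(iter(channels.values())).dtype.itemsize > 1 else 8))
    return SectionImage(
        channels=channels,
        um_per_px=float(um_per_px if um_per_px is not None else meta.get("um_per_px", 1.0)),
        bit_depth=bit_depth,
        provenance=str(path),
    )


def write_section(image: SectionImage, path: str | Path) -> None:
    """Write a :class:`SectionImage` as a multi-page TIFF.

    Channel roles, pixel size and bit depth go into the image description so
    that :func:`read_section` round-trips without an explicit channel map.
    """
    roles = list(image.channels)
    meta = {
        "channel_roles": roles,
        "um_per_px": image.um_per_px,
        "bit_depth": image.bit_depth,
    }
    stack = np.stack([image.channels[r] for r in roles])
    tifffile.imwrite(Path(path), stack, description=json.dumps(meta))


def rasterize_roi(roi: RoiPolygon, shape: tuple[int, int]) -> np.ndarray:
    """Rasterise an ROI polygon to a boolean mask over ``shape`` (rows, cols).

    A pixel belongs to the mask iff its centre lies strictly inside the
    polygon (even-odd rule).
    """
    poly = roi.as_shapely()
    minx, miny, maxx, maxy = poly.bounds
    h, w = shape
    if minx < 0 or miny < 0 or maxx > w or maxy > h:
        raise ValueError(
            f"ROI polygon bounds {poly.bounds} exceed image extent {w}x{h}"
        )
    cols, rows = np.meshgrid(np.arange(w), np.arange(h))
    xs = cols.ravel() + 0.5
    ys = rows.ravel() + 0.5
    inside = shapely.contains_xy(poly, xs, ys)
    return inside.reshape(shape)


def to_8bit(channel: np.ndarray, bit_depth: int) -> np.ndarray:
    """Convert a raster to the 8-bit analysis range.

    8-bit input is returned unchanged.  16-bit input is linearly scaled from
    the full nominal range (``v * 255 / 65535``) and rounded half-up, which
    keeps thresholds comparable across sections.
    """
    if bit_depth == 8:
        return channel.astype(np.uint8, copy=False)
    if bit_depth != 16:
        raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")
    scaled = np.floor(channel.astype(np.float64) * 255.0 / 65535.0 + 0.5)
    return scaled.astype(np.uint8)
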