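"""Flap geometry, Hartrampf-zone ROI partition and the whole-flap bright zone.

The flap is an abdominal tissue paddle supplied by a single perforator.  Its
geometry is captured by a boolean mask, the body midline (a column index) and
the perforator emergence point.  Four regions of interest are derived from
it, mapped onto the classical Hartrampf perfusion zones:

* ROI 1 — peripheral flap end on the perforator side (zone III)
* ROI 2 — perforator emergence area (zone I)
* ROI 3 — area adjacent to the perforator across the midline (zone II)
* ROI 4 — peripheral flap end contralateral to the perforator (zone IV)

Each half of the flap (split by the midline) is divided at the midpoint of
its column extent: the half nearest the midline becomes the central ROI, the
rest the peripheral one.  The four masks are pairwise disjoint and their
union is exactly the flap mask.

The "bright zone" is the highest-fluorescence subregion of the flap on which
whole-flap perfusion parameters are estimated.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .errors import GeometryError

__all__ = [
    "FlapGeometry",
    "ZoneSet",
    "partition_zones",
    "bright_zone",
    "load_geometry",
    "save_geometry",
]


@dataclass
class FlapGeometry:
    """Flap mask, midline column and perforator emergence point.

    ``midline_col`` is the boundary between the two body halves: columns
    ``< midline_col`` are one side, columns ``>= midline_col`` the other.
    The perforator must lie strictly off the midline boundary column so its
    side is unambiguous.
    """

    mask: np.ndarray
    midline_col: int
    perforator: tuple[int, int]
    pixel_size_mm: float = 1.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise GeometryError("flap mask must be a 2-D boolean image")
        if not self.mask.any():
            raise GeometryError("flap mask is empty")
        h, w = self.mask.shape
        if not (0 < self.midline_col < w):
            raise GeometryError(f"midline column {self.midline_col} outside image width {w}")
        r, c = self.perforator
        if not (0 <= r < h and 0 <= c < w) or not self.mask[r, c]:
            raise GeometryError(f"perforator point {self.perforator} outside the flap mask")
        if self.pixel_size_mm <= 0:
            raise GeometryError("pixel size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def perforator_side(self) -> str:
        """'left' if the perforator column is below the midline, else 'right'."""
        if self.perforator[1] == self.midline_col:
            raise GeometryError("perforator lies on the midline; side is undefined")
        return "left" if self.perforator[1] < self.midline_col else "right"

    def column_extent(self) -> tuple[int, int]:
        """Half-open column extent ``(c0, c1)`` of the flap mask."""
        cols = np.flatnonzero(self.mask.any(axis=0))
        return int(cols[0]), int(cols[-1]) + 1

    def distance_mm(self) -> np.ndarray:
        """Euclidean distance of every pixel from the perforator, in mm."""
        h, w = self.mask.shape
        rr, cc = np.mgrid[0:h, 0:w]
        pr, pc = self.perforator
        return np.hypot(rr - pr, cc - pc) * self.pixel_size_mm

    def crosses_midline(self) -> np.ndarray:
        """Boolean image of pixels on the opposite side of the midline."""
        cols = np.arange(self.mask.shape[1])
        if self.perforator_side == "left":
            return np.broadcast_to(cols >= self.midline_col, self.mask.shape)
        return np.broadcast_to(cols < self.midline_col, self.mask.shape)


@dataclass
class ZoneSet:
    """The four ROI masks of the Hartrampf-zone partition."""

    roi1: np.ndarray
    roi2: np.ndarray
    roi3: np.ndarray
    roi4: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"roi1": self.roi1, "roi2": self.roi2, "roi3": self.roi3, "roi4": self.roi4}

    def labels(self) -> np.ndarray:
        """Labeled image: 0 outside the flap, 1..4 for ROI1..ROI4."""
        lab = np.zeros(self.roi1.shape, dtype=np.uint8)
        for i, m in enumerate((self.roi1, self.roi2, self.roi3, self.roi4), start=1):
            lab[m] = i
        return lab


def _central_split(lo: int, hi: int, midline: int) -> int:
    """Column where a half flap [lo, hi) is divided; the ``ceil(width/2)``
    columns nearest the midline form the central ROI."""
    if hi <= midline:  # half on the left of the midline
        return midline - math.ceil((midline - lo) / 2)
    return midline + math.ceil((hi - midline) / 2)


def partition_zones(geometry: FlapGeometry) -> ZoneSet:
    """Partition the flap mask into ROI1..ROI4.

    The perforator half is split at the midpoint of its column extent into a
    peripheral part (ROI1) and a central, perforator-containing part (ROI2);
    the contralateral half likewise into a central part adjacent to the
    midline (ROI3) and the far peripheral end (ROI4).

    Raises
    ------
    GeometryError
        If the perforator column coincides with the midline (side undefined).
    """
    side = geometry.perforator_side  # raises on ambiguous geometry
    c0, c1 = geometry.column_extent()
    m = geometry.midline_col
    cols = np.arange(geometry.mask.shape[1])

    if side == "left":
        split_ipsi = _central_split(c0, m, m)
        split_contra = _central_split(m, c1, m)
        in1 = cols < split_ipsi
        in2 = (cols >= split_ipsi) & (cols < m)
        in3 = (cols >= m) & (cols < split_contra)
        in4 = cols >= split_contra
    else:
        split_ipsi = _central_split(m, c1, m)
        split_contra = _central_split(c0, m, m)
        in1 = cols >= split_ipsi
        in2 = (cols >= m) & (cols < split_ipsi)
        in3 = (cols >= split_contra) & (cols < m)
        in4 = cols < split_contra

    mask = geometry.mask
    zones = ZoneSet(
        roi1=mask & in1[None, :],
        roi2=mask & in2[None, :],
        roi3=mask & in3[None, :],
        roi4=mask & in4[None, :],
    )
    pr, pc = geometry.perforator
    if not zones.roi2[pr, pc]:
        raise GeometryError("perforator point does not fall in ROI2; geometry too narrow")
    return zones


def bright_zone(frames: np.ndarray, mask: np.ndarray, fraction: float = 0.2) -> np.ndarray:
    """Flap pixels whose peak fluorescence lies in the top ``fraction`` quantile.

    This emulates the automatic whole-flap selection of the highest-intensity
    subregion on which whole-flap parameters are computed.  Ties at the
    threshold are kept (``>=``), so a spatially uniform video yields the full
    flap mask.  Membership depends only on intensity ranks, hence is invariant
    to any strictly increasing rescaling of the pixel values.

    Parameters
    ----------
    frames
        ``(T, H, W)`` stack, or a precomputed ``(H, W)`` peak image.
    mask
        Flap mask.
    fraction
        Target proportion of flap pixels selected, in (0, 1).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise GeometryError("flap mask is empty")
    if not (0.0 < fraction < 1.0):
        raise GeometryError("fraction must be in (0, 1)")
    frames = np.asarray(frames)
    peak = frames if frames.ndim == 2 else frames.max(axis=0)
    vals = peak[mask]
    thr = np.quantile(vals, 1.0 - fraction)
    return mask & (peak >= thr)


def save_geometry(geometry: FlapGeometry, path: str | Path) -> None:
    """Write geometry as JSON ``{mask_path, midline_col, perforator}`` + mask TIFF."""
    path = Path(path)
    mask_path = path.with_suffix(".mask.tiff")
    tifffile.imwrite(mask_path, geometry.mask.astype(np.uint8))
    payload = {
        "mask_path": mask_path.name,
        "midline_col": int(geometry.midline_col),
        "perforator": [int(geometry.perforator[0]), int(geometry.perforator[1])],
        "pixel_size_mm": geometry.pixel_size_mm,
    }
    path.write_text(json.dumps(payload, indent=2))


def load_geometry(path: str | Path) -> FlapGeometry:
    """Read a geometry JSON written by :func:`save_geometry`."""
    path = Path(path)
    payload = json.loads(path.read_text())
    mask = tifffile.imread(path.parent / payload["mask_path"]).astype(bool)
    return FlapGeometry(
        mask=mask,
        midline_col=int(payload["midline_col"]),
        perforator=tuple(payload["perforator"]),
        pixel_size_mm=float(payload.get("pixel_size_mm", 1.0)),
    )
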