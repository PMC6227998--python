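"""Binary colony masks and their basic geometry.

A colony is represented by the set of occupied pixels in a 2-D binary
raster, together with the image resolution in square micrometres per
pixel.  All downstream shape descriptors are computed from this
representation.  The geometric convention used throughout the package:
pixel ``(row r, col c)`` occupies the closed unit square
``[c, c+1] x [r, r+1]`` in a continuous plane with x pointing right and
y pointing down; its centre is ``(c + 1/2, r + 1/2)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "BinaryImage",
    "ColonyGeometry",
    "load_mask",
    "boundary_pixels",
    "colony_geometry",
]


@dataclass(frozen=True)
class BinaryImage:
    """A 2-D occupancy grid with physical resolution and a group label.

    Parameters
    ----------
    pixels
        2-D boolean array; ``True`` marks occupied pixels.
    resolution
        Image resolution in um^2 per pixel (area of one pixel).  The
        linear pixel pitch is ``sqrt(resolution)`` um.
    group_label
        Experimental group the image belongs to (e.g. a strain or
        nutrient condition).
    image_id
        Identifier for the image, usually derived from the filename.
    """

    pixels: np.ndarray
    resolution: float
    group_label: str = ""
    image_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {arr.shape}")
        if arr.size < 1:
            raise ValueError("mask must contain at least one pixel")
        object.__setattr__(self, "pixels", arr.astype(bool))
        if not (self.resolution > 0):
            raise ValueError(f"resolution must be positive, got {self.resolution}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def n_occupied(self) -> int:
        return int(self.pixels.sum())

    @property
    def pixel_pitch(self) -> float:
        """Linear size of one pixel in um (square root of the resolution)."""
        return float(np.sqrt(self.resolution))

    def require_occupied(self) -> None:
        if not self.pixels.any():
            raise ValueError(f"empty colony: no occupied pixels in {self.image_id!r}")


@dataclass(frozen=True)
class ColonyGeometry:
    """Centroid and maximum radius of a colony.

    The centroid is the unweighted mean of occupied pixel centres in
    (x, y) coordinates; the maximum radius R is the largest Euclidean
    distance from the centroid to an occupied pixel centre.
    """

    centroid: tuple[float, float]
    max_radius_px: float
    max_radius_um: float = field(default=float("nan"))


def load_mask(path: str | Path, resolution: float, group_label: str = "") -> BinaryImage:
    """Read a PNG/TIFF raster as a binary occupancy mask.

    Any nonzero raster value marks a pixel as occupied.  For RGB input,
    a pixel is occupied when any colour channel is nonzero; an alpha
    channel (4th channel) is ignored.

    Raises
    ------
    ValueError
        If the raster is not 2-D (after channel reduction) or contains
        no occupied pixels.
    """
    import imageio.v3 as iio

    path = Path(path)
    arr = iio.imread(path)
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        occupied = (arr != 0).any(axis=2)
    elif arr.ndim == 2:
        occupied = arr != 0
    else:
        raise ValueError(f"expected a 2-D raster, got shape {arr.shape} from {path}")
    if not occupied.any():
        raise ValueError(f"empty colony: {path} has no nonzero pixels")
    image = BinaryImage(
        pixels=occupied,
        resolution=resolution,
        group_label=group_label,
        image_id=path.stem,
    )
    _warn_on_oddities(image)
    return image


def _warn_on_oddities(image: BinaryImage) -> None:
    occ = image.pixels
    _, n_components = ndimage.label(occ)
    if n_components > 1:
        logger.warning(
            "colony %r has %d connected components", image.image_id, n_components
        )
    if occ[0, :].any() or occ[-1, :].any() or occ[:, 0].any() or occ[:, -1].any():
        logger.warning(
            "colony %r touches the raster border; chords are truncated there",
            image.image_id,
        )


def boundary_pixels(image: BinaryImage) -> np.ndarray:
    """Occupied pixels with at least one unoccupied or off-grid 4-neighbour.

    Returns an ``(N, 2)`` integer array of (row, col) coordinates in
    row-major order.  Only these pixels carry shape primitives: interior
    pixels, whose four edge-neighbours are all occupied, say nothing
    about the outline of the colony.
    """
    image.require_occupied()
    occ = image.pixels
    padded = np.pad(occ, 1, mode="constant", constant_values=False)
    interior = (
        padded[:-2, 1:-1]
        & padded[2:, 1:-1]
        & padded[1:-1, :-2]
        & padded[1:-1, 2:]
    )
    return np.argwhere(occ & ~interior)


def colony_geometry(image: BinaryImage) -> ColonyGeometry:
    """Centroid and maximum radius of the occupied set."""
    image.require_occupied()
    rows, cols = np.nonzero(image.pixels)
    cx = float(cols.mean() + 0.5)
    cy = float(rows.mean() + 0.5)
    dist = np.hypot(cols + 0.5 - cx, rows + 0.5 - cy)
    r_px = float(dist.max())
    return ColonyGeometry(
        centroid=(cx, cy),
        max_radius_px=r_px,
        max_radius_um=r_px * image.pixel_pitch,
    )
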