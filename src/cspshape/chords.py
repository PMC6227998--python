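"""Shape primitives: maximal chord lengths through boundary pixels.

A shape primitive describes the local shape of a colony at one boundary
pixel p.  For each of D equally spaced angles phi_d = (d-1)*pi/D the
length of the longest line segment through the centre of p, at angle
phi_d, lying entirely inside the occupied region is recorded.  The
occupied region is modelled as the union of the closed unit squares of
the occupied pixels, and the chord is measured as a continuous segment
length, not a pixel count: on a 3x3 filled square this yields the chord
set {3, sqrt(2), 2*sqrt(2), 3*sqrt(2)} at D = 4, which no integer pixel
count reproduces.  Points on shared edges or corners of occupied squares
count as inside (closed union), so a chord may pass through the corner
between two diagonally adjacent occupied pixels.

Pixel-unit lengths are converted to physical micrometres by multiplying
with sqrt(resolution), the linear pixel pitch, so that images taken at
different resolutions are comparable.

Chords are computed by exact ray-grid traversal: the line is marched
through cell-boundary crossings in both directions from the pixel centre
until it first enters an unoccupied (or off-grid) cell, accumulating the
traversed parameter length.  Only the maximal segment containing the
pixel centre is measured; for concave shapes the same line may re-enter
the occupied region elsewhere, and those disjoint runs are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .image import BinaryImage, boundary_pixels

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

__all__ = [
    "AngleSet",
    "ShapePrimitive",
    "PrimitiveTable",
    "chord_length",
    "shape_primitive",
    "image_primitives",
    "representation_space",
]


@dataclass(frozen=True)
class AngleSet:
    """The D measurement angles phi_d = (d-1)*pi/D, d = 1..D."""

    D: int

    def __post_init__(self) -> None:
        if self.D < 1:
            raise ValueError("D must be a positive integer")

    @property
    def angles(self) -> np.ndarray:
        return np.arange(self.D) * np.pi / self.D


@dataclass(frozen=True)
class ShapePrimitive:
    """Chord lengths through one boundary pixel, in pixels and in um."""

    pixel: tuple[int, int]
    lengths_px: np.ndarray
    lengths_um: np.ndarray
    image_id: str = ""


@dataclass(frozen=True)
class PrimitiveTable:
    """Shape primitives for many boundary pixels, kept as flat arrays.

    ``vectors_um`` (N x D, micrometres) is the representation used for
    clustering and classification; ``vectors_px`` retains pixel units
    for geometric checks.  ``image_ids`` records provenance per row.
    """

    pixels: np.ndarray          # (N, 2) int, (row, col)
    vectors_px: np.ndarray      # (N, D) float
    vectors_um: np.ndarray      # (N, D) float
    image_ids: np.ndarray       # (N,) str

    def __len__(self) -> int:
        return self.vectors_um.shape[0]

    @property
    def D(self) -> int:
        return self.vectors_um.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Primitive table as a DataFrame (CSV-exportable)."""
        d = self.D
        df = pd.DataFrame(
            {
                "image_id": self.image_ids,
                "row": self.pixels[:, 0],
                "col": self.pixels[:, 1],
            }
        )
        for j in range(d):
            df[f"v_um_{j + 1}"] = self.vectors_um[:, j]
        return df


@njit(cache=True)
def _march(occ, r, c, dx, dy):
    """Distance from the centre of cell (r, c) along unit direction
    (dx, dy) to the first crossing into an unoccupied or off-grid cell.

    Crossings exactly through a lattice corner step diagonally: the open
    interval beyond the corner lies in the diagonal cell, so that cell
    decides continuation (the corner point itself is in the closure of
    all four adjacent cells).
    """
    nrows, ncols = occ.shape
    x = c + 0.5
    y = r + 0.5
    cr = r
    cc = c
    t = 0.0
    while True:
        if dx > 1e-15:
            tx = (cc + 1.0 - x) / dx
        elif dx < -1e-15:
            tx = (cc - x) / dx
        else:
            tx = 1e30
        if dy > 1e-15:
            ty = (cr + 1.0 - y) / dy
        elif dy < -1e-15:
            ty = (cr - y) / dy
        else:
            ty = 1e30
        if tx < ty - 1e-12:
            step = tx
            cc += 1 if dx > 0 else -1
        elif ty < tx - 1e-12:
            step = ty
            cr += 1 if dy > 0 else -1
        else:  # corner crossing
            step = 0.5 * (tx + ty)
            cc += 1 if dx > 0 else -1
            cr += 1 if dy > 0 else -1
        t += step
        x += step * dx
        y += step * dy
        if cr < 0 or cr >= nrows or cc < 0 or cc >= ncols or not occ[cr, cc]:
            return t


@njit(cache=True)
def _chords_batch(occ, pixels, dxs, dys):
    n = pixels.shape[0]
    d = dxs.shape[0]
    out = np.empty((n, d))
    for i in range(n):
        r = pixels[i, 0]
        c = pixels[i, 1]
        for j in range(d):
            out[i, j] = _march(occ, r, c, dxs[j], dys[j]) + _march(
                occ, r, c, -dxs[j], -dys[j]
            )
    return out


def chord_length(image: BinaryImage, p: tuple[int, int], phi: float) -> float:
    """Length in pixels of the maximal chord through pixel p at angle phi.

    The chord is the longest connected segment of the line through the
    centre of p at angle ``phi`` (radians from the horizontal axis) that
    contains the centre and lies in the closed union of occupied pixel
    squares; it is truncated at the raster edge.
    """
    r, c = int(p[0]), int(p[1])
    if not image.pixels[r, c]:
        raise ValueError(f"pixel {p} is not occupied")
    dx = float(np.cos(phi))
    dy = float(np.sin(phi))
    occ = np.ascontiguousarray(image.pixels)
    return float(_march(occ, r, c, dx, dy) + _march(occ, r, c, -dx, -dy))


def shape_primitive(
    image: BinaryImage, p: tuple[int, int], angles: AngleSet
) -> ShapePrimitive:
    """The shape primitive at boundary pixel p: one chord per angle."""
    lengths_px = np.array([chord_length(image, p, phi) for phi in angles.angles])
    return ShapePrimitive(
        pixel=(int(p[0]), int(p[1])),
        lengths_px=lengths_px,
        lengths_um=lengths_px * image.pixel_pitch,
        image_id=image.image_id,
    )


def image_primitives(image: BinaryImage, angles: AngleSet) -> PrimitiveTable:
    """Shape primitives for every boundary pixel of one image."""
    image.require_occupied()
    pix = boundary_pixels(image)
    occ = np.ascontiguousarray(image.pixels)
    phis = angles.angles
    dxs = np.cos(phis)
    dys = np.sin(phis)
    vec_px = _chords_batch(occ, np.ascontiguousarray(pix), dxs, dys)
    return PrimitiveTable(
        pixels=pix,
        vectors_px=vec_px,
        vectors_um=vec_px * image.pixel_pitch,
        image_ids=np.full(len(pix), image.image_id, dtype=object),
    )


def representation_space(
    images: list[BinaryImage], angles: AngleSet
) -> PrimitiveTable:
    """All shape primitives of a group of images, with provenance.

    The representation space of a group is the multiset of shape
    primitives over all boundary pixels of all images in the group; it
    is the input to per-group clustering.
    """
    if not images:
        raise ValueError("representation space requires at least one image")
    tables = [image_primitives(img, angles) for img in images]
    return concat_primitives(tables)


def concat_primitives(tables: list[PrimitiveTable]) -> PrimitiveTable:
    return PrimitiveTable(
        pixels=np.concatenate([t.pixels for t in tables]),
        vectors_px=np.concatenate([t.vectors_px for t in tables]),
        vectors_um=np.concatenate([t.vectors_um for t in tables]),
        image_ids=np.concatenate([t.image_ids for t in tables]),
    )
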