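"""Shared fixtures: small raster fixtures, random blob shapes and
miniature synthetic datasets used across the suite.

All fixtures are generated programmatically with fixed seeds; nothing
is read from disk except rasters the tests themselves write to tmp
paths.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from cspshape import (
    BinaryImage,
    ColonyParams,
    GroupSpec,
    generate_grouped_dataset,
    prepare_dataset,
)


def make_image(array, resolution: float = 1.0, **kwargs) -> BinaryImage:
    return BinaryImage(np.asarray(array, dtype=bool), resolution, **kwargs)


@pytest.fixture
def square3() -> BinaryImage:
    """A 3x3 filled square (the classic worked example shape)."""
    return make_image(np.ones((3, 3)), image_id="square3")


def random_blob(rng: np.random.Generator, size: int = 48) -> BinaryImage:
    """A random smooth blob: thresholded filtered noise, largest
    connected component kept; always nonempty."""
    field = ndimage.gaussian_filter(rng.normal(size=(size, size)), 4.0)
    occ = field > np.quantile(field, 0.72)
    labels, n = ndimage.label(occ)
    if n == 0:  # fall back to a single pixel (never happens at this size)
        occ = np.zeros((size, size), bool)
        occ[size // 2, size // 2] = True
        return make_image(occ)
    counts = np.bincount(labels.ravel())[1:]
    occ = labels == (1 + int(np.argmax(counts)))
    return make_image(occ)


def closed_union_contains(occ: np.ndarray, x: float, y: float) -> bool:
    """Membership of a point in the union of closed occupied unit
    squares — the geometric model the chord measurement is defined on."""
    eps = 1e-9
    nrows, ncols = occ.shape
    for cx in {int(np.floor(x - eps)), int(np.floor(x + eps))}:
        for cy in {int(np.floor(y - eps)), int(np.floor(y + eps))}:
            if 0 <= cy < nrows and 0 <= cx < ncols and occ[cy, cx]:
                return True
    return False


def _inside_closed_union(occ: np.ndarray, xs: np.ndarray, ys: np.ndarray):
    eps = 1e-9
    nrows, ncols = occ.shape
    ok = np.zeros(xs.shape, bool)
    for sx in (-eps, eps):
        for sy in (-eps, eps):
            cc = np.floor(xs + sx).astype(int)
            rr = np.floor(ys + sy).astype(int)
            valid = (cc >= 0) & (cc < ncols) & (rr >= 0) & (rr < nrows)
            ok |= valid & occ[np.clip(rr, 0, nrows - 1), np.clip(cc, 0, ncols - 1)]
    return ok


def dense_chord_length(
    image: BinaryImage, p: tuple[int, int], phi: float, step: float = 0.01
) -> float:
    """Dense-sampling chord oracle, independent of the grid traversal.

    Points are sampled every ``step`` px along the line through the
    pixel centre in both directions; the chord extent is bounded by the
    first sampled point outside the closed union.  Underestimates by at
    most one step per side.
    """
    occ = image.pixels
    r, c = p
    x0, y0 = c + 0.5, r + 0.5
    dx, dy = np.cos(phi), np.sin(phi)
    tmax = float(np.hypot(*occ.shape)) + 1.0
    ts = np.arange(step, tmax, step)
    total = 0.0
    for sign in (1.0, -1.0):
        inside = _inside_closed_union(occ, x0 + sign * ts * dx, y0 + sign * ts * dy)
        if inside.all():
            total += ts[-1]
        else:
            first_out = int(np.argmin(inside))
            total += ts[first_out - 1] if first_out > 0 else 0.0
    return total


def tiny_colony_params(mean_len: float, sd: float = 3.0, **overrides) -> ColonyParams:
    """Small, fast colony parameters for classification tests."""
    defaults = dict(
        core_radius=15.0,
        n_filaments=10,
        filament_length_mean=mean_len,
        filament_length_sd=sd,
        filament_width=3,
        angular_jitter=0.2,
        branching_prob=0.0,
        image_size=160,
        resolution=1.5,
    )
    defaults.update(overrides)
    return ColonyParams(**defaults)


def tiny_dataset(length_means: dict[str, float], n_images: int = 6, seed: int = 0,
                 D: int = 4):
    """Generate and featurize a miniature grouped dataset."""
    specs = [
        GroupSpec(name=name, params=tiny_colony_params(mu), n_images=n_images)
        for name, mu in length_means.items()
    ]
    images = generate_grouped_dataset(specs, seed=seed)
    return prepare_dataset(images, D=D, seed=seed + 1)


@pytest.fixture(scope="session")
def separable_tiny_dataset():
    """Two small groups with well-separated filament lengths."""
    return tiny_dataset({"short": 12.0, "long": 45.0}, n_images=6, seed=11)
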