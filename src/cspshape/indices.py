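"""Spatial point-pattern indices for colony masks.

Three indices quantify how the occupied pixels deviate from complete
spatial randomness (CSR: pixels placed uniformly and independently),
each constructed so it is ~0 for a CSR pattern:

* radial index  I_r = 1 - R_CSR / R, where R is the maximum colony
  radius and R_CSR is the radius at which the radial occupancy density
  drops to its CSR reference value.  Filamentous colonies, dense in the
  centre and sparse far out, give I_r near 1; compact discs give ~0.
* angular index  I_theta: the variance of the CSR-normalized angular
  occupancy counts about the centroid; measures angular non-uniformity.
* pair-correlation index  I_Theta = F_Theta(first bin) - 1, the
  small-separation excess of the angular pair-correlation function;
  measures local angular aggregation.

All occupied pixels (not only boundary pixels) enter these statistics.
The constructions here follow the published sketch — the stated
1 - R_CSR/R form, 178/200/200 bins and a 1000-pixel subsample for the
pair-correlation function — with the remaining details (the exact
normalization and crossing rule) reconstructed so that every index
vanishes under CSR; absolute values may therefore differ from other
implementations even where the qualitative behaviour matches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .image import BinaryImage, colony_geometry

logger = logging.getLogger(__name__)

__all__ = [
    "SpatialIndexSet",
    "radial_index",
    "angular_index",
    "pair_correlation_index",
    "spatial_indices",
]

RADIAL_BINS = 178
ANGULAR_BINS = 200
PAIR_BINS = 200
PAIR_SAMPLE = 1000


@dataclass(frozen=True)
class SpatialIndexSet:
    """The three spatial indices of one image, plus raw profile data."""

    I_r: float
    R_csr_px: float
    I_theta: float
    I_Theta: float
    F_Theta: np.ndarray
    pc_seed: int
    radial_bins: int = RADIAL_BINS
    angular_bins: int = ANGULAR_BINS
    pair_bins: int = PAIR_BINS
    pair_sample: int = PAIR_SAMPLE


def _occupied_offsets(image: BinaryImage) -> tuple[np.ndarray, np.ndarray, float]:
    """(dx, dy) of occupied pixel centres relative to the centroid, and R."""
    geom = colony_geometry(image)
    rows, cols = np.nonzero(image.pixels)
    dx = cols + 0.5 - geom.centroid[0]
    dy = rows + 0.5 - geom.centroid[1]
    return dx, dy, geom.max_radius_px


def radial_index(image: BinaryImage, bins: int = RADIAL_BINS) -> tuple[float, float]:
    """Radial index I_r and the CSR-equivalent radius R_CSR (pixels).

    The disc of radius R about the centroid is split into ``bins``
    equal-width annuli; each annulus' occupancy density (occupied count
    per unit annulus area) is compared with the CSR reference density
    N / (pi R^2).  R_CSR is the outer edge of the outermost annulus
    whose density still reaches the reference; beyond it the colony is
    sparser than CSR.  I_r = 1 - R_CSR/R, clamped to [0, 1]; a single
    pixel (R = 0) gives I_r = 0 by convention.
    """
    image.require_occupied()
    dx, dy, R = _occupied_offsets(image)
    if R == 0:
        return 0.0, 0.0
    dist = np.hypot(dx, dy)
    counts, edges = np.histogram(dist, bins=bins, range=(0.0, R))
    areas = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    density = counts / areas
    reference = dist.size / (np.pi * R**2)
    at_least_csr = np.nonzero(density >= reference)[0]
    if at_least_csr.size == 0:
        r_csr = 0.0
    else:
        r_csr = float(edges[at_least_csr[-1] + 1])
    i_r = float(np.clip(1.0 - r_csr / R, 0.0, 1.0))
    return i_r, r_csr


def angular_index(image: BinaryImage, bins: int = ANGULAR_BINS) -> float:
    """Angular index I_theta: variance of CSR-normalized angular counts.

    Angles of occupied pixel centres about the centroid are binned into
    ``bins`` equal bins over [0, 2*pi); each count is divided by its CSR
    expectation N/bins, and I_theta is the population variance of the
    normalized counts.  Zero iff the angular occupancy is perfectly
    uniform across bins.
    """
    image.require_occupied()
    dx, dy, R = _occupied_offsets(image)
    if R == 0:
        logger.warning("degenerate colony %r: I_theta set to 0", image.image_id)
        return 0.0
    theta = np.mod(np.arctan2(dy, dx), 2 * np.pi)
    counts, _ = np.histogram(theta, bins=bins, range=(0.0, 2 * np.pi))
    normalized = counts / (theta.size / bins)
    return float(np.var(normalized))


def pair_correlation_index(
    image: BinaryImage,
    bins: int = PAIR_BINS,
    sample: int = PAIR_SAMPLE,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Pair-correlation index I_Theta and the profile F_Theta.

    ``min(sample, N)`` occupied pixels are drawn without replacement
    (seeded) and all pairwise angular separations about the centroid,
    folded onto [0, pi], are binned into ``bins`` equal bins.  Under
    independent uniform angles the folded separation is uniform on
    [0, pi], so each bin is normalized by n_pairs/bins; F_Theta is the
    vector of normalized bins and I_Theta = F_Theta[first bin] - 1.
    """
    image.require_occupied()
    dx, dy, _ = _occupied_offsets(image)
    n = dx.size
    if n < 2:
        return 0.0, np.ones(bins)
    rng = np.random.default_rng(seed)
    if n > sample:
        keep = rng.choice(n, size=sample, replace=False)
        dx, dy = dx[keep], dy[keep]
    theta = np.mod(np.arctan2(dy, dx), 2 * np.pi)
    iu, ju = np.triu_indices(theta.size, k=1)
    delta = np.abs(theta[iu] - theta[ju])
    delta = np.minimum(delta, 2 * np.pi - delta)
    counts, _ = np.histogram(delta, bins=bins, range=(0.0, np.pi))
    expected = delta.size / bins
    f_theta = counts / expected
    return float(f_theta[0] - 1.0), f_theta


def spatial_indices(image: BinaryImage, pc_seed: int = 0) -> SpatialIndexSet:
    """All three indices of one image with the default bin settings."""
    i_r, r_csr = radial_index(image)
    i_theta = angular_index(image)
    i_pc, f_theta = pair_correlation_index(image, seed=pc_seed)
    return SpatialIndexSet(
        I_r=i_r,
        R_csr_px=r_csr,
        I_theta=i_theta,
        I_Theta=i_pc,
        F_Theta=f_theta,
        pc_seed=pc_seed,
    )
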