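"""Synthetic colony masks with controllable pseudohyphal morphology.

Colonies grown under nutrient limitation develop a roughly circular
dense core surrounded by radial filamentous protrusions (pseudohyphae).
The generator emulates exactly that geometry: a filled disc core plus
``n_filaments`` thick radial segments whose lengths are drawn from a
truncated normal and whose directions are evenly spaced around the
circle with Gaussian angular jitter, optionally with one level of
branching.  It produces shape statistics — long thin chords along
filaments, short chords across them, radially decaying density — of the
kind real filamentous colonies show, without simulating growth
biophysics, cell texture or image noise.

Three presets mimic the structure of a three-condition laboratory
dataset (10 + 9 + 10 images): ``a7_50`` (long sparse filaments, strong
pseudohyphal growth at low nutrient), ``a7_500`` (short dense fringe,
near-uniform growth at high nutrient) and ``ar_50`` (intermediate
filaments, a second strain at low nutrient), at pixel resolutions
1.52 / 1.55 / 1.53 um^2 per pixel respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.morphology import dilation, footprint_rectangle

from .image import BinaryImage

__all__ = [
    "ColonyParams",
    "GroupSpec",
    "PRESETS",
    "generate_colony",
    "generate_grouped_dataset",
]


@dataclass(frozen=True)
class ColonyParams:
    """Parameters of one synthetic colony.

    All lengths are in pixels.  ``angular_jitter`` (radians) perturbs
    the evenly spaced filament directions: 0 gives perfectly regular
    spacing, larger values give increasingly irregular angular coverage.
    ``branching_prob`` is the chance that a filament carries one child
    branch of half its length.
    """

    core_radius: float = 40.0
    n_filaments: int = 12
    filament_length_mean: float = 100.0
    filament_length_sd: float = 20.0
    filament_width: int = 3
    angular_jitter: float = 0.2
    branching_prob: float = 0.1
    image_size: int = 512
    resolution: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.core_radius <= 0 or self.filament_width <= 0:
            raise ValueError("scale parameters must be positive")
        if self.filament_length_mean < 0 or self.filament_length_sd <= 0:
            raise ValueError("filament length distribution must have sd > 0")
        if not 0 <= self.branching_prob <= 1:
            raise ValueError("branching_prob must lie in [0, 1]")
        if self.n_filaments < 0:
            raise ValueError("n_filaments must be >= 0")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        reach = self.core_radius + self.max_filament_length + self.filament_width
        if reach > self.image_size / 2 - 2:
            raise ValueError(
                f"colony reach {reach:.0f} px exceeds image bounds "
                f"(need a 2 px margin in a {self.image_size} px image)"
            )

    @property
    def max_filament_length(self) -> float:
        """Truncation point of the length distribution (mean + 3 sd)."""
        return self.filament_length_mean + 3 * self.filament_length_sd


@dataclass(frozen=True)
class GroupSpec:
    """A named group of colonies drawn from one parameter setting."""

    name: str
    params: ColonyParams
    n_images: int

    def __post_init__(self) -> None:
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")


def _sample_lengths(params: ColonyParams, n: int, rng: np.random.Generator):
    mu, sd = params.filament_length_mean, params.filament_length_sd
    a = (0.0 - mu) / sd
    b = (params.max_filament_length - mu) / sd
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=n, random_state=rng)


def generate_colony(params: ColonyParams) -> BinaryImage:
    """Rasterize one synthetic colony mask; deterministic given the seed."""
    rng = np.random.default_rng(params.seed)
    size = params.image_size
    mask = np.zeros((size, size), dtype=bool)
    centre = (size / 2.0, size / 2.0)
    rr, cc = draw_disk(centre, params.core_radius, shape=mask.shape)
    mask[rr, cc] = True

    n = params.n_filaments
    if n > 0:
        skeleton = np.zeros_like(mask)
        base = 2 * np.pi * np.arange(n) / n
        angles = base + rng.normal(0.0, params.angular_jitter, size=n)
        lengths = _sample_lengths(params, n, rng)
        branch = rng.random(n) < params.branching_prob
        for theta, length, has_branch in zip(angles, lengths, branch):
            _draw_filament(skeleton, centre, theta, length, params, rng, has_branch)
        half = max(1, params.filament_width // 2)
        skeleton = dilation(
            skeleton, footprint_rectangle((2 * half + 1, 2 * half + 1))
        )
        mask |= skeleton
    return BinaryImage(
        pixels=mask,
        resolution=params.resolution,
        image_id=f"synthetic-{params.seed}",
    )


def _draw_filament(
    skeleton: np.ndarray,
    centre: tuple[float, float],
    theta: float,
    length: float,
    params: ColonyParams,
    rng: np.random.Generator,
    has_branch: bool,
) -> None:
    cy, cx = centre
    direction = np.array([np.sin(theta), np.cos(theta)])  # (row, col)
    # start just inside the core so the filament is connected to it
    r0 = params.core_radius - 2.0
    start = np.array([cy, cx]) + r0 * direction
    end = np.array([cy, cx]) + (params.core_radius + length) * direction
    rr, cc = draw_line(*np.round(start).astype(int), *np.round(end).astype(int))
    skeleton[rr, cc] = True
    if has_branch and length > 4:
        u = rng.uniform(0.4, 0.8)
        origin = start + u * (end - start)
        child_theta = theta + rng.choice([-1.0, 1.0]) * abs(
            rng.normal(0.5, 0.15)
        )
        child_dir = np.array([np.sin(child_theta), np.cos(child_theta)])
        child_end = origin + (length / 2.0) * child_dir
        child_end = np.clip(child_end, 2, params.image_size - 3)
        rr, cc = draw_line(
            *np.round(origin).astype(int), *np.round(child_end).astype(int)
        )
        skeleton[rr, cc] = True


def generate_grouped_dataset(
    specs: list[GroupSpec], seed: int = 0
) -> list[BinaryImage]:
    """Generate labelled colonies for several groups.

    Per-image seeds are derived deterministically from ``seed`` and the
    position of the image in the dataset, so the same call always
    produces bit-identical masks.
    """
    if not specs:
        raise ValueError("at least one group spec is required")
    images: list[BinaryImage] = []
    rng = np.random.default_rng(seed)
    for spec in specs:
        image_seeds = rng.integers(2**31, size=spec.n_images)
        for i, s in enumerate(image_seeds):
            img = generate_colony(replace(spec.params, seed=int(s)))
            images.append(
                BinaryImage(
                    pixels=img.pixels,
                    resolution=spec.params.resolution,
                    group_label=spec.name,
                    image_id=f"{spec.name}-{i:02d}",
                )
            )
    return images


# Preset morphologies: filament-length regimes chosen to span the
# qualitative range from strongly pseudohyphal (long sparse filaments)
# through intermediate to near-uniform growth (short dense fringe).
# The truncated supports (mean +/- 3 sd) of the three length
# distributions are pairwise disjoint: [75, 165], [21, 69], [3, 21] px.
PRESETS: dict[str, GroupSpec] = {
    "a7_50": GroupSpec(
        name="a7_50",
        params=ColonyParams(
            core_radius=40,
            n_filaments=14,
            filament_length_mean=120.0,
            filament_length_sd=15.0,
            filament_width=3,
            angular_jitter=0.25,
            branching_prob=0.2,
            image_size=512,
            resolution=1.52,
        ),
        n_images=10,
    ),
    "a7_500": GroupSpec(
        name="a7_500",
        params=ColonyParams(
            core_radius=40,
            n_filaments=40,
            filament_length_mean=12.0,
            filament_length_sd=3.0,
            filament_width=3,
            angular_jitter=0.15,
            branching_prob=0.0,
            image_size=512,
            resolution=1.55,
        ),
        n_images=9,
    ),
    "ar_50": GroupSpec(
        name="ar_50",
        params=ColonyParams(
            core_radius=40,
            n_filaments=22,
            filament_length_mean=45.0,
            filament_length_sd=8.0,
            filament_width=3,
            angular_jitter=0.2,
            branching_prob=0.1,
            image_size=512,
            resolution=1.53,
        ),
        n_images=10,
    ),
}
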