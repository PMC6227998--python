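"""Clustered shape primitives (CSPs) and histogram features.

Within each experimental group, k-means is applied to the group's
representation space (all shape primitives, in micrometres).  The K
cluster centres per group are the group's CSPs — learned "visual words"
of local shape.  With m groups this yields M = K*m centres, labelled
sequentially so that centre (g-1)*K + k is the k-th CSP of group g.

Every boundary pixel of an image is then assigned the label of its
nearest CSP (Euclidean distance, ties to the smallest index), producing
the image's CSP map, and the normalized histogram of labels h =
(h_1, ..., h_M) summarizes the shape content of the image.  Optionally
the three spatial indices, each scaled by 1/M so all coordinates share
a comparable magnitude, are appended to form the augmented feature
vector of length M + 3.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .chords import PrimitiveTable
from .indices import SpatialIndexSet

__all__ = [
    "CSPModel",
    "fit_csp_model",
    "assign_csp_labels",
    "csp_histogram",
    "augment_features",
    "SPATIAL_FEATURE_NAMES",
]

SPATIAL_FEATURE_NAMES = ("I_r", "I_theta", "I_Theta")

# k-means settings: k-means++ seeding, 10 restarts, tight tolerance.
_KMEANS_KWARGS = dict(init="k-means++", n_init=10, max_iter=300, tol=1e-6)


@dataclass(frozen=True)
class CSPModel:
    """Per-group k-means centres over shape primitives.

    ``centres`` is an (M, D) array in micrometres with M = K * m; row
    (g-1)*K + k is the k-th centre of group g (0-based: g*K + k).
    """

    centres: np.ndarray
    group_names: tuple[str, ...]
    K: int
    D: int
    seed: int
    inertia: dict[str, float]

    @property
    def m(self) -> int:
        return len(self.group_names)

    @property
    def M(self) -> int:
        return self.centres.shape[0]

    def group_of_centre(self, i: int) -> str:
        """Group owning 1-based centre label i."""
        return self.group_names[(i - 1) // self.K]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "format": "cspshape.model/1",
            "K": self.K,
            "D": self.D,
            "m": self.m,
            "seed": self.seed,
            "group_names": list(self.group_names),
            "centres_um": self.centres.tolist(),
            "inertia": self.inertia,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CSPModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "cspshape.model/1":
            raise ValueError(f"unrecognized model file format in {path}")
        return cls(
            centres=np.asarray(payload["centres_um"], dtype=float),
            group_names=tuple(payload["group_names"]),
            K=int(payload["K"]),
            D=int(payload["D"]),
            seed=int(payload["seed"]),
            inertia={k: float(v) for k, v in payload["inertia"].items()},
        )


def fit_csp_model(
    spaces: dict[str, PrimitiveTable | np.ndarray], K: int, seed: int
) -> CSPModel:
    """Cluster each group's representation space into K CSPs.

    ``spaces`` maps group name -> primitives (a PrimitiveTable or a raw
    (N, D) array in micrometres); group order follows dict insertion
    order and fixes the centre labelling.  Deterministic given ``seed``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if not spaces:
        raise ValueError("at least one group is required")
    centres = []
    inertia: dict[str, float] = {}
    D = None
    for g, (name, space) in enumerate(spaces.items()):
        X = space.vectors_um if isinstance(space, PrimitiveTable) else np.asarray(space)
        if X.ndim != 2:
            raise ValueError(f"group {name!r}: primitives must be a 2-D array")
        if D is None:
            D = X.shape[1]
        elif X.shape[1] != D:
            raise ValueError("all groups must share the primitive dimension D")
        if X.shape[0] < K:
            raise ValueError(
                f"group {name!r} has {X.shape[0]} primitives, fewer than K={K}"
            )
        km = KMeans(n_clusters=K, random_state=seed + g, **_KMEANS_KWARGS)
        km.fit(X)
        centres.append(km.cluster_centers_)
        inertia[name] = float(km.inertia_)
    return CSPModel(
        centres=np.concatenate(centres, axis=0),
        group_names=tuple(spaces.keys()),
        K=K,
        D=int(D),
        seed=seed,
        inertia=inertia,
    )


def assign_csp_labels(
    primitives: PrimitiveTable | np.ndarray, model: CSPModel
) -> np.ndarray:
    """CSP map: 1-based label of the nearest centre for each primitive.

    Ties are broken toward the smallest centre index.
    """
    X = (
        primitives.vectors_um
        if isinstance(primitives, PrimitiveTable)
        else np.asarray(primitives, dtype=float)
    )
    if X.shape[1] != model.D:
        raise ValueError(
            f"primitive dimension {X.shape[1]} does not match model D={model.D}"
        )
    dist = cdist(X, model.centres)
    return np.argmin(dist, axis=1) + 1


def csp_histogram(labels: np.ndarray, M: int) -> np.ndarray:
    """Normalized histogram h of CSP labels: h_i = proportion of label i."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("cannot build a histogram from an empty CSP map")
    if labels.min() < 1 or labels.max() > M:
        raise ValueError("labels must lie in 1..M")
    counts = np.bincount(labels - 1, minlength=M)
    return counts / labels.size


def augment_features(h: np.ndarray, indices: SpatialIndexSet, M: int) -> np.ndarray:
    """Append the 1/M-scaled spatial indices (I_r, I_theta, I_Theta) to h."""
    h = np.asarray(h, dtype=float)
    if h.shape != (M,):
        raise ValueError(f"histogram length {h.shape} does not match M={M}")
    tail = np.array([indices.I_r, indices.I_theta, indices.I_Theta]) / M
    return np.concatenate([h, tail])
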