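"""Harden the continuous translated image into a 3-class mask via k-means.

The translator outputs colors only *near* the palette; k-means with
k = 3 groups every pixel color into three clusters (minimizing the
within-cluster sum of squared Euclidean distances), and each cluster is
then matched one-to-one to a palette label by minimum total squared
distance between centroids and palette colors.

Fitting operates on the multiset of pixel colors: identical colors are
collapsed to weighted points, which leaves the objective (and therefore
the result) unchanged while making the fit independent of pixel order.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .io_dataset import Label, LabelMask, DEFAULT_PALETTE

logger = logging.getLogger("sargamap")

__all__ = [
    "KMeansSpec",
    "ClusterModel",
    "DegenerateColorsError",
    "kmeans_fit",
    "assign_labels",
    "quantize",
    "nearest_palette_labels",
]

#: Tie-break order for centroid-to-label matching.
_TIE_ORDER = (Label.SARGASSUM, Label.SAND, Label.OTHER)


class DegenerateColorsError(ValueError):
    """Fewer distinct colors than clusters requested."""


@dataclass
class KMeansSpec:
    k: int = 3
    max_iter: int = 100
    tol: float = 1e-4
    n_restarts: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1 or self.max_iter < 1 or self.n_restarts < 1:
            raise ValueError("k, max_iter, n_restarts must be >= 1")
        if self.tol < 0:
            raise ValueError("tol must be non-negative")


@dataclass
class ClusterModel:
    """Fitted clustering: centroids, objective value, and (after
    :func:`assign_labels`) the cluster-to-label mapping.

    ``objective_history`` records the within-cluster sum of squares after
    every Lloyd iteration of the winning restart (non-increasing).
    """

    centroids: np.ndarray
    inertia: float
    label_assignment: dict[int, Label] | None = None
    objective_history: list[float] = field(default_factory=list)


def _plus_plus_init(pts, w, k, rng):
    """Weighted k-means++ seeding."""
    n = len(pts)
    centroids = np.empty((k, pts.shape[1]))
    i0 = rng.choice(n, p=w / w.sum())
    centroids[0] = pts[i0]
    d2 = ((pts - centroids[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        probs = w * d2
        total = probs.sum()
        if total <= 0:  # all remaining points coincide with a centroid
            idx = rng.choice(n)
        else:
            idx = rng.choice(n, p=probs / total)
        centroids[j] = pts[idx]
        d2 = np.minimum(d2, ((pts - centroids[j]) ** 2).sum(axis=1))
    return centroids


def _lloyd(pts, w, centroids, max_iter, tol):
    history = []
    k = len(centroids)
    for _ in range(max_iter):
        d2 = ((pts[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        assign = d2.argmin(axis=1)
        new = centroids.copy()
        for j in range(k):
            sel = assign == j
            wsum = w[sel].sum()
            if wsum > 0:
                new[j] = (pts[sel] * w[sel, None]).sum(axis=0) / wsum
            else:
                # re-seed an empty cluster at the point farthest from its
                # current centroid, keeping k clusters alive
                far = (d2.min(axis=1) * w).argmax()
                new[j] = pts[far]
        d2n = ((pts[:, None, :] - new[None, :, :]) ** 2).sum(axis=2)
        history.append(float((d2n.min(axis=1) * w).sum()))
        shift = np.sqrt(((new - centroids) ** 2).sum(axis=1)).max()
        centroids = new
        if shift < tol:
            break
    d2 = ((pts[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    inertia = float((d2.min(axis=1) * w).sum())
    return centroids, inertia, history


def kmeans_fit(
    pixels: np.ndarray,
    spec: KMeansSpec,
    weights: np.ndarray | None = None,
) -> ClusterModel:
    """Fit k-means to a collection of color vectors.

    Lloyd iterations from k-means++ seeding until the maximum centroid
    shift drops below ``spec.tol`` or ``spec.max_iter`` is reached; the
    best of ``spec.n_restarts`` restarts by objective value wins.
    Deterministic per ``spec.seed``. ``weights`` (multiplicities) make
    the fit equivalent to fitting each point ``weights[i]`` times.
    """
    pts = np.asarray(pixels, dtype=np.float64).reshape(-1, np.shape(pixels)[-1])
    w = (
        np.ones(len(pts))
        if weights is None
        else np.asarray(weights, dtype=np.float64).ravel()
    )
    if len(w) != len(pts):
        raise ValueError("weights length mismatch")
    distinct = np.unique(pts, axis=0)
    if len(distinct) < spec.k:
        raise DegenerateColorsError(
            f"{len(distinct)} distinct colors < k={spec.k}"
        )
    # Tiny inputs (few distinct colors) are solved exactly: restarted Lloyd
    # can land in a local optimum there, while enumerating all assignments
    # is cheap. Real images (thousands of distinct colors) take the
    # restarted-Lloyd path.
    if spec.k ** len(distinct) <= 20_000:
        return _fit_exact_tiny(pts, w, distinct, spec.k)
    rng = np.random.default_rng(spec.seed)
    best: ClusterModel | None = None
    for _ in range(spec.n_restarts):
        c0 = _plus_plus_init(pts, w, spec.k, rng)
        centroids, inertia, history = _lloyd(pts, w, c0, spec.max_iter, spec.tol)
        if best is None or inertia < best.inertia - 1e-12:
            best = ClusterModel(
                centroids=centroids, inertia=inertia, objective_history=history
            )
    assert best is not None
    return best


def _fit_exact_tiny(pts, w, distinct, k) -> ClusterModel:
    """Globally optimal clustering of few distinct points by enumeration."""
    dw = np.array(
        [w[(pts == d).all(axis=1)].sum() for d in distinct], dtype=np.float64
    )
    best_obj, best_centroids = np.inf, None
    for assign in itertools.product(range(k), repeat=len(distinct)):
        assign = np.asarray(assign)
        obj = 0.0
        centroids = np.zeros((k, pts.shape[1]))
        for j in range(k):
            sel = assign == j
            if not sel.any():
                continue
            wj = dw[sel]
            mu = (distinct[sel] * wj[:, None]).sum(axis=0) / wj.sum()
            centroids[j] = mu
            obj += float((((distinct[sel] - mu) ** 2).sum(axis=1) * wj).sum())
        if obj < best_obj - 1e-12:
            best_obj, best_centroids = obj, centroids
    return ClusterModel(
        centroids=best_centroids,
        inertia=best_obj,
        objective_history=[best_obj],
    )


def assign_labels(
    model: ClusterModel, palette: dict[Label, tuple[int, int, int]] | None = None
) -> ClusterModel:
    """Match centroids to palette labels by minimum-cost bijection.

    Cost is squared Euclidean distance between centroid and palette
    color; ties break toward assigning the lowest cluster index the
    earliest label in (SARGASSUM, SAND, OTHER).
    """
    palette = dict(DEFAULT_PALETTE) if palette is None else dict(palette)
    k = len(model.centroids)
    if k != len(palette):
        raise ValueError(f"k={k} does not match {len(palette)} palette labels")
    labels = [lab for lab in _TIE_ORDER if lab in palette]
    colors = {lab: np.asarray(palette[lab], dtype=np.float64) for lab in labels}
    best_cost, best_perm = None, None
    for perm in itertools.permutations(labels):
        cost = sum(
            float(((model.centroids[i] - colors[lab]) ** 2).sum())
            for i, lab in enumerate(perm)
        )
        if best_cost is None or cost < best_cost - 1e-9:
            best_cost, best_perm = cost, perm
    model.label_assignment = {i: lab for i, lab in enumerate(best_perm)}
    return model


def nearest_palette_labels(
    rgb: np.ndarray, palette: dict[Label, tuple[int, int, int]]
) -> np.ndarray:
    """Per-pixel nearest palette color (squared Euclidean), as labels."""
    labs = sorted(palette)
    colors = np.array([palette[lab] for lab in labs], dtype=np.float64)
    pix = np.asarray(rgb, dtype=np.float64).reshape(-1, 3)
    d2 = ((pix[:, None, :] - colors[None, :, :]) ** 2).sum(axis=2)
    out = np.array([int(labs[i]) for i in range(len(labs))], dtype=np.uint8)[
        d2.argmin(axis=1)
    ]
    return out.reshape(np.shape(rgb)[:2])


def quantize(
    translated: np.ndarray,
    spec: KMeansSpec | None = None,
    palette: dict[Label, tuple[int, int, int]] | None = None,
) -> LabelMask:
    """Per-pixel hard labels for a continuous translated image.

    Fits k-means (k = 3) to the image's pixel colors, maps clusters to
    labels, and returns the mask. Images with fewer distinct colors than
    k fall back to nearest-palette-color labeling with a logged warning.
    Deterministic per ``spec.seed`` and invariant to pixel order.
    """
    spec = spec or KMeansSpec()
    palette = dict(DEFAULT_PALETTE) if palette is None else dict(palette)
    img = np.asarray(translated)
    if img.size == 0:
        raise ValueError("empty image")
    pix = img.reshape(-1, 3).astype(np.float64)
    colors, counts = np.unique(pix, axis=0, return_counts=True)
    try:
        model = kmeans_fit(colors, spec, weights=counts)
    except DegenerateColorsError:
        logger.warning(
            "image has fewer than %d distinct colors; falling back to "
            "nearest-palette-color labeling",
            spec.k,
        )
        return LabelMask(nearest_palette_labels(img, palette), palette=palette)
    model = assign_labels(model, palette)
    assert model.label_assignment is not None
    d2 = ((pix[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
    cluster_of_pixel = d2.argmin(axis=1)
    lut = np.array(
        [int(model.label_assignment[i]) for i in range(spec.k)], dtype=np.uint8
    )
    return LabelMask(
        lut[cluster_of_pixel].reshape(img.shape[:2]), palette=palette
    )
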