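"""Pairwise similarity between feature vectors and affinity assembly.

Each node (surface vertex, pixel, region of interest) carries a feature
vector — an fMRI time series, a tract-density profile flattened to 1-D,
or the HSV channels of a pixel.  Similarity between two such vectors can
be measured at several levels of invariance:

======================  =========================================
``dot_product``         magnitude *and* angle (confounded)
``cosine_similarity``   angle only (scale-invariant)
``pearson``             angle of the mean-centered vectors
                        (scale- and shift-invariant)
``norm_angle``          the centered angle itself, in units of 90°
                        (0 = collinear, 1 = orthogonal,
                        2 = anti-collinear)
``ang_sim``             ``1 - norm_angle``; linear in the angle, so
                        +0.5 means exactly halfway between
                        orthogonal and collinear
======================  =========================================

Spectral gradient analysis requires a *non-negative* affinity matrix.
:func:`build_affinity` assembles one under a configurable
:class:`AffinityPolicy`; the default recipe computes Pearson
correlations, discards negative ones, and maps the retained values
through the angular transform ``r -> 1 - arccos(r) * 2 / pi`` so that
all weights land in ``[0, 1]`` without an arbitrary shift constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .exceptions import DegenerateFeatureError, ParameterError, ShapeError
from .graph import AffinityMatrix

__all__ = [
    "FeatureMatrix",
    "AffinityPolicy",
    "dot_product",
    "cosine_similarity",
    "pearson",
    "norm_angle",
    "ang_sim",
    "build_affinity",
]

#: clamp tolerance for correlations drifting past +/-1 by round-off
_CLAMP_TOL = 1e-12

METRICS = ("dot", "cosine", "pearson", "ang_sim")
NEGATIVITY_POLICIES = ("zero_negatives", "shift_constant", "none")
DEGENERATE_POLICIES = ("exclude", "zero", "error")


@dataclass(frozen=True)
class FeatureMatrix:
    """Per-node feature vectors: rows are nodes, columns feature dimensions."""

    features: np.ndarray
    node_ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        f = np.asarray(self.features, dtype=float)
        if f.ndim != 2:
            raise ShapeError(f"features must be 2-D (nodes x dims), got {f.ndim}-D")
        if f.shape[1] < 2:
            raise ShapeError("need at least 2 feature dimensions per node")
        if not np.isfinite(f).all():
            raise ShapeError("features contain non-finite entries")
        object.__setattr__(self, "features", f)
        ids = self.node_ids
        ids = np.arange(f.shape[0]) if ids is None else np.asarray(ids)
        if ids.shape != (f.shape[0],):
            raise ShapeError("node_ids length must equal the number of rows")
        object.__setattr__(self, "node_ids", ids)

    @property
    def n(self) -> int:
        return self.features.shape[0]

    def degenerate_rows(self) -> np.ndarray:
        """Indices of zero-variance (constant) rows, where Pearson is undefined."""
        return np.flatnonzero(self.features.std(axis=1) == 0)


@dataclass(frozen=True)
class AffinityPolicy:
    """How pairwise similarities become a non-negative affinity matrix.

    Parameters
    ----------
    metric
        One of ``dot``, ``cosine``, ``pearson``, ``ang_sim``.
    negativity
        ``zero_negatives`` clamps negative similarities to 0 (default),
        ``shift_constant`` adds ``shift`` to every weight, ``none``
        leaves values untouched (the result must already be
        non-negative).
    angular
        After ``zero_negatives`` on a ``pearson`` metric, map each
        retained correlation ``r`` to ``1 - arccos(r) * 2 / pi``.  The
        default pipeline; keeps weights in ``[0, 1]``.
    shift
        The constant added under ``shift_constant``.  No default is
        meaningful; it must be supplied explicitly.
    threshold_eps
        Optional sparsification: weights below ``eps`` are zeroed.
        Mutually exclusive with ``knn_k``.
    knn_k
        Optional k-nearest-neighbour sparsification; symmetrized by
        union (an edge survives if either endpoint ranks the other in
        its top *k*).
    binarize
        Replace every surviving positive weight with 1.
    degenerate
        Policy for zero-variance feature rows under centered metrics:
        ``exclude`` drops the node (index map returned), ``zero``
        isolates it, ``error`` raises.
    """

    metric: str = "pearson"
    negativity: str = "zero_negatives"
    angular: bool = True
    shift: Optional[float] = None
    threshold_eps: Optional[float] = None
    knn_k: Optional[int] = None
    binarize: bool = False
    degenerate: str = "exclude"

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ParameterError(f"unknown metric {self.metric!r}")
        if self.negativity not in NEGATIVITY_POLICIES:
            raise ParameterError(f"unknown negativity policy {self.negativity!r}")
        if self.degenerate not in DEGENERATE_POLICIES:
            raise ParameterError(f"unknown degenerate-node policy {self.degenerate!r}")
        if self.threshold_eps is not None and self.knn_k is not None:
            raise ParameterError("threshold_eps and knn_k are mutually exclusive")
        if self.negativity == "shift_constant":
            if self.shift is None or self.shift < 0:
                raise ParameterError("shift_constant requires a non-negative shift")
        if self.angular and self.metric not in ("pearson", "cosine"):
            raise ParameterError("angular transform applies to pearson/cosine only")
        if self.knn_k is not None and self.knn_k < 1:
            raise ParameterError("knn_k must be a positive integer")


def _check_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ShapeError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ShapeError("non-finite entries in feature vector")
    return x, y


def dot_product(x, y) -> float:
    """Plain inner product: ``||x|| ||y|| cos(x, y)``."""
    x, y = _check_pair(x, y)
    return float(x @ y)


def cosine_similarity(x, y) -> float:
    """Dot product of the unit-normalized vectors; in ``[-1, 1]``."""
    x, y = _check_pair(x, y)
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise DegenerateFeatureError("cosine undefined for a zero-norm vector")
    return float(x @ y / (nx * ny))


def pearson(x, y) -> float:
    """Cosine similarity of the mean-centered vectors (shift-invariant)."""
    x, y = _check_pair(x, y)
    xc, yc = x - x.mean(), y - y.mean()
    nx, ny = np.linalg.norm(xc), np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        raise DegenerateFeatureError("correlation undefined for a constant vector")
    return float(xc @ yc / (nx * ny))


def _clamp_corr(r):
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1 + _CLAMP_TOL):
        raise DegenerateFeatureError(f"correlation {r} outside [-1,1] beyond round-off")
    return np.clip(r, -1.0, 1.0)


def norm_angle(x, y) -> float:
    """Centered angle between two vectors in units of 90°; in ``[0, 2]``.

    Equals ``arccos(corr(x, y))`` in degrees divided by 90, but is
    computed as ``2 * atan2(|u - v|, |u + v|)`` on the centered unit
    vectors, which stays accurate where arccos loses half the working
    precision (angles near 0 and 180°).
    """
    x, y = _check_pair(x, y)
    xc, yc = x - x.mean(), y - y.mean()
    nx, ny = np.linalg.norm(xc), np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        raise DegenerateFeatureError("angle undefined for a constant vector")
    u, v = xc / nx, yc / ny
    angle = 2.0 * np.arctan2(np.linalg.norm(u - v), np.linalg.norm(u + v))
    return float(np.degrees(angle) / 90.0)


def ang_sim(x, y) -> float:
    """Angular similarity ``1 - norm_angle``; in ``[-1, 1]`` and linear in the angle."""
    return 1.0 - norm_angle(x, y)


def _pairwise_pearson(f: np.ndarray) -> np.ndarray:
    fc = f - f.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(fc, axis=1)
    r = (fc @ fc.T) / np.outer(norms, norms)
    return np.clip(r, -1.0, 1.0)


def _pairwise_cosine(f: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(f, axis=1)
    if np.any(norms == 0):
        raise DegenerateFeatureError("zero-norm feature row under cosine metric")
    return np.clip((f @ f.T) / np.outer(norms, norms), -1.0, 1.0)


def _knn_union(w: np.ndarray, k: int) -> np.ndarray:
    """Keep w_ij iff j is among i's k largest weights OR i among j's."""
    n = w.shape[0]
    keep = np.zeros_like(w, dtype=bool)
    for i in range(n):
        order = np.argsort(w[i])[::-1]
        order = order[order != i][:k]
        keep[i, order] = True
    keep |= keep.T
    out = np.where(keep, w, 0.0)
    np.fill_diagonal(out, 0.0)
    return out


def build_affinity(
    features: FeatureMatrix | np.ndarray,
    policy: AffinityPolicy | None = None,
) -> tuple[AffinityMatrix, np.ndarray]:
    """Assemble a non-negative affinity matrix from per-node features.

    Returns
    -------
    affinity
        The resulting :class:`~vbgrad.graph.AffinityMatrix`.
    kept
        Indices (into the input rows) of the nodes present in the
        affinity.  Equal to ``arange(n)`` unless the ``exclude``
        degenerate-node policy dropped constant rows.

    Raises
    ------
    DegenerateFeatureError
        If degenerate rows are present under the ``error`` policy, or if
        fewer than 3 usable nodes remain.
    """
    if policy is None:
        policy = AffinityPolicy()
    if not isinstance(features, FeatureMatrix):
        features = FeatureMatrix(features)

    f = features.features
    kept = np.arange(features.n)

    centered = policy.metric in ("pearson", "ang_sim")
    zero_out: np.ndarray = np.array([], dtype=int)
    if centered:
        bad = features.degenerate_rows()
        if bad.size:
            if policy.degenerate == "error":
                raise DegenerateFeatureError(
                    f"constant feature rows at {bad.tolist()}; correlation undefined"
                )
            if policy.degenerate == "exclude":
                kept = np.setdiff1d(kept, bad)
                f = f[kept]
            else:  # "zero": keep the node but isolate it
                zero_out = bad
                f = f.copy()
                # center-safe placeholder; its weights are zeroed below
                f[bad] += np.arange(f.shape[1])

    if f.shape[0] < 3:
        raise DegenerateFeatureError(
            f"need at least 3 non-degenerate nodes, have {f.shape[0]}"
        )

    if policy.metric == "dot":
        w = f @ f.T
    elif policy.metric == "cosine":
        w = _pairwise_cosine(f)
    else:
        w = _pairwise_pearson(f)
        if policy.metric == "ang_sim":
            w = 1.0 - np.degrees(np.arccos(w)) / 90.0

    if policy.negativity == "zero_negatives":
        w = np.where(w < 0, 0.0, w)
        if policy.angular and policy.metric in ("pearson", "cosine"):
            w = 1.0 - np.arccos(np.clip(w, 0.0, 1.0)) * 2.0 / np.pi
            # arccos(0) maps a clamped weight to 0 again, preserving sparsity
    elif policy.negativity == "shift_constant":
        w = w + policy.shift
    else:
        if policy.angular and policy.metric in ("pearson", "cosine"):
            w = 1.0 - np.arccos(np.clip(w, -1.0, 1.0)) * 2.0 / np.pi
        if w.min(initial=0.0) < 0:
            raise ParameterError(
                "negativity='none' but the metric produced negative weights"
            )

    if zero_out.size:
        w[zero_out, :] = 0.0
        w[:, zero_out] = 0.0

    if policy.threshold_eps is not None:
        w = np.where(w < policy.threshold_eps, 0.0, w)
    np.fill_diagonal(w, 0.0)
    if policy.knn_k is not None:
        w = _knn_union(w, policy.knn_k)
    if policy.binarize:
        w = (w > 0).astype(float)

    if w.max(initial=0.0) == 0.0:
        warnings.warn(
            "affinity is identically zero (fully disconnected graph)",
            stacklevel=2,
        )
    return AffinityMatrix(w), kept


def default_policy(**overrides) -> AffinityPolicy:
    """The default recipe: Pearson, zero negatives, angular transform."""
    return replace(AffinityPolicy(), **overrides)
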