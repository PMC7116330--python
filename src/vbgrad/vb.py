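"""The Vogt-Bailey index: normalized algebraic connectivity.

The algebraic connectivity (second-smallest Laplacian eigenvalue,
``lambda_2``) of an affinity graph measures how hard the graph is to
cut: it is zero iff the graph is disconnected, and grows as the graph
becomes more uniformly connected.  The VB index normalizes it into
``[0, 1]`` by dividing by the mean of all eigenvalues except the first::

    VB = lambda_2 / mean(lambda_2, ..., lambda_n)

The denominator is the value ``lambda_2`` attains on the uniform
complete graph (affinity of all ones off the diagonal), so VB = 1 means
the region is perfectly homogeneous and VB = 0 means a complete split
exists.  The normalization uses the eigenvalues of the *same*
eigenproblem that produced ``lambda_2`` (standard, generalized, or a
normalized variant), which preserves the [0, 1] bound in every variant.

Three analysis modes mirror how the index is used on cortical data:

``full_analysis``
    one affinity over all nodes; a single VB value and a whole-surface
    gradient map.
``clustered_analysis``
    a VB value and gradient per region of interest.
``searchlight_analysis``
    a VB value per vertex from the affinity of the vertex plus its
    one-ring neighbours — effectively a cortical edge detector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .exceptions import DegenerateFeatureError, ShapeError
from .graph import AffinityMatrix
from .similarity import AffinityPolicy, FeatureMatrix, build_affinity
from .spectral import GradientMap, fiedler, gradient_map, solve_affinity
from .surface import SurfaceMesh, VertexMask, one_ring

__all__ = [
    "VBResult",
    "vb_index",
    "full_analysis",
    "clustered_analysis",
    "searchlight_analysis",
]

_VB_CLAMP = 1e-8


@dataclass
class VBResult:
    """Output of one VB analysis.

    ``vb`` is a scalar for ``full`` mode, a ``{cluster_id: value}`` dict
    for ``clustered`` mode (missing clusters map to NaN), and a length-n
    vector with NaN at undefined vertices for ``searchlight`` mode.
    ``vertex_vb`` always provides the per-vertex expansion suitable for
    writing onto a surface.
    """

    mode: str
    vb: object
    problem: str
    gradient: Optional[GradientMap] = None
    cluster_gradients: Optional[dict] = None
    vertex_vb: Optional[np.ndarray] = None
    neighborhood_sizes: Optional[np.ndarray] = None
    kept: Optional[np.ndarray] = field(default=None, repr=False)


def vb_index(affinity: AffinityMatrix | np.ndarray, problem: str = "generalized") -> float:
    """Normalized algebraic connectivity of an affinity graph, in [0, 1].

    Parameters
    ----------
    affinity
        Symmetric non-negative weights over >= 3 nodes.
    problem
        ``standard`` (``L x = lambda x``), ``generalized``
        (``L x = lambda D x``, the default), ``symmetric_normalized`` or
        ``random_walk``.

    Notes
    -----
    A graph with an isolated (degree-0) node, or with no edges at all,
    is disconnected, so its algebraic connectivity — and hence its VB
    index — is 0; this is returned directly rather than raising, since
    the singular degree matrix only obstructs the *computation*, not the
    value.  Tiny negative ``lambda_2`` from round-off is clamped to 0.
    """
    if not isinstance(affinity, AffinityMatrix):
        affinity = AffinityMatrix(affinity)
    if affinity.n < 3:
        raise ShapeError(f"VB index needs >= 3 nodes, got {affinity.n}")
    degrees = affinity.weights.sum(axis=1)
    if np.all(degrees == 0):
        warnings.warn("graph has no edges; VB index is 0", stacklevel=2)
        return 0.0
    if problem != "standard" and np.any(degrees == 0):
        # disconnected by an isolated node: algebraic connectivity is 0
        return 0.0
    sol = solve_affinity(affinity, problem=problem)
    lam = sol.eigenvalues
    denom = lam[1:].mean()
    if denom <= 0:
        return 0.0
    vb = float(lam[1] / denom)
    if vb < 0:
        if vb < -_VB_CLAMP:
            warnings.warn(f"negative VB {vb:g} beyond round-off; clamping", stacklevel=2)
        vb = 0.0
    return min(vb, 1.0) if vb <= 1.0 + _VB_CLAMP else vb


def full_analysis(
    features: FeatureMatrix | np.ndarray,
    policy: AffinityPolicy | None = None,
    problem: str = "generalized",
    d: int = 1,
) -> VBResult:
    """Single affinity over all nodes: one VB value plus a gradient map.

    ``d`` is the number of embedding dimensions retained in the gradient
    (eigenvectors 2..d+1).  Nodes dropped by the degenerate-feature
    policy appear as NaN in ``vertex_vb``; ``kept`` maps gradient rows
    back to input rows.
    """
    if not isinstance(features, FeatureMatrix):
        features = FeatureMatrix(features)
    aff, kept = build_affinity(features, policy)
    vb = vb_index(aff, problem=problem)
    sol = solve_affinity(aff, problem=problem) if _solvable(aff, problem) else None
    grad = gradient_map(sol, d) if sol is not None else None
    vertex_vb = np.full(features.n, np.nan)
    vertex_vb[kept] = vb
    return VBResult(
        mode="full", vb=vb, problem=problem, gradient=grad,
        vertex_vb=vertex_vb, kept=kept,
    )


def _solvable(aff: AffinityMatrix, problem: str) -> bool:
    d = aff.weights.sum(axis=1)
    if problem == "standard":
        return True
    return bool(np.all(d > 0))


def clustered_analysis(
    features: FeatureMatrix | np.ndarray,
    labels: np.ndarray,
    policy: AffinityPolicy | None = None,
    problem: str = "generalized",
    d: int = 1,
) -> VBResult:
    """A VB value and gradient per region of interest.

    ``labels`` assigns each node a non-negative integer cluster id; 0
    means unassigned.  Clusters with fewer than 3 members are reported
    as NaN with a warning rather than aborting the run.
    """
    if not isinstance(features, FeatureMatrix):
        features = FeatureMatrix(features)
    labels = np.asarray(labels, dtype=int).ravel()
    if labels.shape[0] != features.n:
        raise ShapeError(
            f"labels has {labels.shape[0]} entries for {features.n} nodes"
        )
    ids = np.unique(labels)
    ids = ids[ids > 0]
    vb_by_cluster: dict[int, float] = {}
    grads: dict[int, GradientMap] = {}
    vertex_vb = np.full(features.n, np.nan)
    for cid in ids:
        members = np.flatnonzero(labels == cid)
        if members.size < 3:
            warnings.warn(
                f"cluster {cid} has {members.size} member(s) (< 3); VB undefined",
                stacklevel=2,
            )
            vb_by_cluster[int(cid)] = float("nan")
            continue
        sub = FeatureMatrix(features.features[members])
        try:
            aff, kept = build_affinity(sub, policy)
        except DegenerateFeatureError:
            vb_by_cluster[int(cid)] = float("nan")
            continue
        vb = vb_index(aff, problem=problem)
        vb_by_cluster[int(cid)] = vb
        if _solvable(aff, problem):
            sol = solve_affinity(aff, problem=problem)
            grads[int(cid)] = gradient_map(sol, min(d, aff.n - 1))
        vertex_vb[members[kept]] = vb
    return VBResult(
        mode="clustered", vb=vb_by_cluster, problem=problem,
        cluster_gradients=grads, vertex_vb=vertex_vb,
    )


def _searchlight_one(
    f: np.ndarray, nb: np.ndarray, policy: AffinityPolicy | None, problem: str,
    center: int,
) -> float:
    """VB index of one neighbourhood; NaN when the center drops out."""
    try:
        aff, kept = build_affinity(FeatureMatrix(f[nb]), policy)
    except DegenerateFeatureError:
        return float("nan")
    if center not in nb[kept]:
        return float("nan")
    return vb_index(aff, problem=problem)


def searchlight_analysis(
    features: FeatureMatrix | np.ndarray,
    mesh: SurfaceMesh | None = None,
    mask: VertexMask | np.ndarray | None = None,
    policy: AffinityPolicy | None = None,
    problem: str = "generalized",
    jobs: int = 1,
    adjacency: Optional[list] = None,
) -> VBResult:
    """Vertex-wise VB index over one-ring neighbourhoods.

    For every masked, non-orphan vertex the neighbourhood is the vertex
    itself plus its directly adjacent (one-ring) vertices, intersected
    with the mask.  Neighbourhoods reduced below 3 vertices yield NaN so
    that mask borders (e.g. the medial wall) do not abort a run.

    Instead of a mesh, precomputed per-node ``adjacency`` lists may be
    supplied (e.g. a pixel lattice); exactly one of the two is required.

    ``jobs`` distributes vertices over processes via joblib; results are
    identical to the serial path regardless of ``jobs``.
    """
    if not isinstance(features, FeatureMatrix):
        features = FeatureMatrix(features)
    if (mesh is None) == (adjacency is None):
        raise ShapeError("supply exactly one of mesh or adjacency")
    if mesh is not None:
        if features.n != mesh.n_vertices:
            raise ShapeError(
                f"features has {features.n} rows but mesh has "
                f"{mesh.n_vertices} vertices"
            )
        ring = one_ring(mesh)
        orphans = set(mesh.orphan_vertices().tolist())
    else:
        if len(adjacency) != features.n:
            raise ShapeError(
                f"adjacency has {len(adjacency)} entries for {features.n} nodes"
            )
        ring = [np.asarray(a, dtype=int) for a in adjacency]
        orphans = {v for v, a in enumerate(ring) if len(a) == 0}
    n = features.n
    if mask is None:
        included = np.ones(n, dtype=bool)
    else:
        if not isinstance(mask, VertexMask):
            mask = VertexMask(mask)
        if mask.n != n:
            raise ShapeError(
                f"mask has {mask.n} entries but there are {n} nodes"
            )
        included = mask.included

    f = features.features
    neighborhoods: list[Optional[np.ndarray]] = []
    sizes = np.zeros(n, dtype=int)
    for v in range(n):
        if not included[v] or v in orphans:
            neighborhoods.append(None)
            continue
        nb = np.concatenate(([v], ring[v][included[ring[v]]]))
        sizes[v] = nb.size
        neighborhoods.append(nb if nb.size >= 3 else None)

    centers = [v for v in range(n) if neighborhoods[v] is not None]
    if jobs == 1:
        values = [
            _searchlight_one(f, neighborhoods[v], policy, problem, v) for v in centers
        ]
    else:
        from joblib import Parallel, delayed

        values = Parallel(n_jobs=jobs)(
            delayed(_searchlight_one)(f, neighborhoods[v], policy, problem, v)
            for v in centers
        )

    vb = np.full(n, np.nan)
    for v, val in zip(centers, values):
        vb[v] = val
    return VBResult(
        mode="searchlight", vb=vb, problem=problem,
        vertex_vb=vb, neighborhood_sizes=sizes,
    )
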