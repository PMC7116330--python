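"""Synthetic inputs with known ground truth.

Everything here is deterministic given a seed, so every stage of the
pipeline is testable without external data:

* :func:`parcellate_mesh` — contiguous parcels on a mesh by seeded
  farthest-point sampling plus balanced region growing;
* :func:`parcel_timeseries` — one shared time series per parcel with an
  exactly controlled cross-parcel correlation, emulating a piecewise-
  homogeneous cortex (each vertex optionally gets independent additive
  noise);
* :func:`toy_graphs` — small named affinity fixtures with closed-form
  spectra;
* :func:`test_image` — rasters with known edge structure for the
  pixel-searchlight demonstration.
"""

from __future__ import annotations

from dataclasses import dataclass
from heapq import heappop, heappush

import numpy as np

from .exceptions import ParameterError
from .graph import AffinityMatrix
from .similarity import FeatureMatrix
from .surface import ClusterLabels, SurfaceMesh, one_ring

__all__ = [
    "SyntheticSpec",
    "parcellate_mesh",
    "parcel_timeseries",
    "toy_graphs",
    "test_image",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the parcellated-time-series generator.

    ``cross_corr`` is the target Pearson correlation between the base
    series of two distinct parcels (exact by construction, up to
    round-off).  ``noise_sd`` is the standard deviation of independent
    Gaussian noise added per vertex; 0 reproduces the exact-copy design
    where all vertices of a parcel share one identical series.
    """

    n_parcels: int = 6
    series_length: int = 200
    cross_corr: float = 0.3
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_parcels < 2:
            raise ParameterError("need at least 2 parcels")
        if self.series_length < 8:
            raise ParameterError("series_length must be >= 8")
        if not 0.0 <= self.cross_corr <= 0.9:
            raise ParameterError("cross_corr must be in [0, 0.9]")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")


def parcellate_mesh(mesh: SurfaceMesh, n_parcels: int, seed: int = 0) -> ClusterLabels:
    """Split a mesh into contiguous, non-empty parcels (labels 1..P).

    Parcel seeds are chosen by farthest-point sampling (first seed
    random, each next seed maximizing Euclidean distance to the chosen
    set), then parcels grow by balanced breadth-first expansion over the
    one-ring graph: at each step the currently smallest parcel claims an
    unlabeled frontier vertex.  Every parcel is connected in the
    one-ring graph by construction.
    """
    n = mesh.n_vertices
    if n_parcels < 1:
        raise ParameterError("n_parcels must be >= 1")
    if n_parcels > 1 and n_parcels > n // 10:
        raise ParameterError(
            f"{n_parcels} parcels on {n} vertices: need n_parcels <= n/10"
        )
    rng = np.random.default_rng(seed)
    labels = np.zeros(n, dtype=int)
    if n_parcels == 1:
        labels[:] = 1
        return ClusterLabels(labels)

    # farthest-point sampling of parcel seeds
    v = mesh.vertices
    first = int(rng.integers(n))
    seeds = [first]
    dist = np.linalg.norm(v - v[first], axis=1)
    for _ in range(n_parcels - 1):
        nxt = int(np.argmax(dist))
        seeds.append(nxt)
        dist = np.minimum(dist, np.linalg.norm(v - v[nxt], axis=1))

    ring = one_ring(mesh)
    sizes = np.zeros(n_parcels + 1, dtype=int)
    # per-parcel priority frontier: (insertion order, vertex) keeps growth
    # deterministic; parcels take turns smallest-first
    frontiers: list[list[tuple[int, int]]] = [[] for _ in range(n_parcels + 1)]
    counter = 0
    for p, s in enumerate(seeds, start=1):
        labels[s] = p
        sizes[p] = 1
        for u in ring[s]:
            heappush(frontiers[p], (counter, int(u)))
            counter += 1

    remaining = n - n_parcels
    while remaining:
        # the smallest parcel with a non-empty frontier grows next
        order = np.argsort(sizes[1:], kind="stable") + 1
        grew = False
        for p in order:
            while frontiers[p]:
                _, u = heappop(frontiers[p])
                if labels[u] == 0:
                    labels[u] = p
                    sizes[p] += 1
                    remaining -= 1
                    for w in ring[u]:
                        if labels[w] == 0:
                            heappush(frontiers[p], (counter, int(w)))
                            counter += 1
                    grew = True
                    break
            if grew:
                break
        if not grew:
            raise ParameterError(
                "region growing stalled; mesh has unreachable vertices"
            )
    return ClusterLabels(labels)


def _correlated_base_series(
    n_parcels: int, length: int, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean unit-norm base series with controlled pairwise correlation.

    Pairwise targets are ``rho`` plus a small seeded jitter (at most
    ±0.04, shrunk further when ``rho`` is close to 1 so the target
    correlation matrix stays positive definite).  The jitter mirrors the
    spread of sample correlations a common-component construction would
    produce, and breaks the exact permutation symmetry that identical
    off-diagonal correlations would impose on the parcel-level graph —
    under that symmetry the Fiedler eigenvalue is degenerate and the
    gradient between parcels is not identifiable.

    The series are built exactly: an orthonormal zero-mean basis ``Q``
    (so Pearson equals the plain inner product) mixed by the Cholesky
    factor of the target correlation matrix.
    """
    if n_parcels >= length:
        raise ParameterError(
            f"series_length {length} too short for {n_parcels} orthonormal parcels"
        )
    jitter = min(0.04, (1.0 - rho) / (2.0 * max(n_parcels - 1, 1)))
    C = np.full((n_parcels, n_parcels), rho)
    off = rng.uniform(-jitter, jitter, size=(n_parcels, n_parcels))
    off = np.triu(off, 1)
    C += off + off.T
    np.fill_diagonal(C, 1.0)
    chol = np.linalg.cholesky(C)

    raw = rng.standard_normal((length, n_parcels))
    raw -= raw.mean(axis=0, keepdims=True)
    q, r = np.linalg.qr(raw)
    q = q * np.sign(np.diag(r))  # fix QR sign ambiguity for determinism
    return chol @ q.T  # parcels x length; Gram matrix is exactly C


def parcel_timeseries(labels: ClusterLabels, spec: SyntheticSpec) -> FeatureMatrix:
    """Assign each vertex its parcel's base series plus optional noise.

    With ``noise_sd = 0`` all vertices of a parcel carry bit-identical
    copies, so within-parcel Pearson correlations are exactly 1 and the
    whole-surface affinity has a block structure determined solely by
    the parcel-level correlations.
    """
    ids = labels.cluster_ids()
    if ids.size != spec.n_parcels:
        raise ParameterError(
            f"labels contain {ids.size} parcels but spec says {spec.n_parcels}"
        )
    rng = np.random.default_rng(spec.seed)
    base = _correlated_base_series(
        spec.n_parcels, spec.series_length, spec.cross_corr, rng
    )
    features = np.zeros((labels.n, spec.series_length))
    for i, cid in enumerate(ids):
        features[labels.labels == cid] = base[i]
    if spec.noise_sd > 0:
        features = features + spec.noise_sd * rng.standard_normal(features.shape)
    return FeatureMatrix(features)


def toy_graphs() -> dict[str, AffinityMatrix]:
    """Named small affinity fixtures with known spectra.

    ``fig1``
        the 4-node graph with edges a-b, a-c, a-d, b-c; degree sequence
        (3, 2, 2, 1) and Laplacian eigenvalues {0, 1, 3, 4}.
    ``path3``
        the 3-path a-b-c (algebraic connectivity 1).
    ``k4``
        the complete unit-weight graph on 4 nodes.
    ``disjoint_edges``
        two disjoint unit-weight edges on 4 nodes (disconnected).
    ``uniform_n`` (n = 4..10)
        complete unit-weight graphs; the VB-index ceiling fixtures.
    """
    out: dict[str, AffinityMatrix] = {}
    fig1 = np.array(
        [
            [0, 1, 1, 1],
            [1, 0, 1, 0],
            [1, 1, 0, 0],
            [1, 0, 0, 0],
        ],
        dtype=float,
    )
    out["fig1"] = AffinityMatrix(fig1)
    out["path3"] = AffinityMatrix(
        np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
    )
    k4 = np.ones((4, 4)) - np.eye(4)
    out["k4"] = AffinityMatrix(k4)
    out["disjoint_edges"] = AffinityMatrix(
        np.array(
            [[0, 1, 0, 0], [1, 0, 0, 0], [0, 0, 0, 1], [0, 0, 1, 0]], dtype=float
        )
    )
    for n in range(4, 11):
        out[f"uniform_{n}"] = AffinityMatrix(np.ones((n, n)) - np.eye(n))
    return out


def test_image(kind: str, size: int = 32, seed: int = 0) -> np.ndarray:
    """Deterministic RGB rasters (uint8, size x size x 3) with known edges.

    ``two_tone``
        one straight vertical boundary at column ``size // 2`` between
        two flat colors.
    ``gradient_ramp``
        a smooth left-to-right intensity ramp with no sharp boundary.
    ``blocks``
        a 2 x 2 partition into four flat-colored quadrants.
    """
    if size < 8:
        raise ParameterError("size must be >= 8")
    rng = np.random.default_rng(seed)
    # saturated palette keeps hue/saturation/value contrasts strong no
    # matter which entries the seed picks
    palette = np.array(
        [
            [200, 40, 40],   # red
            [40, 170, 60],   # green
            [40, 70, 210],   # blue
            [220, 180, 40],  # yellow
            [160, 40, 190],  # purple
            [40, 190, 190],  # cyan
        ],
        dtype=np.uint8,
    )
    img = np.zeros((size, size, 3), dtype=np.uint8)
    if kind == "two_tone":
        i, j = rng.choice(len(palette), size=2, replace=False)
        img[:, : size // 2] = palette[i]
        img[:, size // 2 :] = palette[j]
    elif kind == "gradient_ramp":
        ramp = np.linspace(40, 215, size).astype(np.uint8)
        img[:] = ramp[None, :, None]
    elif kind == "blocks":
        picks = rng.choice(len(palette), size=4, replace=False)
        h = size // 2
        img[:h, :h] = palette[picks[0]]
        img[:h, h:] = palette[picks[1]]
        img[h:, :h] = palette[picks[2]]
        img[h:, h:] = palette[picks[3]]
    else:
        raise ParameterError(f"unknown image kind {kind!r}")
    return img
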