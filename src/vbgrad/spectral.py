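"""Laplacian eigenproblems and gradient representations.

The embedding that places strongly-similar nodes close together on a
line minimizes the quadratic cost ``U(x) = sum_ij W_ij (x_i - x_j)^2``
subject to a normalization constraint.  With ``x^T x = 1`` the
stationarity condition is the standard eigenproblem ``L x = lambda x``;
with the degree-weighted constraint ``x^T D x = 1`` it becomes the
generalized problem ``L x = lambda D x``, which compensates for the
tendency of high-degree nodes to dominate the embedding.

The eigenvector paired with the second-smallest eigenvalue — the
Fiedler vector — is the optimal one-dimensional embedding (the first
eigenpair is the trivial constant solution at eigenvalue 0).  Higher
eigenvectors extend the embedding to more dimensions; the first three
non-trivial ones can be rendered as an RGB map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.linalg

from .exceptions import DegenerateDegreeError, ParameterError, ShapeError
from .graph import AffinityMatrix, DegreeMatrix, Laplacian, laplacian

__all__ = [
    "EigenSolution",
    "GradientMap",
    "solve_eigenproblem",
    "solve_affinity",
    "fiedler",
    "spectral_reorder",
    "eigenmap_coords",
    "rgb_map",
    "gradient_map",
]

PROBLEMS = ("standard", "generalized", "symmetric_normalized", "random_walk")

#: relative gap below which lambda_2 is flagged as degenerate (repeated)
_DEGENERACY_RTOL = 1e-10


@dataclass(frozen=True)
class EigenSolution:
    """Full ascending eigendecomposition of a Laplacian problem.

    ``eigenvectors[:, i]`` pairs with ``eigenvalues[i]``.  For the
    generalized problem the vectors satisfy ``x^T D x = 1``; otherwise
    ``x^T x = 1``.  ``degenerate_fiedler`` is set when the second and
    third eigenvalues coincide within round-off, in which case the
    Fiedler vector is only defined up to rotation within its eigenspace.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    problem: str
    degenerate_fiedler: bool = False

    @property
    def n(self) -> int:
        return self.eigenvalues.shape[0]


@dataclass(frozen=True)
class GradientMap:
    """Embedding coordinates plus their visualization transforms.

    ``coords`` holds eigenvectors 2..d+1 (column 0 is the Fiedler
    vector); ``ranks`` is its spectral reordering; ``rgb`` is the
    min-max-scaled first three dimensions when ``d >= 3``.
    """

    coords: np.ndarray
    ranks: np.ndarray
    rgb: Optional[np.ndarray] = None

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def d(self) -> int:
        return self.coords.shape[1]


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive.

    Ties between exactly opposite extreme entries are broken by making
    the lowest-index extreme entry positive, so the convention is a
    deterministic function of the eigenspace.
    """
    vecs = vecs.copy()
    for j in range(vecs.shape[1]):
        col = vecs[:, j]
        i = int(np.argmax(np.abs(col)))  # argmax takes the lowest index on ties
        if col[i] < 0:
            vecs[:, j] = -col
    return vecs


def solve_eigenproblem(
    lap: Laplacian,
    degrees: DegreeMatrix | None = None,
    problem: str = "generalized",
) -> EigenSolution:
    """Solve a Laplacian eigenproblem, returning all eigenpairs ascending.

    Parameters
    ----------
    lap
        An *unnormalized* Laplacian for the ``standard`` and
        ``generalized`` problems; the matching normalized Laplacian for
        ``symmetric_normalized`` / ``random_walk``.
    degrees
        Node degrees; defaults to those stored on ``lap``.
    problem
        Which constraint/normalization to use.  ``generalized`` solves
        ``L x = lambda D x`` with ``x^T D x = 1``; ``random_walk``
        solves the (similar) ``D^{-1} L`` operator and shares its
        spectrum with the generalized problem.

    Notes
    -----
    The generalized and random-walk problems are solved through the
    symmetric form ``D^{-1/2} L D^{-1/2}`` and back-transformed, which
    keeps the solver symmetric-definite and the eigenvalues real.
    """
    if problem not in PROBLEMS:
        raise ParameterError(f"unknown eigenproblem {problem!r}; expected {PROBLEMS}")
    if degrees is None:
        degrees = lap.degrees
    d = degrees.degrees
    L = lap.matrix
    if L.shape[0] != d.shape[0]:
        raise ShapeError(
            f"Laplacian is {L.shape[0]}x{L.shape[0]} but degrees has {d.shape[0]} entries"
        )

    if problem == "standard":
        if lap.variant != "unnormalized":
            raise ParameterError("standard problem expects the unnormalized Laplacian")
        vals, vecs = scipy.linalg.eigh(L)
    elif problem == "symmetric_normalized":
        Ls = L
        if lap.variant == "unnormalized":
            if np.any(d == 0):
                raise DegenerateDegreeError("degree-0 node: symmetric form undefined")
            inv_sqrt = 1.0 / np.sqrt(d)
            Ls = L * inv_sqrt[:, None] * inv_sqrt[None, :]
        elif lap.variant != "symmetric":
            raise ParameterError("symmetric_normalized expects unnormalized or symmetric input")
        vals, vecs = scipy.linalg.eigh(Ls)
    else:  # generalized / random_walk share the spectrum of D^{-1} L
        if lap.variant == "random_walk":
            # recover L = D * L_rw for the symmetric-form solve
            L = L * d[:, None]
        elif lap.variant != "unnormalized":
            raise ParameterError(f"{problem} expects the unnormalized Laplacian")
        if np.any(d <= 0):
            raise DegenerateDegreeError(
                "degree-0 node makes D singular; apply an isolated-node policy upstream"
            )
        inv_sqrt = 1.0 / np.sqrt(d)
        Ls = L * inv_sqrt[:, None] * inv_sqrt[None, :]
        Ls = (Ls + Ls.T) / 2.0
        vals, vecs = scipy.linalg.eigh(Ls)
        vecs = vecs * inv_sqrt[:, None]  # y -> D^{-1/2} y, giving x^T D x = 1

    order = np.argsort(vals, kind="stable")
    vals = vals[order]
    vecs = _fix_signs(vecs[:, order])
    degenerate = False
    if len(vals) >= 3:
        scale = max(abs(vals[-1]), 1.0)
        degenerate = (vals[2] - vals[1]) < _DEGENERACY_RTOL * scale
    return EigenSolution(vals, vecs, problem, degenerate)


def solve_affinity(
    affinity: AffinityMatrix | np.ndarray,
    problem: str = "generalized",
) -> EigenSolution:
    """Convenience path: affinity -> degrees -> Laplacian -> eigensolution.

    Degree-zero nodes raise :class:`DegenerateDegreeError` under any
    normalized problem; drop them (or the features that created them)
    before building the affinity.
    """
    if not isinstance(affinity, AffinityMatrix):
        affinity = AffinityMatrix(affinity)
    lap = laplacian(affinity, "unnormalized")
    return solve_eigenproblem(lap, problem=problem)


def fiedler(solution: EigenSolution) -> tuple[float, np.ndarray]:
    """The algebraic connectivity and its eigenvector.

    Returns ``(lambda_2, x_2)``.  ``lambda_2 = 0`` iff the graph is
    disconnected; larger values mean the graph is harder to cut.
    """
    if solution.n < 2:
        raise ShapeError("Fiedler pair needs at least 2 nodes")
    return float(solution.eigenvalues[1]), solution.eigenvectors[:, 1]


def spectral_reorder(fiedler_vector: np.ndarray) -> np.ndarray:
    """Ordinal ranks (1..n) of the Fiedler-vector entries, ascending.

    Invariant under any strictly increasing transform of the vector;
    ties are broken by node index (stable sort).
    """
    v = np.asarray(fiedler_vector, dtype=float).ravel()
    if not np.isfinite(v).all():
        raise ShapeError("non-finite entries in Fiedler vector")
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v), dtype=int)
    ranks[order] = np.arange(1, len(v) + 1)
    return ranks


def eigenmap_coords(solution: EigenSolution, d: int) -> np.ndarray:
    """Embedding coordinates: eigenvectors 2..d+1 as columns."""
    if not 1 <= d <= solution.n - 1:
        raise ParameterError(f"d must be in [1, {solution.n - 1}], got {d}")
    return solution.eigenvectors[:, 1 : d + 1]


def rgb_map(coords: np.ndarray) -> np.ndarray:
    """Min-max scale three embedding dimensions into RGB channels.

    Each column is scaled to ``[0, 1]`` independently; a constant column
    (degenerate range) maps to 0.5 everywhere.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ShapeError(f"rgb_map expects n x 3 coords, got {coords.shape}")
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    span = hi - lo
    out = np.full_like(coords, 0.5)
    ok = span > 0
    out[:, ok] = (coords[:, ok] - lo[ok]) / span[ok]
    return out


def gradient_map(solution: EigenSolution, d: int) -> GradientMap:
    """Bundle coordinates, spectral reordering, and (if d >= 3) RGB."""
    coords = eigenmap_coords(solution, d)
    ranks = spectral_reorder(coords[:, 0])
    rgb = rgb_map(coords[:, :3]) if d >= 3 else None
    return GradientMap(coords, ranks, rgb)
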