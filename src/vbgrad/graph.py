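"""Weighted graphs as matrices: affinity, degree, and Laplacian.

A graph over *n* nodes is represented by a symmetric, non-negative
``n x n`` affinity (weighted adjacency) matrix ``W`` with a zero
diagonal.  The degree of node *i* is the *i*-th row sum of ``W`` and the
(unnormalized) graph Laplacian is ``L = D - W`` with ``D = diag(degrees)``.
Two degree-normalized variants are provided:

``symmetric``
    ``D^{-1/2} L D^{-1/2}`` — symmetric, unit diagonal on non-isolated
    nodes.
``random_walk``
    ``D^{-1} L`` — row sums zero; its spectrum equals that of the
    generalized problem ``L x = lambda D x``.

Self-loops are excluded by construction: the diagonal of every affinity
matrix is forced to zero before degrees are computed.  Self-similarity
would cancel in ``D - W`` but would inflate the normalized variants and
the ceiling used by the VB-index normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateDegreeError, ShapeError, SymmetryError

__all__ = [
    "AffinityMatrix",
    "DegreeMatrix",
    "Laplacian",
    "degree_matrix",
    "laplacian",
    "read_affinity_csv",
    "write_affinity_csv",
]

SYMMETRY_TOL = 1e-10

LAPLACIAN_VARIANTS = ("unnormalized", "symmetric", "random_walk")


@dataclass(frozen=True)
class AffinityMatrix:
    """Symmetric non-negative weighted adjacency matrix with zero diagonal.

    Parameters
    ----------
    weights
        Square array of pairwise similarity weights.  Must be symmetric
        within ``1e-10`` and entry-wise non-negative.  The diagonal is
        zeroed on construction (self-loops are excluded); any other
        violation raises rather than being silently repaired, since
        asymmetry or negativity indicates a bug upstream.
    """

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ShapeError(f"affinity must be square, got shape {w.shape}")
        if not np.isfinite(w).all():
            raise ShapeError("affinity contains non-finite entries")
        if np.abs(w - w.T).max(initial=0.0) > SYMMETRY_TOL:
            raise SymmetryError(
                "affinity asymmetric beyond 1e-10; symmetrize explicitly upstream"
            )
        if w.size and w.min() < 0:
            raise ShapeError(f"affinity has negative entries (min {w.min():g})")
        w = w.copy()
        np.fill_diagonal(w, 0.0)
        w.flags.writeable = False
        object.__setattr__(self, "weights", w)

    @property
    def n(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class DegreeMatrix:
    """Node degrees (row sums of the affinity), stored as a vector."""

    degrees: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.degrees, dtype=float)
        if d.ndim != 1:
            raise ShapeError("degrees must be a vector")
        object.__setattr__(self, "degrees", d)

    @property
    def n(self) -> int:
        return self.degrees.shape[0]

    def as_matrix(self) -> np.ndarray:
        return np.diag(self.degrees)


@dataclass(frozen=True)
class Laplacian:
    """A graph Laplacian in one of three variants, with its degrees."""

    matrix: np.ndarray
    variant: str
    degrees: DegreeMatrix = field(repr=False)

    def __post_init__(self) -> None:
        if self.variant not in LAPLACIAN_VARIANTS:
            raise ShapeError(
                f"unknown Laplacian variant {self.variant!r}; "
                f"expected one of {LAPLACIAN_VARIANTS}"
            )

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def degree_matrix(affinity: AffinityMatrix) -> DegreeMatrix:
    """Row-wise sum of the affinity matrix.

    For an unweighted graph this is the classical node degree (number of
    adjacent nodes); for a weighted graph it is the total weight incident
    on each node.
    """
    if not isinstance(affinity, AffinityMatrix):
        affinity = AffinityMatrix(affinity)
    return DegreeMatrix(affinity.weights.sum(axis=1))


def laplacian(
    affinity: AffinityMatrix,
    variant: str = "unnormalized",
    isolated: str = "error",
) -> Laplacian:
    """Build a graph Laplacian from an affinity matrix.

    Parameters
    ----------
    affinity
        The graph.
    variant
        ``"unnormalized"`` (``L = D - W``), ``"symmetric"``
        (``D^{-1/2} L D^{-1/2}``), or ``"random_walk"`` (``D^{-1} L``).
    isolated
        Policy for degree-zero nodes under a normalized variant:
        ``"error"`` (default) raises :class:`DegenerateDegreeError`;
        ``"drop"`` removes them (the kept-node index map is attached to
        the result as ``kept_nodes``).

    Notes
    -----
    Degree-zero nodes are harmless for the unnormalized variant (their
    Laplacian row is zero) but make ``D`` singular for the normalized
    ones, hence the policy.
    """
    if not isinstance(affinity, AffinityMatrix):
        affinity = AffinityMatrix(affinity)
    if variant not in LAPLACIAN_VARIANTS:
        raise ShapeError(
            f"unknown Laplacian variant {variant!r}; expected one of {LAPLACIAN_VARIANTS}"
        )
    deg = degree_matrix(affinity)
    w = affinity.weights
    d = deg.degrees
    kept = None
    if variant != "unnormalized" and np.any(d == 0):
        if isolated == "drop":
            kept = np.flatnonzero(d > 0)
            w = w[np.ix_(kept, kept)]
            d = w.sum(axis=1)
            if np.any(d == 0):
                # dropping can orphan further nodes; iterate until stable
                while np.any(d == 0):
                    sub = np.flatnonzero(d > 0)
                    kept = kept[sub]
                    w = w[np.ix_(sub, sub)]
                    d = w.sum(axis=1)
            deg = DegreeMatrix(d)
        elif isolated == "error":
            idx = np.flatnonzero(d == 0)
            raise DegenerateDegreeError(
                f"nodes {idx.tolist()} have degree 0; normalized Laplacian "
                "undefined (set isolated='drop' to remove them)"
            )
        else:
            raise ShapeError(f"unknown isolated-node policy {isolated!r}")
        warnings.warn(
            f"dropped {affinity.n - len(d)} isolated node(s) for "
            f"{variant} Laplacian",
            stacklevel=2,
        )

    lap = np.diag(d) - w
    if variant == "symmetric":
        inv_sqrt = 1.0 / np.sqrt(d)
        lap = lap * inv_sqrt[:, None] * inv_sqrt[None, :]
    elif variant == "random_walk":
        lap = lap / d[:, None]

    out = Laplacian(lap, variant, DegreeMatrix(d) if kept is not None else deg)
    if kept is not None:
        object.__setattr__(out, "kept_nodes", kept)  # type: ignore[attr-defined]
    return out


def write_affinity_csv(path, affinity: AffinityMatrix) -> None:
    """Plain comma-separated dump (no header) for debugging."""
    np.savetxt(path, affinity.weights, delimiter=",")


def read_affinity_csv(path) -> AffinityMatrix:
    return AffinityMatrix(np.loadtxt(path, delimiter=",", ndmin=2))
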