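"""Searchlight VB index on 2D color images: pixels as graph nodes.

A photograph gives the same structure as a cortical surface: every
pixel is a node, its "functional data" is the color of the pixel, and
its neighbourhood is the surrounding lattice patch.  Running the
searchlight VB index over the image quantifies its boundaries — dark
(VB near 0) where there are sharp transitions, bright (VB near 1) where
the structure is homogeneous.

Each pixel's feature vector is built from its HSV decomposition as
``(cos h, sin h, s, v)``.  Hue is an angle, so encoding it as a raw
scalar would make colors on either side of the 0°/360° wrap maximally
dissimilar; the (cos, sin) pair respects its circularity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2hsv

from .exceptions import ParameterError, ShapeError
from .similarity import AffinityPolicy
from .vb import VBResult, searchlight_analysis

__all__ = [
    "PixelFeatures",
    "image_to_features",
    "pixel_neighborhood",
    "image_vb_map",
]


@dataclass(frozen=True)
class PixelFeatures:
    """Per-pixel feature vectors in row-major order.

    ``features[r * cols + c]`` is ``(cos h, sin h, s, v)`` for the pixel
    at row ``r``, column ``c``.
    """

    rows: int
    cols: int
    features: np.ndarray


def image_to_features(rgb: np.ndarray) -> PixelFeatures:
    """HSV-derived feature vectors for every pixel of an RGB raster.

    Accepts uint8 (0..255) or float (0..1) arrays of shape
    ``(rows, cols, 3)``.  A 2-D grayscale array is broadcast to three
    channels with a warning: its hue features are constant.
    """
    img = np.asarray(rgb)
    if img.ndim == 2:
        warnings.warn(
            "grayscale input: hue features will be constant", stacklevel=2
        )
        img = np.repeat(img[:, :, None], 3, axis=2)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ShapeError(f"expected rows x cols x 3 RGB raster, got {img.shape}")
    if img.dtype == np.uint8:
        img = img.astype(float) / 255.0
    hsv = rgb2hsv(img)
    h = hsv[:, :, 0] * 2.0 * np.pi  # skimage hue is in [0, 1)
    feats = np.stack(
        [np.cos(h), np.sin(h), hsv[:, :, 1], hsv[:, :, 2]], axis=-1
    )
    rows, cols = img.shape[:2]
    return PixelFeatures(rows, cols, feats.reshape(rows * cols, 4))


def pixel_neighborhood(
    dims: tuple[int, int], connectivity: int = 8
) -> list[np.ndarray]:
    """4- or 8-connected lattice adjacency, row-major, clipped at borders."""
    rows, cols = dims
    if rows < 3 or cols < 3:
        raise ParameterError(f"image must be at least 3 x 3, got {rows} x {cols}")
    if connectivity == 4:
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    elif connectivity == 8:
        offsets = [
            (dr, dc)
            for dr in (-1, 0, 1)
            for dc in (-1, 0, 1)
            if (dr, dc) != (0, 0)
        ]
    else:
        raise ParameterError(f"connectivity must be 4 or 8, got {connectivity}")
    out = []
    for r in range(rows):
        for c in range(cols):
            nb = [
                (r + dr) * cols + (c + dc)
                for dr, dc in offsets
                if 0 <= r + dr < rows and 0 <= c + dc < cols
            ]
            out.append(np.array(sorted(nb), dtype=int))
    return out


def image_vb_map(
    features: PixelFeatures,
    connectivity: int = 8,
    policy: AffinityPolicy | None = None,
    problem: str = "generalized",
    jobs: int = 1,
) -> np.ndarray:
    """Per-pixel searchlight VB index, returned as a rows x cols map.

    Values lie in [0, 1]: 0 marks a sharp transition through the
    pixel's neighbourhood, 1 a perfectly homogeneous patch.  Pixels
    whose neighbourhood degenerates below 3 usable nodes are NaN.
    """
    rows, cols = features.rows, features.cols
    if rows < 3 or cols < 3:
        raise ParameterError(f"image must be at least 3 x 3, got {rows} x {cols}")
    adjacency = pixel_neighborhood((rows, cols), connectivity)
    result: VBResult = searchlight_analysis(
        features.features, adjacency=adjacency,
        policy=policy, problem=problem, jobs=jobs,
    )
    return result.vertex_vb.reshape(rows, cols)


def vb_map_to_gray(vb: np.ndarray) -> np.ndarray:
    """Render a VB map as a uint8 grayscale raster (NaN -> 0)."""
    out = np.nan_to_num(np.clip(vb, 0.0, 1.0), nan=0.0)
    return np.round(out * 255).astype(np.uint8)
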