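"""Gray-level co-occurrence texture features.

The co-occurrence matrix counts pairs of quantized gray levels over all
eight neighbor offsets (distance 1, angles 0/45/90/135 degrees accumulated
symmetrically), normalized to sum to one.  From it:

    homogeneity = sum_ij T(i,j) / (1 + |i - j|)
    contrast    = sum_ij (i - j)^2 T(i,j)

Homogeneity measures closeness of the mass to the diagonal (1 for a
constant image, smaller for noisier images); contrast measures the mean
squared level difference between neighbors.  Note the homogeneity
denominator is 1 + |i-j|, not the squared-difference form some libraries
use for their "homogeneity" (inverse difference moment).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import graycomatrix


@dataclass
class GLCMFeatures:
    T: np.ndarray  # (levels, levels), sums to 1
    homogeneity: float
    contrast: float
    levels: int


def quantize(image: np.ndarray, levels: int = 256) -> np.ndarray:
    """Linear min-max binning of a float image to integer gray levels."""
    image = np.asarray(image, dtype=np.float64)
    lo, hi = image.min(), image.max()
    if hi == lo:
        return np.zeros(image.shape, dtype=np.int32)
    q = np.floor((image - lo) / (hi - lo) * levels).astype(np.int32)
    return np.clip(q, 0, levels - 1)


def glcm(image: np.ndarray, levels: int = 256) -> np.ndarray:
    """Normalized symmetric co-occurrence matrix over the 8-neighborhood."""
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if np.issubdtype(image.dtype, np.integer):
        q = np.asarray(image)
        if q.min() < 0 or q.max() >= levels:
            raise ValueError("integer image values outside [0, levels)")
        q = q.astype(np.uint16)
    else:
        q = quantize(image, levels).astype(np.uint16)
    angles = [0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4]
    counts = graycomatrix(q, distances=[1], angles=angles, levels=levels,
                          symmetric=True, normed=False)
    T = counts[:, :, 0, :].sum(axis=-1).astype(np.float64)
    total = T.sum()
    if total == 0:
        raise ValueError("image too small for co-occurrence counting")
    return T / total


def _check_normalized(T: np.ndarray) -> np.ndarray:
    T = np.asarray(T, dtype=np.float64)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError("T must be a square matrix")
    if np.any(T < 0) or abs(T.sum() - 1.0) > 1e-9:
        raise ValueError("T must be non-negative and sum to 1")
    return T


def homogeneity(T: np.ndarray) -> float:
    """sum_ij T(i,j) / (1 + |i - j|)."""
    T = _check_normalized(T)
    i, j = np.indices(T.shape)
    return float((T / (1.0 + np.abs(i - j))).sum())


def contrast(T: np.ndarray) -> float:
    """sum_ij (i - j)^2 T(i,j)."""
    T = _check_normalized(T)
    i, j = np.indices(T.shape)
    return float(((i - j) ** 2 * T).sum())


def glcm_features(image: np.ndarray, levels: int = 256) -> GLCMFeatures:
    T = glcm(image, levels)
    return GLCMFeatures(T=T, homogeneity=homogeneity(T), contrast=contrast(T),
                        levels=levels)
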