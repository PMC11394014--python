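"""Perception-based image quality evaluator (PIQE), a no-reference score.

The image is rescaled to [0, 255] and converted to mean-subtracted
contrast-normalized (MSCN) coefficients using 7x7 Gaussian local statistics.
It is then tiled into 16x16 blocks:

* a block is *spatially active* when the variance of its MSCN coefficients
  exceeds the activity threshold (0.1);
* an active block is *distorted by artifacts* when any short segment along
  its border is nearly flat (low MSCN variation indicates a blocking or
  streak edge);
* otherwise it is *distorted by noise* when its MSCN spread is high and
  uniform between block center and surround (the signature of i.i.d. noise);
* remaining active blocks are undistorted.

The score is ``100 * (sum of distorted-block penalties + 1) /
(number of blocks + 1)``, in [0, 100], lower = better.  By default the
denominator counts all blocks; ``normalization="active_blocks"`` restores
the published active-only average, which degenerates to 100 on images so
smooth that no block is active and is therefore not the default here.  All
thresholds are configurable; numeric parity with any specific vendor
implementation is not claimed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

BLOCK_UNDISTORTED = 0
BLOCK_ARTIFACT = 1
BLOCK_NOISE = 2


@dataclass
class PIQEResult:
    score: float
    block_class_map: np.ndarray  # per-block labels (see BLOCK_* constants)
    activity_map: np.ndarray  # per-block spatial activity flags
    mscn: np.ndarray


def mscn(image: np.ndarray, sigma: float = 7.0 / 6.0, c: float = 1.0,
         truncate: float = 18.0 / 7.0) -> np.ndarray:
    """Mean-subtracted contrast-normalized coefficients.

    (I - mu) / (sigma_local + c) with Gaussian local statistics over a
    7x7 window (sigma 7/6, kernel radius 3).  ``c`` stabilizes flat regions; it is expressed on
    the image's own scale, so coefficients are invariant to a global affine
    rescale of the input provided ``c`` is rescaled with it.
    """
    image = np.asarray(image, dtype=np.float64)
    if min(image.shape) < 32:
        raise ValueError("image must be at least 32x32 for local statistics")
    mu = gaussian_filter(image, sigma, truncate=truncate, mode="nearest")
    second = gaussian_filter(image * image, sigma, truncate=truncate, mode="nearest")
    var = np.maximum(second - mu * mu, 0.0)
    return (image - mu) / (np.sqrt(var) + c)


def _segment_stds(edge: np.ndarray, seg_len: int = 6) -> np.ndarray:
    """Standard deviations of sliding segments along a block border."""
    n = len(edge)
    if n < seg_len:
        return np.array([edge.std()])
    windows = np.lib.stride_tricks.sliding_window_view(edge, seg_len)
    return windows.std(axis=1)


def piqe(image: np.ndarray, block_size: int = 16,
         activity_threshold: float = 0.1,
         artifact_threshold: float = 0.1,
         noise_threshold: float = 0.35,
         normalization: str = "all_blocks") -> PIQEResult:
    """PIQE score and per-block distortion classification."""
    if normalization not in ("all_blocks", "active_blocks"):
        raise ValueError("normalization must be 'all_blocks' or 'active_blocks'")
    image = np.asarray(image, dtype=np.float64)
    if min(image.shape) < block_size:
        raise ValueError("image smaller than one block")
    lo, hi = image.min(), image.max()
    scaled = np.zeros_like(image) if hi == lo else (image - lo) / (hi - lo) * 255.0
    coeffs = mscn(scaled)

    nbr = image.shape[0] // block_size
    nbc = image.shape[1] // block_size
    classes = np.full((nbr, nbc), BLOCK_UNDISTORTED, dtype=np.int8)
    active = np.zeros((nbr, nbc), dtype=bool)
    penalties = []
    for bi in range(nbr):
        for bj in range(nbc):
            blk = coeffs[bi * block_size : (bi + 1) * block_size,
                         bj * block_size : (bj + 1) * block_size]
            var = blk.var()
            if var <= activity_threshold:
                continue
            active[bi, bj] = True
            edges = [blk[0], blk[-1], blk[:, 0], blk[:, -1]]
            flat_edge = any(_segment_stds(e).min() < artifact_threshold
                            for e in edges)
            if flat_edge:
                classes[bi, bj] = BLOCK_ARTIFACT
                penalties.append(1.0)
            elif np.sqrt(var) > noise_threshold:
                classes[bi, bj] = BLOCK_NOISE
                penalties.append(1.0)
    n_active = int(active.sum())
    denom = n_active if normalization == "active_blocks" else nbr * nbc
    score = 100.0 * (sum(penalties) + 1.0) / (denom + 1.0)
    return PIQEResult(score=float(score), block_class_map=classes,
                      activity_map=active, mscn=coeffs)
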