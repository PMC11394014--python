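"""Extreme-value (Gumbel) statistics of streak/ripple artifacts.

A rectangular window is placed on the in-focus plane near the breast
periphery, oriented so its long side runs along the X-ray sweep direction
and cuts across the streaks.  Pixel-value profiles are read along the sweep
direction at 1-pixel intervals; for each profile the maximal absolute
difference between adjacent pixels is recorded.  If the streaks behave like
random high-frequency ripples these per-profile maxima follow a Gumbel
distribution, so plotting the sorted maxima against the reduced variate

    u = -ln(-ln Q),   Q(x_r) = (r - 0.5) / l,   r = 1..l   (symmetry-rank)

should be linear.  A least-squares line x = mu + b*u estimates the Gumbel
location and scale; the Pearson correlation between sorted maxima and u
quantifies linearity, and the mean maximal variation +/- its standard
error summarizes artifact strength.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class GumbelResult:
    maxima: np.ndarray  # sorted ascending
    Q: np.ndarray  # plotting positions, strictly increasing in (0, 1)
    u: np.ndarray  # reduced variate -ln(-ln Q)
    location: float  # mu
    scale: float  # b
    pearson_r: float
    p_value: float
    mean_max: float
    stderr_max: float


def extract_profiles(image: np.ndarray, window_origin: tuple[int, int],
                     width: int = 30, length: int = 24,
                     sweep_axis: int = 1) -> np.ndarray:
    """Parallel pixel-value lines along the sweep direction.

    Returns an array of shape (length, width): ``length`` profiles at
    1-pixel intervals across the sweep direction, each sampling ``width``
    pixels along it.  ``window_origin`` is the top-left (row, col) of the
    window on the image.
    """
    image = np.asarray(image, dtype=np.float64)
    r0, c0 = int(window_origin[0]), int(window_origin[1])
    if sweep_axis == 1:
        rows, cols = length, width
    elif sweep_axis == 0:
        rows, cols = width, length
    else:
        raise ValueError("sweep_axis must be 0 or 1")
    if r0 < 0 or c0 < 0 or r0 + rows > image.shape[0] or c0 + cols > image.shape[1]:
        raise ValueError("window out of bounds")
    win = image[r0 : r0 + rows, c0 : c0 + cols]
    return win if sweep_axis == 1 else win.T


def max_adjacent_variation(profile: np.ndarray) -> float:
    """Largest absolute difference between adjacent samples."""
    profile = np.asarray(profile, dtype=np.float64)
    if profile.ndim != 1 or len(profile) < 2:
        raise ValueError("profile must be 1-D with at least 2 samples")
    return float(np.max(np.abs(np.diff(profile))))


def plotting_positions(l: int) -> np.ndarray:
    """Symmetry-rank cumulative probabilities Q_r = (r - 0.5) / l."""
    if l < 1:
        raise ValueError("l must be >= 1")
    return (np.arange(1, l + 1) - 0.5) / l


def gumbel_fit(maxima) -> GumbelResult:
    """Fit a Gumbel line through the order statistics of the maxima."""
    x = np.sort(np.asarray(list(maxima), dtype=np.float64))
    l = len(x)
    if l < 3:
        raise ValueError("need at least 3 maxima")
    q = plotting_positions(l)
    u = -np.log(-np.log(q))
    fit = stats.linregress(u, x)
    r, p = stats.pearsonr(x, u)
    stderr = x.std(ddof=1) / np.sqrt(l)
    return GumbelResult(maxima=x, Q=q, u=u, location=float(fit.intercept),
                        scale=float(fit.slope), pearson_r=float(r),
                        p_value=float(p), mean_max=float(x.mean()),
                        stderr_max=float(stderr))


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation and its two-sided p-value."""
    x = np.asarray(list(x), dtype=np.float64)
    y = np.asarray(list(y), dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-D sequences, n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def streak_statistic(image: np.ndarray, window_origin: tuple[int, int],
                     width: int = 30, n_profiles: int = 29,
                     sweep_axis: int = 1) -> GumbelResult:
    """Window -> profiles -> per-profile maxima -> Gumbel fit.

    Defaults follow the published evaluation convention: a 30-pixel sweep
    extent and a sampling size of l = 29 maxima (one per profile).
    """
    profiles = extract_profiles(image, window_origin, width=width,
                                length=n_profiles, sweep_axis=sweep_axis)
    maxima = [max_adjacent_variation(p) for p in profiles]
    return gumbel_fit(maxima)
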