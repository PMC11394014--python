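"""Synthetic digital breast phantoms.

The phantom is a 3-D linear-attenuation map standing in for a compressed
breast: a half-ellipsoid of adipose tissue pressed against the chest-wall
edge of the detector, an internal fibroglandular pattern (a smoothed random
field thresholded at a type-dependent fraction), optional soft-contrast mass
ellipsoids and small high-attenuation microcalcification spheres.

Attenuation values are in mm^-1 at mammographic energies (~20 keV):
adipose ~0.045, fibroglandular ~0.080; masses sit slightly above
fibroglandular, microcalcifications an order of magnitude higher.  Air is
exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

LABELS = {"air": 0, "adipose": 1, "fibroglandular": 2, "mass": 3,
          "microcalcification": 4}

MU = {  # linear attenuation, mm^-1
    "air": 0.0,
    "adipose": 0.045,
    "fibroglandular": 0.080,
    "mass": 0.095,
    "microcalcification": 0.60,
}

# volume fraction of fibroglandular tissue inside the breast
_FIBRO_FRACTION = {"dense": 0.55, "non-dense": 0.20}


@dataclass
class DigitalPhantom:
    volume: np.ndarray  # (nz, rows, cols) attenuation, mm^-1
    voxel_size: float  # mm, isotropic
    label_map: np.ndarray  # same shape, integer tissue classes
    breast_type: str

    def __post_init__(self):
        self.volume = np.asarray(self.volume, dtype=np.float64)
        self.label_map = np.asarray(self.label_map, dtype=np.int8)
        if self.volume.shape != self.label_map.shape:
            raise ValueError("volume and label_map shapes differ")
        if np.any(self.volume < 0):
            raise ValueError("attenuation must be non-negative")
        if np.any(self.volume[self.label_map == LABELS["air"]] != 0):
            raise ValueError("air voxels must have zero attenuation")


def _half_ellipsoid_mask(shape: tuple[int, int, int]) -> np.ndarray:
    """Breast envelope: half-ellipsoid with its flat face on the col=0 edge."""
    nz, ny, nx = shape
    z, y, x = np.ogrid[:nz, :ny, :nx]
    cz, cy = (nz - 1) / 2.0, (ny - 1) / 2.0
    rz, ry, rx = 0.45 * nz, 0.45 * ny, 0.85 * nx
    return ((z - cz) / rz) ** 2 + ((y - cy) / ry) ** 2 + (x / rx) ** 2 <= 1.0


def _fibro_pattern(breast: np.ndarray, fraction: float,
                   rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal(breast.shape)
    smooth = ndimage.gaussian_filter(noise, sigma=2.0)
    vals = smooth[breast]
    thresh = np.quantile(vals, 1.0 - fraction) if fraction > 0 else np.inf
    return breast & (smooth >= thresh)


def _place_blobs(breast: np.ndarray, n: int, radii_range: tuple[float, float],
                 rng: np.random.Generator, min_gap: float) -> list[tuple]:
    """Non-overlapping (center, radii) placements fully inside the breast."""
    eroded = ndimage.binary_erosion(breast, iterations=int(np.ceil(radii_range[1])) + 1)
    candidates = np.argwhere(eroded)
    if len(candidates) == 0 and n > 0:
        raise ValueError("phantom too small to host the requested inclusions")
    placed = []
    attempts = 0
    while len(placed) < n:
        attempts += 1
        if attempts > 5000:
            raise RuntimeError("could not place non-overlapping inclusions")
        center = candidates[rng.integers(len(candidates))]
        radii = rng.uniform(*radii_range, size=3)
        ok = all(
            np.linalg.norm(center - np.asarray(c0)) > np.max(r0) + np.max(radii) + min_gap
            for c0, r0 in placed
        )
        if ok:
            placed.append((center, radii))
    return placed


def _stamp_ellipsoid(mask_out: np.ndarray, center, radii):
    nz, ny, nx = mask_out.shape
    z, y, x = np.ogrid[:nz, :ny, :nx]
    e = (((z - center[0]) / radii[0]) ** 2 + ((y - center[1]) / radii[1]) ** 2
         + ((x - center[2]) / radii[2]) ** 2) <= 1.0
    mask_out |= e


def make_phantom(shape: tuple[int, int, int], breast_type: str = "dense",
                 n_masses: int = 1, n_mcs: int = 0, voxel_size: float = 1.0,
                 seed: int = 0) -> DigitalPhantom:
    """Build a reproducible synthetic breast phantom.

    Parameters
    ----------
    shape : (nz, rows, cols) voxel counts; rows/cols match the detector grid.
    breast_type : "dense" or "non-dense" (fibroglandular volume fraction
        0.55 vs 0.20).
    n_masses : number of soft-contrast mass ellipsoids.
    n_mcs : number of microcalcification spheres.
    voxel_size : isotropic voxel edge, mm.
    seed : RNG seed; identical seeds give voxel-identical phantoms.
    """
    shape = tuple(int(s) for s in shape)
    if any(s <= 0 for s in shape):
        raise ValueError("shape must be positive")
    if n_masses < 0 or n_mcs < 0:
        raise ValueError("inclusion counts must be >= 0")
    if breast_type not in _FIBRO_FRACTION:
        raise ValueError("breast_type must be 'dense' or 'non-dense'")
    rng = np.random.default_rng(seed)

    breast = _half_ellipsoid_mask(shape)
    fibro = _fibro_pattern(breast, _FIBRO_FRACTION[breast_type], rng)

    label = np.zeros(shape, dtype=np.int8)
    label[breast] = LABELS["adipose"]
    label[fibro] = LABELS["fibroglandular"]

    max_r = max(2.0, min(shape) / 8.0)
    mass_mask = np.zeros(shape, dtype=bool)
    for center, radii in _place_blobs(breast, n_masses, (2.0, max_r), rng, min_gap=2.0):
        _stamp_ellipsoid(mass_mask, center, radii)
    label[mass_mask] = LABELS["mass"]

    mc_mask = np.zeros(shape, dtype=bool)
    for center, _ in _place_blobs(breast & ~mass_mask, n_mcs, (1.0, 1.5), rng,
                                  min_gap=3.0):
        _stamp_ellipsoid(mc_mask, center, (1.2, 1.2, 1.2))
    mc_mask &= ~mass_mask
    label[mc_mask] = LABELS["microcalcification"]

    volume = np.zeros(shape, dtype=np.float64)
    for name, lab in LABELS.items():
        volume[label == lab] = MU[name]

    return DigitalPhantom(volume=volume, voxel_size=float(voxel_size),
                          label_map=label, breast_type=breast_type)
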