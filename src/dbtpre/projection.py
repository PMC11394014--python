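"""Limited-angle projection simulation with dose-dependent Poisson noise.

Forward model: a shear (shifted parallel-ray) approximation, appropriate for
the small +/-7.5 degree sweep of breast tomosynthesis.  A voxel at height z
above the detector appears on the detector displaced along the sweep axis by
z*tan(theta); each projection is therefore a per-height shifted line sum
through the attenuation volume.  This choice makes shift-and-add
backprojection an exact adjoint of the forward operator (zero-fill boundary
on both sides), which the reconstruction tests exploit.

Noise model: expected photon counts per pixel follow Beer--Lambert,
N = N0 * exp(-L) with L the attenuation line integral; counts are Poisson
sampled and log-converted back to a line-integral image.  Detector-dose
indices (EI/DI) are stamped from the mean detected signal over the breast
region.
"""

from __future__ import annotations

import numpy as np

from .geometry import AcquisitionGeometry, DoseIndices, ProjectionSet
from .phantom import DigitalPhantom

#: detected-signal calibration target used when the caller does not supply
#: one: mean breast-region counts of a typical reference-dose acquisition
#: (dose 1e4 photons/pixel through ~4 cm of breast tissue).
DEFAULT_EI_TARGET = 2000.0


def _int_shift(a: np.ndarray, k: int) -> np.ndarray:
    """Gather a[..., c + k] with zero fill outside, along the last axis."""
    out = np.zeros_like(a)
    n = a.shape[-1]
    if k >= 0:
        if k < n:
            out[..., : n - k] = a[..., k:]
    else:
        if -k < n:
            out[..., -k:] = a[..., : n + k]
    return out


def shift_lines(a: np.ndarray, s: float) -> np.ndarray:
    """Linear-interpolated gather shift by ``s`` pixels along the last axis.

    out[..., c] = a[..., c + s]; samples outside the array read zero.  Its
    exact adjoint is ``shift_lines(., -s)``.
    """
    k = int(np.floor(s))
    f = s - k
    if f == 0.0:
        return _int_shift(a, k)
    return (1.0 - f) * _int_shift(a, k) + f * _int_shift(a, k + 1)


def _oriented(volume: np.ndarray, sweep_axis: int) -> np.ndarray:
    """View the volume with the sweep axis last."""
    return volume if sweep_axis == 1 else np.swapaxes(volume, 1, 2)


def project(phantom: DigitalPhantom, geometry: AcquisitionGeometry,
            angle_deg: float) -> np.ndarray:
    """Noiseless attenuation line integrals at one tube angle."""
    half = geometry.arc_deg / 2.0
    if abs(angle_deg) > half + 1e-9:
        raise ValueError(f"angle {angle_deg} outside the +/-{half} degree arc")
    vol = phantom.volume
    if vol.shape[1:] != geometry.detector_shape:
        raise ValueError("phantom in-plane shape must match the detector grid")
    v = _oriented(vol, geometry.sweep_axis)
    tan = np.tan(np.deg2rad(angle_deg))
    dz = phantom.voxel_size
    proj = np.zeros(v.shape[1:], dtype=np.float64)
    for z in range(v.shape[0]):
        height = (z + 0.5) * dz  # mm above the detector plane
        s = height * tan / geometry.pixel_pitch
        proj += dz * shift_lines(v[z], s)
    return proj if geometry.sweep_axis == 1 else proj.T


def breast_region_mask(image: np.ndarray, rel_threshold: float = 0.01) -> np.ndarray:
    """Pixels with attenuation signal above ``rel_threshold`` of the maximum."""
    image = np.asarray(image, dtype=np.float64)
    return image > rel_threshold * image.max()


def compute_dose_indices(projection: np.ndarray, EI_target: float,
                         calibration: float = 1.0,
                         region_mask: np.ndarray | None = None) -> DoseIndices:
    """Exposure and deviation indices from a detector-signal image.

    EI = calibration * mean signal over the breast region;
    DI = 10*log10(EI / EI_target).
    """
    projection = np.asarray(projection, dtype=np.float64)
    if not np.all(np.isfinite(projection)):
        raise ValueError("projection contains non-finite values")
    if EI_target <= 0:
        raise ValueError("EI_target must be positive")
    mask = breast_region_mask(projection) if region_mask is None else region_mask
    if not np.any(mask):
        raise ValueError("empty breast region")
    ei = calibration * float(projection[mask].mean())
    return DoseIndices(EI=ei, EI_target=float(EI_target))


def simulate_acquisition(phantom: DigitalPhantom, geometry: AcquisitionGeometry,
                         dose_level: float, seed: int, *,
                         EI_target: float = DEFAULT_EI_TARGET,
                         calibration: float = 1.0,
                         ei_split: float | None = None,
                         noise: bool = True) -> ProjectionSet:
    """Simulate one tomographic pass.

    Parameters
    ----------
    dose_level : unattenuated photons per pixel (N0).
    seed : Poisson sampling seed; fixed seed gives an identical set.
    EI_target : detector calibration target for the deviation index.
    ei_split : EI above this mean value labels the set "reference", below it
        "object"; defaults to half of ``EI_target``.
    noise : disable to obtain the noiseless line integrals (infinite-dose
        limit).
    """
    if dose_level <= 0:
        raise ValueError("dose_level must be positive")
    if ei_split is None:
        ei_split = EI_target / 2.0
    rng = np.random.default_rng(seed)
    angles = geometry.angles_deg
    images, indices = [], []
    for ang in angles:
        line = project(phantom, geometry, ang)
        counts = dose_level * np.exp(-line)
        detected = rng.poisson(counts).astype(np.float64) if noise else counts
        mask = breast_region_mask(line)
        indices.append(compute_dose_indices(detected, EI_target, calibration,
                                            region_mask=mask))
        if noise:
            safe = np.maximum(detected, 0.5)  # guard the log at zero counts
            images.append(-np.log(safe / dose_level))
        else:
            images.append(line)
    mean_ei = float(np.mean([d.EI for d in indices]))
    domain = "reference" if mean_ei >= ei_split else "object"
    return ProjectionSet(images=np.stack(images), angles_deg=angles,
                         geometry=geometry, dose_domain=domain,
                         dose_indices=indices, seed=seed)
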