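"""Filtered backprojection for linear-sweep tomosynthesis.

Each projection line along the sweep axis is filtered by the
Ramachandran--Lakshminarayanan ramp |f| in the frequency domain (edge-padded
against wraparound), then shift-and-add backprojected: for a reconstruction
plane at height z, the projection taken at tube angle theta is displaced by
-z*tan(theta)/pitch pixels along the sweep axis and the displaced
projections are averaged.  The sub-pixel shifts use the same linear
interpolation as the forward model, so (with sum weighting) backprojection
is the exact adjoint of projection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .geometry import AcquisitionGeometry, ProjectionSet
from .projection import shift_lines


@dataclass
class FilterKernel:
    """Discrete ramp-filter response sampled on an FFT grid."""

    response: np.ndarray  # |f| per FFT bin, cycles/mm
    length: int
    pitch: float

    def __post_init__(self):
        if self.response[0] != 0.0:
            raise ValueError("ramp response must vanish at DC")


def ramlak_kernel(n: int, pitch: float, hann: bool = False) -> FilterKernel:
    """Ramp |f| response for an n-sample line at the given pixel pitch."""
    freqs = np.fft.fftfreq(n, d=pitch)
    resp = np.abs(freqs)
    if hann:
        resp *= 0.5 * (1.0 + np.cos(np.pi * freqs / np.abs(freqs).max()))
    return FilterKernel(response=resp, length=n, pitch=pitch)


def ramlak_filter(projection: np.ndarray, pitch: float, *,
                  hann: bool = False) -> np.ndarray:
    """Apply the ramp filter to every line (last axis = sweep direction).

    Lines are edge-padded to at least twice their length before the FFT:
    this suppresses circular wraparound like zero-padding does, but keeps a
    constant line exactly constant so the ramp's DC zero removes it without
    boundary leakage.
    """
    projection = np.asarray(projection, dtype=np.float64)
    n = projection.shape[-1]
    npad = 1 << int(np.ceil(np.log2(2 * n)))  # suppress circular wraparound
    pad = [(0, 0)] * (projection.ndim - 1) + [(0, npad - n)]
    padded = np.pad(projection, pad, mode="edge")
    kern = ramlak_kernel(npad, pitch, hann=hann)
    spec = np.fft.fft(padded, axis=-1)
    filtered = np.fft.ifft(spec * kern.response, axis=-1).real
    return filtered[..., :n]


@dataclass
class ReconVolume:
    """Stack of reconstructed in-plane slices at given heights (mm)."""

    slices: np.ndarray  # (n_planes, rows, cols)
    heights: np.ndarray  # mm above the detector
    geometry: AcquisitionGeometry

    def __post_init__(self):
        self.slices = np.asarray(self.slices, dtype=np.float64)
        self.heights = np.asarray(self.heights, dtype=np.float64)
        if len(self.slices) != len(self.heights):
            raise ValueError("one slice per requested height required")

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        tifffile.imwrite(path, self.slices.astype(np.float32),
                         photometric="minisblack")
        meta = {"heights": self.heights.tolist(),
                "geometry": self.geometry.to_dict()}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "ReconVolume":
        path = Path(path)
        slices = tifffile.imread(path).astype(np.float64)
        if slices.ndim == 2:
            slices = slices[None]
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(slices=slices, heights=np.asarray(meta["heights"]),
                   geometry=AcquisitionGeometry.from_dict(meta["geometry"]))

    def export_png(self, directory: str | Path, window: tuple[float, float] = (0.0, 0.02)):
        """Write one display-windowed PNG per slice (window applied at export)."""
        from imageio.v3 import imwrite

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        lo, hi = window
        for i, sl in enumerate(self.slices):
            disp = np.clip((sl - lo) / (hi - lo), 0.0, 1.0)
            imwrite(directory / f"slice_{i:03d}.png",
                    (disp * 255).astype(np.uint8))


def backproject(projections: ProjectionSet, plane_heights,
                filtered: bool = True, *, weight: str = "mean",
                hann: bool = False) -> ReconVolume:
    """Shift-and-add (optionally filtered) backprojection.

    weight="mean" averages over angles (the reconstruction convention);
    weight="sum" makes the unfiltered operator the exact adjoint of the
    forward projector.
    """
    geom = projections.geometry
    if projections.images.shape[1:] != geom.detector_shape:
        raise ValueError("projection images inconsistent with the geometry")
    if weight not in ("mean", "sum"):
        raise ValueError("weight must be 'mean' or 'sum'")
    heights = np.atleast_1d(np.asarray(plane_heights, dtype=np.float64))
    imgs = projections.images
    if geom.sweep_axis == 0:
        imgs = np.swapaxes(imgs, 1, 2)
    if filtered:
        imgs = ramlak_filter(imgs, geom.pixel_pitch, hann=hann)
    tans = np.tan(np.deg2rad(projections.angles_deg))
    slices = np.zeros((len(heights),) + imgs.shape[1:])
    for i, h in enumerate(heights):
        acc = np.zeros(imgs.shape[1:])
        for img, tan in zip(imgs, tans):
            acc += shift_lines(img, -h * tan / geom.pixel_pitch)
        slices[i] = acc / len(imgs) if weight == "mean" else acc
    if geom.sweep_axis == 0:
        slices = np.swapaxes(slices, 1, 2)
    return ReconVolume(slices=slices, heights=heights, geometry=geom)


def in_focus_plane(volume: ReconVolume, target_height: float) -> np.ndarray:
    """Slice whose height is nearest the target; ties pick the lower plane."""
    if len(volume.slices) == 0:
        raise ValueError("empty reconstruction volume")
    d = np.abs(volume.heights - target_height)
    # stable argmin returns the first (lower-height) plane on ties given
    # heights sorted ascending; enforce that ordering first
    order = np.argsort(volume.heights, kind="stable")
    best = order[np.argmin(d[order])]
    return volume.slices[best]
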