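"""Acquisition geometry, dose indices and the projection-set container.

The scanner model is a linear-sweep tomosynthesis system: the tube travels
along one detector axis over a small symmetric arc while the detector stays
put, producing a handful of low-dose projections in a single pass.  Defaults
follow a clinical breast-tomosynthesis acquisition (15 projections over a
15 degree arc) with the 2560x4096 detector scaled to a desk-size 256x512
grid; full-size detectors are supported by configuration.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class AcquisitionGeometry:
    """Limited-angle sweep geometry.

    The sweep axis is the image axis along which the tube travels; per-angle
    parallax shifts (and the reconstruction filter) act along it.
    """

    n_projections: int = 15
    arc_deg: float = 15.0
    detector_shape: tuple[int, int] = (256, 512)
    pixel_pitch: float = 0.14  # mm
    source_to_detector: float = 700.0  # mm
    source_to_rotation_center: float = 650.0  # mm
    sweep_axis: int = 1

    def __post_init__(self):
        if self.n_projections < 1:
            raise ValueError("n_projections must be >= 1")
        if self.arc_deg <= 0:
            raise ValueError("arc_deg must be positive")
        if self.sweep_axis not in (0, 1):
            raise ValueError("sweep_axis must be 0 or 1")
        self.detector_shape = tuple(int(s) for s in self.detector_shape)

    @property
    def angles_deg(self) -> np.ndarray:
        """Evenly spaced projection angles, symmetric about 0 degrees."""
        half = self.arc_deg / 2.0
        if self.n_projections == 1:
            return np.zeros(1)
        return np.linspace(-half, half, self.n_projections)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionGeometry":
        return cls(**d)


@dataclass
class DoseIndices:
    """Standardized detector-dose indicators.

    EI is proportional to the air kerma at the detector; the deviation index
    relates it to the calibration target: DI = 10*log10(EI / EI_target).
    """

    EI: float
    EI_target: float
    DI: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.EI <= 0 or self.EI_target <= 0:
            raise ValueError("EI and EI_target must be positive")
        expected = 10.0 * np.log10(self.EI / self.EI_target)
        if self.DI is None:
            self.DI = float(expected)
        elif abs(self.DI - expected) > 1e-9:
            raise ValueError("DI inconsistent with 10*log10(EI/EI_target)")


@dataclass
class ProjectionSet:
    """Ordered stack of 2-D projections plus everything needed to reuse it."""

    images: np.ndarray  # (n_projections, rows, cols) float
    angles_deg: np.ndarray
    geometry: AcquisitionGeometry
    dose_domain: str = "reference"  # or "object"
    dose_indices: list[DoseIndices] | None = None
    seed: int | None = None

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float64)
        self.angles_deg = np.asarray(self.angles_deg, dtype=np.float64)
        if self.images.ndim != 3:
            raise ValueError("images must be a (n, rows, cols) stack")
        n = self.geometry.n_projections
        if not (len(self.images) == len(self.angles_deg) == n):
            raise ValueError("images, angles and geometry.n_projections disagree")
        if self.dose_domain not in ("reference", "object"):
            raise ValueError("dose_domain must be 'reference' or 'object'")

    def __len__(self) -> int:
        return len(self.images)

    # -- persistence: multi-page float32 TIFF + JSON sidecar -----------
    def save(self, path: str | Path) -> Path:
        path = Path(path)
        tifffile.imwrite(path, self.images.astype(np.float32),
                         photometric="minisblack")
        meta = {
            "angles_deg": self.angles_deg.tolist(),
            "geometry": self.geometry.to_dict(),
            "dose_domain": self.dose_domain,
            "seed": self.seed,
            "dose_indices": None if self.dose_indices is None else [
                {"EI": d.EI, "EI_target": d.EI_target, "DI": d.DI}
                for d in self.dose_indices
            ],
        }
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(meta, indent=2))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "ProjectionSet":
        path = Path(path)
        images = tifffile.imread(path).astype(np.float64)
        if images.ndim == 2:
            images = images[None]
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        di = meta.get("dose_indices")
        return cls(
            images=images,
            angles_deg=np.asarray(meta["angles_deg"]),
            geometry=AcquisitionGeometry.from_dict(meta["geometry"]),
            dose_domain=meta["dose_domain"],
            dose_indices=None if di is None else [DoseIndices(**d) for d in di],
            seed=meta.get("seed"),
        )


def read_dicom_pixels(path: str | Path) -> np.ndarray:
    """Extract the pixel array from a DICOM file (ingest only)."""
    import pydicom

    ds = pydicom.dcmread(str(path))
    return np.asarray(ds.pixel_array, dtype=np.float64)
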