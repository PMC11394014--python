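"""Image normalization, cropping and seeded patch extraction.

Normalization first standardizes the image (subtract the image mean, divide
by the population standard deviation) and then affinely maps the result to a
fixed range:

    I_temp = (I_org - mean(I_org)) / sigma
    I_norm = 1.0 + (I_temp - min) / (max - min)        ("as_printed", [1, 2])
    I_norm =       (I_temp - min) / (max - min)        ("zero_one",  [0, 1])

Both variants are one offset apart; the default follows the printed
equation.  Patch extraction draws fully-inside 128x128 windows uniformly at
random (numpy PCG64 generator) and flips each horizontally with a configured
probability, the augmentation used to grow 128 patches per projection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass
class NormalizedImage:
    data: np.ndarray
    source_mean: float
    source_std: float
    mode: str

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("normalized image must be finite")


@dataclass
class PatchBatch:
    """Seeded patch samples from one source image."""

    patches: np.ndarray  # (n, patch, patch)
    origins: np.ndarray  # (n, 2) top-left (row, col)
    flipped: np.ndarray  # (n,) bool
    source_id: str
    seed: int

    def __post_init__(self):
        self.patches = np.asarray(self.patches, dtype=np.float64)
        self.origins = np.asarray(self.origins, dtype=np.int64)
        self.flipped = np.asarray(self.flipped, dtype=bool)
        if not (len(self.patches) == len(self.origins) == len(self.flipped)):
            raise ValueError("patch/origin/flip lengths disagree")

    def __len__(self) -> int:
        return len(self.patches)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        np.savez(path, patches=self.patches.astype(np.float32))
        manifest = {"origins": self.origins.tolist(),
                    "flipped": self.flipped.tolist(),
                    "source_id": self.source_id, "seed": self.seed}
        path.with_suffix(".json").write_text(json.dumps(manifest))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "PatchBatch":
        path = Path(path)
        arrs = np.load(path.with_suffix(".npz") if path.suffix != ".npz" else path)
        manifest = json.loads(path.with_suffix(".json").read_text())
        return cls(patches=arrs["patches"].astype(np.float64),
                   origins=np.asarray(manifest["origins"]),
                   flipped=np.asarray(manifest["flipped"]),
                   source_id=manifest["source_id"], seed=manifest["seed"])


def normalize_image(image: np.ndarray, mode: str = "as_printed") -> NormalizedImage:
    """Standardize then range-map an image (population sigma)."""
    if mode not in ("as_printed", "zero_one"):
        raise ValueError("mode must be 'as_printed' or 'zero_one'")
    image = np.asarray(image, dtype=np.float64)
    mean = float(image.mean())
    std = float(image.std())  # population (divide by N)
    if std == 0.0 or image.max() == image.min():
        raise ValueError("constant image cannot be normalized")
    temp = (image - mean) / std
    lo, hi = temp.min(), temp.max()
    scaled = (temp - lo) / (hi - lo)
    if mode == "as_printed":
        scaled = 1.0 + scaled
    return NormalizedImage(data=scaled, source_mean=mean, source_std=std, mode=mode)


def crop_projection(image: np.ndarray, target: tuple[int, int],
                    anchor: str = "chest_wall") -> np.ndarray:
    """Crop a target-shaped window anchored at the chest-wall edge.

    The chest wall sits on the col=0 edge; rows are centered.  "center"
    centers both axes.
    """
    image = np.asarray(image)
    tr, tc = int(target[0]), int(target[1])
    if tr > image.shape[0] or tc > image.shape[1]:
        raise ValueError("crop target larger than the image")
    if anchor not in ("chest_wall", "center"):
        raise ValueError("anchor must be 'chest_wall' or 'center'")
    r0 = (image.shape[0] - tr) // 2
    c0 = 0 if anchor == "chest_wall" else (image.shape[1] - tc) // 2
    return image[r0 : r0 + tr, c0 : c0 + tc]


def extract_patches(image: np.ndarray, n_patches: int = 128, patch_size: int = 128,
                    flip_prob: float = 0.5, seed: int = 0,
                    source_id: str = "") -> PatchBatch:
    """Sample fully-inside random patches with horizontal-flip augmentation."""
    image = np.asarray(image, dtype=np.float64)
    if patch_size > min(image.shape):
        raise ValueError("patch larger than the image")
    if not 0.0 <= flip_prob <= 1.0:
        raise ValueError("flip_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = rng.integers(0, image.shape[0] - patch_size + 1, size=n_patches)
    cols = rng.integers(0, image.shape[1] - patch_size + 1, size=n_patches)
    flips = rng.random(n_patches) < flip_prob
    patches = np.empty((n_patches, patch_size, patch_size))
    for i, (r, c, fl) in enumerate(zip(rows, cols, flips)):
        tile = image[r : r + patch_size, c : c + patch_size]
        patches[i] = tile[:, ::-1] if fl else tile
    return PatchBatch(patches=patches, origins=np.stack([rows, cols], axis=1),
                      flipped=flips, source_id=source_id, seed=seed)
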