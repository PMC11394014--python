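"""Image-quality evaluation: PIQE, GLCM texture, Gumbel streak statistics."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .gumbel import (GumbelResult, extract_profiles, gumbel_fit,
                     max_adjacent_variation, pearson_r, plotting_positions,
                     streak_statistic)
from .piqe import PIQEResult, mscn, piqe
from .texture import (GLCMFeatures, contrast, glcm, glcm_features,
                      homogeneity, quantize)

__all__ = [
    "GumbelResult", "extract_profiles", "gumbel_fit", "max_adjacent_variation",
    "pearson_r", "plotting_positions", "streak_statistic",
    "PIQEResult", "mscn", "piqe",
    "GLCMFeatures", "contrast", "glcm", "glcm_features", "homogeneity",
    "quantize", "QualityReport", "evaluate_image",
]


@dataclass
class QualityReport:
    """All three metric families for one in-focus plane image."""

    image_id: str
    piqe_score: float
    homogeneity: float
    contrast: float
    gumbel_mean_max: float
    gumbel_stderr_max: float
    gumbel_location: float
    gumbel_scale: float
    gumbel_pearson_r: float
    gumbel_p_value: float

    def to_dict(self) -> dict:
        return asdict(self)

    def save_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path


def evaluate_image(image: np.ndarray, image_id: str = "",
                   glcm_levels: int = 256,
                   gumbel_window: tuple[int, int] | None = None,
                   gumbel_width: int = 30, gumbel_profiles: int = 29,
                   sweep_axis: int = 1) -> QualityReport:
    """Compute the full quality report for one image.

    If no Gumbel window origin is given, the window is centered on the rows
    and placed at the breast-periphery side (right quarter of the sweep
    extent), where ripple artifacts concentrate.
    """
    image = np.asarray(image, dtype=np.float64)
    p = piqe(image)
    feats = glcm_features(image, levels=glcm_levels)
    if gumbel_window is None:
        if sweep_axis == 1:
            r0 = max(0, image.shape[0] // 2 - gumbel_profiles // 2)
            c0 = max(0, min(image.shape[1] - gumbel_width,
                            3 * image.shape[1] // 4))
        else:
            r0 = max(0, min(image.shape[0] - gumbel_width,
                            3 * image.shape[0] // 4))
            c0 = max(0, image.shape[1] // 2 - gumbel_profiles // 2)
        gumbel_window = (r0, c0)
    g = streak_statistic(image, gumbel_window, width=gumbel_width,
                         n_profiles=gumbel_profiles, sweep_axis=sweep_axis)
    return QualityReport(
        image_id=image_id, piqe_score=p.score, homogeneity=feats.homogeneity,
        contrast=feats.contrast, gumbel_mean_max=g.mean_max,
        gumbel_stderr_max=g.stderr_max, gumbel_location=g.location,
        gumbel_scale=g.scale, gumbel_pearson_r=g.pearson_r,
        gumbel_p_value=g.p_value)
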