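"""Training losses and their numpy metric counterparts.

The numpy-array functions are the evaluation surface (shape-checked,
oracle-tested); the ``t_``-prefixed functions are the differentiable
versions used inside the training loop, written on the autodiff core.
The SSIM fidelity term uses the standard constants C1=(0.01 R)^2,
C2=(0.03 R)^2 for dynamic range R.
"""

from __future__ import annotations

import numpy as np
from skimage.metrics import structural_similarity

from .nn import autograd as ag
from .nn.autograd import Tensor


def _check_same_shape(a: np.ndarray, b: np.ndarray):
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def mse(a: np.ndarray, b: np.ndarray) -> float:
    """Mean squared error."""
    a, b = np.asarray(a, dtype=np.float64), np.asarray(b, dtype=np.float64)
    _check_same_shape(a, b)
    return float(np.mean((a - b) ** 2))


def ssim_fidelity_loss(a: np.ndarray, b: np.ndarray,
                       data_range: float | None = None) -> float:
    """1 - SSIM(a, b); zero for identical images, up to 2 for anticorrelated."""
    a, b = np.asarray(a, dtype=np.float64), np.asarray(b, dtype=np.float64)
    _check_same_shape(a, b)
    if data_range is None:
        lo = min(a.min(), b.min())
        hi = max(a.max(), b.max())
        data_range = hi - lo if hi > lo else 1.0
    return float(1.0 - structural_similarity(a, b, data_range=data_range))


def cycle_consistency_loss(x: np.ndarray, x_cycled: np.ndarray) -> float:
    """Mean absolute difference between originals and their round trips."""
    x = np.asarray(x, dtype=np.float64)
    x_cycled = np.asarray(x_cycled, dtype=np.float64)
    _check_same_shape(x, x_cycled)
    return float(np.mean(np.abs(x - x_cycled)))


def adversarial_loss(scores: np.ndarray, is_real_target: bool) -> float:
    """Least-squares GAN loss: mean (score - target)^2, target 1/0."""
    scores = np.asarray(scores, dtype=np.float64)
    target = 1.0 if is_real_target else 0.0
    return float(np.mean((scores - target) ** 2))


# -- differentiable versions -------------------------------------------


def t_l1(a: Tensor, b: Tensor) -> Tensor:
    return ag.mean(ag.absolute(a - b))


def t_lsgan(scores: Tensor, is_real_target: bool) -> Tensor:
    target = 1.0 if is_real_target else 0.0
    d = scores - target
    return ag.mean(d * d)


def t_ssim_loss(a: Tensor, b: Tensor, data_range: float = 1.0) -> Tensor:
    """Differentiable global-statistics SSIM loss per image, averaged.

    Uses whole-patch means/variances/covariance rather than a sliding
    window; adequate for 32--128 px training patches and far cheaper to
    differentiate.
    """
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    axes = tuple(range(1, len(a.shape)))  # per-sample statistics
    mu_a = ag.mean(a, axis=axes, keepdims=True)
    mu_b = ag.mean(b, axis=axes, keepdims=True)
    da, db = a - mu_a, b - mu_b
    var_a = ag.mean(da * da, axis=axes, keepdims=True)
    var_b = ag.mean(db * db, axis=axes, keepdims=True)
    cov = ag.mean(da * db, axis=axes, keepdims=True)
    ssim = ((2.0 * mu_a * mu_b + c1) * (2.0 * cov + c2)) / (
        (mu_a * mu_a + mu_b * mu_b + c1) * (var_a + var_b + c2))
    return ag.mean(1.0 - ssim)
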