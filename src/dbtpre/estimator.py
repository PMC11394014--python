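"""Scikit-learn style front end for the domain translator.

``CycleGANTranslator`` wraps unpaired cycleGAN training behind the familiar
``fit`` / ``transform`` contract: ``fit`` consumes two unpaired pools of
patches (low-dose "object" domain X and reference-dose domain), ``transform``
maps full projection images toward the reference domain by tiled inference.
It composes with sklearn model selection and pipelines.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .nn.networks import DiscriminatorSpec, GeneratorSpec
from .tiling import tile_apply
from .train import (LossWeights, OptimizerConfig, select_optimal_epoch, train)


class CycleGANTranslator(BaseEstimator, TransformerMixin):
    """Unpaired object->reference projection-domain translator.

    Parameters
    ----------
    kind : generator architecture, "rSEAG", "ResUNet" or "U-Net".
    depth, base_channels : generator capacity (downsampling levels, stem
        width).
    n_epochs : training epochs; the reported optimal epoch is the argmin of
        the held-out validation MSE.
    lambda_adv, lambda_cycle, lambda_fidelity : loss weights of the
        adversarial, cycle-consistency and SSIM fidelity terms.
    learning_rate, gradient_decay, squared_gradient_decay, minibatch :
        Adam settings (defaults follow the clinical-run hyperparameters).
    tile, stride : tiled-inference window and step for ``transform``.
    random_state : seed controlling initialization, shuffling and noise.

    Attributes
    ----------
    generator_or_ : fitted object->reference generator.
    generator_ro_ : fitted reference->object generator.
    training_state_ : loss curves and per-epoch validation MSE.
    optimal_epoch_ : 1-based epoch with the lowest validation MSE.
    """

    def __init__(self, kind: str = "rSEAG", depth: int = 2,
                 base_channels: int = 8, n_epochs: int = 3,
                 lambda_adv: float = 1.0, lambda_cycle: float = 10.0,
                 lambda_fidelity: float = 5.0, learning_rate: float = 1e-4,
                 gradient_decay: float = 0.5,
                 squared_gradient_decay: float = 0.999, minibatch: int = 16,
                 val_fraction: float = 0.1, image_pool_size: int = 50,
                 tile: int = 128, stride: int | None = None,
                 random_state: int = 0):
        self.kind = kind
        self.depth = depth
        self.base_channels = base_channels
        self.n_epochs = n_epochs
        self.lambda_adv = lambda_adv
        self.lambda_cycle = lambda_cycle
        self.lambda_fidelity = lambda_fidelity
        self.learning_rate = learning_rate
        self.gradient_decay = gradient_decay
        self.squared_gradient_decay = squared_gradient_decay
        self.minibatch = minibatch
        self.val_fraction = val_fraction
        self.image_pool_size = image_pool_size
        self.tile = tile
        self.stride = stride
        self.random_state = random_state

    # X is the object-domain pool; the reference pool rides in y.
    def fit(self, X, y=None):
        if y is None:
            raise ValueError("fit requires the reference-domain pool as y")
        gen_spec = GeneratorSpec(kind=self.kind, depth=self.depth,
                                 base_channels=self.base_channels)
        disc_spec = DiscriminatorSpec(base_channels=self.base_channels,
                                      n_layers=2)
        state, models = train(
            ref_patches=y, obj_patches=X, gen_spec=gen_spec,
            disc_spec=disc_spec,
            weights=LossWeights(self.lambda_adv, self.lambda_cycle,
                                self.lambda_fidelity),
            opt=OptimizerConfig(self.learning_rate, self.gradient_decay,
                                self.squared_gradient_decay, self.minibatch),
            n_epochs=self.n_epochs, seed=self.random_state,
            val_fraction=self.val_fraction,
            image_pool_size=self.image_pool_size)
        self.generator_or_ = models["G_or"]
        self.generator_ro_ = models["G_ro"]
        self.models_ = models
        self.training_state_ = state
        self.optimal_epoch_ = (select_optimal_epoch(state.val_mse)
                               if state.val_mse else state.epoch)
        return self

    def transform(self, X):
        """Translate full images (n, H, W) or a single (H, W) image."""
        if not hasattr(self, "generator_or_"):
            raise AttributeError("CycleGANTranslator is not fitted yet")
        arr = np.asarray(X, dtype=np.float64)
        single = arr.ndim == 2
        if single:
            arr = arr[None]
        out = np.stack([
            tile_apply(img, self.generator_or_.translate, tile=self.tile,
                       stride=self.stride)
            for img in arr
        ])
        return out[0] if single else out
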