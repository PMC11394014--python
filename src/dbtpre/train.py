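"""Unpaired cycleGAN training between the low-dose (object) and
reference-dose projection-patch domains.

Two generator/discriminator pairs are trained jointly: G_or maps object
patches toward the reference domain, G_ro maps back.  The generator
objective is the weighted sum of a least-squares adversarial term, an L1
cycle-consistency term and an SSIM fidelity term that keeps each translated
patch structurally close to its input.  Discriminators are updated on a
replay buffer of past fakes (image pool).  Optimization is Adam with the
clinical-run hyperparameters (lr 1e-4, decay factors 0.5 / 0.999,
minibatch 16); desk-scale runs shrink the pools and patch size, not the
algorithm.

The optimal epoch is chosen afterwards as the one with the lowest held-out
validation MSE between object patches and their translated outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .losses import mse, t_l1, t_lsgan, t_ssim_loss
from .nn import Adam, Tensor, build_discriminator, build_generator
from .nn.networks import DiscriminatorSpec, GeneratorSpec
from .preprocess import PatchBatch


@dataclass
class LossWeights:
    lambda_adv: float = 1.0
    lambda_cycle: float = 10.0
    lambda_fidelity: float = 5.0

    def __post_init__(self):
        if min(self.lambda_adv, self.lambda_cycle, self.lambda_fidelity) < 0:
            raise ValueError("loss weights must be non-negative")
        if self.lambda_adv == self.lambda_cycle == self.lambda_fidelity == 0:
            raise ValueError("at least one loss weight must be positive")


@dataclass
class OptimizerConfig:
    learning_rate: float = 1e-4
    gradient_decay: float = 0.5
    squared_gradient_decay: float = 0.999
    minibatch: int = 16

    def __post_init__(self):
        if min(self.learning_rate, self.gradient_decay,
               self.squared_gradient_decay) <= 0 or self.minibatch < 1:
            raise ValueError("optimizer settings must be positive")
        if max(self.gradient_decay, self.squared_gradient_decay) >= 1:
            raise ValueError("decay factors must be < 1")


@dataclass
class TrainingState:
    """Loss curves and bookkeeping for one training run."""

    epoch: int = 0
    seed: int = 0
    loss_curves: dict = field(default_factory=lambda: {
        "generator_total": [], "adversarial": [], "cycle": [], "fidelity": [],
        "discriminator": []})
    val_mse: list = field(default_factory=list)

    def record(self, **means):
        for k, v in means.items():
            self.loss_curves[k].append(float(v))


def iterations_per_epoch(pool_size: int, minibatch: int) -> int:
    """Number of optimizer steps per epoch (pool size // minibatch)."""
    if pool_size < 1 or minibatch < 1:
        raise ValueError("pool size and minibatch must be positive")
    return pool_size // minibatch


def select_optimal_epoch(mse_curve) -> int:
    """1-based index of the lowest validation MSE; ties pick the earliest."""
    curve = np.asarray(list(mse_curve), dtype=np.float64)
    if curve.size == 0:
        raise ValueError("empty MSE curve")
    return int(np.argmin(curve)) + 1


class ImagePool:
    """Replay buffer of generated fakes for discriminator updates."""

    def __init__(self, size: int, rng: np.random.Generator):
        self.size = size
        self.rng = rng
        self.buffer: list[np.ndarray] = []

    def query(self, fakes: np.ndarray) -> np.ndarray:
        if self.size <= 0:
            return fakes
        out = []
        for img in fakes:
            if len(self.buffer) < self.size:
                self.buffer.append(img.copy())
                out.append(img)
            elif self.rng.random() < 0.5:
                j = self.rng.integers(len(self.buffer))
                out.append(self.buffer[j].copy())
                self.buffer[j] = img.copy()
            else:
                out.append(img)
        return np.stack(out)


def _as_array(pool) -> np.ndarray:
    if isinstance(pool, PatchBatch):
        return pool.patches
    arr = np.asarray(pool, dtype=np.float64)
    if arr.ndim != 3:
        raise ValueError("patch pool must be (n, h, w)")
    return arr


def save_checkpoint(path: str | Path, models: dict) -> Path:
    path = Path(path)
    arrays = {}
    for name, model in models.items():
        for k, v in model.state_dict().items():
            arrays[f"{name}/{k}"] = v
    np.savez(path, **arrays)
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_checkpoint(path: str | Path, models: dict):
    data = np.load(Path(path), allow_pickle=False)
    for name, model in models.items():
        state = {k.split("/", 1)[1]: data[k] for k in data.files
                 if k.startswith(name + "/")}
        model.load_state_dict(state)


def build_models(gen_spec: GeneratorSpec, disc_spec: DiscriminatorSpec,
                 seed: int) -> dict:
    """Two generator/discriminator pairs with deterministic, distinct inits."""
    return {
        "G_or": build_generator(gen_spec, seed),
        "G_ro": build_generator(gen_spec, seed + 1),
        "D_r": build_discriminator(disc_spec, seed + 2),
        "D_o": build_discriminator(disc_spec, seed + 3),
    }


def validation_mse(generator, patches: np.ndarray, batch: int = 16) -> float:
    """Mean MSE between object patches and their translated outputs."""
    total, n = 0.0, 0
    for i in range(0, len(patches), batch):
        x = patches[i : i + batch]
        total += mse(generator.translate(x), x) * len(x)
        n += len(x)
    return total / max(n, 1)


def train(ref_patches, obj_patches, gen_spec: GeneratorSpec,
          disc_spec: DiscriminatorSpec | None = None,
          weights: LossWeights | None = None,
          opt: OptimizerConfig | None = None,
          n_epochs: int = 3, seed: int = 0, *,
          val_fraction: float = 0.1, image_pool_size: int = 50,
          checkpoint_dir: str | Path | None = None,
          models: dict | None = None):
    """Run cycleGAN training and return (TrainingState, models).

    ``ref_patches`` / ``obj_patches`` are unpaired pools, (n, h, w) arrays or
    :class:`PatchBatch`.  A ``val_fraction`` tail of the object pool (after a
    seeded shuffle) is held out for the per-epoch validation MSE.
    """
    ref = _as_array(ref_patches)
    obj = _as_array(obj_patches)
    if len(ref) == 0 or len(obj) == 0:
        raise ValueError("empty patch pool")
    weights = weights or LossWeights()
    opt = opt or OptimizerConfig()
    disc_spec = disc_spec or DiscriminatorSpec(base_channels=gen_spec.base_channels,
                                               n_layers=2)
    rng = np.random.default_rng(seed)
    if models is None:
        models = build_models(gen_spec, disc_spec, seed)
    g_or, g_ro = models["G_or"], models["G_ro"]
    d_r, d_o = models["D_r"], models["D_o"]

    obj_idx = rng.permutation(len(obj))
    n_val = max(1, int(round(val_fraction * len(obj)))) if val_fraction > 0 else 0
    val_obj = obj[obj_idx[len(obj) - n_val:]] if n_val else obj[:0]
    train_obj = obj[obj_idx[: len(obj) - n_val]]

    gen_params = list(g_or.parameters()) + list(g_ro.parameters())
    opt_g = Adam(gen_params, opt.learning_rate, opt.gradient_decay,
                 opt.squared_gradient_decay)
    opt_d = Adam(list(d_r.parameters()) + list(d_o.parameters()),
                 opt.learning_rate, opt.gradient_decay, opt.squared_gradient_decay)
    pool_r = ImagePool(image_pool_size, rng)
    pool_o = ImagePool(image_pool_size, rng)

    state = TrainingState(seed=seed)
    n_iter = iterations_per_epoch(min(len(ref), len(train_obj)), opt.minibatch)
    if n_iter == 0:
        raise ValueError("minibatch larger than the training pool")
    checkpoint_dir = Path(checkpoint_dir) if checkpoint_dir is not None else None
    if checkpoint_dir is not None:
        checkpoint_dir.mkdir(parents=True, exist_ok=True)

    def batches(arr, order):
        for i in range(n_iter):
            yield arr[order[i * opt.minibatch : (i + 1) * opt.minibatch]]

    for epoch in range(1, n_epochs + 1):
        order_r = rng.permutation(len(ref))
        order_o = rng.permutation(len(train_obj))
        sums = dict.fromkeys(("generator_total", "adversarial", "cycle",
                              "fidelity", "discriminator"), 0.0)
        for y_np, x_np in zip(batches(ref, order_r), batches(train_obj, order_o)):
            x = Tensor(x_np[:, None])
            y = Tensor(y_np[:, None])

            # -- generator update --
            for m in models.values():
                m.zero_grad()
            fake_y = g_or(x)
            fake_x = g_ro(y)
            cyc_x = g_ro(fake_y)
            cyc_y = g_or(fake_x)
            adv = t_lsgan(d_r(fake_y), True) + t_lsgan(d_o(fake_x), True)
            cyc = t_l1(cyc_x, x) + t_l1(cyc_y, y)
            fid = t_ssim_loss(fake_y, x) + t_ssim_loss(fake_x, y)
            total = (weights.lambda_adv * adv + weights.lambda_cycle * cyc
                     + weights.lambda_fidelity * fid)
            fake_y_np = fake_y.data.copy()
            fake_x_np = fake_x.data.copy()
            total.backward()
            opt_g.step()

            # -- discriminator update (on pooled, detached fakes) --
            for m in models.values():
                m.zero_grad()
            d_loss = Tensor(0.0)
            for disc, real, fakes, pool in ((d_r, y, fake_y_np, pool_r),
                                            (d_o, x, fake_x_np, pool_o)):
                mixed = pool.query(fakes)
                d_loss = d_loss + 0.5 * (t_lsgan(disc(real), True)
                                         + t_lsgan(disc(Tensor(mixed)), False))
            d_loss.backward()
            opt_d.step()

            sums["generator_total"] += float(total.data)
            sums["adversarial"] += float(adv.data)
            sums["cycle"] += float(cyc.data)
            sums["fidelity"] += float(fid.data)
            sums["discriminator"] += float(d_loss.data)

        state.epoch = epoch
        state.record(**{k: v / n_iter for k, v in sums.items()})
        if n_val:
            state.val_mse.append(validation_mse(g_or, val_obj, opt.minibatch))
        if checkpoint_dir is not None:
            save_checkpoint(checkpoint_dir / f"epoch_{epoch:03d}.npz", models)

    return state, models
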