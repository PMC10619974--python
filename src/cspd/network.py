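"""Learned contrast-free super-resolution power Doppler reconstruction.

The generator f maps a clutter-filtered spatiotemporal ensemble U(z, x, t) —
slow-time frames entering as input channels — to a super-resolved vessel
image on an R-times upsampled grid, trained against ULM accumulation maps.
Architecture: U-Net encoder/decoder (two 3x3 conv + batch-norm + ReLU per
block, 2x2 max pooling down, 2x2 stride-2 transpose convolution up with skip
concatenation) followed by log2(R) bilinear-upsampling stages and a
nonnegative (ReLU) output head.

Three objective functions are supported: plain L1; L1 plus a feature-space
loss weighted by lambda1; and L1 plus a Wasserstein adversarial loss weighted
by lambda2, where a weight-clipped critic approximates the Earth-Mover
distance between generated and target image distributions.

The public modelling surface follows the Model/Results idiom: ``CspdModel``
is built from training pairs, its ``fit`` returns a ``CspdResults`` carrying
the trained generator, training history and a ``summary()``; ``train`` and
``infer`` are thin functional wrappers over the same machinery.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import nn
from .doppler import power_doppler
from .forward import SpatiotemporalBlock

__all__ = [
    "GeneratorSpec", "LossSpec", "TrainConfig", "Generator",
    "build_generator", "build_discriminator", "FeatureExtractor",
    "compute_loss", "CspdModel", "CspdResults", "train", "infer",
    "predict_flow_separated", "block_to_input", "save_model", "load_model",
]


# --------------------------------------------------------------------------- #
# specifications
# --------------------------------------------------------------------------- #

@dataclass
class GeneratorSpec:
    """Architecture of the generator.

    ``in_frames`` slow-time frames enter as input channels; ``upsampling`` R
    must be a power of two and match the ULM target grid.
    """

    in_frames: int = 16
    n_levels: int = 2
    base_channels: int = 12
    upsampling: int = 4
    tail_channels: int = 8

    def __post_init__(self):
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        if self.in_frames < 1:
            raise ValueError("in_frames must be >= 1")
        u = np.log2(self.upsampling)
        if self.upsampling < 1 or u != int(u):
            raise ValueError("upsampling factor must be a power of two")

    @property
    def n_upsample_stages(self) -> int:
        return int(np.log2(self.upsampling))


@dataclass
class LossSpec:
    """Objective function: 'l1', 'l1+feature' or 'l1+adversarial', with
    regularization weights lambda1 (feature term) and lambda2 (adversarial
    term)."""

    mode: str = "l1"
    lambda1: float = 1e-3
    lambda2: float = 1e-2
    feature_seed: int = 7

    _MODES = ("l1", "l1+feature", "l1+adversarial")

    def __post_init__(self):
        if self.mode not in self._MODES:
            raise ValueError(f"loss mode must be one of {self._MODES}")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("loss weights must be >= 0")


@dataclass
class TrainConfig:
    """Optimization settings: Adam with an initial learning rate decayed by
    ``lr_decay`` when the validation loss stops improving for ``patience``
    epochs; in adversarial mode the critic takes ``critic_steps`` updates per
    generator step with weights clipped to ``clip_bound``."""

    learning_rate: float = 1e-3
    lr_decay: float = 0.5
    patience: int = 10
    min_lr: float = 1e-5
    max_epochs: int = 75
    validation_fraction: float = 0.1
    batch_size: int = 1
    # random horizontal/vertical flips of (input, target) pairs during
    # training: the forward physics is reflection-equivariant in each axis
    # (the PSF is axis-symmetric), so flips are exact invariances of the task.
    # Off by default: at the dataset sizes and epoch budgets this package
    # targets, flips slow convergence on fine two-vessel structure more than
    # they help generalization (see docs/methods.md §5).
    flip_augment: bool = False
    critic_steps: int = 5
    clip_bound: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.lr_decay < 1.0):
            raise ValueError("lr_decay must be in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if not (0.0 < self.validation_fraction < 1.0):
            raise ValueError("validation fraction must be in (0, 1)")


# --------------------------------------------------------------------------- #
# generator / critic / feature extractor
# --------------------------------------------------------------------------- #

def _conv_bn_relu(c_in, c_out, rng):
    return nn.Sequential(nn.Conv2d(c_in, c_out, 3, rng),
                         nn.BatchNorm2d(c_out), nn.ReLU())


class Generator:
    """U-Net encoder/decoder with an R-times upsampling tail; maps
    (N, T, Z, X) to (N, 1, R*Z, R*X); the output is rectified with a small
    leaky slope (clamped to nonnegative at inference)."""

    def __init__(self, spec: GeneratorSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        B, L = spec.base_channels, spec.n_levels
        ch = [B * 2 ** i for i in range(L + 1)]

        self.enc = []
        c_in = spec.in_frames
        for i in range(L):
            self.enc.append(nn.Sequential(_conv_bn_relu(c_in, ch[i], rng),
                                          _conv_bn_relu(ch[i], ch[i], rng)))
            c_in = ch[i]
        self.pools = [nn.MaxPool2x2() for _ in range(L)]
        self.bottleneck = nn.Sequential(_conv_bn_relu(ch[L - 1], ch[L], rng),
                                        _conv_bn_relu(ch[L], ch[L], rng))
        self.up = []
        self.dec = []
        for i in reversed(range(L)):
            self.up.append(nn.ConvTranspose2x2(ch[i + 1], ch[i], rng))
            self.dec.append(nn.Sequential(_conv_bn_relu(2 * ch[i], ch[i], rng),
                                          _conv_bn_relu(ch[i], ch[i], rng)))
        # upsampling tail: conv refinement after every bilinear 2x stage, so
        # the network can place structure at the finest grid instead of only
        # interpolating a coarse map (vessels closer than the coarse pixel
        # pitch need learnable filtering at the output resolution)
        tail = []
        c = ch[0]
        u = spec.n_upsample_stages
        for _ in range(u):
            tail.append(nn.UpsampleBilinear2x())
            tail.append(_conv_bn_relu(c, spec.tail_channels, rng))
            c = spec.tail_channels
        self.tail = nn.Sequential(*tail)
        head_conv = nn.Conv2d(c, 1, 1, rng)
        head_conv.b.value[...] = 0.01
        # leaky rectification: on mostly-empty targets a hard ReLU output can
        # reach an all-negative pre-activation state with zero gradient and
        # never recover; the small negative slope keeps the optimization
        # alive, and inference clamps the output to be nonnegative
        self.head = nn.Sequential(head_conv, nn.LeakyReLU(0.1))

    # -- parameter bookkeeping ------------------------------------------------

    def _modules(self):
        return (self.enc + self.pools + [self.bottleneck] + self.up +
                self.dec + [self.tail, self.head])

    def params(self):
        return [p for m in self._modules() for p in m.params()]

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def _bn_layers(self):
        out = []

        def walk(m):
            if isinstance(m, nn.BatchNorm2d):
                out.append(m)
            if isinstance(m, nn.Sequential):
                for sub in m.layers:
                    walk(sub)
        for m in self._modules():
            walk(m)
        return out

    def state_arrays(self):
        arrs = [p.value for p in self.params()]
        for bn in self._bn_layers():
            arrs += [bn.running_mean, bn.running_var]
        return arrs

    def load_state_arrays(self, arrs):
        ps = self.params()
        for p, a in zip(ps, arrs[:len(ps)]):
            p.value[...] = a
        rest = arrs[len(ps):]
        for bn, mean, var in zip(self._bn_layers(), rest[0::2], rest[1::2]):
            bn.running_mean[...] = mean
            bn.running_var[...] = var

    # -- forward / backward ---------------------------------------------------

    def _check_input(self, x):
        N, T, Z, X = x.shape
        if T != self.spec.in_frames:
            raise ValueError(
                f"input has {T} frames but the model expects "
                f"{self.spec.in_frames}; pass the block through "
                "truncate_and_interpolate or retrain")
        d = 2 ** self.spec.n_levels
        if Z % d or X % d:
            raise ValueError(
                f"spatial dims ({Z}, {X}) must be divisible by {d}; pad by "
                f"({(-Z) % d}, {(-X) % d})")

    def forward(self, x, train=True):
        self._check_input(x)
        skips = []
        h = x
        for enc, pool in zip(self.enc, self.pools):
            h = enc.forward(h, train)
            skips.append(h)
            h = pool.forward(h, train)
        h = self.bottleneck.forward(h, train)
        self._skip_channels = []
        for up, dec, skip in zip(self.up, self.dec, reversed(skips)):
            h = up.forward(h, train)
            self._skip_channels.append(skip.shape[1])
            h = dec.forward(np.concatenate([skip, h], axis=1), train)
        h = self.tail.forward(h, train)
        return self.head.forward(h, train)

    def backward(self, gy):
        g = self.head.backward(gy)
        g = self.tail.backward(g)
        skip_grads = []
        for up, dec, c_skip in zip(reversed(self.up), reversed(self.dec),
                                   reversed(self._skip_channels)):
            g = dec.backward(g)
            skip_grads.append(g[:, :c_skip])
            g = up.backward(g[:, c_skip:])
        g = self.bottleneck.backward(g)
        skip_grads = skip_grads[::-1]
        for enc, pool, gs in zip(reversed(self.enc), reversed(self.pools),
                                 skip_grads):
            g = pool.backward(g)
            g = enc.backward(g + gs)
        return g


def build_generator(spec: GeneratorSpec, seed: int = 0) -> Generator:
    """Construct a generator with deterministic (seeded) initialization."""
    return Generator(spec, seed=seed)


def build_discriminator(image_size: int, base_channels: int = 8,
                        seed: int = 0) -> nn.Sequential:
    """Wasserstein critic: input 3x3 conv block, three downsampling blocks
    (two 3x3 convs, the second strided), a 3x3 output conv, spatial mean to a
    scalar score.  Leaky ReLU (slope 0.2) throughout, no sigmoid."""
    if image_size < 8:
        raise ValueError("critic input must be at least 8 x 8")
    rng = np.random.default_rng(seed)
    b = base_channels
    layers = [nn.Conv2d(1, b, 3, rng), nn.LeakyReLU(0.2)]
    c = b
    for _ in range(3):
        layers += [nn.Conv2d(c, c, 3, rng), nn.LeakyReLU(0.2),
                   nn.Conv2d(c, 2 * c, 3, rng), nn.Downsample2x(),
                   nn.LeakyReLU(0.2)]
        c *= 2
    layers += [nn.Conv2d(c, 1, 3, rng), nn.GlobalMean()]
    return nn.Sequential(*layers)


class FeatureExtractor:
    """Fixed, seeded, untrained convolutional stack used by the feature-space
    loss (synthetic stand-in for a pretrained perceptual network; the
    extractor is pluggable — any object with ``forward``/``backward`` over
    (N, 1, H, W) works)."""

    def __init__(self, seed: int = 7):
        rng = np.random.default_rng(seed)
        self.net = nn.Sequential(nn.Conv2d(1, 8, 3, rng), nn.ReLU(),
                                 nn.MaxPool2x2(),
                                 nn.Conv2d(8, 16, 3, rng), nn.ReLU())

    def forward(self, x):
        return self.net.forward(x, train=False)

    def backward(self, gy):
        return self.net.backward(gy)


# --------------------------------------------------------------------------- #
# losses
# --------------------------------------------------------------------------- #

def compute_loss(pred: np.ndarray, target: np.ndarray, spec: LossSpec,
                 critic_scores: Optional[np.ndarray] = None,
                 feature_extractor: Optional[FeatureExtractor] = None):
    """Total loss and per-term components for a prediction/target pair.

    L1 term: mean absolute difference.  Feature term: mean squared difference
    of extractor feature maps (weight lambda1).  Adversarial term: minus the
    mean critic score of the generated images (weight lambda2).  Terms not
    selected by ``spec.mode`` are reported as 0 and excluded from the total.
    """
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise ValueError("prediction/target shape mismatch")
    comps = {"l1": float(np.mean(np.abs(pred - target))),
             "feature": 0.0, "adversarial": 0.0}
    total = comps["l1"]
    if spec.mode == "l1+feature":
        fe = feature_extractor or FeatureExtractor(spec.feature_seed)
        p4 = pred.reshape(-1, 1, *pred.shape[-2:])
        t4 = target.reshape(-1, 1, *target.shape[-2:])
        comps["feature"] = float(np.mean(
            (fe.forward(p4) - fe.forward(t4)) ** 2))
        total += spec.lambda1 * comps["feature"]
    elif spec.mode == "l1+adversarial":
        if critic_scores is None:
            raise ValueError("adversarial mode requires critic scores")
        comps["adversarial"] = float(-np.mean(critic_scores))
        total += spec.lambda2 * comps["adversarial"]
    comps["total"] = float(total)
    return total, comps


# --------------------------------------------------------------------------- #
# model / results
# --------------------------------------------------------------------------- #

def block_to_input(block: SpatiotemporalBlock, *, collapse: bool = False,
                   scale: Optional[float] = None,
                   percentile: float = 99.0) -> np.ndarray:
    """Turn a clutter-filtered block into a network input tensor (C, Z, X):
    slow-time frames as channels (or a single accumulated power Doppler
    channel when ``collapse``), magnitudes divided by the block's 99th
    percentile (or an explicit ``scale``)."""
    if block.kind != "clutter_filtered":
        raise ValueError("network input must be a clutter-filtered block")
    mag = np.abs(block.data)
    if scale is None:
        scale = float(np.percentile(mag, percentile))
    scale = max(scale, 1e-30)
    if collapse:
        pdimg = power_doppler(block).intensity
        return (pdimg / max(pdimg.max(), 1e-30))[None]
    return (mag / scale).transpose(2, 0, 1)


class CspdResults:
    """Fit results: the trained generator, training history and diagnostics."""

    def __init__(self, model: Generator, gen_spec: GeneratorSpec,
                 loss_spec: LossSpec, config: TrainConfig,
                 history: pd.DataFrame, best_val_loss: float,
                 n_train: int, n_val: int, collapse_input: bool = False):
        self.model = model
        self.gen_spec = gen_spec
        self.loss_spec = loss_spec
        self.config = config
        self.history = history
        self.best_val_loss = best_val_loss
        self.n_train = n_train
        self.n_val = n_val
        self.collapse_input = collapse_input

    # -- inference ------------------------------------------------------------

    def predict_array(self, x: np.ndarray) -> np.ndarray:
        """Run the generator on a (C, Z, X) input tensor; returns the
        nonnegative (RZ, RX) reconstruction."""
        return np.maximum(self.model.forward(x[None], train=False)[0, 0], 0.0)

    def predict(self, block: SpatiotemporalBlock, *, normalize: bool = True,
                scale: Optional[float] = None) -> np.ndarray:
        """Reconstruct the super-resolved image from a clutter-filtered block.

        With ``normalize`` the output is scaled to [0, 1]; pass
        ``normalize=False`` (and optionally a fixed input ``scale``) to keep
        the native network intensity, e.g. for temporal series analysis.
        Inference is deterministic: normalization layers use running
        statistics.
        """
        x = block_to_input(block, collapse=self.collapse_input, scale=scale)
        if not self.collapse_input and x.shape[0] != self.gen_spec.in_frames:
            raise ValueError(
                f"block has {x.shape[0]} frames, model expects "
                f"{self.gen_spec.in_frames}; apply truncate_and_interpolate "
                "or retrain with matching in_frames")
        out = self.predict_array(x)
        if normalize:
            m = out.max()
            if m > 0:
                out = out / m
        return out

    # -- reporting ------------------------------------------------------------

    def summary(self) -> str:
        h = self.history
        buf = _io.StringIO()
        w = 58
        print("=" * w, file=buf)
        print("Contrast-free super-resolution power Doppler — fit".center(w),
              file=buf)
        print("=" * w, file=buf)
        rows = [
            ("Loss mode", self.loss_spec.mode),
            ("Generator parameters", f"{self.model.n_parameters():,}"),
            ("Input frames (channels)",
             "1 (collapsed PD)" if self.collapse_input
             else str(self.gen_spec.in_frames)),
            ("Upsampling factor R", str(self.gen_spec.upsampling)),
            ("Training / validation samples",
             f"{self.n_train} / {self.n_val}"),
            ("Epochs run", str(len(h))),
            ("Final learning rate",
             f"{h['lr'].iloc[-1]:.2e}" if len(h) else "-"),
            ("Best validation loss", f"{self.best_val_loss:.5f}"),
            ("Final training loss",
             f"{h['train_loss'].iloc[-1]:.5f}" if len(h) else "-"),
        ]
        for k, v in rows:
            print(f"{k:<34}{v:>24}", file=buf)
        print("=" * w, file=buf)
        return buf.getvalue()

    def plot_history(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.history["epoch"], self.history["train_loss"],
                label="train")
        ax.plot(self.history["epoch"], self.history["val_loss"],
                label="validation")
        ax.set_xlabel("epoch")
        ax.set_ylabel("loss")
        ax.legend()
        return ax

    def save(self, path) -> None:
        save_model(path, self)


class CspdModel:
    """The learned reconstruction model, built from (blocks, ULM) training
    pairs; ``fit`` trains the generator and returns :class:`CspdResults`."""

    def __init__(self, inputs: Sequence[np.ndarray],
                 targets: Sequence[np.ndarray],
                 gen_spec: GeneratorSpec,
                 loss_spec: LossSpec = LossSpec(),
                 collapse_input: bool = False):
        if len(inputs) != len(targets) or not inputs:
            raise ValueError("need >= 1 training pair with matching lengths")
        self.inputs = [np.asarray(x, dtype=float) for x in inputs]
        self.targets = [np.asarray(t, dtype=float).reshape(
            1, *np.asarray(t).shape[-2:]) for t in targets]
        self.gen_spec = gen_spec
        self.loss_spec = loss_spec
        self.collapse_input = collapse_input

    @classmethod
    def from_pairs(cls, pairs, gen_spec: GeneratorSpec,
                   loss_spec: LossSpec = LossSpec(),
                   collapse_input: bool = False,
                   target_sigma_px: float = 1.0) -> "CspdModel":
        """Build from per-plane ``(blocks, UlmImage)`` pairs of clutter-filtered
        blocks; every block of a plane is paired with that plane's ULM target
        rendered with a ``target_sigma_px`` Gaussian spot per event (0 keeps
        the raw Dirac accumulation map).  The target grid must match the
        generator's upsampling."""
        inputs, targets = [], []
        for blocks, ulm in pairs:
            target = ulm.rendered(target_sigma_px)
            for blk in blocks:
                x = block_to_input(blk, collapse=collapse_input)
                Z, X = blk.grid_shape
                R = gen_spec.upsampling
                if target.shape != (R * Z, R * X):
                    raise ValueError(
                        f"ULM target grid {target.shape} does not match "
                        f"R x block grid ({R * Z}, {R * X})")
                inputs.append(x)
                targets.append(target)
        return cls(inputs, targets, gen_spec, loss_spec,
                   collapse_input=collapse_input)

    # -- training -------------------------------------------------------------

    def _loss_and_grad(self, pred, target, critic=None, fe=None):
        n = pred.size
        diff = pred - target
        grad = np.sign(diff) / n
        total, comps = None, {"l1": float(np.mean(np.abs(diff))),
                              "feature": 0.0, "adversarial": 0.0}
        total = comps["l1"]
        if self.loss_spec.mode == "l1+feature":
            fp = fe.forward(pred)
            ft = fe.forward(target)
            d = fp - ft
            comps["feature"] = float(np.mean(d ** 2))
            total += self.loss_spec.lambda1 * comps["feature"]
            grad = grad + self.loss_spec.lambda1 * \
                fe.backward(2.0 * d / d.size)
        elif self.loss_spec.mode == "l1+adversarial":
            scores = critic.forward(pred, train=True)
            comps["adversarial"] = float(-np.mean(scores))
            total += self.loss_spec.lambda2 * comps["adversarial"]
            gscore = np.full(scores.shape, -1.0 / scores.size)
            grad = grad + self.loss_spec.lambda2 * critic.backward(gscore)
        comps["total"] = float(total)
        return total, grad, comps

    def fit(self, config: TrainConfig = TrainConfig()) -> CspdResults:
        """Train the generator; returns results at the best-validation
        checkpoint.  Reproducible for a fixed config seed."""
        cfg = config
        rng = np.random.default_rng(cfg.seed)
        n = len(self.inputs)
        n_val = max(1, int(round(cfg.validation_fraction * n)))
        if n_val >= n:
            raise ValueError("validation split leaves no training samples")
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]

        spec = self.gen_spec
        gen = Generator(spec, seed=int(rng.integers(2 ** 31)))
        opt = nn.Adam(gen.params(), lr=cfg.learning_rate)
        adversarial = self.loss_spec.mode == "l1+adversarial"
        fe = (FeatureExtractor(self.loss_spec.feature_seed)
              if self.loss_spec.mode == "l1+feature" else None)
        critic = copt = None
        if adversarial:
            img = self.targets[0].shape[-1]
            critic = build_discriminator(img, seed=int(rng.integers(2 ** 31)))
            copt = nn.Adam(critic.params(), lr=cfg.learning_rate)

        history = []
        best_val = np.inf
        best_state = None
        lr = cfg.learning_rate
        stall = 0
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(tr_idx)
            tr_losses = []
            for s0 in range(0, len(order), cfg.batch_size):
                batch = order[s0:s0 + cfg.batch_size]
                x = np.stack([self.inputs[i] for i in batch])
                y = np.stack([self.targets[i] for i in batch])
                if cfg.flip_augment:
                    for axis in (-2, -1):
                        if rng.random() < 0.5:
                            x = np.flip(x, axis=axis)
                            y = np.flip(y, axis=axis)
                    x = np.ascontiguousarray(x)
                    y = np.ascontiguousarray(y)
                if adversarial:
                    self._critic_steps(critic, copt, gen, x, y, cfg)
                pred = gen.forward(x, train=True)
                loss, grad, _ = self._loss_and_grad(pred, y, critic, fe)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}, batch start {s0} "
                        f"(lr={lr:.3g}); aborting")
                opt.zero_grad()
                gen.backward(grad)
                opt.step()
                tr_losses.append(loss)
            val_loss = self._validation_loss(gen, val_idx, fe)
            history.append({"epoch": epoch, "train_loss": np.mean(tr_losses),
                            "val_loss": val_loss, "lr": lr})
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_state = [a.copy() for a in gen.state_arrays()]
                stall = 0
            else:
                stall += 1
                if stall >= cfg.patience:
                    lr = max(lr * cfg.lr_decay, cfg.min_lr)
                    opt.lr = lr
                    stall = 0
        if best_state is not None:
            gen.load_state_arrays(best_state)
        return CspdResults(gen, spec, self.loss_spec, cfg,
                           pd.DataFrame(history), float(best_val),
                           len(tr_idx), n_val,
                           collapse_input=self.collapse_input)

    def _validation_loss(self, gen, val_idx, fe):
        """Content (non-adversarial) loss on the validation split, evaluated
        with frozen normalization statistics."""
        losses = []
        for i in val_idx:
            pred = gen.forward(self.inputs[i][None], train=False)
            diff = pred - self.targets[i][None]
            loss = float(np.mean(np.abs(diff)))
            if self.loss_spec.mode == "l1+feature":
                d = fe.forward(pred) - fe.forward(self.targets[i][None])
                loss += self.loss_spec.lambda1 * float(np.mean(d ** 2))
            losses.append(loss)
        return float(np.mean(losses))

    def _critic_steps(self, critic, copt, gen, x, y, cfg):
        # critic minimizes mean(score(fake)) - mean(score(real)), with weight
        # clipping enforcing the Lipschitz constraint
        fake = gen.forward(x, train=False)
        for _ in range(cfg.critic_steps):
            copt.zero_grad()
            s_fake = critic.forward(fake, train=True)
            critic.backward(np.full(s_fake.shape, 1.0 / s_fake.size))
            s_real = critic.forward(y, train=True)
            critic.backward(np.full(s_real.shape, -1.0 / s_real.size))
            copt.step()
            nn.clip_params(critic.params(), cfg.clip_bound)


def train(pairs, loss: LossSpec = LossSpec(),
          config: TrainConfig = TrainConfig(),
          gen_spec: Optional[GeneratorSpec] = None,
          collapse_input: bool = False) -> CspdResults:
    """Functional training entry point over (blocks, UlmImage) pairs."""
    if gen_spec is None:
        t = pairs[0][0][0].n_frames
        r = pairs[0][1].upsampling
        gen_spec = GeneratorSpec(in_frames=t, upsampling=r)
    model = CspdModel.from_pairs(pairs, gen_spec, loss,
                                 collapse_input=collapse_input)
    return model.fit(config)


def infer(results: CspdResults, block: SpatiotemporalBlock,
          **kwargs) -> np.ndarray:
    """Reconstruct a super-resolved image from a clutter-filtered block."""
    return results.predict(block, **kwargs)


def predict_flow_separated(results: CspdResults,
                           block: SpatiotemporalBlock,
                           n_bands: int = 3,
                           normalize: bool = True) -> np.ndarray:
    """Flow-separated reconstruction: the block is partitioned into slow-time
    spectral bands, each band is reconstructed independently, and the
    reconstructions are summed.  Vessels whose flow speeds fall in different
    bands are reconstructed in isolation, which separates vessels that overlap
    below the diffraction limit in the composite image."""
    from .doppler import flow_separation_augment

    out = None
    for band in flow_separation_augment(block, n_bands):
        img = results.predict(band, normalize=False)
        out = img if out is None else out + img
    if normalize:
        m = out.max()
        if m > 0:
            out = out / m
    return out


# --------------------------------------------------------------------------- #
# persistence
# --------------------------------------------------------------------------- #

def save_model(path, results: CspdResults) -> None:
    """Self-describing checkpoint: architecture/loss/config as JSON plus all
    parameter and normalization-statistics arrays."""
    meta = json.dumps({
        "gen_spec": asdict(results.gen_spec),
        "loss_spec": asdict(results.loss_spec),
        "config": asdict(results.config),
        "collapse_input": results.collapse_input,
        "best_val_loss": results.best_val_loss,
        "n_train": results.n_train,
        "n_val": results.n_val,
    })
    arrays = {f"arr_{i}": a for i, a in
              enumerate(results.model.state_arrays())}
    hist = results.history.to_json() if len(results.history) else "{}"
    np.savez(path, meta=np.array(meta), history=np.array(hist), **arrays)


def load_model(path) -> CspdResults:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        arrays = [z[f"arr_{i}"] for i in range(len(z.files) - 2)]
        hist = pd.read_json(_io.StringIO(str(z["history"])))
    gen_spec = GeneratorSpec(**meta["gen_spec"])
    gen = Generator(gen_spec, seed=0)
    gen.load_state_arrays(arrays)
    return CspdResults(gen, gen_spec, LossSpec(**meta["loss_spec"]),
                       TrainConfig(**meta["config"]), hist,
                       meta["best_val_loss"], meta["n_train"], meta["n_val"],
                       collapse_input=meta["collapse_input"])
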