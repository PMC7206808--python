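"""Encoder-decoder segmentation networks, training loop and inference.

Three architectures are provided, all mapping a grayscale image to a
two-channel per-pixel class probability map (channel 1 = nerve):

``autoencoder``
    Plain encoder-decoder: conv/BN/ReLU pairs with 2x2 max pooling on the
    way down and parameter-free 2x nearest upsampling on the way up.
``unet``
    The autoencoder plus skip connections: each decoder level concatenates
    the same-resolution encoder feature map before its convolutions. The
    canonical "deep" configuration (depth 4, base 16 filters) has 487,730
    trainable parameters.
``unet_residual``
    The U-Net with additional residual branches within each conv pair
    (identity or 1x1-projection shortcut), easing gradient flow in deeper
    networks.

Training minimizes per-pixel categorical cross-entropy with Adam, re-splits
the data 90/10 into train/validation at each epoch, and keeps the weights
with the best validation loss. Everything is seeded and bit-reproducible on
CPU.
"""

from __future__ import annotations

import io
import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .core import IVCMImage, ProbabilityMap, TracingMap
from .nn import (
    Adam,
    BatchNorm2D,
    Conv2D,
    ConvBNReLU,
    Dropout,
    MaxPool2x2,
    Param,
    ReLU,
    UpsampleNearest2x,
    softmax,
    softmax_cross_entropy,
)

__all__ = [
    "ModelConfig",
    "AugmentConfig",
    "TrainConfig",
    "TrainedModel",
    "deep_unet_config",
    "build_model",
    "count_trainable_parameters",
    "apply_geometric",
    "augment",
    "train",
    "predict_probability",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyper-parameters.

    ``depth`` counts encoder levels including the bottleneck; channel width
    doubles per level starting from ``base_filters``. Dropout (rate
    ``dropout_rate``) is applied after the conv pair of the ``dropout_levels``
    deepest encoder levels.
    """

    architecture: str = "unet"
    depth: int = 4
    base_filters: int = 16
    dropout_rate: float = 0.2
    dropout_levels: int = 2
    n_classes: int = 2
    input_size_px: int = 384

    def __post_init__(self) -> None:
        if self.architecture not in ("autoencoder", "unet", "unet_residual"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_filters < 4:
            raise ValueError("base_filters must be >= 4")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.n_classes != 2:
            raise ValueError("only two-class (nerve vs background) output is supported")
        stride = 2 ** (self.depth - 1)
        if self.input_size_px % stride:
            pad = stride - self.input_size_px % stride
            raise ValueError(
                f"input_size_px {self.input_size_px} is not divisible by "
                f"2^(depth-1) = {stride}; pad by {pad} px or change depth"
            )


def deep_unet_config() -> ModelConfig:
    """The canonical deep U-Net configuration (487,730 trainable parameters)."""
    return ModelConfig(architecture="unet", depth=4, base_filters=16)


@dataclass(frozen=True)
class AugmentConfig:
    """Random geometric augmentation: rotations, skews (shears) and flips."""

    enabled: bool = True
    rotation_degrees_max: float = 15.0
    skew_shear_max: float = 0.1
    flip_horizontal: bool = True
    flip_vertical: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.rotation_degrees_max <= 180.0):
            raise ValueError("rotation_degrees_max must lie in [0, 180]")
        if self.skew_shear_max < 0:
            raise ValueError("skew_shear_max must be >= 0")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyper-parameters.

    The learning-rate schedule drops the rate every ``lr_drop_every_epochs``
    epochs. Two modes are exposed because the drop rule admits more than one
    reading: ``multiply`` (default) scales the rate so it halves every 100
    epochs; ``subtract_floor`` subtracts ``lr_drop`` at each boundary,
    floored at 1e-5.
    """

    optimizer: str = "adam"
    lr_initial: float = 1e-3
    lr_drop: float = 5e-4
    lr_drop_every_epochs: int = 10
    lr_schedule_mode: str = "multiply"
    epochs: int = 650
    batch_size: int = 8
    val_fraction: float = 0.10
    seed: int = 0
    augmentation: AugmentConfig = field(default_factory=AugmentConfig)
    foreground_weight: float = 1.0
    resplit_each_epoch: bool = True
    intensity_scale: float = 255.0

    def __post_init__(self) -> None:
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if not (0.0 < self.val_fraction < 1.0):
            raise ValueError("val_fraction must lie in (0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.lr_initial <= 0:
            raise ValueError("lr_initial must be positive")
        if self.lr_schedule_mode not in ("multiply", "subtract_floor"):
            raise ValueError(f"unknown lr_schedule_mode {self.lr_schedule_mode!r}")

    def learning_rate(self, epoch: int) -> float:
        """Learning rate in force during 0-based ``epoch``."""
        drops = epoch // self.lr_drop_every_epochs
        if self.lr_schedule_mode == "multiply":
            factor = 0.5 ** (self.lr_drop_every_epochs / 100.0)
            return self.lr_initial * factor**drops
        return max(self.lr_initial - self.lr_drop * drops, 1e-5)


class _DoubleConv:
    """Two conv/BN/ReLU units."""

    def __init__(self, cin: int, cmid: int, rng: np.random.Generator, name: str) -> None:
        self.a = ConvBNReLU(cin, cmid, 3, rng, f"{name}.0")
        self.b = ConvBNReLU(cmid, cmid, 3, rng, f"{name}.1")

    def params(self) -> list[Param]:
        return self.a.params() + self.b.params()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.b.forward(self.a.forward(x, train), train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.a.backward(self.b.backward(dy))


class _ResidualDoubleConv:
    """Conv pair with a shortcut branch added before the final ReLU."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, name: str) -> None:
        self.a = ConvBNReLU(cin, cout, 3, rng, f"{name}.0")
        self.conv_b = Conv2D(cout, cout, 3, rng, bias=False, name=f"{name}.1")
        self.bn_b = BatchNorm2D(cout, name=f"{name}.1")
        self.proj = (
            None if cin == cout else Conv2D(cin, cout, 1, rng, bias=True, name=f"{name}.proj")
        )
        self.relu_out = ReLU()

    def params(self) -> list[Param]:
        p = self.a.params() + self.conv_b.params() + self.bn_b.params()
        if self.proj is not None:
            p += self.proj.params()
        return p

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        main = self.bn_b.forward(self.conv_b.forward(self.a.forward(x, train), train), train)
        short = x if self.proj is None else self.proj.forward(x, train)
        return self.relu_out.forward(main + short, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.relu_out.backward(dy)
        dx_main = self.a.backward(self.conv_b.backward(self.bn_b.backward(d)))
        dx_short = d if self.proj is None else self.proj.backward(d)
        return dx_main + dx_short


class SegmentationNet:
    """Encoder-decoder network instance (see module docstring)."""

    def __init__(self, cfg: ModelConfig, seed: int = 0) -> None:
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.skip_connections = cfg.architecture in ("unet", "unet_residual")
        Block = (
            _ResidualDoubleConv if cfg.architecture == "unet_residual" else _DoubleConv
        )
        ch = [cfg.base_filters * 2**i for i in range(cfg.depth)]
        self.channels = ch
        self.enc = []
        cin = 1
        for lvl in range(cfg.depth):
            self.enc.append(Block(cin, ch[lvl], rng, f"enc{lvl}"))
            cin = ch[lvl]
        self.pools = [MaxPool2x2() for _ in range(cfg.depth - 1)]
        self.ups = [UpsampleNearest2x() for _ in range(cfg.depth - 1)]
        self.dec = []
        cin = ch[-1]
        for i, lvl in enumerate(range(cfg.depth - 2, -1, -1)):
            dec_in = cin + (ch[lvl] if self.skip_connections else 0)
            self.dec.append(Block(dec_in, ch[lvl], rng, f"dec{lvl}"))
            cin = ch[lvl]
        self.final = Conv2D(ch[0], cfg.n_classes, 1, rng, bias=True, name="final")
        drop_levels = set(range(cfg.depth - cfg.dropout_levels, cfg.depth))
        self.dropouts = {
            lvl: Dropout(cfg.dropout_rate) for lvl in drop_levels if cfg.dropout_rate > 0
        }

    def params(self) -> list[Param]:
        out: list[Param] = []
        for blk in self.enc:
            out += blk.params()
        for blk in self.dec:
            out += blk.params()
        out += self.final.params()
        return out

    def batchnorms(self) -> list[BatchNorm2D]:
        bns = []
        for blk in self.enc + self.dec:
            for attr in ("a", "b", "bn_b"):
                unit = getattr(blk, attr, None)
                if isinstance(unit, ConvBNReLU):
                    bns.append(unit.bn)
                elif isinstance(unit, BatchNorm2D):
                    bns.append(unit)
        return bns

    def forward(
        self, x: np.ndarray, train: bool = True, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        """Logits (N, H, W, n_classes) for input (N, H, W, 1)."""
        stride = 2 ** (self.cfg.depth - 1)
        if x.shape[1] % stride or x.shape[2] % stride:
            raise ValueError(
                f"input spatial size {x.shape[1:3]} not divisible by {stride}"
            )
        skips: list[np.ndarray] = []
        h = x.astype(np.float32)
        for lvl in range(self.cfg.depth):
            h = self.enc[lvl].forward(h, train)
            if lvl in self.dropouts:
                h = self.dropouts[lvl].forward(h, train, rng)
            if lvl < self.cfg.depth - 1:
                skips.append(h)
                h = self.pools[lvl].forward(h, train)
        self._skip_channels = []
        for i, lvl in enumerate(range(self.cfg.depth - 2, -1, -1)):
            h = self.ups[i].forward(h, train)
            if self.skip_connections:
                self._skip_channels.append((h.shape[-1], skips[lvl].shape[-1]))
                h = np.concatenate([h, skips[lvl]], axis=-1)
            h = self.dec[i].forward(h, train)
        return self.final.forward(h, train)

    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients for the last training forward."""
        d = self.final.backward(dlogits)
        depth = self.cfg.depth
        dskips: dict[int, np.ndarray] = {}
        for i in range(depth - 2, -1, -1):
            lvl = depth - 2 - i
            d = self.dec[i].backward(d)
            if self.skip_connections:
                c_up, _ = self._skip_channels[i]
                dskips[lvl] = d[..., c_up:]
                d = d[..., :c_up]
            d = self.ups[i].backward(d)
        for lvl in range(depth - 1, -1, -1):
            if lvl < depth - 1:
                d = self.pools[lvl].backward(d)
                if lvl in dskips:
                    d = d + dskips[lvl]
            if lvl in self.dropouts:
                d = self.dropouts[lvl].backward(d)
            d = self.enc[lvl].backward(d)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities (N, H, W, n_classes), eval mode."""
        return softmax(self.forward(x, train=False))

    def state(self) -> list[np.ndarray]:
        arrays = [p.value.copy() for p in self.params()]
        for bn in self.batchnorms():
            arrays += [bn.running_mean.copy(), bn.running_var.copy()]
        return arrays

    def load_state(self, arrays: list[np.ndarray]) -> None:
        params = self.params()
        for p, a in zip(params, arrays[: len(params)]):
            p.value[...] = a
        rest = arrays[len(params) :]
        for bn, mean, var in zip(self.batchnorms(), rest[0::2], rest[1::2]):
            bn.running_mean[...] = mean
            bn.running_var[...] = var


def build_model(cfg: ModelConfig, seed: int = 0) -> SegmentationNet:
    """Instantiate an untrained network from its configuration."""
    return SegmentationNet(cfg, seed=seed)


def count_trainable_parameters(model: SegmentationNet) -> int:
    """Total number of learnable weight, bias and batch-norm entries."""
    return sum(p.size for p in model.params())


def apply_geometric(
    image: np.ndarray,
    mask: np.ndarray,
    angle_deg: float = 0.0,
    shear: float = 0.0,
    flip_h: bool = False,
    flip_v: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one geometric transform identically to an image and its mask.

    The image is resampled bilinearly with reflect padding; the mask uses
    nearest-neighbour resampling so it stays strictly binary.
    """
    img = image[::-1] if flip_v else image
    msk = mask[::-1] if flip_v else mask
    if flip_h:
        img, msk = img[:, ::-1], msk[:, ::-1]
    if angle_deg == 0.0 and shear == 0.0:
        return np.ascontiguousarray(img), np.ascontiguousarray(msk)
    theta = math.radians(angle_deg)
    rot = np.array(
        [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
    )
    sh = np.array([[1.0, shear], [0.0, 1.0]])
    matrix = rot @ sh
    center = (np.array(image.shape) - 1) / 2.0
    offset = center - matrix @ center
    out_img = ndimage.affine_transform(
        img, matrix, offset=offset, order=1, mode="reflect"
    )
    # same reflect padding as the image so border labels stay consistent
    out_msk = ndimage.affine_transform(
        msk.astype(np.uint8), matrix, offset=offset, order=0, mode="reflect"
    )
    return out_img, out_msk


def augment(
    image: np.ndarray,
    mask: np.ndarray,
    cfg: AugmentConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one random rotation/skew/flip combination and apply it to both."""
    if not cfg.enabled:
        return image, mask
    angle = rng.uniform(-cfg.rotation_degrees_max, cfg.rotation_degrees_max)
    shear = rng.uniform(-cfg.skew_shear_max, cfg.skew_shear_max)
    flip_h = cfg.flip_horizontal and rng.uniform() < 0.5
    flip_v = cfg.flip_vertical and rng.uniform() < 0.5
    return apply_geometric(image, mask, angle, shear, flip_h, flip_v)


@dataclass
class TrainedModel:
    """A trained network with its configs and per-epoch loss history."""

    model: SegmentationNet
    model_config: ModelConfig
    train_config: TrainConfig
    history: dict[str, list[float]]

    def save(self, path) -> None:
        meta = json.dumps(
            {
                "model_config": asdict(self.model_config),
                "train_config": asdict(self.train_config),
                "history": self.history,
            }
        )
        arrays = {f"arr{i}": a for i, a in enumerate(self.model.state())}
        np.savez(path, meta=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            arrays = [data[f"arr{i}"] for i in range(len(data.files) - 1)]
        mcfg = ModelConfig(**meta["model_config"])
        tc = dict(meta["train_config"])
        tc["augmentation"] = AugmentConfig(**tc["augmentation"])
        tcfg = TrainConfig(**tc)
        model = build_model(mcfg)
        model.load_state(arrays)
        return cls(model, mcfg, tcfg, meta["history"])


def _as_batch(images: list[np.ndarray]) -> np.ndarray:
    return np.stack(images)[..., None].astype(np.float32)


def train(
    model: SegmentationNet,
    dataset: list[tuple[IVCMImage, TracingMap]],
    cfg: TrainConfig,
) -> TrainedModel:
    """Train a segmentation network on (image, tracing) pairs.

    Images are expected flat-fielded; intensities are scaled by
    ``1 / intensity_scale`` before entering the network. At each epoch the
    dataset is randomly re-split into 90/10 train/validation (configurable);
    the returned model carries the weights of the best validation epoch.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    xs = [img.pixels / cfg.intensity_scale for img, _ in dataset]
    ys = [tr.pixels.astype(np.int64) for _, tr in dataset]
    if not any(y.any() for y in ys):
        warnings.warn("dataset has no foreground pixels; training is degenerate")

    n = len(dataset)
    n_val = min(max(1, round(cfg.val_fraction * n)), n - 1)
    rng = np.random.default_rng(cfg.seed)
    class_weights = np.array([1.0, cfg.foreground_weight])

    optimizer = Adam(model.params(), lr=cfg.lr_initial)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": [], "lr": []}
    best_val = np.inf
    best_state = model.state()
    split = rng.permutation(n)

    for epoch in range(cfg.epochs):
        lr = cfg.learning_rate(epoch)
        optimizer.lr = lr
        if cfg.resplit_each_epoch or epoch == 0:
            split = rng.permutation(n)
        val_idx, train_idx = split[:n_val], split[n_val:]

        order = rng.permutation(len(train_idx))
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch = [train_idx[o] for o in order[start : start + cfg.batch_size]]
            imgs, masks = [], []
            for idx in batch:
                im, mk = augment(xs[idx], ys[idx], cfg.augmentation, rng)
                imgs.append(im)
                masks.append(mk.astype(np.int64))
            x = _as_batch(imgs)
            y = np.stack(masks)
            logits = model.forward(x, train=True, rng=rng)
            loss, dlogits = softmax_cross_entropy(logits, y, class_weights)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {loss}"
                )
            optimizer.zero_grad()
            model.backward(dlogits)
            optimizer.step()
            epoch_losses.append(loss)

        val_losses = []
        for start in range(0, len(val_idx), cfg.batch_size):
            batch = val_idx[start : start + cfg.batch_size]
            x = _as_batch([xs[i] for i in batch])
            y = np.stack([ys[i] for i in batch])
            logits = model.forward(x, train=False)
            loss, _ = softmax_cross_entropy(logits, y, class_weights)
            val_losses.append(loss * len(batch))
        val_loss = float(np.sum(val_losses) / len(val_idx))
        if not np.isfinite(val_loss):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")

        history["train_loss"].append(float(np.mean(epoch_losses)))
        history["val_loss"].append(val_loss)
        history["lr"].append(lr)
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state()

    model.load_state(best_state)
    return TrainedModel(model, model.cfg, cfg, history)


def predict_probability(trained: TrainedModel | SegmentationNet, image: IVCMImage,
                        intensity_scale: float | None = None) -> ProbabilityMap:
    """Nerve-class probability map for one image (channel 1 of the softmax).

    Inputs whose size is not a multiple of the network stride are
    reflect-padded for inference and cropped back afterwards.
    """
    if isinstance(trained, TrainedModel):
        model = trained.model
        scale = intensity_scale or trained.train_config.intensity_scale
    else:
        model = trained
        scale = intensity_scale or 255.0
    x = image.pixels / scale
    stride = 2 ** (model.cfg.depth - 1)
    h, w = x.shape
    ph = (-h) % stride
    pw = (-w) % stride
    if ph or pw:
        x = np.pad(x, ((0, ph), (0, pw)), mode="reflect")
    probs = model.predict(x[None, ..., None])[0, ..., 1]
    probs = probs[:h, :w]
    return ProbabilityMap(np.clip(probs.astype(np.float64), 0.0, 1.0), image.calibration)
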