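"""End-to-end profusion-level classifier.

The architecture follows the texture-encoding design: an 18-layer residual
backbone (global average pooling removed) produces a W/32 x H/32 x 512
feature map, a 1x1 convolution reduces the channels, the texture encoding
and suppression (TES) layer turns the spatial descriptors into a K x C
orderless encoding, which is flattened, L2-normalized and fed to a fully
connected layer scoring the four profusion levels.  For a 256-pixel input
with the standard backbone the intermediate shapes are 8x8x512 -> 8x8x256
-> (8 codewords x 256) -> 2048 -> 4.

Training optimizes a weighted sum of the supervised contrastive loss on the
normalized encodings and the class-reweighted KL divergence between the
predicted softmax and the ordinal ground-truth label distribution.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from . import nn, objectives
from .config import ConfigError, LossConfig, ModelConfig, TrainConfig

__all__ = [
    "NetworkModel",
    "build_model",
    "forward",
    "predict_profusion",
    "train",
    "train_arrays",
    "save_checkpoint",
    "load_checkpoint",
    "load_manifest_images",
]

_WIDTHS = {"resnet18": (64, 64, 128, 256, 512), "small": (32, 32, 64, 128, 256)}


class _BasicBlock:
    """Two 3x3 conv+BN with a residual connection; 1x1 projection on stride."""

    def __init__(self, in_ch, out_ch, stride, rng):
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, stride, 1, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, 1, 1, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(out_ch)
        self.relu2 = nn.ReLU()
        if stride != 1 or in_ch != out_ch:
            self.proj = nn.Conv2d(in_ch, out_ch, 1, stride, 0, bias=False, rng=rng)
            self.proj_bn = nn.BatchNorm2d(out_ch)
        else:
            self.proj = self.proj_bn = None

    def sublayers(self):
        out = [("conv1", self.conv1), ("bn1", self.bn1), ("conv2", self.conv2), ("bn2", self.bn2)]
        if self.proj is not None:
            out += [("proj", self.proj), ("proj_bn", self.proj_bn)]
        return out

    def forward(self, x, train=False):
        y = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        y = self.bn2.forward(self.conv2.forward(y, train), train)
        if self.proj is not None:
            skip = self.proj_bn.forward(self.proj.forward(x, train), train)
        else:
            skip = x
        return self.relu2.forward(y + skip, train)

    def backward(self, dout):
        d = self.relu2.backward(dout)
        dmain = self.conv2.backward(self.bn2.backward(d))
        dmain = self.conv1.backward(self.bn1.backward(self.relu1.backward(dmain)))
        if self.proj is not None:
            dskip = self.proj.backward(self.proj_bn.backward(d))
        else:
            dskip = d
        return dmain + dskip


class NetworkModel:
    """The assembled classifier; see module docstring for the layer plan."""

    def __init__(self, config: ModelConfig):
        config.validate()
        widths = _WIDTHS[config.backbone]
        if config.reduced_channels < 1:
            raise ConfigError("reduced_channels must be >= 1")
        self.config = config
        rng = np.random.default_rng(config.seed)

        self.conv1 = nn.Conv2d(3, widths[0], 7, 2, 3, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(widths[0])
        self.relu1 = nn.ReLU()
        self.pool = nn.MaxPool2d(3, 2, 1)
        self.stages = []
        in_ch = widths[0]
        for si, out_ch in enumerate(widths[1:]):
            blocks = []
            for bi in range(2):
                stride = 2 if (si > 0 and bi == 0) else 1
                blocks.append(_BasicBlock(in_ch, out_ch, stride, rng))
                in_ch = out_ch
            self.stages.append(blocks)
        self.reduce = nn.Conv2d(in_ch, config.reduced_channels, 1, 1, 0, bias=False, rng=rng)
        self.reduce_bn = nn.BatchNorm2d(config.reduced_channels)
        self.reduce_relu = nn.ReLU()
        self.tes = nn.TextureEncoding(config.codewords, config.reduced_channels,
                                      lam=config.suppression, rng=rng)
        self.l2norm = nn.L2Normalize()
        self.embedding_dim = config.codewords * config.reduced_channels
        self.fc = nn.Linear(self.embedding_dim, config.classes, rng=rng)
        self._spatial = config.input_size // 32

    # -- bookkeeping ---------------------------------------------------

    def _named_layers(self):
        yield "conv1", self.conv1
        yield "bn1", self.bn1
        for si, blocks in enumerate(self.stages):
            for bi, block in enumerate(blocks):
                for name, layer in block.sublayers():
                    yield f"stage{si}.block{bi}.{name}", layer
        yield "reduce", self.reduce
        yield "reduce_bn", self.reduce_bn
        yield "tes", self.tes
        yield "fc", self.fc

    def named_params(self):
        for lname, layer in self._named_layers():
            for pname, p in layer.params():
                yield f"{lname}.{pname}", p

    def params(self):
        return [p for _, p in self.named_params()]

    def named_buffers(self):
        for lname, layer in self._named_layers():
            for bname, b in layer.buffers():
                yield f"{lname}.{bname}", b

    # -- forward / backward --------------------------------------------

    def forward(self, images: np.ndarray, train: bool = False):
        """Map a batch of grayscale images to (embeddings, scores).

        ``images`` is (B, H, W) with values in [0, 1]; embeddings are the
        flattened L2-normalized TES encodings (unit rows), scores the raw
        fully connected outputs.
        """
        images = np.asarray(images, dtype=np.float32)
        if images.ndim == 2:
            images = images[None]
        if images.ndim != 3 or images.shape[1] != self.config.input_size or \
                images.shape[2] != self.config.input_size:
            raise ValueError(
                f"expected (B, {self.config.input_size}, {self.config.input_size}) images, "
                f"got {images.shape}")
        x = np.repeat(images[:, None, :, :], 3, axis=1)  # grayscale -> 3 channels
        x = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        x = self.pool.forward(x, train)
        for blocks in self.stages:
            for block in blocks:
                x = block.forward(x, train)
        x = self.reduce_relu.forward(self.reduce_bn.forward(self.reduce.forward(x, train), train), train)
        b, c, h, w = x.shape
        self._desc_shape = (b, c, h, w)
        desc = x.transpose(0, 2, 3, 1).reshape(b, h * w, c)  # N = h*w descriptors
        enc = self.tes.forward(desc, train)                  # (B, K, C)
        flat = enc.reshape(b, -1)
        z = self.l2norm.forward(flat, train)
        scores = self.fc.forward(z, train)
        return z, scores

    def backward(self, dz: np.ndarray, dscores: np.ndarray):
        """Backpropagate gradients arriving at the embeddings and scores."""
        d = self.fc.backward(dscores) + dz
        d = self.l2norm.backward(d)
        b, c, h, w = self._desc_shape
        d = self.tes.backward(d.reshape(b, self.config.codewords, c))
        d = d.reshape(b, h, w, c).transpose(0, 3, 1, 2)
        d = self.reduce.backward(self.reduce_bn.backward(self.reduce_relu.backward(d)))
        for blocks in reversed(self.stages):
            for block in reversed(blocks):
                d = block.backward(d)
        d = self.pool.backward(d)
        d = self.conv1.backward(self.bn1.backward(self.relu1.backward(d)))
        return d.sum(axis=1)  # undo channel replication


def build_model(config: ModelConfig) -> NetworkModel:
    """Construct the classifier; all randomness is fixed by ``config.seed``."""
    return NetworkModel(config)


def forward(model: NetworkModel, images: np.ndarray):
    """Evaluation-mode forward pass returning (embeddings, scores)."""
    return model.forward(images, train=False)


def predict_profusion(scores: np.ndarray) -> int | np.ndarray:
    """Argmax profusion level; ties break toward the lower level.

    Softmax is monotone, so the argmax of the predicted distribution equals
    the argmax of the raw scores.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if scores.ndim == 1:
        return int(np.argmax(scores))
    return np.argmax(scores, axis=-1)


# -- training ----------------------------------------------------------


def _balanced_batches(labels: np.ndarray, batch_size: int, rng: np.random.Generator):
    """Yield index batches with at least 2 samples per class present.

    Classes are cycled through shuffled per-class pools in pairs, so every
    emitted batch contains each of its classes at least twice (required by
    the contrastive loss).
    """
    classes = np.unique(labels)
    pools = {c: rng.permutation(np.flatnonzero(labels == c)).tolist() for c in classes}
    n_batches = max(1, int(np.ceil(labels.size / batch_size)))
    order = rng.permutation(np.repeat(classes, 2))  # pair-granular class schedule
    for _ in range(n_batches):
        batch = []
        ci = 0
        while len(batch) < batch_size:
            c = order[ci % order.size]
            ci += 1
            pool = pools[c]
            if len(pool) < 2:
                pool = rng.permutation(np.flatnonzero(labels == c)).tolist()
                pools[c] = pool
            batch.append(pool.pop())
            if len(batch) < batch_size:
                batch.append(pool.pop())
        order = rng.permutation(order)
        yield np.asarray(batch)


def _augment(images: np.ndarray, cfg: TrainConfig, rng: np.random.Generator) -> np.ndarray:
    out = images.copy()
    if cfg.augment_flip:
        flip = rng.random(len(out)) < 0.5
        out[flip] = out[flip, :, ::-1]
    if cfg.augment_rotation > 0:
        angles = rng.uniform(-cfg.augment_rotation, cfg.augment_rotation, size=len(out))
        for i, a in enumerate(angles):
            out[i] = ndimage.rotate(out[i], a, reshape=False, order=1, mode="nearest")
    return out


def train_arrays(model: NetworkModel, images: np.ndarray, labels: np.ndarray,
                 train_config: TrainConfig | None = None,
                 loss_config: LossConfig | None = None,
                 class_prior: np.ndarray | None = None) -> pd.DataFrame:
    """Train in place on an array dataset; returns the per-epoch history.

    ``images`` is (n, H, W) in [0, 1]; ``labels`` integer profusion levels.
    History columns: epoch, supcon, kl, total, accuracy (training split).
    """
    tc = (train_config or TrainConfig()).validate()
    lc = (loss_config or LossConfig()).validate()
    images = np.asarray(images, dtype=np.float32)
    labels = np.asarray(labels, dtype=np.intp)
    _validate_dataset(images, labels, model.config)

    n_levels = model.config.classes
    prior = (class_prior if class_prior is not None
             else objectives.class_frequencies(labels, n_levels))
    y_table = np.stack([objectives.ordinal_label_distribution(t, n_levels)
                        for t in range(n_levels)])
    rng = np.random.default_rng(tc.seed)
    opt = nn.Adam(model.params(), lr=tc.learning_rate)

    history = []
    for epoch in range(tc.epochs):
        sup_sum = kl_sum = tot_sum = 0.0
        correct = seen = 0
        n_steps = 0
        for batch_idx in _balanced_batches(labels, tc.batch_size, rng):
            xb = _augment(images[batch_idx], tc, rng)
            yb = labels[batch_idx]
            z, scores = model.forward(xb, train=True)
            sup, dz = objectives.supcon_loss_grad(z, yb, lc.tau, lc.supcon_variant)
            kl, dscores = objectives.kl_loss_batch(y_table[yb], scores, prior, yb)
            total = objectives.total_loss(sup, kl, lc.alpha, lc.beta)
            opt.zero_grad()
            model.backward((lc.alpha * dz).astype(np.float32),
                           (lc.beta * dscores).astype(np.float32))
            opt.step()
            sup_sum += sup
            kl_sum += kl
            tot_sum += total
            pred = predict_profusion(scores)
            correct += int((pred == yb).sum())
            seen += yb.size
            n_steps += 1
        history.append({
            "epoch": epoch,
            "supcon": sup_sum / n_steps,
            "kl": kl_sum / n_steps,
            "total": tot_sum / n_steps,
            "accuracy": correct / seen,
        })
    recalibrate_batchnorm(model, images, tc.batch_size)
    return pd.DataFrame(history)


def recalibrate_batchnorm(model: NetworkModel, images: np.ndarray,
                          batch_size: int = 16) -> None:
    """Replace BN running statistics with exact averages over ``images``.

    Momentum-based running estimates lag the rapidly moving batch
    statistics of a short training run, which degrades evaluation-mode
    accuracy; one pass over the (unaugmented) training data with frozen
    weights makes the stored statistics consistent with the final weights.
    """
    bns = [layer for _, layer in model._named_layers()
           if isinstance(layer, nn.BatchNorm2d)]
    saved = [layer.momentum for layer in bns]
    for layer in bns:
        layer.running_mean[...] = 0.0
        layer.running_var[...] = 0.0
    n_batches = 0
    for i in range(0, len(images), batch_size):
        batch = images[i : i + batch_size]
        if len(batch) < 2:
            continue
        n_batches += 1
        for layer in bns:                      # cumulative-average schedule
            layer.momentum = 1.0 - 1.0 / n_batches
        model.forward(batch, train=True)
    for layer, mom in zip(bns, saved):
        layer.momentum = mom


class DataValidationError(ValueError):
    """Raised for unreadable images or out-of-range labels, listing offenders."""


def _validate_dataset(images, labels, config: ModelConfig):
    if images.shape[0] == 0:
        raise DataValidationError("empty dataset")
    if images.shape[0] != labels.shape[0]:
        raise DataValidationError("images and labels have different lengths")
    bad = np.flatnonzero((labels < 0) | (labels >= config.classes))
    if bad.size:
        raise DataValidationError(f"labels outside [0, {config.classes - 1}] at rows {bad.tolist()[:20]}")
    if images.shape[1:] != (config.input_size, config.input_size):
        raise DataValidationError(
            f"images must be {config.input_size}x{config.input_size}, got {images.shape[1:]}")


def load_manifest_images(manifest_path, input_size: int):
    """Read a ``path,level`` manifest CSV and load its PNGs as a float array."""
    from pathlib import Path
    from PIL import Image

    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    if not {"path", "level"} <= set(df.columns):
        raise DataValidationError("manifest must have columns 'path' and 'level'")
    images, bad = [], []
    for i, rel in enumerate(df["path"]):
        p = Path(rel)
        if not p.is_absolute():
            p = manifest_path.parent / p
        try:
            with Image.open(p) as im:
                arr = np.asarray(im.convert("I" if im.mode.startswith("I") else "L"),
                                 dtype=np.float32)
        except OSError:
            bad.append(i)
            continue
        denom = 65535.0 if arr.max() > 255 else 255.0
        arr = arr / denom
        if arr.shape != (input_size, input_size):
            from skimage.transform import resize
            arr = resize(arr, (input_size, input_size), anti_aliasing=True).astype(np.float32)
        images.append(arr)
    if bad:
        raise DataValidationError(f"unreadable images at manifest rows {bad[:20]}")
    return np.stack(images), df["level"].to_numpy(dtype=np.intp)


def train(model: NetworkModel, manifest_path, train_config: TrainConfig | None = None,
          loss_config: LossConfig | None = None) -> pd.DataFrame:
    """Train from a ``path,level`` manifest CSV (thin wrapper over train_arrays)."""
    images, labels = load_manifest_images(manifest_path, model.config.input_size)
    return train_arrays(model, images, labels, train_config, loss_config)


# -- checkpoints -------------------------------------------------------


def save_checkpoint(model: NetworkModel, path) -> None:
    """Single archive holding every parameter/buffer array plus the config JSON."""
    arrays = {f"param:{name}": p.value for name, p in model.named_params()}
    arrays.update({f"buffer:{name}": b for name, b in model.named_buffers()})
    arrays["config_json"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> NetworkModel:
    with np.load(path) as npz:
        cfg = ModelConfig(**json.loads(bytes(npz["config_json"]).decode()))
        model = NetworkModel(cfg)
        params = dict(model.named_params())
        buffers = dict(model.named_buffers())
        for key in npz.files:
            if key.startswith("param:"):
                params[key[6:]].value[...] = npz[key]
            elif key.startswith("buffer:"):
                buffers[key[7:]][...] = npz[key]
    return model
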