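"""Encoder-decoder segmentation of root pixels from soil background.

A SegNet-style fully convolutional network in the SegRoot lineage: stacked
conv/ReLU/maxpool encoder blocks mirrored by nearest-upsample/conv/ReLU
decoder blocks, a 1x1 output convolution and a sigmoid.  Regularisation
follows the fine-tuning recipe for field minirhizotron imagery: dropout 0.2
in every encoder and decoder block, L2 weight penalty 1e-4, and early
stopping once the validation loss has not improved for 20 epochs.  Loss is
binary cross-entropy on the root/background labels.

The implementation is pure numpy (forward and backward passes written out),
sized so the narrow preset trains on a desktop CPU.  Images are processed
as square patches cut on an overlapping grid (default 256 px, 30% overlap);
at inference the per-patch probabilities are averaged where patches overlap
and thresholded at 0.5.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage.color import hsv2rgb, rgb2hsv
from skimage.transform import rescale

from .io import RhizopipeError

#: Narrow preset: 4 encoder/decoder levels at widths a CPU can train.
NARROW_WIDTHS = (4, 8, 16, 32)
#: Wide preset mirroring the VGG-ish SegRoot encoder.
WIDE_WIDTHS = (64, 128, 256, 512)


# ---------------------------------------------------------------------------
# patch grid
# ---------------------------------------------------------------------------

@dataclass
class PatchPair:
    """One image patch, its (optional) mask patch, and its source origin."""

    image_patch: np.ndarray  # (size, size, 3)
    mask_patch: np.ndarray | None  # (size, size) in {0,1}
    origin: tuple[int, int]  # (row, col) in the source image


def _grid_origins(dim: int, size: int, stride: int) -> list[int]:
    """Origins 0, stride, 2*stride, ... with the last clamped to dim - size."""
    origins = list(range(0, max(dim - size, 0) + 1, stride))
    last = dim - size
    if origins[-1] != last:
        origins.append(last)
    return origins


def cut_patches(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    size: int = 256,
    overlap: float = 0.3,
    pad: bool = False,
) -> list[PatchPair]:
    """Cut an image (and aligned mask) into overlapping square patches.

    The stride is ``floor(size * (1 - overlap))``; the final origin on each
    axis is clamped so the last patch ends exactly at the image edge, which
    guarantees every pixel is covered.  ``pad=True`` edge-pads images smaller
    than ``size``; otherwise such images are fatal.
    """
    h, w = image.shape[:2]
    if mask is not None and mask.shape[:2] != (h, w):
        raise RhizopipeError("image and mask shapes differ")
    if (h < size or w < size) and not pad:
        raise RhizopipeError(
            f"image {h}x{w} smaller than patch size {size} and padding disabled"
        )
    if h < size or w < size:
        ph, pw = max(size - h, 0), max(size - w, 0)
        image = np.pad(image, ((0, ph), (0, pw), (0, 0)), mode="edge")
        if mask is not None:
            mask = np.pad(mask, ((0, ph), (0, pw)), mode="edge")
        h, w = image.shape[:2]
    stride = max(int(math.floor(size * (1.0 - overlap))), 1)
    patches = []
    for r in _grid_origins(h, size, stride):
        for c in _grid_origins(w, size, stride):
            patches.append(
                PatchPair(
                    image_patch=image[r : r + size, c : c + size],
                    mask_patch=None if mask is None else mask[r : r + size, c : c + size],
                    origin=(r, c),
                )
            )
    return patches


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclass
class AugmentationConfig:
    """Ranges of the six augmentation transforms.

    Geometric transforms (rotation, zoom, flips) apply to image and mask;
    one morphological op (dilate or close, chosen at random) applies to the
    mask only; photometric transforms (brightness/contrast, hue/saturation)
    apply to the image only.
    """

    rotation_angles: tuple[int, ...] = (0, 90, 180, 270)
    zoom_range: tuple[float, float] = (0.9, 1.1)
    brightness_contrast_range: tuple[float, float] = (0.9, 1.1)
    hue_range: tuple[float, float] = (-0.1, 0.1)
    saturation_range: tuple[float, float] = (0.9, 1.1)
    flip_prob: float = 0.5


def _zoom_to_size(arr: np.ndarray, factor: float, order: int) -> np.ndarray:
    """Rescale by ``factor`` then center-crop / edge-pad back to the input size."""
    h, w = arr.shape[:2]
    channel_axis = 2 if arr.ndim == 3 else None
    out = rescale(
        arr.astype(np.float64),
        factor,
        order=order,
        channel_axis=channel_axis,
        anti_aliasing=False,
        mode="edge",
    )
    oh, ow = out.shape[:2]
    if oh >= h:
        r0, c0 = (oh - h) // 2, (ow - w) // 2
        out = out[r0 : r0 + h, c0 : c0 + w]
    else:
        pr, pc = h - oh, w - ow
        pad = ((pr // 2, pr - pr // 2), (pc // 2, pc - pc // 2))
        if arr.ndim == 3:
            pad = pad + ((0, 0),)
        out = np.pad(out, pad, mode="edge")
    return out


def augment(p: PatchPair, cfg: AugmentationConfig, seed: int) -> PatchPair:
    """Apply the six seeded augmentation transforms to one patch pair.

    Identical seed gives identical output; the mask stays binary and both
    patches keep their size.
    """
    rng = np.random.default_rng(seed)
    img = p.image_patch.astype(np.float64) / 255.0
    msk = None if p.mask_patch is None else p.mask_patch.astype(bool)

    # (i) dilate or morphological close on the mask
    if msk is not None:
        op = rng.choice(["dilate", "close"])
        struct = np.ones((3, 3), dtype=bool)
        if op == "dilate":
            msk = ndi.binary_dilation(msk, structure=struct)
        else:
            msk = ndi.binary_closing(msk, structure=struct)

    # (ii) rotation by a multiple of 90 degrees
    k = int(rng.choice(len(cfg.rotation_angles)))
    k_quarter = cfg.rotation_angles[k] // 90
    img = np.rot90(img, k_quarter)
    if msk is not None:
        msk = np.rot90(msk, k_quarter)

    # (iii) zoom
    zf = rng.uniform(*cfg.zoom_range)
    img = _zoom_to_size(img, zf, order=1)
    if msk is not None:
        msk = _zoom_to_size(msk.astype(np.float64), zf, order=0) > 0.5

    # (iv) horizontal and/or vertical flip
    if rng.random() < cfg.flip_prob:
        img = img[:, ::-1]
        if msk is not None:
            msk = msk[:, ::-1]
    if rng.random() < cfg.flip_prob:
        img = img[::-1]
        if msk is not None:
            msk = msk[::-1]

    # (v) brightness and contrast
    img = img * rng.uniform(*cfg.brightness_contrast_range)
    cfac = rng.uniform(*cfg.brightness_contrast_range)
    img = (img - img.mean()) * cfac + img.mean()
    img = np.clip(img, 0.0, 1.0)

    # (vi) hue and saturation in HSV space
    hsv = rgb2hsv(img)
    hsv[..., 0] = (hsv[..., 0] + rng.uniform(*cfg.hue_range)) % 1.0
    hsv[..., 1] = np.clip(hsv[..., 1] * rng.uniform(*cfg.saturation_range), 0.0, 1.0)
    img = hsv2rgb(hsv)

    return PatchPair(
        image_patch=np.clip(img * 255.0, 0, 255).astype(np.uint8),
        mask_patch=None if msk is None else np.ascontiguousarray(msk).astype(np.uint8),
        origin=p.origin,
    )


# ---------------------------------------------------------------------------
# dice
# ---------------------------------------------------------------------------

@dataclass
class SegmentationScore:
    """Pixel counts behind a dice score."""

    gt_positives: int
    pred_positives: int
    true_pred_positives: int
    dice: float


def dice_score(pred: np.ndarray, truth: np.ndarray) -> SegmentationScore:
    """Dice similarity 2*TP / (GT + Pred); both-empty is perfect agreement (1)."""
    if pred.shape != truth.shape:
        raise RhizopipeError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    p = pred.astype(bool)
    t = truth.astype(bool)
    gt = int(t.sum())
    pp = int(p.sum())
    tp = int((p & t).sum())
    dice = 1.0 if gt + pp == 0 else 2.0 * tp / (gt + pp)
    return SegmentationScore(gt, pp, tp, dice)


# ---------------------------------------------------------------------------
# network layers (numpy, manual backprop)
# ---------------------------------------------------------------------------

def _im2col3(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N, C*9, H*W) columns of 3x3 neighbourhoods (same pad)."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    # win: (N, C, H, W, 3, 3) -> (N, C, 3, 3, H, W) -> (N, C*9, H*W)
    return np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3)).reshape(n, c * 9, h * w)


class _Conv3x3:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = math.sqrt(2.0 / (c_in * 9))  # He init
        self.W = rng.normal(0.0, scale, size=(c_out, c_in * 9))
        self.b = np.zeros(c_out)
        self._adam = None
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        cols = _im2col3(x)
        y = np.einsum("oc,ncp->nop", self.W, cols) + self.b[None, :, None]
        if train:
            self._cache = (cols, x.shape)
        return y.reshape(n, -1, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        n, c, h, w = xshape
        dyf = dy.reshape(n, -1, h * w)
        self.dW = np.einsum("nop,ncp->oc", dyf, cols) / n
        self.db = dyf.sum(axis=(0, 2)) / n
        dcols = np.einsum("oc,nop->ncp", self.W, dyf)  # (N, C*9, H*W)
        dcols = dcols.reshape(n, c, 3, 3, h, w)
        dxp = np.zeros((n, c, h + 2, w + 2))
        for di in range(3):
            for dj in range(3):
                dxp[:, :, di : di + h, dj : dj + w] += dcols[:, :, di, dj]
        return dxp[:, :, 1 : 1 + h, 1 : 1 + w]

    def params(self):
        return [("W", self.W, "dW"), ("b", self.b, "db")]


class _Conv1x1(_Conv3x3):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = math.sqrt(2.0 / c_in)
        self.W = rng.normal(0.0, scale, size=(c_out, c_in))
        self.b = np.zeros(c_out)
        self._adam = None
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        xf = x.reshape(n, c, h * w)
        y = np.einsum("oc,ncp->nop", self.W, xf) + self.b[None, :, None]
        if train:
            self._cache = (xf, x.shape)
        return y.reshape(n, -1, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xf, xshape = self._cache
        n, c, h, w = xshape
        dyf = dy.reshape(n, -1, h * w)
        self.dW = np.einsum("nop,ncp->oc", dyf, xf) / n
        self.db = dyf.sum(axis=(0, 2)) / n
        dx = np.einsum("oc,nop->ncp", self.W, dyf)
        return dx.reshape(xshape)


class _ReLU:
    def forward(self, x, train):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy):
        return dy * self._mask


class _Dropout:
    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng

    def forward(self, x, train):
        if not train or self.p <= 0:
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask if self.p > 0 else dy


class _MaxPool2:
    def forward(self, x, train):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx = idx
            self._shape = (n, c, h, w)
        return out

    def backward(self, dy):
        n, c, h, w = self._shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        dxr = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dxr.reshape(n, c, h, w)


class _Upsample2:
    def forward(self, x, train):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy):
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Training hyperparameters; defaults follow the fine-tuning recipe."""

    dropout_rate: float = 0.2
    l2_weight: float = 1e-4
    patience_epochs: int = 20
    max_epochs: int = 100
    batch_size: int = 16
    learning_rate: float = 3e-3
    threshold: float = 0.5
    seed: int = 0
    widths: tuple[int, ...] = NARROW_WIDTHS

    def __post_init__(self) -> None:
        if self.patience_epochs < 1:
            raise RhizopipeError("patience_epochs must be >= 1")
        if not (0.0 < self.threshold < 1.0):
            raise RhizopipeError("threshold must be in (0, 1)")


class SegmentationModel:
    """Encoder-decoder with dropout in every block and an L2 weight penalty."""

    def __init__(
        self,
        widths: tuple[int, ...] = NARROW_WIDTHS,
        dropout_rate: float = 0.2,
        l2_weight: float = 1e-4,
        seed: int = 0,
        in_channels: int = 3,
    ):
        self.widths = tuple(widths)
        self.dropout_rate = dropout_rate
        self.l2_weight = l2_weight
        self.in_channels = in_channels
        self.seed = seed
        self.trained = False
        rng = np.random.default_rng(seed)
        self._drop_rng = np.random.default_rng(rng.integers(2**31))
        self.layers: list = []
        c = in_channels
        for wdt in self.widths:  # encoder
            self.layers += [
                _Conv3x3(c, wdt, rng),
                _ReLU(),
                _Dropout(dropout_rate, self._drop_rng),
                _MaxPool2(),
            ]
            c = wdt
        for wdt in reversed(self.widths):  # decoder
            self.layers += [
                _Upsample2(),
                _Conv3x3(c, wdt, rng),
                _ReLU(),
                _Dropout(dropout_rate, self._drop_rng),
            ]
            c = wdt
        self.layers.append(_Conv1x1(c, 1, rng))

    # -- plumbing -----------------------------------------------------------

    @property
    def min_divisor(self) -> int:
        """Input sides must be divisible by 2**n_levels."""
        return 2 ** len(self.widths)

    def _conv_layers(self):
        return [l for l in self.layers if isinstance(l, _Conv3x3)]

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (N, H, W, 3) uint8/float -> logits (N, H, W).

        Inputs are scaled to [-0.5, 0.5]; zero-centering keeps the first
        convolution well-conditioned and speeds convergence markedly.
        """
        z = np.ascontiguousarray(
            x.astype(np.float64).transpose(0, 3, 1, 2) / 255.0 - 0.5
        )
        for layer in self.layers:
            z = layer.forward(z, train)
        return z[:, 0]

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        z = self.forward_logits(x, train=False)
        return 1.0 / (1.0 + np.exp(-z))

    def backward(self, dlogits: np.ndarray) -> None:
        dz = dlogits[:, None]
        for layer in reversed(self.layers):
            dz = layer.backward(dz)

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        arrays = {}
        for i, layer in enumerate(self.layers):
            if isinstance(layer, _Conv3x3):
                arrays[f"W{i}"] = layer.W
                arrays[f"b{i}"] = layer.b
        meta = dict(
            widths=list(self.widths),
            dropout_rate=self.dropout_rate,
            l2_weight=self.l2_weight,
            in_channels=self.in_channels,
            seed=self.seed,
            trained=self.trained,
        )
        np.savez(Path(path), _meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "SegmentationModel":
        data = np.load(Path(path), allow_pickle=False)
        meta = json.loads(str(data["_meta"]))
        model = cls(
            widths=tuple(meta["widths"]),
            dropout_rate=meta["dropout_rate"],
            l2_weight=meta["l2_weight"],
            seed=meta["seed"],
            in_channels=meta["in_channels"],
        )
        for i, layer in enumerate(model.layers):
            if isinstance(layer, _Conv3x3):
                layer.W = data[f"W{i}"]
                layer.b = data[f"b{i}"]
        model.trained = bool(meta["trained"])
        return model

    def get_weights(self) -> list[np.ndarray]:
        out = []
        for layer in self._conv_layers():
            out += [layer.W.copy(), layer.b.copy()]
        return out

    def set_weights(self, weights: list[np.ndarray]) -> None:
        it = iter(weights)
        for layer in self._conv_layers():
            layer.W = next(it).copy()
            layer.b = next(it).copy()


class _Adam:
    def __init__(self, model: SegmentationModel, lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.state = {}
        for li, layer in enumerate(model._conv_layers()):
            self.state[li] = {
                "mW": np.zeros_like(layer.W),
                "vW": np.zeros_like(layer.W),
                "mb": np.zeros_like(layer.b),
                "vb": np.zeros_like(layer.b),
            }

    def step(self, model: SegmentationModel) -> None:
        self.t += 1
        c1 = 1 - self.b1**self.t
        c2 = 1 - self.b2**self.t
        for li, layer in enumerate(model._conv_layers()):
            gW = layer.dW + model.l2_weight * layer.W
            gb = layer.db
            st = self.state[li]
            st["mW"] = self.b1 * st["mW"] + (1 - self.b1) * gW
            st["vW"] = self.b2 * st["vW"] + (1 - self.b2) * gW**2
            st["mb"] = self.b1 * st["mb"] + (1 - self.b1) * gb
            st["vb"] = self.b2 * st["vb"] + (1 - self.b2) * gb**2
            layer.W -= self.lr * (st["mW"] / c1) / (np.sqrt(st["vW"] / c2) + self.eps)
            layer.b -= self.lr * (st["mb"] / c1) / (np.sqrt(st["vb"] / c2) + self.eps)


def _stack_pairs(pairs: list[PatchPair]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([p.image_patch for p in pairs]).astype(np.float64)
    t = np.stack([p.mask_patch for p in pairs]).astype(np.float64)
    return x, t


def split_dataset(
    dataset: list[PatchPair],
    fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
    seed: int = 0,
) -> tuple[list[PatchPair], list[PatchPair], list[PatchPair]]:
    """Seeded train/validation/test split by patch."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(dataset))
    n_train = int(round(fractions[0] * len(dataset)))
    n_val = int(round(fractions[1] * len(dataset)))
    tr = [dataset[i] for i in order[:n_train]]
    va = [dataset[i] for i in order[n_train : n_train + n_val]]
    te = [dataset[i] for i in order[n_train + n_val :]]
    return tr, va, te


def evaluate(
    model: SegmentationModel,
    pairs: list[PatchPair],
    threshold: float = 0.5,
    batch_size: int = 16,
) -> tuple[float, float]:
    """(mean BCE loss, dice over all pixels) on a patch set, eval mode."""
    losses = []
    tp = gt = pp = 0
    for i in range(0, len(pairs), batch_size):
        x, t = _stack_pairs(pairs[i : i + batch_size])
        z = model.forward_logits(x, train=False)
        loss = np.maximum(z, 0.0) - z * t + np.log1p(np.exp(-np.abs(z)))
        losses.append(loss.mean() * len(x))
        pred = (1.0 / (1.0 + np.exp(-z))) >= threshold
        tb = t.astype(bool)
        tp += int((pred & tb).sum())
        gt += int(tb.sum())
        pp += int(pred.sum())
    dice = 1.0 if gt + pp == 0 else 2.0 * tp / (gt + pp)
    return float(np.sum(losses) / len(pairs)), dice


def train(
    dataset: list[PatchPair],
    cfg: TrainConfig,
    split: tuple[float, float, float] = (0.7, 0.15, 0.15),
    val_loss_override=None,
) -> tuple[SegmentationModel, list[dict]]:
    """Train the encoder-decoder with early stopping on validation loss.

    Returns the best-validation-loss checkpoint and a per-epoch history of
    train/validation loss and dice.  Training halts at ``cfg.max_epochs`` or
    once the validation loss has not improved for ``cfg.patience_epochs``
    consecutive epochs.  Identical dataset + config give identical history.

    ``val_loss_override`` (epoch index -> float) replaces the measured
    validation loss; it exists to exercise the stopping rule in isolation.
    """
    if any(p.mask_patch is None for p in dataset):
        raise RhizopipeError("training requires mask patches for every image patch")
    tr, va, te = split_dataset(dataset, split, cfg.seed)
    if not tr or not va:
        raise RhizopipeError("empty train or validation split")
    sizes = {p.image_patch.shape[0] for p in dataset}
    model = SegmentationModel(
        widths=cfg.widths,
        dropout_rate=cfg.dropout_rate,
        l2_weight=cfg.l2_weight,
        seed=cfg.seed,
    )
    if min(sizes) % model.min_divisor:
        raise RhizopipeError(
            f"patch size must be divisible by {model.min_divisor} for {len(cfg.widths)} levels"
        )
    opt = _Adam(model, cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    history: list[dict] = []
    best_val = np.inf
    best_weights = model.get_weights()
    best_epoch = 0
    since_best = 0
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(tr))
        ep_loss = 0.0
        tp = gt = pp = 0
        for i in range(0, len(tr), cfg.batch_size):
            batch = [tr[j] for j in order[i : i + cfg.batch_size]]
            x, t = _stack_pairs(batch)
            z = model.forward_logits(x, train=True)
            loss = np.maximum(z, 0.0) - z * t + np.log1p(np.exp(-np.abs(z)))
            batch_loss = float(loss.mean())
            if not np.isfinite(batch_loss):
                raise RhizopipeError(f"non-finite training loss at epoch {epoch}")
            ep_loss += batch_loss * len(batch)
            p = 1.0 / (1.0 + np.exp(-z))
            pred = p >= cfg.threshold
            tb = t.astype(bool)
            tp += int((pred & tb).sum())
            gt += int(tb.sum())
            pp += int(pred.sum())
            model.backward((p - t) / (z.shape[1] * z.shape[2]))
            opt.step(model)
        train_loss = ep_loss / len(tr)
        train_dice = 1.0 if gt + pp == 0 else 2.0 * tp / (gt + pp)
        val_loss, val_dice = evaluate(model, va, cfg.threshold, cfg.batch_size)
        if val_loss_override is not None:
            val_loss = float(val_loss_override(epoch))
        if not np.isfinite(val_loss):
            raise RhizopipeError(f"non-finite validation loss at epoch {epoch}")
        history.append(
            dict(
                epoch=epoch,
                train_loss=train_loss,
                val_loss=val_loss,
                train_dice=train_dice,
                val_dice=val_dice,
            )
        )
        if val_loss < best_val:
            best_val = val_loss
            best_weights = model.get_weights()
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
        if since_best >= cfg.patience_epochs:
            break
    model.set_weights(best_weights)
    model.trained = True
    model.best_epoch = best_epoch
    return model, history


def predict_mask(
    model: SegmentationModel,
    image: np.ndarray,
    size: int = 256,
    overlap: float = 0.3,
    threshold: float = 0.5,
    batch_size: int = 8,
) -> np.ndarray:
    """Tiled inference: per-patch probabilities averaged, then thresholded.

    Patches follow the same clamped grid as :func:`cut_patches`; overlapping
    predictions are averaged per pixel before binarisation, so the output
    mask has exactly the input shape.
    """
    if not model.trained:
        raise RhizopipeError("predict_mask requires a trained model")
    h, w = image.shape[:2]
    eff = min(size, h, w)
    eff -= eff % model.min_divisor  # pooling needs sides divisible by 2**levels
    if eff < model.min_divisor:
        raise RhizopipeError("image too small to tile")
    patches = cut_patches(image, None, size=eff, overlap=overlap, pad=False)
    acc = np.zeros((h, w))
    cnt = np.zeros((h, w))
    for i in range(0, len(patches), batch_size):
        chunk = patches[i : i + batch_size]
        x = np.stack([p.image_patch for p in chunk]).astype(np.float64)
        probs = model.predict_proba(x)
        for p, pr in zip(chunk, probs):
            r, c = p.origin
            acc[r : r + eff, c : c + eff] += pr
            cnt[r : r + eff, c : c + eff] += 1.0
    return (acc / cnt >= threshold).astype(np.uint8)
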