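"""Stage-1 AI: background elimination of tomographic blastocyst slices.

A compact U-style encoder-decoder (11 convolutional layers + a 1x1 sigmoid
head, skip connections, ~12 conv layers total) is trained per pixel against
binary foreground masks. Slices are processed independently; the model works
at a reduced internal resolution (``work_px``) and the probability map is
resampled back to the input size before thresholding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize

from ._nn import Adam, AvgPool, BatchNorm, Conv, ReLU, Sequential, Upsample
from ._nn.losses import bce_with_logits, sigmoid


@dataclass
class SliceStack:
    """One embryo's ordered tomographic slices (bottom -> top)."""

    embryo_id: str
    slices: np.ndarray  # (n_slices, H, W) grayscale
    pixel_size_um: float
    slice_pitch_um: float = 10.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.slices = np.asarray(self.slices, dtype=np.float64)
        if self.slices.ndim != 3:
            raise ValueError("slices must be a (n_slices, H, W) array")
        if self.slices.shape[1] != self.slices.shape[2]:
            raise ValueError("slices must be square")
        if not np.all(np.isfinite(self.slices)):
            raise ValueError("slice intensities must be finite")

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]

    @property
    def image_px(self) -> int:
        return self.slices.shape[1]

    def as_array(self) -> np.ndarray:
        return self.slices

    @property
    def center_index(self) -> int:
        return (self.n_slices - 1) // 2


@dataclass
class SegMetrics:
    per_image_iou: list[float]
    miou: float
    miou_sd: float
    iou_min: float
    iou_max: float
    sd_defined: bool = True


@dataclass
class SegTrainConfig:
    epochs: int = 10
    learning_rate: float = 3e-3
    batch_size: int = 16
    channels: int = 6
    work_px: int = 64
    val_fraction: float = 0.15
    seed: int = 0
    patience: int = 5


class _UNet:
    """Two-scale U-net: 11 3x3 convs + one 1x1 logit conv."""

    def __init__(self, channels: int, rng: np.random.Generator):
        c = channels

        def block(cin, cout):
            return Sequential([
                Conv(2, cin, cout, 3, rng=rng), BatchNorm(cout), ReLU(),
                Conv(2, cout, cout, 3, rng=rng), BatchNorm(cout), ReLU(),
            ])

        self.enc1 = block(1, c)
        self.pool1 = AvgPool((2, 2))
        self.enc2 = block(c, 2 * c)
        self.pool2 = AvgPool((2, 2))
        self.bott = block(2 * c, 4 * c)
        self.up2 = Upsample((2, 2))
        self.dec2 = block(6 * c, 2 * c)
        self.up1 = Upsample((2, 2))
        self.dec1 = block(3 * c, c)
        self.head = Conv(2, c, 1, 1, pad=0, rng=rng)
        self._split = (4 * c, 2 * c, c)

    def params(self):
        out = []
        for m in (self.enc1, self.enc2, self.bott, self.dec2, self.dec1, self.head):
            out.extend(m.params())
        return out

    def forward(self, x, train=False):
        e1 = self.enc1.forward(x, train)
        e2 = self.enc2.forward(self.pool1.forward(e1, train), train)
        b = self.bott.forward(self.pool2.forward(e2, train), train)
        d2 = self.dec2.forward(
            np.concatenate([self.up2.forward(b, train), e2], axis=1), train)
        d1 = self.dec1.forward(
            np.concatenate([self.up1.forward(d2, train), e1], axis=1), train)
        return self.head.forward(d1, train)

    def backward(self, dy):
        g = self.head.backward(dy)
        g = self.dec1.backward(g)
        c = self._split[2]
        g_e1 = g[:, 2 * c:]
        g = self.up1.backward(g[:, :2 * c])
        g = self.dec2.backward(g)
        c2 = self._split[1]
        g_e2 = g[:, 2 * c2:]
        g = self.up2.backward(g[:, :2 * c2])
        g = self.bott.backward(g)
        g = self.pool2.backward(g) + g_e2
        g = self.enc2.backward(g)
        g = self.pool1.backward(g) + g_e1
        return self.enc1.backward(g)

    def _batchnorms(self):
        out = []
        for m in (self.enc1, self.enc2, self.bott, self.dec2, self.dec1):
            out.extend(lyr for lyr in m.layers if isinstance(lyr, BatchNorm))
        return out

    def state(self):
        """Learnable parameters plus batch-norm running statistics."""
        arrays = [p.value.copy() for p in self.params()]
        for bn in self._batchnorms():
            arrays.append(bn.running_mean.copy())
            arrays.append(bn.running_var.copy())
        return arrays

    def load_state(self, state):
        params = self.params()
        for p, v in zip(params, state):
            p.value = v.copy()
        rest = state[len(params):]
        for i, bn in enumerate(self._batchnorms()):
            bn.running_mean = rest[2 * i].copy()
            bn.running_var = rest[2 * i + 1].copy()


@dataclass
class SegmenterModel:
    net: _UNet
    work_px: int
    threshold: float = 0.5
    metadata: dict = field(default_factory=dict)

    def signature(self) -> str:
        vals = np.concatenate([p.value.ravel() for p in self.net.params()])
        return f"unet-{self.work_px}-{float(vals.sum()):.9e}-{vals.size}"


def _to_work(images: np.ndarray, work_px: int) -> np.ndarray:
    """Resize (N, H, W) image batch to the working resolution and min-max
    normalize each image (robust to the phantom's intensity scale)."""
    from .reconstruction import area_resize

    out = np.empty((images.shape[0], 1, work_px, work_px))
    for i, img in enumerate(images):
        small = img if img.shape[0] == work_px else area_resize(img, (work_px, work_px))
        lo, hi = small.min(), small.max()
        out[i, 0] = (small - lo) / (hi - lo) if hi > lo else 0.0
    return out


def train_segmenter(pairs, config: SegTrainConfig | None = None) -> SegmenterModel:
    """Train the background-elimination segmenter on (slice, mask) pairs.

    Deterministic for a fixed seed. A held-out fraction tracks validation
    loss; the best-validation checkpoint is returned.
    """
    config = config or SegTrainConfig()
    if len(pairs) < 2:
        raise ValueError("need at least 2 training pairs")
    images, masks = [], []
    for img, msk in pairs:
        img = np.asarray(img, dtype=np.float64)
        msk = np.asarray(msk)
        if img.shape != msk.shape:
            raise ValueError("slice/mask shape mismatch")
        if not set(np.unique(msk)) <= {0, 1, False, True}:
            raise ValueError("masks must be binary")
        images.append(img)
        masks.append(msk.astype(np.float64))
    images = np.stack(images)
    masks = np.stack(masks)

    rng = np.random.default_rng([config.seed, 0x5E6])
    x = _to_work(images, config.work_px)
    from .reconstruction import area_resize

    y = np.stack([
        (m if m.shape[0] == config.work_px
         else area_resize(m, (config.work_px, config.work_px)) > 0.5).astype(np.float64)
        for m in masks
    ])[:, None]

    n = x.shape[0]
    perm = rng.permutation(n)
    n_val = max(1, int(round(config.val_fraction * n))) if n > 4 else 0
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if tr_idx.size == 0:
        tr_idx = perm
    net = _UNet(config.channels, rng=np.random.default_rng([config.seed, 0x11]))
    opt = Adam(net.params(), lr=config.learning_rate)

    def val_loss():
        if val_idx.size == 0:
            return np.nan
        logits = net.forward(x[val_idx], train=False)
        loss, _ = bce_with_logits(logits, y[val_idx])
        return loss

    best = (np.inf, net.state())
    history = {"train_loss": [], "val_loss": []}
    stale = 0
    for epoch in range(config.epochs):
        order = rng.permutation(tr_idx)
        ep_loss = 0.0
        nb = 0
        for s in range(0, order.size, config.batch_size):
            idx = order[s:s + config.batch_size]
            opt.zero_grad()
            logits = net.forward(x[idx], train=True)
            loss, dlogits = bce_with_logits(logits, y[idx])
            net.backward(dlogits)
            opt.step()
            ep_loss += loss
            nb += 1
        vl = val_loss()
        history["train_loss"].append(ep_loss / max(nb, 1))
        history["val_loss"].append(vl)
        score = vl if np.isfinite(vl) else ep_loss / max(nb, 1)
        if score < best[0] - 1e-9:
            best = (score, net.state())
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    net.load_state(best[1])
    meta = {"epochs_run": len(history["train_loss"]), "seed": config.seed,
            "history": history, "best_val_loss": float(best[0]),
            "n_train": int(tr_idx.size), "n_val": int(val_idx.size)}
    return SegmenterModel(net=net, work_px=config.work_px, metadata=meta)


def predict_proba(model: SegmenterModel, image: np.ndarray) -> np.ndarray:
    """Foreground probability map at the input resolution."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("expected a square 2-D slice")
    x = _to_work(image[None], model.work_px)
    logits = model.net.forward(x, train=False)[0, 0]
    proba = sigmoid(logits)
    if image.shape[0] != model.work_px:
        proba = _sk_resize(proba, image.shape, order=1, mode="edge",
                           anti_aliasing=False)
    return np.clip(proba, 0.0, 1.0)


def predict_mask(model: SegmenterModel, image: np.ndarray,
                 threshold: float = 0.5) -> np.ndarray:
    return predict_proba(model, image) >= threshold


def apply_masks(stack: SliceStack, masks: np.ndarray) -> SliceStack:
    """Zero out background pixels: slice * mask, elementwise."""
    masks = np.asarray(masks)
    if masks.shape != stack.slices.shape:
        raise ValueError("mask stack shape mismatch")
    meta = dict(stack.meta)
    return SliceStack(embryo_id=stack.embryo_id,
                      slices=stack.slices * (masks > 0),
                      pixel_size_um=stack.pixel_size_um,
                      slice_pitch_um=stack.slice_pitch_um, meta=meta)


def eliminate_background(model: SegmenterModel, stack: SliceStack,
                         threshold: float = 0.5) -> SliceStack:
    """Per slice, keep pixels whose predicted foreground probability is
    >= threshold and set the rest to 0.

    The output records the masking provenance; re-applying the same model and
    threshold to an already-masked stack is a no-op (idempotent).
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    provenance = {"masked_by": model.signature(), "threshold": threshold}
    if stack.meta.get("masking") == provenance:
        return SliceStack(embryo_id=stack.embryo_id, slices=stack.slices.copy(),
                          pixel_size_um=stack.pixel_size_um,
                          slice_pitch_um=stack.slice_pitch_um,
                          meta=dict(stack.meta))
    masks = np.stack([predict_mask(model, s, threshold) for s in stack.slices])
    out = apply_masks(stack, masks)
    out.meta["masking"] = provenance
    return out


# ---------------------------------------------------------------------------
# metrics


def iou(pred_mask: np.ndarray, true_mask: np.ndarray) -> float:
    """Intersection over union of two binary masks (1.0 when both empty)."""
    pred = np.asarray(pred_mask)
    true = np.asarray(true_mask)
    if pred.shape != true.shape:
        raise ValueError("mask shape mismatch")
    for m in (pred, true):
        if not set(np.unique(m)) <= {0, 1, False, True}:
            raise ValueError("masks must be binary")
    pred = pred.astype(bool)
    true = true.astype(bool)
    union = np.logical_or(pred, true).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(pred, true).sum() / union)


def mean_iou(model: SegmenterModel, test_pairs, threshold: float = 0.5) -> SegMetrics:
    """Per-image IOU of predicted vs true masks, with mean/SD (ddof=1)/min/max."""
    if len(test_pairs) == 0:
        raise ValueError("empty test set")
    vals = [iou(predict_mask(model, img, threshold), msk)
            for img, msk in test_pairs]
    arr = np.asarray(vals)
    sd_defined = arr.size > 1
    return SegMetrics(
        per_image_iou=[float(v) for v in vals],
        miou=float(arr.mean()),
        miou_sd=float(arr.std(ddof=1)) if sd_defined else 0.0,
        iou_min=float(arr.min()),
        iou_max=float(arr.max()),
        sd_defined=sd_defined,
    )


# ---------------------------------------------------------------------------
# checkpointing


def save_model(model: SegmenterModel, path) -> None:
    """Single-file .npz archive plus a JSON metadata sidecar."""
    arrays = {f"p{i}": a for i, a in enumerate(model.net.state())}
    np.savez(path, **arrays)
    side = str(path) + ".json"
    channels = model.net._split[2]
    with open(side, "w") as fh:
        json.dump({"work_px": model.work_px, "channels": channels,
                   "threshold": model.threshold, "metadata": model.metadata}, fh)


def load_model(path) -> SegmenterModel:
    side = str(path) + ".json"
    with open(side) as fh:
        info = json.load(fh)
    net = _UNet(info["channels"], rng=np.random.default_rng(0))
    with np.load(str(path) if str(path).endswith(".npz") else str(path)) as data:
        state = [data[f"p{i}"] for i in range(len(net.state()))]
    net.load_state(state)
    return SegmenterModel(net=net, work_px=info["work_px"],
                          threshold=info["threshold"], metadata=info["metadata"])
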