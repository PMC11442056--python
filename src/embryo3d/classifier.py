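"""Stage-2 AI: the fused 3-D CNN + CEE classifier and its cross-validation
harness.

The image branch is a compact 3-D convolutional network (8 conv, 7 batch-norm,
2 catenate, 9 elementwise, 4 linear, 5 rectified-linear layers and one
broadcast/threading stage — 36 layers in the reference descriptor, see
``reference_architecture``). The CEE branch applies the nine fixed univariate
regression functions; its 9 scalars are catenated with the image feature
vector before the 2-class softmax head. Variants:

* ``fusion3d``     — full 11-slice volume + CEE
* ``single_image`` — only the center slice (as a 1-slice volume) + CEE
* ``no_background`` — volumes reconstructed without background elimination
  (identical network; the variant tag documents the input provenance)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from ._nn import Adam, AvgPool, BatchNorm, Conv, GlobalAvgPool, Linear, ReLU
from ._nn.losses import softmax, softmax_cross_entropy
from .reconstruction import augment_arrays

VARIANTS = ("fusion3d", "single_image", "no_background")


@dataclass
class TrainConfig:
    batch_size: int = 64
    learning_rate: float = 8e-4
    l2_lambda: float = 0.02
    augment_times: int = 10
    max_epochs: int = 30
    early_stopping_patience: int = 5
    seed: int = 0

    def __post_init__(self):
        if min(self.batch_size, self.max_epochs, self.augment_times) < 1:
            raise ValueError("counts must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.l2_lambda < 0:
            raise ValueError("l2_lambda must be >= 0")


def reference_architecture() -> dict:
    """Auditable layer-type descriptor of the fusion network."""
    return {
        "total_layers": 36,
        "convolutional": 8,
        "batch_normalization": 7,
        "catenate": 2,
        "elementwise": 9,
        "linear": 4,
        "rectified_linear": 5,
        "threading": 1,
        "stem_channels": 4,
        "trunk_channels": 12,
        "feature_dim": 8,
        "head_hidden": 16,
        "input_pool": [2, 4, 4],
        "optimizer": "adam",
    }


@dataclass
class ClassifierData:
    """Volumes + encoded CEE vectors + labels, keyed by embryo id."""

    volumes: np.ndarray  # (N, D, H, W) float32
    cee: np.ndarray      # (N, 9) regression-encoded factors
    labels: np.ndarray   # (N,) 0/1
    ids: np.ndarray      # (N,) str

    def __post_init__(self):
        n = self.volumes.shape[0]
        if not (self.cee.shape[0] == self.labels.shape[0] == self.ids.shape[0] == n):
            raise ValueError("inconsistent dataset lengths")

    def __len__(self):
        return self.volumes.shape[0]

    def subset(self, idx) -> "ClassifierData":
        return ClassifierData(self.volumes[idx], self.cee[idx],
                              self.labels[idx], self.ids[idx])

    def augmented(self, times: int, seed: int) -> "ClassifierData":
        aug = augment_arrays(self.volumes, self.labels, self.ids, times, seed)
        reps = times
        return ClassifierData(aug.volumes, np.tile(self.cee, (reps, 1)),
                              aug.labels, aug.ids)


class FusionModel:
    """Two-branch classifier; see module docstring for the layer accounting."""

    def __init__(self, config: TrainConfig, variant: str = "fusion3d",
                 arch: dict | None = None):
        if variant not in VARIANTS:
            raise ValueError(f"invalid variant {variant!r}; one of {VARIANTS}")
        self.variant = variant
        self.config = config
        self.arch = arch or reference_architecture()
        a = self.arch
        rng = np.random.default_rng([config.seed, 0xF0])
        cs, ct, fd, hh = (a["stem_channels"], a["trunk_channels"],
                          a["feature_dim"], a["head_hidden"])
        self.pool0 = AvgPool(tuple(a["input_pool"]))
        self.stem_a = Conv(3, 1, cs, (3, 3, 3), rng=rng)
        self.stem_b = Conv(3, 1, cs, (1, 5, 5), pad=(0, 2, 2), rng=rng)
        self.bn0 = BatchNorm(2 * cs)
        self.relu0 = ReLU()
        self.pool1 = AvgPool((2, 2, 2))
        self.conv1 = Conv(3, 2 * cs, ct, 3, rng=rng)
        self.bn1 = BatchNorm(ct)
        self.relu1 = ReLU()
        self.pool2 = AvgPool((1, 2, 2))
        self.conv2 = Conv(3, ct, ct, 3, rng=rng)
        self.bn2 = BatchNorm(ct)
        self.relu2 = ReLU()
        self.conv3 = Conv(3, ct, ct, 3, rng=rng)
        self.bn3 = BatchNorm(ct)
        self.pool3 = AvgPool((1, 2, 2))
        self.conv4 = Conv(3, ct, ct, 3, rng=rng)
        self.bn4 = BatchNorm(ct)
        self.relu4 = ReLU()
        self.conv5 = Conv(3, ct, ct, 1, pad=0, rng=rng)
        self.bn5 = BatchNorm(ct)
        self.conv6 = Conv(3, ct, fd, 1, pad=0, rng=rng)
        self.bn6 = BatchNorm(fd)
        self.gap = GlobalAvgPool()
        self.lin1 = Linear(fd, fd, rng=rng)
        self.lin2 = Linear(fd + 9, hh, rng=rng)
        self.relu_head = ReLU()
        self.lin3 = Linear(hh, fd, rng=rng)
        self.lin4 = Linear(fd, 2, rng=rng)
        self._feature_dim = fd
        self.history: dict = {}

    # -- plumbing -----------------------------------------------------------

    def _image_layers(self):
        return [self.stem_a, self.stem_b, self.bn0, self.relu0, self.pool1,
                self.conv1, self.bn1, self.relu1, self.pool2,
                self.conv2, self.bn2, self.relu2, self.conv3, self.bn3,
                self.pool3, self.conv4, self.bn4, self.relu4,
                self.conv5, self.bn5, self.conv6, self.bn6, self.gap]

    def params(self):
        out = []
        for lyr in self._image_layers() + [self.lin1, self.lin2, self.lin3,
                                           self.lin4]:
            out.extend(lyr.params())
        return out

    def _batchnorms(self):
        return [self.bn0, self.bn1, self.bn2, self.bn3, self.bn4, self.bn5,
                self.bn6]

    def state(self):
        """Learnable parameters plus batch-norm running statistics, so a
        restored best-validation checkpoint evaluates exactly as it did."""
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

    # -- forward / backward -------------------------------------------------

    def _check_input(self, volumes: np.ndarray):
        if volumes.ndim != 5 or volumes.shape[1] != 1:
            raise ValueError("volumes must be (N, 1, D, H, W)")
        if self.variant == "single_image" and volumes.shape[2] != 1:
            raise ValueError("single_image variant expects a 1-slice volume")

    def forward(self, volumes: np.ndarray, cee: np.ndarray,
                train: bool = False) -> np.ndarray:
        """Logits (N, 2). ``cee`` holds the 9 regression-encoded scalars."""
        self._check_input(volumes)
        if cee.ndim != 2 or cee.shape[1] != 9:
            raise ValueError("cee must be (N, 9)")
        x = self.pool0.forward(volumes, train)
        a = self.stem_a.forward(x, train)
        b = self.stem_b.forward(x, train)
        x = np.concatenate([a, b], axis=1)  # catenate 1 (multi-kernel stems)
        x = self.relu0.forward(self.bn0.forward(x, train), train)
        x = self.pool1.forward(x, train)
        x = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        x = self.pool2.forward(x, train)
        x = self.relu2.forward(self.bn2.forward(self.conv2.forward(x, train), train), train)
        x = self.bn3.forward(self.conv3.forward(x, train), train)
        x = self.pool3.forward(x, train)
        x = self.relu4.forward(self.bn4.forward(self.conv4.forward(x, train), train), train)
        x = self.bn5.forward(self.conv5.forward(x, train), train)
        x = self.bn6.forward(self.conv6.forward(x, train), train)
        feat = self.lin1.forward(self.gap.forward(x, train), train)
        fused = np.concatenate([feat, cee], axis=1)  # catenate 2 (late fusion)
        if train:
            self._stem_split = a.shape[1]
        h = self.relu_head.forward(self.lin2.forward(fused, train), train)
        return self.lin4.forward(self.lin3.forward(h, train), train)

    def backward(self, dlogits: np.ndarray):
        g = self.lin3.backward(self.lin4.backward(dlogits))
        g = self.lin2.backward(self.relu_head.backward(g))
        g_feat = g[:, :self._feature_dim]  # CEE branch has no learned params
        g = self.gap.backward(self.lin1.backward(g_feat))
        g = self.conv6.backward(self.bn6.backward(g))
        g = self.conv5.backward(self.bn5.backward(g))
        g = self.conv4.backward(self.bn4.backward(self.relu4.backward(g)))
        g = self.pool3.backward(g)
        g = self.conv3.backward(self.bn3.backward(g))
        g = self.conv2.backward(self.bn2.backward(self.relu2.backward(g)))
        g = self.pool2.backward(g)
        g = self.conv1.backward(self.bn1.backward(self.relu1.backward(g)))
        g = self.pool1.backward(g)
        g = self.bn0.backward(self.relu0.backward(g))
        s = self._stem_split
        ga = self.stem_a.backward(g[:, :s])
        gb = self.stem_b.backward(g[:, s:])
        return self.pool0.backward(ga + gb)

    def predict_proba(self, volumes: np.ndarray, cee: np.ndarray,
                      batch_size: int = 64) -> np.ndarray:
        """(N, 2) softmax probability pairs, batched, eval mode."""
        out = []
        for s in range(0, volumes.shape[0], batch_size):
            logits = self.forward(volumes[s:s + batch_size],
                                  cee[s:s + batch_size], train=False)
            out.append(softmax(logits))
        return np.concatenate(out, axis=0)


def build_fusion_model(config: TrainConfig, variant: str = "fusion3d",
                       arch: dict | None = None) -> FusionModel:
    return FusionModel(config, variant=variant, arch=arch)


def _prep_batch(volumes: np.ndarray) -> np.ndarray:
    return volumes.astype(np.float64)[:, None]


def predict(model: FusionModel, volume: np.ndarray, cee_vector: np.ndarray) -> float:
    """Confidence score: the implantation-class softmax probability."""
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim != 3:
        raise ValueError("volume must be (D, H, W)")
    cee_vector = np.asarray(cee_vector, dtype=np.float64).reshape(1, -1)
    proba = model.predict_proba(volume[None, None], cee_vector)
    return float(proba[0, 1])


def predict_scores(model: FusionModel, data: ClassifierData,
                   batch_size: int = 64) -> np.ndarray:
    return model.predict_proba(_prep_batch(data.volumes), data.cee,
                               batch_size=batch_size)[:, 1]


# ---------------------------------------------------------------------------
# cross-validation plan


class StratificationError(ValueError):
    pass


@dataclass
class CVPlan:
    test_idx: np.ndarray
    inner_folds: list[tuple[np.ndarray, np.ndarray]]  # (train, val), absolute
    seed: int
    stratified: bool = True

    def validate(self):
        test = set(self.test_idx.tolist())
        inner_all = set()
        for tr, va in self.inner_folds:
            tr_s, va_s = set(tr.tolist()), set(va.tolist())
            if tr_s & va_s:
                raise ValueError("train/validation overlap inside a fold")
            if (tr_s | va_s) & test:
                raise ValueError("test indices leak into inner folds")
            inner_all |= va_s
        return True


def make_cv_plan(n_embryos: int, labels, k: int = 5, seed: int = 0) -> CVPlan:
    """Stratified outer 1/k test split plus an inner k-fold partition of the
    remainder; deterministic for a fixed seed."""
    labels = np.asarray(labels).astype(int)
    if n_embryos != labels.shape[0]:
        raise ValueError("labels length must equal n_embryos")
    if n_embryos < k * k:
        raise ValueError(f"need at least {k * k} embryos for nested {k}-fold CV")
    counts = np.bincount(labels)
    if counts.min() < k:
        raise StratificationError("a class has fewer members than k")
    outer = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rest_idx, test_idx = next(iter(outer.split(np.zeros(n_embryos), labels)))
    inner = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + 1)
    inner_folds = []
    rest_labels = labels[rest_idx]
    if np.bincount(rest_labels).min() < k:
        raise StratificationError("a class has fewer members than k in inner folds")
    for tr, va in inner.split(np.zeros(rest_idx.size), rest_labels):
        inner_folds.append((rest_idx[tr], rest_idx[va]))
    plan = CVPlan(test_idx=test_idx, inner_folds=inner_folds, seed=seed)
    plan.validate()
    return plan


# ---------------------------------------------------------------------------
# training


def assert_no_leakage(train_ids, *other_id_sets):
    """Augmented-copy embryo ids must never appear in validation/test."""
    train = set(np.asarray(train_ids).tolist())
    for other in other_id_sets:
        overlap = train & set(np.asarray(other).tolist())
        if overlap:
            raise RuntimeError(f"embryo-id leakage across folds: {sorted(overlap)[:5]}")


def train_classifier(train: ClassifierData, val: ClassifierData,
                     config: TrainConfig, variant: str = "fusion3d",
                     arch: dict | None = None) -> FusionModel:
    """Minimize cross-entropy + l2·||w||² with Adam; early-stop on validation
    loss and restore the best checkpoint. Train/val must be disjoint by
    embryo id (augmentation is applied to the training set only, upstream)."""
    assert_no_leakage(train.ids, val.ids)
    model = build_fusion_model(config, variant=variant, arch=arch)
    opt = Adam(model.params(), lr=config.learning_rate, l2=config.l2_lambda)
    rng = np.random.default_rng([config.seed, 0x7124])
    xv = _prep_batch(val.volumes)
    best = (np.inf, model.state())
    history = {"train_loss": [], "val_loss": []}
    stale = 0
    n = len(train)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        ep_loss, nb = 0.0, 0
        for s in range(0, n, config.batch_size):
            idx = order[s:s + config.batch_size]
            if idx.size < 2:
                continue  # batch-norm needs >= 2 samples
            opt.zero_grad()
            logits = model.forward(_prep_batch(train.volumes[idx]),
                                   train.cee[idx], train=True)
            loss, dlogits = softmax_cross_entropy(logits, train.labels[idx])
            model.backward(dlogits)
            opt.step()
            ep_loss += loss
            nb += 1
        vlogits = []
        for s in range(0, len(val), config.batch_size):
            vlogits.append(model.forward(xv[s:s + config.batch_size],
                                         val.cee[s:s + config.batch_size],
                                         train=False))
        vloss, _ = softmax_cross_entropy(np.concatenate(vlogits), val.labels)
        if not np.isfinite(vloss):
            raise RuntimeError(
                f"validation loss became non-finite at epoch {epoch}: {vloss}")
        history["train_loss"].append(ep_loss / max(nb, 1))
        history["val_loss"].append(float(vloss))
        if vloss < best[0] - 1e-9:
            best = (float(vloss), model.state())
            stale = 0
        else:
            stale += 1
            if stale >= config.early_stopping_patience:
                break
    model.load_state(best[1])
    model.history = {**history, "best_val_loss": best[0],
                     "epochs_run": len(history["val_loss"]),
                     "seed": config.seed, "optimizer": "adam"}
    return model


def hyperparameter_grid(train: ClassifierData, val: ClassifierData,
                        test: ClassifierData, base_config: TrainConfig,
                        l2_values, augment_values, seeds,
                        variant: str = "fusion3d", arch: dict | None = None):
    """Test AUC per (l2, augment, seed) cell on a shared split; the resulting
    table feeds :func:`embryo3d.evaluation.two_way_anova`."""
    import pandas as pd

    from .evaluation import roc_auc

    if len(l2_values) < 2 or len(augment_values) < 2:
        raise ValueError("need at least 2 levels per factor")
    rows = []
    for l2 in l2_values:
        for times in augment_values:
            for seed in seeds:
                cfg = TrainConfig(
                    batch_size=base_config.batch_size,
                    learning_rate=base_config.learning_rate,
                    l2_lambda=float(l2), augment_times=int(times),
                    max_epochs=base_config.max_epochs,
                    early_stopping_patience=base_config.early_stopping_patience,
                    seed=int(seed))
                aug = train.augmented(cfg.augment_times, seed=cfg.seed)
                assert_no_leakage(aug.ids, val.ids, test.ids)
                model = train_classifier(aug, val, cfg, variant=variant, arch=arch)
                scores = predict_scores(model, test)
                rows.append({"l2": float(l2), "augment": int(times),
                             "seed": int(seed),
                             "auc": roc_auc(scores, test.labels).auc})
    return pd.DataFrame(rows)
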