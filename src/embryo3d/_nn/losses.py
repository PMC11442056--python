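"""Loss heads and activation helpers."""

from __future__ import annotations

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def bce_with_logits(logits: np.ndarray, targets: np.ndarray):
    """Mean binary cross-entropy; returns (loss, dlogits)."""
    p = sigmoid(logits)
    eps = 1e-12
    loss = -np.mean(targets * np.log(p + eps) + (1 - targets) * np.log(1 - p + eps))
    dlogits = (p - targets) / targets.size
    return float(loss), dlogits


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean CE over integer class labels; returns (loss, dlogits)."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.mean(np.log(p[np.arange(n), labels] + eps))
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits /= n
    return float(loss), dlogits
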