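"""Softmax and cross-entropy with analytic gradient."""

from __future__ import annotations

import numpy as np


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - np.max(logits, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient wrt the logits.

    ``labels`` are integer class indices of shape (B,).
    """
    logits = np.asarray(logits, dtype=np.float64)
    labels = np.asarray(labels)
    b = logits.shape[0]
    p = softmax(logits)
    eps = 1e-12
    loss = float(-np.mean(np.log(p[np.arange(b), labels] + eps)))
    dlogits = p.copy()
    dlogits[np.arange(b), labels] -= 1.0
    return loss, (dlogits / b).astype(np.float32)
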