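"""Softmax and cross-entropy primitives shared by training and inference."""

from __future__ import annotations

import numpy as np

PROB_EPS = 1e-12  # probabilities are clamped here before any log


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax with max-subtraction for overflow safety.

    Accepts a single logit vector or a batch ``(B, N)``; returns the same
    shape with rows summing to 1.
    """
    z = np.asarray(logits, dtype=np.float64)
    single = z.ndim == 1
    if single:
        z = z[None, :]
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    return p[0] if single else p


def one_hot(labels: np.ndarray, num_classes: int) -> np.ndarray:
    y = np.zeros((len(labels), num_classes), dtype=np.float64)
    y[np.arange(len(labels)), labels] = 1.0
    return y


def cross_entropy_batch(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-likelihood of the true classes (natural log)."""
    p = np.clip(probs[np.arange(len(labels)), labels], PROB_EPS, None)
    return float(-np.log(p).mean())
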