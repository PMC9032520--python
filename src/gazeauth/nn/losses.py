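"""Verification losses: multi-similarity (open-set) and ArcFace (closed-set).

Both operate on L2-normalized embeddings and return the scalar loss together
with analytic gradients, verified against numerical differentiation in the
test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["multisimilarity_loss", "arcface_loss", "softmax_cross_entropy"]


class SingleClassError(ValueError):
    """A metric-learning batch must contain at least two classes."""


def multisimilarity_loss(
    embeddings: np.ndarray,
    labels: np.ndarray,
    alpha: float = 2.0,
    beta: float = 50.0,
    base: float = 0.5,
    eps: float = 0.1,
) -> tuple[float, np.ndarray]:
    """Multi-similarity loss with pair mining on cosine similarities.

    For each anchor i with positive set P and negative set N (after mining:
    negatives harder than the easiest positive minus ``eps``, positives
    harder than the hardest negative plus ``eps``):

        L_i = (1/alpha) log(1 + sum_P exp(-alpha (S_ij - base)))
            + (1/beta)  log(1 + sum_N exp( beta  (S_ij - base)))

    averaged over the batch.  Mining is treated as a constant selection for
    the gradient.  Returns (loss, dL/dembeddings).
    """
    E = np.asarray(embeddings, dtype=np.float64)
    labels = np.asarray(labels)
    B = len(labels)
    if len(np.unique(labels)) < 2:
        raise SingleClassError("multi-similarity loss needs >= 2 classes in batch")
    S = E @ E.T
    same = labels[:, None] == labels[None, :]
    eye = np.eye(B, dtype=bool)
    pos = same & ~eye
    neg = ~same

    G = np.zeros_like(S)  # dL/dS
    total = 0.0
    for i in range(B):
        p = np.flatnonzero(pos[i])
        n = np.flatnonzero(neg[i])
        if len(p) == 0 or len(n) == 0:
            continue
        # pair mining (constant w.r.t. gradient)
        hardest_neg = S[i, n].max()
        easiest_pos = S[i, p].min()
        p = p[S[i, p] - eps < hardest_neg]
        n = n[S[i, n] + eps > easiest_pos]
        if len(p):
            ep = np.exp(-alpha * (S[i, p] - base))
            sp = ep.sum()
            total += np.log1p(sp) / alpha
            G[i, p] += -ep / (1.0 + sp) / B
        if len(n):
            en = np.exp(beta * (S[i, n] - base))
            sn = en.sum()
            total += np.log1p(sn) / beta
            G[i, n] += en / (1.0 + sn) / B
    loss = total / B
    dE = (G + G.T) @ E
    return float(loss), dE.astype(embeddings.dtype)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy; returns (loss, dL/dlogits)."""
    z = np.asarray(logits, dtype=np.float64)
    B = z.shape[0]
    z = z - z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    idx = (np.arange(B), np.asarray(labels))
    loss = -np.mean(np.log(p[idx] + 1e-300))
    dz = p.copy()
    dz[idx] -= 1.0
    return float(loss), (dz / B).astype(logits.dtype)


def arcface_loss(
    embeddings: np.ndarray,
    labels: np.ndarray,
    class_weights: np.ndarray,
    margin: float = 0.5,
    scale: float = 64.0,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Additive angular margin softmax loss.

    Cosine logits between unit embeddings and (internally L2-normalized)
    class weight vectors; the target-class cosine is replaced by
    cos(theta + margin) before scaling by ``scale`` and applying softmax
    cross-entropy.  Where theta + margin would exceed pi, the standard linear
    fallback cos(theta) - margin*sin(margin) is used.

    Returns (loss, dL/dembeddings, dL/dclass_weights).
    """
    E = np.asarray(embeddings, dtype=np.float64)
    W = np.asarray(class_weights, dtype=np.float64)
    labels = np.asarray(labels)
    B, C = len(labels), W.shape[0]
    if labels.max() >= C:
        raise ValueError("label index exceeds class count")
    norms = np.sqrt((W * W).sum(axis=1, keepdims=True)) + 1e-12
    Wn = W / norms
    cos = np.clip(E @ Wn.T, -1.0 + 1e-7, 1.0 - 1e-7)

    idx = (np.arange(B), labels)
    c = cos[idx]
    sin = np.sqrt(1.0 - c * c)
    cos_m, sin_m = np.cos(margin), np.sin(margin)
    phi = c * cos_m - sin * sin_m  # cos(theta + margin)
    safe = c > np.cos(np.pi - margin)  # theta + margin <= pi
    fallback = c - margin * sin_m
    target_logit = np.where(safe, phi, fallback)
    dphi_dc = np.where(safe, cos_m + (c / np.maximum(sin, 1e-12)) * sin_m, 1.0)

    logits = scale * cos
    logits[idx] = scale * target_logit
    loss, dlogits = softmax_cross_entropy(logits, labels)
    dlogits = dlogits.astype(np.float64)

    dcos = scale * dlogits
    dcos[idx] *= dphi_dc
    dE = dcos @ Wn
    dWn = dcos.T @ E
    # backprop through row normalization of W
    dW = (dWn - Wn * (dWn * Wn).sum(axis=1, keepdims=True)) / norms
    return (
        float(loss),
        dE.astype(embeddings.dtype),
        dW.astype(class_weights.dtype),
    )
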