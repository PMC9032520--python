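"""Training loops for open-set (metric learning) and closed-set (margin
classification) authentication.

Open-set defaults follow the verification protocol: AdamW, lr 1e-4, weight
decay 1e-4, batches of 8 subjects x 4 samples, multi-similarity loss with
default parameters (alpha 2, beta 50, base 0.5).  Closed-set defaults: Adam,
lr 1e-3, weight decay 1e-4, ArcFace loss with reference defaults (margin
0.5, scale 64).  Checkpoint selection is by validation EER.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..evaluate import evaluate_embeddings
from .losses import arcface_loss, multisimilarity_loss
from .model import EmbeddingNet
from .optim import AdamW

__all__ = ["FeatureSet", "TrainConfig", "TrainResult", "train", "embed_in_batches"]


@dataclass
class FeatureSet:
    """Feature arrays with integer subject labels.

    ``mi``: (N, 2, L) or None; ``sdm``: (N, 1, H, W) or None; ``labels``: (N,).
    """

    labels: np.ndarray
    mi: np.ndarray | None = None
    sdm: np.ndarray | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        n = len(self.labels)
        if self.mi is None and self.sdm is None:
            raise ValueError("FeatureSet needs mi and/or sdm arrays")
        for name in ("mi", "sdm"):
            arr = getattr(self, name)
            if arr is not None and len(arr) != n:
                raise ValueError(f"{name} length != labels length")

    def __len__(self) -> int:
        return len(self.labels)

    def take(self, idx: np.ndarray) -> tuple[np.ndarray | None, np.ndarray | None]:
        mi = self.mi[idx] if self.mi is not None else None
        sdm = self.sdm[idx] if self.sdm is not None else None
        return mi, sdm


@dataclass
class TrainConfig:
    mode: str = "open_set"  # or "closed_set"
    lr: float | None = None  # default 1e-4 open, 1e-3 closed
    weight_decay: float = 1e-4
    max_steps: int = 2000
    subjects_per_batch: int = 8
    samples_per_subject: int = 4
    ms_alpha: float = 2.0
    ms_beta: float = 50.0
    ms_base: float = 0.5
    ms_eps: float = 0.1
    arc_margin: float = 0.5
    arc_scale: float = 64.0
    seed: int = 0
    val_every: int = 250
    log_every: int = 50

    def __post_init__(self):
        if self.mode not in ("open_set", "closed_set"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.lr is None:
            self.lr = 1e-4 if self.mode == "open_set" else 1e-3


@dataclass
class TrainResult:
    best_state: dict
    final_state: dict
    history: list = field(default_factory=list)  # dicts: step, loss, val_eer
    best_val_eer: float = float("nan")

    def loss_curve(self) -> np.ndarray:
        return np.array([h["loss"] for h in self.history])


def embed_in_batches(
    model: EmbeddingNet, features: FeatureSet, batch: int = 64
) -> np.ndarray:
    """Embed a whole feature set in evaluation mode."""
    out = []
    for s in range(0, len(features), batch):
        idx = np.arange(s, min(s + batch, len(features)))
        mi, sdm = features.take(idx)
        out.append(model.forward(mi=mi, sdm=sdm, train=False))
    return np.concatenate(out, axis=0)


def _sample_batch(
    rng: np.random.Generator,
    labels: np.ndarray,
    by_label: dict,
    n_subjects: int,
    n_per: int,
) -> np.ndarray:
    subs = rng.choice(list(by_label.keys()), size=n_subjects, replace=False)
    idx = []
    for s in subs:
        pool = by_label[s]
        take = rng.choice(pool, size=n_per, replace=len(pool) < n_per)
        idx.extend(take)
    return np.asarray(idx)


def train(
    model: EmbeddingNet,
    train_set: FeatureSet,
    cfg: TrainConfig,
    val_set: FeatureSet | None = None,
) -> TrainResult:
    """Seeded mini-batch training with validation-EER checkpoint selection.

    Raises RuntimeError with a diagnostic if the loss becomes non-finite.
    """
    rng = np.random.default_rng(cfg.seed)
    labels = train_set.labels
    classes = np.unique(labels)
    if len(classes) < min(2, cfg.subjects_per_batch):
        raise ValueError("training set needs at least 2 subjects")
    n_subjects = min(cfg.subjects_per_batch, len(classes))
    by_label = {int(c): np.flatnonzero(labels == c) for c in classes}

    params = model.parameters()
    class_W = None
    if cfg.mode == "closed_set":
        remap = {int(c): i for i, c in enumerate(classes)}
        class_W = (
            rng.standard_normal((len(classes), model.embed_dim)) * 0.01
        ).astype(np.float32)
        dclass_W = np.zeros_like(class_W)
        params = params + [(class_W, dclass_W)]

    opt = AdamW(
        params,
        lr=cfg.lr,
        weight_decay=cfg.weight_decay,
        decoupled=(cfg.mode == "open_set"),
    )

    result = TrainResult(best_state={}, final_state={})
    best_eer = float("inf")

    for step in range(1, cfg.max_steps + 1):
        idx = _sample_batch(rng, labels, by_label, n_subjects, cfg.samples_per_subject)
        mi, sdm = train_set.take(idx)
        emb = model.forward(mi=mi, sdm=sdm, train=True)
        if not np.all(np.isfinite(emb)):
            raise RuntimeError(
                f"training diverged: non-finite embeddings at step {step} "
                f"(lr={cfg.lr}, mode={cfg.mode})"
            )
        batch_labels = labels[idx]
        if cfg.mode == "open_set":
            loss, demb = multisimilarity_loss(
                emb, batch_labels,
                alpha=cfg.ms_alpha, beta=cfg.ms_beta,
                base=cfg.ms_base, eps=cfg.ms_eps,
            )
        else:
            mapped = np.array([remap[int(c)] for c in batch_labels])
            loss, demb, dW = arcface_loss(
                emb, mapped, class_W, margin=cfg.arc_margin, scale=cfg.arc_scale
            )
            dclass_W[...] = dW
        if not np.isfinite(loss):
            raise RuntimeError(
                f"training diverged: non-finite loss at step {step} "
                f"(lr={cfg.lr}, mode={cfg.mode})"
            )
        model.backward(demb)
        opt.step()

        entry = {"step": step, "loss": float(loss), "val_eer": None}
        validate = val_set is not None and (
            step % cfg.val_every == 0 or step == cfg.max_steps
        )
        if validate:
            emb_val = embed_in_batches(model, val_set)
            eer = evaluate_embeddings(emb_val, val_set.labels).eer
            entry["val_eer"] = float(eer)
            if eer < best_eer:
                best_eer = eer
                result.best_state = model.state_dict()
        if validate or step % cfg.log_every == 0 or step == 1:
            result.history.append(entry)

    result.final_state = model.state_dict()
    if not result.best_state:
        result.best_state = result.final_state
    result.best_val_eer = best_eer if np.isfinite(best_eer) else float("nan")
    return result
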