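"""Training protocol for the two branches and the feature-level ensemble.

The optimization recipe mirrors the published setup: Adam with default
moments, initial learning rates 1e-4 (2D branch) and 1e-5 (3D branch),
learning-rate decay by 0.8 when the training loss stops reaching new
minima, dropout p = 0.5 before the classification layer, and per-class
augmentation factors that balance the training set.  Checkpoint selection
is by best validation AUC, matching the reporting metric.

Everything is deterministic given the config seed: data order, dropout
masks, augmentation draws and weight initialization all derive from it.
"""

from __future__ import annotations

import copy
import random
from dataclasses import dataclass, field

import numpy as np

from .evaluation import PredictionRecord, roc_auc
from .focus import find_focus
from .networks import Classifier, FeatureEnsembleHead
from .nn import Adam
from .nn.losses import softmax, softmax_cross_entropy
from .phantom import Cohort, augmentation_plan
from .preprocess import (
    SlabConfig,
    augment_sample,
    minmax_normalize,
    resize_slice,
    select_slab,
)

__all__ = [
    "TrainConfig",
    "BranchData",
    "lr_schedule_step",
    "set_global_seed",
    "build_branch_data",
    "train_branch",
    "predict_proba",
    "predictions_for",
    "train_feature_ensemble",
    "feature_ensemble_predictions",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (defaults follow the published protocol)."""

    lr_2d: float = 1e-4
    lr_3d: float = 1e-5
    decay_factor: float = 0.8
    plateau_patience: int = 3
    epochs: int = 10
    batch_size: int = 16
    seed: int = 0
    dropout_p: float = 0.5
    augment_factors: tuple[int, int] = (1, 1)  # (benign, malignant)

    def __post_init__(self) -> None:
        if self.lr_2d <= 0 or self.lr_3d <= 0:
            raise ValueError("learning rates must be positive")
        if not 0.0 < self.decay_factor < 1.0:
            raise ValueError("decay factor must lie in (0, 1)")
        if self.plateau_patience < 1 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("patience, epochs and batch size must be >= 1")


def lr_schedule_step(
    loss_history: list[float],
    current_lr: float,
    decay_factor: float = 0.8,
    patience: int = 3,
) -> float:
    """Plateau decay: multiply the rate by ``decay_factor`` each time the
    training loss has gone ``patience`` consecutive epochs without a new
    minimum (the plateau counter restarts after every decay).
    """
    if not loss_history:
        raise ValueError("loss history must be non-empty")
    best = np.inf
    since_best = 0
    for loss in loss_history:
        if loss < best:
            best = loss
            since_best = 0
        else:
            since_best += 1
    if since_best > 0 and since_best % patience == 0:
        return current_lr * decay_factor
    return current_lr


def set_global_seed(seed: int) -> np.random.Generator:
    """Seed the process-wide RNG streams and return a dedicated generator.

    Residual nondeterminism sources: none on CPU — all layers, data
    ordering and augmentation use explicit generators derived from seeds.
    """
    np.random.seed(seed % 2**32)
    random.seed(seed)
    return np.random.default_rng(seed)


@dataclass
class BranchData:
    """Preprocessed arrays for one split.

    ``x2d`` is (n, 1, H, W) resized focus slices; ``x3d`` is
    (n, 1, N, h, w) focus-centered slabs; labels are 1 for malignant.
    """

    x2d: np.ndarray
    x3d: np.ndarray
    labels: np.ndarray
    lesion_ids: list[str]
    views: list[str]


def build_branch_data(
    cohort: Cohort,
    split: str,
    slab_cfg: SlabConfig = SlabConfig(),
    use_oracle_focus: bool = True,
) -> BranchData:
    """Run the preprocessing chain over one split of a cohort.

    With ``use_oracle_focus`` the generator's ground-truth focus slice is
    used; otherwise the focus is located with the oracle microcalcification
    mask through the focus-score statistic.
    """
    records = cohort.subset(split)
    if not records:
        raise ValueError(f"split {split!r} is empty")
    x2d, x3d, labels, ids, views = [], [], [], [], []
    for rec in records:
        roi, mask, focus_gt = cohort.volumes[(rec.lesion_id, rec.view)]
        norm = minmax_normalize(roi)
        if use_oracle_focus:
            focus = focus_gt
        else:
            focus = find_focus(norm, oracle_mask=mask).focus_idx
        slab = select_slab(norm, focus, slab_cfg)  # (h, w, N)
        x3d.append(slab.transpose(2, 0, 1)[None])  # (1, N, h, w)
        x2d.append(resize_slice(norm.intensities[:, :, focus],
                                slab_cfg.resize_2d)[None])
        labels.append(1 if rec.label == "malignant" else 0)
        ids.append(rec.lesion_id)
        views.append(rec.view)
    return BranchData(
        x2d=np.asarray(x2d, dtype=np.float32),
        x3d=np.asarray(x3d, dtype=np.float32),
        labels=np.asarray(labels, dtype=np.int64),
        lesion_ids=ids,
        views=views,
    )


def _epoch_plan(labels: np.ndarray, factors: tuple[int, int], seed: int):
    """Expand sample indices by the per-class augmentation factors.

    Returns (indices, ops): index i repeated f_class(i) times, the first
    copy with the identity op, later copies with seeded random ops.
    Epoch size is exactly n_b*f_b + n_m*f_m.
    """
    f_b, f_m = factors
    n_b = int(np.sum(labels == 0))
    n_m = int(np.sum(labels == 1))
    (_, _), ops = augmentation_plan(n_b, n_m, factors, seed=seed)
    indices: list[int] = []
    benign_idx = np.flatnonzero(labels == 0)
    malignant_idx = np.flatnonzero(labels == 1)
    for idx_list, f in ((benign_idx, f_b), (malignant_idx, f_m)):
        for i in idx_list:
            indices.extend([int(i)] * f)
    return np.asarray(indices), ops


def _apply_ops(x: np.ndarray, ops: list[tuple]) -> np.ndarray:
    """Apply per-sample ops to a batch of (1, ...) samples."""
    out = np.empty_like(x)
    for i, op in enumerate(ops):
        sample = x[i, 0]
        if sample.ndim == 3:  # (N, h, w) slab -> in-plane ops expect z last
            aug = augment_sample(sample.transpose(1, 2, 0), op).transpose(2, 0, 1)
        else:
            aug = augment_sample(sample, op)
        out[i, 0] = aug
    return out


def predict_proba(model: Classifier, x: np.ndarray, batch_size: int = 32
                  ) -> np.ndarray:
    """Evaluation-mode class probabilities, batched."""
    probs = []
    for start in range(0, len(x), batch_size):
        probs.append(softmax(model.forward(x[start : start + batch_size],
                                           train=False)))
    return np.concatenate(probs, axis=0)


def _val_metrics(model: Classifier, x, labels) -> tuple[float, float]:
    p = predict_proba(model, x)
    eps = 1e-12
    loss = float(-np.mean(np.log(p[np.arange(len(labels)), labels] + eps)))
    auc = roc_auc(p[:, 1], labels)
    return loss, auc


def train_branch(
    model: Classifier,
    train_data: BranchData,
    val_data: BranchData,
    cfg: TrainConfig,
    arch: str = "3d",
) -> tuple[Classifier, list[dict]]:
    """Train one branch with Adam, plateau LR decay and best-AUC selection.

    Returns the model with the best-validation-AUC weights loaded and the
    per-epoch history (epoch, lr, train_loss, val_loss, val_auc).
    """
    if arch not in ("2d", "3d"):
        raise ValueError(f"arch must be '2d' or '3d', got {arch!r}")
    x_train = train_data.x2d if arch == "2d" else train_data.x3d
    x_val = val_data.x2d if arch == "2d" else val_data.x3d
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("empty training or validation split")
    labels = train_data.labels
    lr = cfg.lr_2d if arch == "2d" else cfg.lr_3d
    opt = Adam(model.params(), lr=lr)
    rng = np.random.default_rng(cfg.seed)
    indices, ops = _epoch_plan(labels, cfg.augment_factors, seed=cfg.seed)

    history: list[dict] = []
    loss_history: list[float] = []
    best_auc = -np.inf
    best_state: dict | None = None
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(indices))
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            xb = x_train[indices[sel]]
            batch_ops = [ops[int(s)] for s in sel]
            if any(op[0] != "identity" for op in batch_ops):
                xb = _apply_ops(xb, batch_ops)
            yb = labels[indices[sel]]
            logits = model.forward(xb, train=True)
            loss, dlogits = softmax_cross_entropy(logits, yb)
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            epoch_losses.append(loss)
        train_loss = float(np.mean(epoch_losses))
        loss_history.append(train_loss)
        val_loss, val_auc = _val_metrics(model, x_val, val_data.labels)
        history.append(
            {
                "epoch": epoch,
                "lr": opt.lr,
                "train_loss": train_loss,
                "val_loss": val_loss,
                "val_auc": val_auc,
                "seed": cfg.seed,
            }
        )
        if val_auc > best_auc:
            best_auc = val_auc
            best_state = copy.deepcopy(model.state_dict())
        opt.lr = lr_schedule_step(
            loss_history, opt.lr, cfg.decay_factor, cfg.plateau_patience
        )
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history


def predictions_for(
    model: Classifier, data: BranchData, arch: str
) -> list[PredictionRecord]:
    """Per-view malignancy scores for a trained branch."""
    x = data.x2d if arch == "2d" else data.x3d
    p = predict_proba(model, x)
    return [
        PredictionRecord(lesion_id=lid, view=view, label=int(lab),
                         p_malignant=float(pm))
        for lid, view, lab, pm in zip(data.lesion_ids, data.views,
                                      data.labels, p[:, 1])
    ]


def _extract_features(model2d, model3d, data: BranchData
                      ) -> tuple[np.ndarray, np.ndarray]:
    f2d_parts = []
    for start in range(0, len(data.x2d), 32):
        model2d.forward(data.x2d[start : start + 32], train=False)
        f2d_parts.append(model2d.last_features.copy())
    f3d_parts = []
    for start in range(0, len(data.x3d), 32):
        model3d.forward(data.x3d[start : start + 32], train=False)
        f3d_parts.append(model3d.last_features.copy())
    return np.concatenate(f2d_parts), np.concatenate(f3d_parts)


def train_feature_ensemble(
    model2d: Classifier,
    model3d: Classifier,
    train_data: BranchData,
    val_data: BranchData,
    cfg: TrainConfig,
) -> FeatureEnsembleHead:
    """Fit the linear head on concatenated pooled features of frozen branches."""
    head = FeatureEnsembleHead(model2d.feat_dim, model3d.feat_dim,
                               n_classes=2, seed=cfg.seed)
    f2d, f3d = _extract_features(model2d, model3d, train_data)
    v2d, v3d = _extract_features(model2d, model3d, val_data)
    opt = Adam(head.params(), lr=cfg.lr_2d)
    rng = np.random.default_rng(cfg.seed + 7)
    best_auc, best_w = -np.inf, None
    for epoch in range(max(cfg.epochs, 20)):
        order = rng.permutation(len(f2d))
        for start in range(0, len(order), cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            logits = head.forward(f2d[sel], f3d[sel], train=True)
            _, dlogits = softmax_cross_entropy(logits, train_data.labels[sel])
            opt.zero_grad()
            head.backward(dlogits)
            opt.step()
        val_p = softmax(head.forward(v2d, v3d))
        auc = roc_auc(val_p[:, 1], val_data.labels)
        if auc > best_auc:
            best_auc = auc
            best_w = [p.value.copy() for p in head.params()]
    if best_w is not None:
        for p, w in zip(head.params(), best_w):
            p.value = w
    return head


def feature_ensemble_predictions(
    model2d: Classifier,
    model3d: Classifier,
    head: FeatureEnsembleHead,
    data: BranchData,
) -> list[PredictionRecord]:
    f2d, f3d = _extract_features(model2d, model3d, data)
    p = softmax(head.forward(f2d, f3d))
    return [
        PredictionRecord(lesion_id=lid, view=view, label=int(lab),
                         p_malignant=float(pm))
        for lid, view, lab, pm in zip(data.lesion_ids, data.views,
                                      data.labels, p[:, 1])
    ]
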