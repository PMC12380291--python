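"""Supervised training: end-to-end, Mixup variant, and freeze-and-fine-tune.

Transfer works because every interaction-layer parameter (the shared
intra-feature MLP and the encoder stack) is feature-count agnostic: a model
pretrained on a wide corpus can be rebuilt around a narrow clinical table
by initializing a fresh embedding layer and output head for the target
schema, copying the interaction parameters, and freezing them.  Training
then only moves the embedding and head ("freeze-and-fine-tune"), which is
the intended remedy for overfitting on small, class-imbalanced tables — no
reweighting or resampling is applied.

Early stopping monitors validation AUC after each epoch and returns the
parameters of the best epoch (ties resolve to the earliest); when the
validation split is single-class, validation loss is monitored instead and
the result carries a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Adam, Tensor
from .head_metrics import auc, bce_logit_loss_t
from .interaction import InteractionConfig
from .model import (
    Checkpoint,
    ENCODER_PREFIXES,
    INTERACTION_PREFIXES,
    ModelParams,
    forward_logits,
    init_model_params,
)
from .schema_data import FeatureSchema, TabularDataset

__all__ = [
    "TrainConfig",
    "TrainResult",
    "TransferError",
    "transfer_and_freeze",
    "mixup_batch",
    "train_supervised",
    "predict",
]

FREEZE_SCOPES = ("none", "encoder_only", "interaction_layer")


class TransferError(ValueError):
    """Pretrained checkpoint cannot be reused for the target table."""


@dataclass
class TrainConfig:
    """Supervised-training hyperparameters (defaults: Adam 2e-4, batch 256)."""

    batch_size: int = 256
    learning_rate: float = 2e-4
    max_epochs: int = 200
    early_stop_patience: int = 10
    freeze_scope: str = "interaction_layer"
    mixup_enabled: bool = False
    mixup_alpha: float = 0.2
    pos_weight: float | None = None
    warm_start_embedding: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.freeze_scope not in FREEZE_SCOPES:
            raise ValueError(f"freeze_scope must be one of {FREEZE_SCOPES}")
        if self.early_stop_patience < 1:
            raise ValueError("early_stop_patience must be >= 1")
        if self.mixup_alpha <= 0:
            raise ValueError("mixup_alpha must be > 0")

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class TrainResult:
    model: ModelParams
    trace: list[dict]
    best_epoch: int
    stopped_on: str = "val_auc"  # or "val_loss" when validation is single-class


def transfer_and_freeze(
    checkpoint: Checkpoint,
    target_schema: FeatureSchema,
    freeze_scope: str = "interaction_layer",
    pooling: str | None = None,
    seed: int = 0,
    warm_start_embedding: bool = False,
) -> ModelParams:
    """Rebuild a model around a target table from pretrained interaction
    parameters.

    A fresh embedding layer sized to the target schema and a fresh output
    head are initialized; the intra-feature MLP and encoder stack are
    copied from the checkpoint, and the scope-selected subset is marked
    non-trainable (``interaction_layer`` = intra + encoder,
    ``encoder_only`` = encoder stack, ``none`` = nothing frozen).

    With ``warm_start_embedding`` (legal only when the target schema
    fingerprint matches the pretraining schema) the embedding layer is
    copied from the checkpoint instead of re-initialized — it stays
    trainable, but starts in the token basis the frozen encoder was
    trained on.  The output head is always fresh.
    """
    if freeze_scope not in FREEZE_SCOPES:
        raise ValueError(f"freeze_scope must be one of {FREEZE_SCOPES}")
    if warm_start_embedding and (
        target_schema.fingerprint() != checkpoint.schema_fingerprint
    ):
        raise TransferError(
            "warm-starting the embedding requires the pretraining schema; "
            "the target schema fingerprint differs"
        )
    cfg_dict = checkpoint.config.to_dict()
    if pooling is not None:
        cfg_dict["pooling"] = pooling
    config = InteractionConfig.from_dict(cfg_dict)
    model = init_model_params(target_schema, config, seed=seed)
    for name in model.names(*INTERACTION_PREFIXES):
        if name not in checkpoint.arrays:
            raise TransferError(f"checkpoint lacks interaction parameter {name!r}")
        if checkpoint.arrays[name].shape != model.params[name].shape:
            raise TransferError(
                f"shape mismatch for {name!r}: checkpoint "
                f"{checkpoint.arrays[name].shape} vs target {model.params[name].shape}"
                " (embedding dimension or widths differ)"
            )
        model.params[name].data = checkpoint.arrays[name].copy()
    if warm_start_embedding:
        for name in model.names("embed/"):
            if name in checkpoint.arrays:
                model.params[name].data = checkpoint.arrays[name].copy()
    if freeze_scope == "interaction_layer":
        model.freeze(model.names(*INTERACTION_PREFIXES))
    elif freeze_scope == "encoder_only":
        model.freeze(model.names(*ENCODER_PREFIXES))
    return model


def mixup_batch(
    X_num: np.ndarray,
    X_cat: np.ndarray,
    y: np.ndarray,
    lam: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mixup restricted to numerical features.

    Rows are paired with a seeded within-batch permutation; numerical
    features and labels are convex-combined with weight ``lam`` while
    categorical features stay those of the anchor row (convex combinations
    of category indices are meaningless).  Soft labels in [0, 1] result.
    """
    if not 0 <= lam <= 1:
        raise ValueError("lambda must lie in [0, 1]")
    if X_num.shape[0] < 2:
        raise ValueError("mixup needs at least two rows")
    perm = rng.permutation(X_num.shape[0])
    X_num_mixed = lam * X_num + (1 - lam) * X_num[perm]
    y_mixed = lam * np.asarray(y, dtype=np.float64) + (1 - lam) * np.asarray(
        y, dtype=np.float64
    )[perm]
    return X_num_mixed, X_cat.copy(), y_mixed


def _weighted_bce(logits: Tensor, y: np.ndarray, pos_weight: float | None) -> Tensor:
    if pos_weight is None:
        return bce_logit_loss_t(logits, y)
    w = np.where(np.asarray(y) > 0.5, pos_weight, 1.0)
    w = w / w.mean()
    from .autodiff import softplus

    y_t = Tensor(np.asarray(y, dtype=np.float64))
    return ((softplus(logits) - y_t * logits) * Tensor(w)).mean()


def train_supervised(
    train: TabularDataset,
    val: TabularDataset,
    model: ModelParams,
    config: TrainConfig,
) -> TrainResult:
    """Minimize BCE-with-logits by Adam with early stopping on validation AUC.

    Stops when the monitored metric has not improved for
    ``early_stop_patience`` epochs (or at ``max_epochs``) and restores the
    best-epoch parameters.  Frozen parameters never change.
    """
    if train.k == 0 or val.k == 0:
        raise ValueError("train and validation splits must be non-empty")
    y_train = train.labels_int().astype(np.float64)
    y_val = val.labels_int()
    single_class_val = len(np.unique(y_val)) < 2
    stopped_on = "val_loss" if single_class_val else "val_auc"

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 29]))
    order_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 31]))
    mix_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 37]))
    opt = Adam(model.trainable(), lr=config.learning_rate)

    best_metric = -np.inf
    best_epoch = -1
    best_snapshot = model.snapshot()
    patience_left = config.early_stop_patience
    trace: list[dict] = []

    for epoch in range(config.max_epochs):
        order = order_rng.permutation(train.k)
        epoch_losses: list[float] = []
        for start in range(0, train.k, config.batch_size):
            idx = order[start : start + config.batch_size]
            Xn, Xc, yb = train.X_num[idx], train.X_cat[idx], y_train[idx]
            if config.mixup_enabled and idx.size >= 2:
                lam = float(mix_rng.beta(config.mixup_alpha, config.mixup_alpha))
                Xn, Xc, yb = mixup_batch(Xn, Xc, yb, lam, mix_rng)
            logits = forward_logits(model, Xn, Xc, rng=rng, training=True)
            loss = _weighted_bce(logits, yb, config.pos_weight)
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"training loss diverged at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))

        val_scores = predict(val, model)
        record: dict = {"epoch": epoch, "train_loss": float(np.mean(epoch_losses))}
        if single_class_val:
            clipped = np.clip(val_scores, 1e-12, 1 - 1e-12)
            val_logits = np.log(clipped) - np.log1p(-clipped)
            val_loss = float(
                np.mean(np.logaddexp(0.0, val_logits) - y_val * val_logits)
            )
            metric = -val_loss
            record["val_loss"] = val_loss
        else:
            metric = auc(val_scores, y_val)
            record["val_auc"] = metric
        trace.append(record)

        if metric > best_metric:
            best_metric = metric
            best_epoch = epoch
            best_snapshot = model.snapshot()
            patience_left = config.early_stop_patience
        else:
            patience_left -= 1
            if patience_left == 0:
                break

    model.restore(best_snapshot)
    return TrainResult(
        model=model, trace=trace, best_epoch=best_epoch, stopped_on=stopped_on
    )


def predict(dataset: TabularDataset, model: ModelParams, batch_size: int = 1024) -> np.ndarray:
    """Deterministic evaluation-mode scores (sigmoid probabilities)."""
    scores = np.empty(dataset.k)
    for start in range(0, dataset.k, batch_size):
        sl = slice(start, start + batch_size)
        logits = forward_logits(
            model, dataset.X_num[sl], dataset.X_cat[sl], training=False
        ).data
        scores[sl] = 1.0 / (1.0 + np.exp(-np.clip(logits, -500, 500)))
    return scores
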