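"""Masked-feature self-supervised pretraining.

Corruption replaces a Bernoulli(p_m)-selected subset of cells with values
resampled from the same column (per-feature independent shuffling of the
sample order, which preserves every feature's marginal distribution
exactly):

    X_tilde = m * X_bar + (1 - m) * X

Two linear heads then read the token-level interaction output Z: a shared
mask head scores each token for "was this cell corrupted", and a
feature head reconstructs the ORIGINAL cell value from the token
concatenated with its (raw, unthresholded) mask logit — a regression output
for each numerical feature, per-category logits for each categorical
feature.  The pretraining loss is

    L = L_mask + alpha * L_feature,

with BCE-with-logits for the mask grid, mean squared error for numerical
reconstructions and cross-entropy for categorical ones.  Minimizing L
trains the embedding layer, the interaction layer and both heads; the
supervised output head is untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .autodiff import Adam, Tensor, concat, log_softmax, softplus
from .head_metrics import bce_logit_loss
from .interaction import InteractionConfig, token_output_t
from .model import Checkpoint, ModelParams, forward_states
from .schema_data import FeatureSchema, TabularDataset

__all__ = [
    "PretrainConfig",
    "MaskedBatch",
    "sample_mask",
    "shuffle_batch",
    "corrupt",
    "make_masked_batch",
    "pretrain_heads_forward",
    "pretrain_heads_forward_t",
    "pretrain_loss",
    "pretrain_loss_t",
    "run_pretraining",
]


@dataclass
class PretrainConfig:
    """Pretraining hyperparameters.

    Defaults follow the published self-supervised configuration: masking
    probability 0.5, batch size 256, 30 epochs, Adam at 2e-4, feature-loss
    weight alpha = 2.  ``beta`` and ``gamma`` are reserved keys carried for
    config compatibility; they enter no computation.
    """

    p_m: float = 0.5
    alpha: float = 2.0
    batch_size: int = 256
    epochs: int = 30
    learning_rate: float = 2e-4
    seed: int = 0
    shuffle_mode: str = "per_feature"  # or "rows": one whole-row permutation
    beta: float = 3.0  # reserved, unused
    gamma: float = 0.75  # reserved, unused

    def __post_init__(self):
        if not 0 <= self.p_m <= 1:
            raise ValueError("p_m must lie in [0, 1]")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.shuffle_mode not in ("per_feature", "rows"):
            raise ValueError("shuffle_mode must be 'per_feature' or 'rows'")


@dataclass
class MaskedBatch:
    """(original, shuffled, mask, corrupted) quadruple for one step.

    The mask grid has one row per feature (numerical block first, then
    categorical) and one column per sample, so ``mask[i, j] == 1`` means
    feature i of sample j was replaced by the shuffled value.
    """

    X_num: np.ndarray
    X_cat: np.ndarray
    Xb_num: np.ndarray
    Xb_cat: np.ndarray
    mask: np.ndarray  # (n + m, batch)
    Xt_num: np.ndarray
    Xt_cat: np.ndarray


def sample_mask(
    n_features: int, batch: int, p_m: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Independent Bernoulli(p_m) mask grid of shape (n_features, batch)."""
    if not 0 <= p_m <= 1:
        raise ValueError("p_m must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return (rng.random((n_features, batch)) < p_m).astype(np.int8)


def shuffle_batch(
    X: np.ndarray, seed: int | np.random.Generator = 0, mode: str = "per_feature"
) -> np.ndarray:
    """Resample each column by shuffling sample order.

    ``per_feature`` draws an independent permutation per column, preserving
    every feature's marginal exactly while destroying joint structure;
    ``rows`` applies one shared permutation to whole rows.
    """
    X = np.asarray(X)
    if X.shape[0] < 2:
        raise ValueError("shuffling needs at least two rows")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if mode == "rows":
        return X[rng.permutation(X.shape[0])]
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        out[:, j] = X[rng.permutation(X.shape[0]), j]
    return out


def corrupt(X: np.ndarray, X_bar: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Elementwise select: shuffled value where masked, original elsewhere.

    ``m`` is in feature-major orientation (features x samples) while the
    data blocks are sample-major, so the mask is transposed to align.
    """
    X = np.asarray(X)
    X_bar = np.asarray(X_bar)
    m = np.asarray(m)
    if X.shape != X_bar.shape or m.T.shape != X.shape:
        raise ValueError("corrupt: shape mismatch between data and mask")
    sel = m.T.astype(bool)
    return np.where(sel, X_bar, X)


def make_masked_batch(
    X_num: np.ndarray,
    X_cat: np.ndarray,
    p_m: float,
    rng: np.random.Generator,
    shuffle_mode: str = "per_feature",
) -> MaskedBatch:
    """One joint Bernoulli mask over the n+m feature grid, then corruption."""
    n = X_num.shape[1]
    m_feat = X_cat.shape[1]
    batch = X_num.shape[0]
    mask = sample_mask(n + m_feat, batch, p_m, rng)
    Xb_num = shuffle_batch(X_num, rng, shuffle_mode) if n else X_num.copy()
    Xb_cat = shuffle_batch(X_cat, rng, shuffle_mode) if m_feat else X_cat.copy()
    Xt_num = corrupt(X_num, Xb_num, mask[:n]) if n else X_num.copy()
    Xt_cat = corrupt(X_cat, Xb_cat, mask[n:]) if m_feat else X_cat.copy()
    return MaskedBatch(
        X_num=X_num, X_cat=X_cat, Xb_num=Xb_num, Xb_cat=Xb_cat,
        mask=mask, Xt_num=Xt_num, Xt_cat=Xt_cat,
    )


# ---------------------------------------------------------------------------
# heads
# ---------------------------------------------------------------------------


def pretrain_heads_forward_t(
    Z: Tensor, params: Mapping[str, Tensor], schema: FeatureSchema
) -> tuple[Tensor, Tensor | None, list[Tensor]]:
    """Dual heads on the token-level output Z of shape (B, t, d).

    Returns ``(mask_logits (B, t), numerical predictions (B, n) or None,
    per-categorical-feature logits [(B, |vocab_i|)])``.  The feature head
    consumes each token concatenated with its raw mask logit.
    """
    B, t, d = Z.shape
    if t != schema.n + schema.m:
        raise ValueError("token count does not match schema feature count")
    mask_logits = (Z @ params["pre/mask_w"] + params["pre/mask_b"]).reshape(B, t)
    Z_aug = concat([Z, mask_logits.reshape(B, t, 1)], axis=2)  # (B, t, d+1)

    num_preds: Tensor | None = None
    if schema.n:
        z_num = Z_aug[:, : schema.n, :]  # (B, n, d+1)
        num_preds = (z_num * params["pre/num_w"]).sum(axis=2) + params["pre/num_b"]

    cat_logits: list[Tensor] = []
    offsets = schema.offsets
    for i, card in enumerate(schema.cardinalities):
        z_i = Z_aug[:, schema.n + i, :]  # (B, d+1)
        w = params["pre/cat_w"][:, offsets[i] : offsets[i] + card]
        b = params["pre/cat_b"][offsets[i] : offsets[i] + card]
        cat_logits.append(z_i @ w + b)
    return mask_logits, num_preds, cat_logits


def pretrain_heads_forward(
    Z: np.ndarray, params: Mapping[str, Tensor], schema: FeatureSchema
) -> tuple[np.ndarray, dict]:
    """Per-row wrapper: Z is d x t; returns (mask_logits (t,), feature preds)."""
    Zt = Tensor(np.asarray(Z, dtype=np.float64).T[None, :, :])
    mask_logits, num_preds, cat_logits = pretrain_heads_forward_t(Zt, params, schema)
    preds = {
        "numerical": None if num_preds is None else num_preds.data[0],
        "categorical": [c.data[0] for c in cat_logits],
    }
    return mask_logits.data[0], preds


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------


def pretrain_loss_t(
    batch: MaskedBatch,
    mask_logits: Tensor,
    num_preds: Tensor | None,
    cat_logits: list[Tensor],
    alpha: float,
) -> tuple[Tensor, float, float]:
    """L = L_mask + alpha * L_feature (differentiable); also returns the two
    component values for tracing."""
    m_target = batch.mask.T.astype(np.float64)  # (B, t)
    y_t = Tensor(m_target)
    l_mask = (softplus(mask_logits) - y_t * mask_logits).mean()

    parts: list[Tensor] = []
    if num_preds is not None:
        diff = num_preds - Tensor(batch.X_num)
        parts.append((diff * diff).mean())
    if cat_logits:
        ce_terms = []
        for i, logits in enumerate(cat_logits):
            target = batch.X_cat[:, i].astype(int)
            logp = log_softmax(logits, axis=-1)
            picked = logp[np.arange(logits.shape[0]), target]
            ce_terms.append(-picked.mean())
        ce = ce_terms[0]
        for t in ce_terms[1:]:
            ce = ce + t
        parts.append(ce * (1.0 / len(cat_logits)))
    if parts:
        l_feat = parts[0]
        for t in parts[1:]:
            l_feat = l_feat + t
    else:
        l_feat = Tensor(0.0)
    total = l_mask + l_feat * alpha
    return total, float(l_mask.data), float(l_feat.data)


def pretrain_loss(
    batch: MaskedBatch,
    mask_logits: np.ndarray,
    feature_preds: dict,
    alpha: float,
) -> float:
    """NumPy evaluation of the combined loss for one single-row batch in the
    per-row layout produced by :func:`pretrain_heads_forward`."""
    n = batch.X_num.shape[1]
    l_mask = bce_logit_loss(
        np.asarray(mask_logits, dtype=np.float64).reshape(-1),
        batch.mask.T.reshape(-1).astype(np.float64),
    )
    parts = []
    if feature_preds.get("numerical") is not None and n:
        diff = np.asarray(feature_preds["numerical"]) - batch.X_num.reshape(-1)
        parts.append(float(np.mean(diff**2)))
    cats = feature_preds.get("categorical") or []
    if cats:
        ces = []
        for i, logits in enumerate(cats):
            logits = np.asarray(logits, dtype=np.float64)
            shifted = logits - logits.max()
            logp = shifted - np.log(np.exp(shifted).sum())
            ces.append(-logp[int(batch.X_cat[0, i])])
        parts.append(float(np.mean(ces)))
    return l_mask + alpha * float(np.sum(parts))


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


def run_pretraining(
    corpus: TabularDataset,
    model: ModelParams,
    config: PretrainConfig,
) -> tuple[ModelParams, list[float]]:
    """Self-supervised training of embedding + interaction + dual heads.

    Per epoch, rows are shuffled into mini-batches, corrupted, passed
    through the embedding and interaction layers (token-level output, no
    pooling), scored by the dual heads and updated by Adam.  Labels on the
    corpus, if any, are ignored.  Returns the model and the per-epoch mean
    loss trace.  Aborts on a non-finite loss.
    """
    if corpus.k < 2:
        raise ValueError("pretraining corpus needs at least two rows")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    order_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))
    trainable = {
        k: t
        for k, t in model.params.items()
        if not k.startswith("head/") and k not in model.frozen
    }
    opt = Adam(trainable, lr=config.learning_rate)
    trace: list[float] = []
    for _epoch in range(config.epochs):
        order = order_rng.permutation(corpus.k)
        losses: list[float] = []
        for start in range(0, corpus.k, config.batch_size):
            idx = order[start : start + config.batch_size]
            if idx.size < 2:
                continue
            batch = make_masked_batch(
                corpus.X_num[idx],
                corpus.X_cat[idx],
                config.p_m,
                rng,
                config.shuffle_mode,
            )
            states = forward_states(
                model, batch.Xt_num, batch.Xt_cat, rng=rng, training=True
            )
            Z = token_output_t(states)
            heads = pretrain_heads_forward_t(Z, model.params, model.schema)
            loss, _, _ = pretrain_loss_t(batch, *heads, alpha=config.alpha)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"pretraining loss diverged at epoch {_epoch}: {loss.data}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        trace.append(float(np.mean(losses)))
    return model, trace


def pretrain_to_checkpoint(
    corpus: TabularDataset,
    int_config: InteractionConfig,
    pre_config: PretrainConfig,
) -> Checkpoint:
    """Convenience: init (seeded), pretrain, wrap as a checkpoint."""
    from .model import init_model_params

    model = init_model_params(
        corpus.schema, int_config, seed=pre_config.seed, with_pretrain_heads=True
    )
    model, trace = run_pretraining(corpus, model, pre_config)
    return Checkpoint.from_model(
        model,
        meta={"pretrain": {
            "p_m": pre_config.p_m, "alpha": pre_config.alpha,
            "batch_size": pre_config.batch_size, "epochs": pre_config.epochs,
            "learning_rate": pre_config.learning_rate, "seed": pre_config.seed,
            "shuffle_mode": pre_config.shuffle_mode,
        }},
        loss_trace=trace,
    )
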