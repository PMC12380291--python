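"""Feature interaction layer: intra-feature MLP, PreNorm encoder stack,
and representation pooling.

Two mechanisms mix information in a token matrix ``T`` of shape
d x t (t = n + m feature tokens, plus one CLS token when CLS pooling is
configured):

* the **intra-feature** module applies one shared two-layer MLP
  (Linear -> ReLU -> Dropout -> Linear) to every token independently,
  refining each feature's own embedding;
* the **inter-feature** module is a stack of N transformer encoder layers
  in PreNorm form — ``u = T + MultiHead(LN(T)); out = u + MLP(LN(u))`` —
  whose multi-head scaled dot-product self-attention aggregates context
  across tokens.

The pooled row representation is either the token-mean of the last layer
(``last_avg``), the token-mean of the elementwise average of the first and
last layers (``first_last_avg``), or the CLS token of the last layer
(``cls``).

Spec-level operations here take plain NumPy arrays in the per-row d x t
layout and run in evaluation mode; the `_t`-suffixed functions are the
differentiable batched forms (layout (B, t, d)) used by training.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .autodiff import Tensor, dropout, layer_norm, softmax

__all__ = [
    "InteractionConfig",
    "EncoderState",
    "attention",
    "attention_matrix",
    "intra_forward",
    "encoder_layer_forward",
    "interaction_forward",
    "pool_representation",
    "intra_forward_t",
    "encoder_layer_forward_t",
    "interaction_forward_t",
    "pool_representation_t",
    "token_output_t",
]

POOLING_MODES = ("first_last_avg", "last_avg", "cls")


@dataclass
class InteractionConfig:
    """Architecture hyperparameters of the feature interaction layer.

    Defaults follow the published pretraining configuration
    (d_token=192, 8 heads, 3 encoder blocks); the intra-MLP hidden width
    and the encoder-MLP hidden width (2*d) are free choices exposed here.
    """

    d: int = 192
    n_heads: int = 8
    n_blocks: int = 3
    intra_hidden: int | None = None
    mlp_hidden: int | None = None
    dropout_rate: float = 0.10
    pooling: str = "first_last_avg"
    use_intra: bool = True
    use_inter: bool = True

    def __post_init__(self):
        if self.d % self.n_heads != 0:
            raise ValueError("d must be divisible by n_heads")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.pooling not in POOLING_MODES:
            raise ValueError(f"pooling must be one of {POOLING_MODES}")
        if self.intra_hidden is None:
            self.intra_hidden = self.d
        if self.mlp_hidden is None:
            self.mlp_hidden = 2 * self.d

    @property
    def d_head(self) -> int:
        return self.d // self.n_heads

    def to_dict(self) -> dict:
        return {
            "d": self.d,
            "n_heads": self.n_heads,
            "n_blocks": self.n_blocks,
            "intra_hidden": self.intra_hidden,
            "mlp_hidden": self.mlp_hidden,
            "dropout_rate": self.dropout_rate,
            "pooling": self.pooling,
            "use_intra": self.use_intra,
            "use_inter": self.use_inter,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InteractionConfig":
        return cls(**d)


@dataclass
class EncoderState:
    """Per-layer token matrices ``T(0)=input, T(1) ... T(N)``."""

    layers: list[np.ndarray]  # each d x t (per-row layout)

    @property
    def first(self) -> np.ndarray:
        return self.layers[1]

    @property
    def last(self) -> np.ndarray:
        return self.layers[-1]


_EVAL_RNG = np.random.default_rng(0)  # dropout is identity in eval mode anyway


# ---------------------------------------------------------------------------
# attention
# ---------------------------------------------------------------------------


def attention_matrix(K: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Row-stochastic attention matrix ``softmax(Q K^T / sqrt(d_k))``."""
    K = np.asarray(K, dtype=np.float64)
    Q = np.asarray(Q, dtype=np.float64)
    scores = Q @ K.T / np.sqrt(K.shape[1])
    scores -= scores.max(axis=1, keepdims=True)
    e = np.exp(scores)
    return e / e.sum(axis=1, keepdims=True)


def attention(K: np.ndarray, Q: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Single-head scaled dot-product attention output ``A V`` (t x d_v)."""
    return attention_matrix(K, Q) @ np.asarray(V, dtype=np.float64)


# ---------------------------------------------------------------------------
# differentiable batched forms
# ---------------------------------------------------------------------------


def intra_forward_t(
    T: Tensor,
    params: Mapping[str, Tensor],
    config: InteractionConfig,
    rng: np.random.Generator,
    training: bool,
) -> Tensor:
    """Shared two-layer MLP applied to each token column independently."""
    if not config.use_intra:
        return T
    h = (T @ params["intra/w1"] + params["intra/b1"]).relu()
    h = dropout(h, config.dropout_rate, rng, training)
    return h @ params["intra/w2"] + params["intra/b2"]


def _multihead_t(
    x: Tensor,
    params: Mapping[str, Tensor],
    layer: int,
    config: InteractionConfig,
    rng: np.random.Generator,
    training: bool,
) -> Tensor:
    p = lambda k: params[f"enc/{layer}/{k}"]
    B, t, d = x.shape
    H, dh = config.n_heads, config.d_head

    def heads(w, b):
        proj = x @ params[w] + params[b]  # (B, t, d)
        return proj.reshape(B, t, H, dh).transpose(0, 2, 1, 3)  # (B, H, t, dh)

    q = heads(f"enc/{layer}/wq", f"enc/{layer}/bq")
    k = heads(f"enc/{layer}/wk", f"enc/{layer}/bk")
    v = heads(f"enc/{layer}/wv", f"enc/{layer}/bv")
    scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(dh))  # (B, H, t, t)
    A = softmax(scores, axis=-1)
    A = dropout(A, config.dropout_rate, rng, training)
    out = (A @ v).transpose(0, 2, 1, 3).reshape(B, t, d)
    return out @ p("wo") + p("bo")


def encoder_layer_forward_t(
    T_in: Tensor,
    params: Mapping[str, Tensor],
    layer: int,
    config: InteractionConfig,
    rng: np.random.Generator,
    training: bool,
) -> Tensor:
    """One PreNorm encoder layer: attention sub-block then MLP sub-block,
    each applied to a layer-normalized input with a residual add outside."""
    p = lambda k: params[f"enc/{layer}/{k}"]
    u = T_in + _multihead_t(
        layer_norm(T_in, p("ln1_g"), p("ln1_b")), params, layer, config, rng, training
    )
    h = layer_norm(u, p("ln2_g"), p("ln2_b"))
    h = (h @ p("mlp_w1") + p("mlp_b1")).relu()
    h = dropout(h, config.dropout_rate, rng, training)
    return u + (h @ p("mlp_w2") + p("mlp_b2"))


def interaction_forward_t(
    T: Tensor,
    params: Mapping[str, Tensor],
    config: InteractionConfig,
    rng: np.random.Generator,
    training: bool,
) -> list[Tensor]:
    """Run the N-layer encoder stack, retaining every layer's output.

    Returns ``[T(0), T(1), ..., T(N)]``; with ``use_inter=False`` the stack
    is skipped and the state degenerates to ``[T, T]``.
    """
    if not config.use_inter:
        return [T, T]
    states = [T]
    for j in range(config.n_blocks):
        states.append(
            encoder_layer_forward_t(states[-1], params, j, config, rng, training)
        )
    return states


def token_output_t(states: Sequence[Tensor]) -> Tensor:
    """Token-level output T(out): elementwise mean of the first and last
    encoder layers (the matrix the pretraining heads consume)."""
    return (states[1] + states[-1]) * 0.5


def pool_representation_t(states: Sequence[Tensor], config: InteractionConfig) -> Tensor:
    """Collapse an encoder state to one length-d vector per row."""
    if config.pooling == "first_last_avg":
        return token_output_t(states).mean(axis=1)
    if config.pooling == "last_avg":
        return states[-1].mean(axis=1)
    if config.pooling == "cls":
        return states[-1][:, 0, :]
    raise ValueError(f"unknown pooling {config.pooling!r}")


# ---------------------------------------------------------------------------
# per-row NumPy wrappers (evaluation mode)
# ---------------------------------------------------------------------------


def _row_to_batch(T: np.ndarray) -> Tensor:
    return Tensor(np.asarray(T, dtype=np.float64).T[None, :, :])  # (1, t, d)


def intra_forward(
    T: np.ndarray, params: Mapping[str, Tensor], config: InteractionConfig
) -> np.ndarray:
    """Per-row intra-feature MLP on a d x t token matrix (eval mode)."""
    out = intra_forward_t(_row_to_batch(T), params, config, _EVAL_RNG, training=False)
    return out.data[0].T


def encoder_layer_forward(
    T_in: np.ndarray,
    params: Mapping[str, Tensor],
    layer: int,
    config: InteractionConfig,
) -> np.ndarray:
    """Per-row single encoder layer on a d x t token matrix (eval mode)."""
    out = encoder_layer_forward_t(
        _row_to_batch(T_in), params, layer, config, _EVAL_RNG, training=False
    )
    return out.data[0].T


def interaction_forward(
    T: np.ndarray, params: Mapping[str, Tensor], config: InteractionConfig
) -> EncoderState:
    """Per-row encoder stack on a d x t token matrix (eval mode)."""
    states = interaction_forward_t(
        _row_to_batch(T), params, config, _EVAL_RNG, training=False
    )
    return EncoderState(layers=[s.data[0].T for s in states])


def pool_representation(state: EncoderState, config: InteractionConfig) -> np.ndarray:
    """Pool a per-row EncoderState (layers d x t) to a length-d vector."""
    if config.pooling == "first_last_avg":
        return ((state.first + state.last) * 0.5).mean(axis=1)
    if config.pooling == "last_avg":
        return state.last.mean(axis=1)
    if config.pooling == "cls":
        if state.last.shape[1] < 1:
            raise ValueError("CLS pooling requested on an empty token matrix")
        return state.last[:, 0]
    raise ValueError(f"unknown pooling {config.pooling!r}")
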