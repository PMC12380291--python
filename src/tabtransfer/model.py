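"""Model parameter container, initialization, forward pass and checkpoints.

Parameters are a flat name -> :class:`~tabtransfer.autodiff.Tensor` mapping
grouped by layer role through name prefixes:

* ``embed/``  — numerical Hadamard weights/biases, category lookup table,
  categorical biases, optional CLS token (per-schema; never transferred);
* ``intra/``  — the shared two-layer intra-feature MLP (phi);
* ``enc/j/``  — encoder layer j: LayerNorms, Q/K/V/output projections and
  the feedforward MLP (psi);
* ``head/``   — the supervised output head (theta);
* ``pre/``    — the self-supervised mask and feature-reconstruction heads.

Prefixes are what freezing scopes name, so "freeze the interaction layer"
is exactly the set of ``intra/`` + ``enc/`` parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .autodiff import Tensor
from .interaction import (
    InteractionConfig,
    interaction_forward_t,
    intra_forward_t,
    pool_representation_t,
)
from .embedding import embed_batch
from .head_metrics import predict_logit_t
from .schema_data import FeatureSchema

__all__ = [
    "ModelParams",
    "init_model_params",
    "forward_states",
    "forward_representation",
    "forward_logits",
    "Checkpoint",
    "INTERACTION_PREFIXES",
    "ENCODER_PREFIXES",
]

INTERACTION_PREFIXES = ("intra/", "enc/")
ENCODER_PREFIXES = ("enc/",)


@dataclass
class ModelParams:
    """All learnable parameters plus the frozen-name registry."""

    schema: FeatureSchema
    config: InteractionConfig
    params: dict[str, Tensor]
    frozen: set[str] = field(default_factory=set)

    def __getitem__(self, name: str) -> Tensor:
        return self.params[name]

    def names(self, *prefixes: str) -> list[str]:
        if not prefixes:
            return list(self.params)
        return [k for k in self.params if k.startswith(prefixes)]

    def freeze(self, names: Iterable[str]) -> None:
        for name in names:
            self.params[name].requires_grad = False
            self.frozen.add(name)

    def trainable(self) -> dict[str, Tensor]:
        return {k: t for k, t in self.params.items() if k not in self.frozen}

    def snapshot(self, names: Iterable[str] | None = None) -> dict[str, np.ndarray]:
        keys = list(self.params) if names is None else list(names)
        return {k: self.params[k].data.copy() for k in keys}

    def restore(self, snapshot: Mapping[str, np.ndarray]) -> None:
        for k, v in snapshot.items():
            self.params[k].data = v.copy()


def _kaiming(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    bound = np.sqrt(3.0 / max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


def init_model_params(
    schema: FeatureSchema,
    config: InteractionConfig,
    seed: int = 0,
    with_pretrain_heads: bool = False,
) -> ModelParams:
    """Seeded Kaiming-uniform initialization of every parameter group."""
    rng = np.random.default_rng(seed)
    d = config.d
    p: dict[str, np.ndarray] = {}

    p["embed/W"] = _kaiming(rng, (d, schema.n), d)
    p["embed/B_num"] = _kaiming(rng, (d, schema.n), d)
    p["embed/lookup"] = _kaiming(rng, (schema.S, d), d)
    p["embed/B_cat"] = _kaiming(rng, (d, schema.m), d)
    if config.pooling == "cls":
        p["embed/cls"] = _kaiming(rng, (d,), d)

    h = config.intra_hidden
    p["intra/w1"] = _kaiming(rng, (d, h), d)
    p["intra/b1"] = np.zeros(h)
    p["intra/w2"] = _kaiming(rng, (h, d), h)
    p["intra/b2"] = np.zeros(d)

    for j in range(config.n_blocks):
        pre = f"enc/{j}/"
        p[pre + "ln1_g"] = np.ones(d)
        p[pre + "ln1_b"] = np.zeros(d)
        for w in ("wq", "wk", "wv", "wo"):
            p[pre + w] = _kaiming(rng, (d, d), d)
        for b in ("bq", "bk", "bv", "bo"):
            p[pre + b] = np.zeros(d)
        p[pre + "ln2_g"] = np.ones(d)
        p[pre + "ln2_b"] = np.zeros(d)
        mh = config.mlp_hidden
        p[pre + "mlp_w1"] = _kaiming(rng, (d, mh), d)
        p[pre + "mlp_b1"] = np.zeros(mh)
        p[pre + "mlp_w2"] = _kaiming(rng, (mh, d), mh)
        p[pre + "mlp_b2"] = np.zeros(d)

    p["head/ln_g"] = np.ones(d)
    p["head/ln_b"] = np.zeros(d)
    p["head/w"] = _kaiming(rng, (d, 1), d)
    p["head/b"] = np.zeros(1)

    if with_pretrain_heads:
        p["pre/mask_w"] = _kaiming(rng, (d, 1), d)
        p["pre/mask_b"] = np.zeros(1)
        p["pre/num_w"] = _kaiming(rng, (schema.n, d + 1), d + 1)
        p["pre/num_b"] = np.zeros(schema.n)
        p["pre/cat_w"] = _kaiming(rng, (d + 1, schema.S), d + 1)
        p["pre/cat_b"] = np.zeros(schema.S)

    tensors = {k: Tensor(v, requires_grad=True) for k, v in p.items()}
    return ModelParams(schema=schema, config=config, params=tensors)


# ---------------------------------------------------------------------------
# forward pass
# ---------------------------------------------------------------------------


def forward_states(
    model: ModelParams,
    X_num: np.ndarray,
    X_cat: np.ndarray,
    rng: np.random.Generator | None = None,
    training: bool = False,
) -> list[Tensor]:
    """Embedding -> (CLS prepend) -> intra MLP -> encoder stack.

    Returns the per-layer token tensors ``[T(0), ..., T(N)]`` with layout
    (B, t, d); T(0) is the intra-module output that enters the stack.
    """
    if training and rng is None:
        raise ValueError("training mode needs an RNG for dropout")
    rng = rng or np.random.default_rng(0)
    cfg = model.config
    tokens = embed_batch(X_num, X_cat, model.params, model.schema)
    if cfg.pooling == "cls":
        B = tokens.shape[0]
        cls = model.params["embed/cls"].reshape(1, 1, cfg.d)
        cls_batch = cls + Tensor(np.zeros((B, 1, cfg.d)))
        from .autodiff import concat

        tokens = concat([cls_batch, tokens], axis=1)
    tokens = intra_forward_t(tokens, model.params, cfg, rng, training)
    return interaction_forward_t(tokens, model.params, cfg, rng, training)


def forward_representation(
    model: ModelParams,
    X_num: np.ndarray,
    X_cat: np.ndarray,
    rng: np.random.Generator | None = None,
    training: bool = False,
) -> Tensor:
    states = forward_states(model, X_num, X_cat, rng, training)
    return pool_representation_t(states, model.config)


def forward_logits(
    model: ModelParams,
    X_num: np.ndarray,
    X_cat: np.ndarray,
    rng: np.random.Generator | None = None,
    training: bool = False,
) -> Tensor:
    rep = forward_representation(model, X_num, X_cat, rng, training)
    return predict_logit_t(rep, model.params)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


@dataclass
class Checkpoint:
    """Serialized parameter state plus the metadata needed to reuse it.

    The schema fingerprint makes a mismatched fine-tuning load fail loudly:
    transfer to a different table is legal (interaction parameters are
    feature-count agnostic), but resuming on the *same* table requires the
    fingerprints to agree.
    """

    arrays: dict[str, np.ndarray]
    schema_fingerprint: str
    config: InteractionConfig
    meta: dict = field(default_factory=dict)
    loss_trace: list[float] = field(default_factory=list)

    @classmethod
    def from_model(cls, model: ModelParams, meta: dict | None = None,
                   loss_trace: list[float] | None = None) -> "Checkpoint":
        return cls(
            arrays=model.snapshot(),
            schema_fingerprint=model.schema.fingerprint(),
            config=model.config,
            meta=dict(meta or {}),
            loss_trace=list(loss_trace or []),
        )

    def save(self, path) -> None:
        meta = {
            "schema_fingerprint": self.schema_fingerprint,
            "config": self.config.to_dict(),
            "meta": self.meta,
            "loss_trace": self.loss_trace,
        }
        np.savez(path, __meta__=np.array(json.dumps(meta)), **self.arrays)

    @classmethod
    def load(cls, path) -> "Checkpoint":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            arrays = {k: np.array(data[k]) for k in data.files if k != "__meta__"}
        return cls(
            arrays=arrays,
            schema_fingerprint=meta["schema_fingerprint"],
            config=InteractionConfig.from_dict(meta["config"]),
            meta=meta.get("meta", {}),
            loss_trace=meta.get("loss_trace", []),
        )
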