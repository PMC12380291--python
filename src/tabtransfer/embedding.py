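"""Feature embedding layer: one d-dimensional token per tabular feature.

Numerical feature i is embedded by a Hadamard product with a learned
per-feature direction plus a bias: ``T[:, i] = W[:, i] * x_i + B_num[:, i]``.
Categorical feature i selects a row of a flat S x d lookup table (S = total
category count across features; each feature owns a consecutive block of
rows located by a cumulative offset) and adds a per-feature bias column.
The two blocks are concatenated in schema order into a d x (n+m) token
matrix.  There are no positional encodings: feature identity is carried
entirely by the per-feature parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .autodiff import Tensor, concat, gather
from .schema_data import FeatureSchema, SchemaError

__all__ = ["EmbeddingParams", "embed_numerical", "embed_categorical", "embed",
           "embed_batch"]


@dataclass
class EmbeddingParams:
    """NumPy view of the embedding-layer parameters for the per-row ops."""

    d: int
    W: np.ndarray  # (d, n)
    B_num: np.ndarray  # (d, n)
    lookup: np.ndarray  # (S, d)
    B_cat: np.ndarray  # (d, m)
    offsets: np.ndarray  # (m,) row offset of each categorical feature

    @classmethod
    def from_tensors(
        cls, params: Mapping[str, Tensor], schema: FeatureSchema
    ) -> "EmbeddingParams":
        return cls(
            d=params["embed/W"].shape[0] if schema.n else params["embed/lookup"].shape[1],
            W=params["embed/W"].data,
            B_num=params["embed/B_num"].data,
            lookup=params["embed/lookup"].data,
            B_cat=params["embed/B_cat"].data,
            offsets=schema.offsets,
        )


def embed_numerical(x_num: np.ndarray, params: EmbeddingParams) -> np.ndarray:
    """Embed one row's numerical block into a d x n token matrix."""
    x_num = np.asarray(x_num, dtype=np.float64)
    if x_num.shape != (params.W.shape[1],):
        raise SchemaError(
            f"expected {params.W.shape[1]} numerical values, got {x_num.shape}"
        )
    return params.W * x_num[None, :] + params.B_num


def embed_categorical(x_cat: np.ndarray, params: EmbeddingParams) -> np.ndarray:
    """Embed one row's categorical block into a d x m token matrix."""
    x_cat = np.asarray(x_cat, dtype=np.int64)
    m = params.B_cat.shape[1]
    if x_cat.shape != (m,):
        raise SchemaError(f"expected {m} categorical indices, got {x_cat.shape}")
    flat = params.offsets + x_cat
    if (x_cat < 0).any() or (flat >= params.lookup.shape[0]).any():
        raise IndexError("categorical index out of range for the lookup table")
    return params.lookup[flat].T + params.B_cat


def embed(x_num: np.ndarray, x_cat: np.ndarray, params: EmbeddingParams) -> np.ndarray:
    """Embed one full row into the d x (n+m) token matrix, schema order."""
    blocks = []
    if params.W.shape[1]:
        blocks.append(embed_numerical(x_num, params))
    if params.B_cat.shape[1]:
        blocks.append(embed_categorical(x_cat, params))
    return np.concatenate(blocks, axis=1)


def embed_batch(
    X_num: np.ndarray,
    X_cat: np.ndarray,
    params: Mapping[str, Tensor],
    schema: FeatureSchema,
) -> Tensor:
    """Differentiable batched embedding: (B, n+m, d) token tensor.

    Pointwise equivalent to stacking :func:`embed` row by row (the batch
    axis comes first and tokens are transposed to rows, which is the layout
    the encoder consumes).
    """
    X_num = np.asarray(X_num, dtype=np.float64)
    X_cat = np.asarray(X_cat, dtype=np.int64)
    parts: list[Tensor] = []
    if schema.n:
        if X_num.shape[1] != schema.n:
            raise SchemaError("numerical block width does not match schema")
        W_t = params["embed/W"].swapaxes(0, 1)  # (n, d)
        B_t = params["embed/B_num"].swapaxes(0, 1)
        x = Tensor(X_num[:, :, None])  # (B, n, 1)
        parts.append(x * W_t + B_t)
    if schema.m:
        if X_cat.shape[1] != schema.m:
            raise SchemaError("categorical block width does not match schema")
        cards = np.asarray(schema.cardinalities)
        if (X_cat < 0).any() or (X_cat >= cards[None, :]).any():
            raise IndexError("categorical index out of range for the lookup table")
        flat = schema.offsets[None, :] + X_cat  # (B, m)
        rows = gather(params["embed/lookup"], flat)  # (B, m, d)
        parts.append(rows + params["embed/B_cat"].swapaxes(0, 1))
    return parts[0] if len(parts) == 1 else concat(parts, axis=1)
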