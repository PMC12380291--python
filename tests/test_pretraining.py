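"""Masked-feature corruption, dual heads, combined loss and the loop."""

import numpy as np
import pytest

from tabtransfer.autodiff import Tensor
from tabtransfer.head_metrics import auc
from tabtransfer.interaction import token_output_t
from tabtransfer.model import forward_states, init_model_params
from tabtransfer.pretraining import (
    MaskedBatch,
    PretrainConfig,
    corrupt,
    make_masked_batch,
    pretrain_heads_forward,
    pretrain_heads_forward_t,
    pretrain_loss_t,
    run_pretraining,
    sample_mask,
    shuffle_batch,
)
from tabtransfer.schema_data import SyntheticSpec, generate_synthetic


# ---------------------------------------------------------------------------
# corruption machinery
# ---------------------------------------------------------------------------


def test_sample_mask_extremes():
    assert sample_mask(5, 7, 0.0, 1).sum() == 0
    assert sample_mask(5, 7, 1.0, 1).sum() == 35


def test_sample_mask_density_within_binomial_band():
    mask = sample_mask(54, 1000, 0.5, seed=3)
    density = mask.mean()
    sigma = np.sqrt(0.5 * 0.5 / mask.size)
    assert abs(density - 0.5) < 3 * sigma


def test_shuffle_preserves_column_multisets(rng):
    X = rng.normal(size=(30, 4))
    Xb = shuffle_batch(X, seed=2)
    for j in range(4):
        np.testing.assert_allclose(np.sort(Xb[:, j]), np.sort(X[:, j]))
    # identical rows shuffle to themselves
    Xc = np.tile(rng.normal(size=(1, 4)), (6, 1))
    np.testing.assert_array_equal(shuffle_batch(Xc, seed=0), Xc)


def test_shuffle_deterministic_and_row_mode(rng):
    X = rng.normal(size=(20, 3))
    np.testing.assert_array_equal(shuffle_batch(X, seed=5), shuffle_batch(X, seed=5))
    Xr = shuffle_batch(X, seed=5, mode="rows")
    # whole-row mode preserves rows as units
    orig_rows = {tuple(r) for r in X}
    assert {tuple(r) for r in Xr} == orig_rows
    with pytest.raises(ValueError):
        shuffle_batch(X[:1], seed=0)


def test_corrupt_identities_and_membership(rng):
    X = rng.normal(size=(10, 3))
    Xb = shuffle_batch(X, seed=1)
    zeros = np.zeros((3, 10), dtype=int)
    ones = np.ones((3, 10), dtype=int)
    np.testing.assert_array_equal(corrupt(X, Xb, zeros), X)
    np.testing.assert_array_equal(corrupt(X, Xb, ones), Xb)
    m = sample_mask(3, 10, 0.4, seed=9)
    Xt = corrupt(X, Xb, m)
    for j in range(3):
        assert set(np.round(Xt[:, j], 12)) <= set(np.round(X[:, j], 12))
    with pytest.raises(ValueError):
        corrupt(X, Xb, np.zeros((4, 10), dtype=int))


def test_masked_batch_invariant(small_dataset, rng):
    n = small_dataset.schema.n
    batch = make_masked_batch(
        small_dataset.X_num, small_dataset.X_cat, 0.5, np.random.default_rng(0)
    )
    sel_num = batch.mask[:n].T.astype(bool)
    np.testing.assert_array_equal(
        batch.Xt_num[~sel_num], batch.X_num[~sel_num]
    )
    np.testing.assert_array_equal(batch.Xt_num[sel_num], batch.Xb_num[sel_num])
    sel_cat = batch.mask[n:].T.astype(bool)
    np.testing.assert_array_equal(batch.Xt_cat[~sel_cat], batch.X_cat[~sel_cat])
    np.testing.assert_array_equal(batch.Xt_cat[sel_cat], batch.Xb_cat[sel_cat])


# ---------------------------------------------------------------------------
# heads
# ---------------------------------------------------------------------------


def test_zero_weight_heads(tiny_model, small_schema, rng):
    for name in ("pre/mask_w", "pre/mask_b", "pre/num_w", "pre/cat_w",
                 "pre/cat_b"):
        tiny_model.params[name].data = np.zeros_like(tiny_model.params[name].data)
    tiny_model.params["pre/num_b"].data = rng.normal(size=small_schema.n)
    Z = rng.normal(size=(4, 6, 8))
    mask_logits, num_preds, cat_logits = pretrain_heads_forward_t(
        Tensor(Z), tiny_model.params, small_schema
    )
    np.testing.assert_array_equal(mask_logits.data, 0.0)
    for b in range(4):
        np.testing.assert_array_equal(
            num_preds.data[b], tiny_model.params["pre/num_b"].data
        )
    for logits in cat_logits:
        np.testing.assert_array_equal(logits.data, 0.0)


def test_heads_rowwise_matches_batched(tiny_model, small_schema, rng):
    Z = rng.normal(size=(3, 6, 8))
    m_b, n_b, c_b = pretrain_heads_forward_t(Tensor(Z), tiny_model.params,
                                             small_schema)
    for b in range(3):
        m_r, preds = pretrain_heads_forward(Z[b].T, tiny_model.params, small_schema)
        np.testing.assert_allclose(m_r, m_b.data[b], atol=1e-12)
        np.testing.assert_allclose(preds["numerical"], n_b.data[b], atol=1e-12)
        for i, logits in enumerate(preds["categorical"]):
            np.testing.assert_allclose(logits, c_b[i].data[b], atol=1e-12)


def test_heads_match_scalar_affine_oracle(tiny_model, small_schema, rng):
    """Token i's mask logit and feature prediction are plain affine maps of
    (token, mask logit)."""
    Z = rng.normal(size=(1, 6, 8))
    mask_logits, num_preds, cat_logits = pretrain_heads_forward_t(
        Tensor(Z), tiny_model.params, small_schema
    )
    p = tiny_model.params
    for i in range(6):
        expected_m = float(Z[0, i] @ p["pre/mask_w"].data[:, 0] +
                           p["pre/mask_b"].data[0])
        assert mask_logits.data[0, i] == pytest.approx(expected_m, abs=1e-10)
    aug = np.concatenate([Z[0], mask_logits.data[0][:, None]], axis=1)
    for i in range(small_schema.n):
        expected = float(aug[i] @ p["pre/num_w"].data[i] + p["pre/num_b"].data[i])
        assert num_preds.data[0, i] == pytest.approx(expected, abs=1e-10)
    offsets = small_schema.offsets
    for i, card in enumerate(small_schema.cardinalities):
        w = p["pre/cat_w"].data[:, offsets[i]:offsets[i] + card]
        b = p["pre/cat_b"].data[offsets[i]:offsets[i] + card]
        expected = aug[small_schema.n + i] @ w + b
        np.testing.assert_allclose(cat_logits[i].data[0], expected, atol=1e-10)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------


def _fake_batch(small_schema, rng, B=5):
    X_num = rng.normal(size=(B, small_schema.n))
    X_cat = np.column_stack(
        [rng.integers(0, c, size=B) for c in small_schema.cardinalities]
    )
    return make_masked_batch(X_num, X_cat, 0.5, np.random.default_rng(3))


def test_perfect_predictions_give_near_zero_loss(small_schema, rng):
    batch = _fake_batch(small_schema, rng)
    B = batch.X_num.shape[0]
    t = small_schema.n + small_schema.m
    mask_logits = Tensor((batch.mask.T * 2.0 - 1.0) * 40.0)
    num_preds = Tensor(batch.X_num.copy())
    cat_logits = []
    for i, card in enumerate(small_schema.cardinalities):
        logits = np.full((B, card), -60.0)
        logits[np.arange(B), batch.X_cat[:, i]] = 60.0
        cat_logits.append(Tensor(logits))
    loss, l_m, l_f = pretrain_loss_t(batch, mask_logits, num_preds, cat_logits, 2.0)
    assert float(loss.data) < 1e-6


def test_alpha_zero_reduces_to_mask_loss(small_schema, rng):
    batch = _fake_batch(small_schema, rng)
    B, t = batch.X_num.shape[0], small_schema.n + small_schema.m
    mask_logits = Tensor(rng.normal(size=(B, t)))
    num_preds = Tensor(rng.normal(size=(B, small_schema.n)))
    cat_logits = [Tensor(rng.normal(size=(B, c)))
                  for c in small_schema.cardinalities]
    loss, l_m, l_f = pretrain_loss_t(batch, mask_logits, num_preds, cat_logits, 0.0)
    assert float(loss.data) == pytest.approx(l_m, abs=1e-12)


def test_loss_affine_in_alpha(small_schema, rng):
    batch = _fake_batch(small_schema, rng)
    B, t = batch.X_num.shape[0], small_schema.n + small_schema.m
    args = (
        Tensor(rng.normal(size=(B, t))),
        Tensor(rng.normal(size=(B, small_schema.n))),
        [Tensor(rng.normal(size=(B, c))) for c in small_schema.cardinalities],
    )
    l0 = float(pretrain_loss_t(batch, *args, 0.0)[0].data)
    l1 = float(pretrain_loss_t(batch, *args, 1.0)[0].data)
    l2 = float(pretrain_loss_t(batch, *args, 2.0)[0].data)
    assert l2 - l1 == pytest.approx(l1 - l0, abs=1e-10)


def test_loss_matches_scalar_oracle(small_schema, rng):
    """BCE + alpha * (MSE + mean CE) recomputed cell by cell."""
    batch = _fake_batch(small_schema, rng, B=4)
    B, n, m = 4, small_schema.n, small_schema.m
    t = n + m
    mask_logits = rng.normal(size=(B, t))
    num_preds = rng.normal(size=(B, n))
    cat_logits = [rng.normal(size=(B, c)) for c in small_schema.cardinalities]
    loss, _, _ = pretrain_loss_t(
        batch, Tensor(mask_logits), Tensor(num_preds),
        [Tensor(c) for c in cat_logits], alpha=2.0,
    )
    bce = 0.0
    for b in range(B):
        for i in range(t):
            z = mask_logits[b, i]
            target = batch.mask[i, b]
            s = 1.0 / (1.0 + np.exp(-z))
            s = min(max(s, 1e-15), 1 - 1e-15)
            bce += -(target * np.log(s) + (1 - target) * np.log(1 - s))
    bce /= B * t
    mse = float(np.mean((num_preds - batch.X_num) ** 2))
    ces = []
    for i, logits in enumerate(cat_logits):
        per_row = []
        for b in range(B):
            row = logits[b]
            p = np.exp(row - row.max())
            p /= p.sum()
            per_row.append(-np.log(p[batch.X_cat[b, i]]))
        ces.append(np.mean(per_row))
    expected = bce + 2.0 * (mse + float(np.mean(ces)))
    assert float(loss.data) == pytest.approx(expected, abs=1e-8)


def test_rowwise_loss_wrapper_agrees_with_batched(small_schema, rng):
    X_num = rng.normal(size=(1, small_schema.n))
    X_cat = np.column_stack(
        [rng.integers(0, c, size=1) for c in small_schema.cardinalities]
    )
    t = small_schema.n + small_schema.m
    mask = rng.integers(0, 2, size=(t, 1)).astype(np.int8)
    batch = MaskedBatch(X_num=X_num, X_cat=X_cat, Xb_num=X_num, Xb_cat=X_cat,
                        mask=mask, Xt_num=X_num, Xt_cat=X_cat)
    ml = rng.normal(size=(1, t))
    npred = rng.normal(size=(1, small_schema.n))
    cl = [rng.normal(size=(1, c)) for c in small_schema.cardinalities]
    from tabtransfer.pretraining import pretrain_loss

    batched, _, _ = pretrain_loss_t(batch, Tensor(ml), Tensor(npred),
                                    [Tensor(c) for c in cl], alpha=2.0)
    rowwise = pretrain_loss(
        batch, ml[0],
        {"numerical": npred[0], "categorical": [c[0] for c in cl]}, alpha=2.0,
    )
    assert rowwise == pytest.approx(float(batched.data), abs=1e-10)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def pretrained_tiny():
    spec = SyntheticSpec(n_rows=400, n_numerical=3, n_categorical=3,
                         categories_per_feature=3, positive_fraction=0.5,
                         signal_strength=2.0, seed=21)
    corpus = generate_synthetic(spec)
    from tabtransfer.interaction import InteractionConfig

    cfg = InteractionConfig(d=16, n_heads=2, n_blocks=1, dropout_rate=0.0)
    model = init_model_params(corpus.schema, cfg, seed=2, with_pretrain_heads=True)
    pre_cfg = PretrainConfig(epochs=5, batch_size=128, learning_rate=1e-3, seed=4)
    model, trace = run_pretraining(corpus, model, pre_cfg)
    return corpus, model, trace, pre_cfg


def test_pretraining_loss_decreases(pretrained_tiny):
    _, _, trace, _ = pretrained_tiny
    assert len(trace) == 5
    assert trace[-1] < trace[0]


def test_pretraining_leaves_supervised_head_untouched(small_dataset):
    from tabtransfer.interaction import InteractionConfig

    cfg = InteractionConfig(d=8, n_heads=2, n_blocks=1, dropout_rate=0.0)
    model = init_model_params(small_dataset.schema, cfg, seed=0,
                              with_pretrain_heads=True)
    head_before = {k: model.params[k].data.copy()
                   for k in model.names("head/")}
    emb_before = model.params["embed/lookup"].data.copy()
    run_pretraining(small_dataset, model,
                    PretrainConfig(epochs=1, batch_size=20, learning_rate=1e-3))
    for k, v in head_before.items():
        np.testing.assert_array_equal(model.params[k].data, v)
    assert not np.array_equal(model.params["embed/lookup"].data, emb_before)


def test_pretraining_zero_lr_is_a_no_op(small_dataset):
    from tabtransfer.interaction import InteractionConfig

    cfg = InteractionConfig(d=8, n_heads=2, n_blocks=1, dropout_rate=0.0)
    model = init_model_params(small_dataset.schema, cfg, seed=0,
                              with_pretrain_heads=True)
    before = model.snapshot()
    run_pretraining(small_dataset, model,
                    PretrainConfig(epochs=1, batch_size=20, learning_rate=0.0))
    for k, v in before.items():
        np.testing.assert_array_equal(model.params[k].data, v)


def test_mask_detection_beats_chance_after_pretraining(pretrained_tiny):
    """On held-out rows the mask head separates corrupted from clean cells."""
    corpus, model, _, pre_cfg = pretrained_tiny
    rng = np.random.default_rng(99)
    spec = SyntheticSpec(n_rows=200, n_numerical=3, n_categorical=3,
                         categories_per_feature=3, positive_fraction=0.5,
                         signal_strength=2.0, seed=77)
    held = generate_synthetic(spec)
    batch = make_masked_batch(held.X_num, held.X_cat, 0.5, rng)
    states = forward_states(model, batch.Xt_num, batch.Xt_cat)
    mask_logits, _, _ = pretrain_heads_forward_t(
        token_output_t(states), model.params, corpus.schema
    )
    score = auc(mask_logits.data.reshape(-1), batch.mask.T.reshape(-1))
    assert score > 0.5
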