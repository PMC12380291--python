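# Methods

This note records the model, the training paradigm, the synthetic data
model, the numerical choices, and the design decisions taken where the
design was genuinely open.  It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Model

A table row is tokenized feature-by-feature: each of the *n* numerical
features gets a learned direction and bias (`w_i x_i + b_i ∈ ℝ^d`), and
each of the *m* categorical features selects one row of a flat `S × d`
lookup table (*S* = total category count over all features; each feature
owns a consecutive row block located by cumulative offsets, a mapping that
is deterministic and serialization-stable).  There are no positional
encodings — feature identity lives entirely in the per-feature parameters,
which makes every interaction-layer computation permutation-equivariant in
the tokens (a tested invariant).

The interaction layer is (a) one two-layer MLP, `Linear(d→h) → ReLU →
Dropout → Linear(h→d)`, applied to every token independently with weights
**shared across features**, then (b) a stack of *N* PreNorm transformer
encoder blocks.  Sharing the intra-MLP weights is essential for transfer:
it keeps every interaction-layer parameter agnostic to the feature count,
so an encoder pretrained on a 54-column corpus drops unchanged into a
14-column clinical table.  A per-feature-weights variant would not be
transferable and is deliberately not implemented.

Pooling averages tokens of the elementwise mean of the first and last
encoder outputs (`first_last_avg`, the default); `last_avg` and a learned
CLS token are configuration variants.  The output head is
`Linear(ReLU(LayerNorm(r)))` to one logit; probability ≥ 0.5 (boundary
inclusive) predicts the positive class.

### Open choices resolved

- **LayerNorm axis**: statistics are taken per token over the *d*
  embedding coordinates (the transformer convention); the alternative
  (per-coordinate over tokens) would break feature-count agnosticism.
- **Encoder MLP width**: 2·d; attention uses `d_k = d_v = d / n_heads`
  with a final `d → d` output projection after head concatenation.
- **Dropout** (default rate 0.10): inside the intra MLP (after ReLU,
  before the second linear layer), on the attention weights after the
  softmax, and inside the encoder MLPs.  Evaluation mode is exactly
  deterministic.
- **Metric conventions**: precision/recall/F1 return 0 on an empty
  denominator (a model that never predicts positive scores 0, not NaN);
  AUC is the Mann–Whitney concordance computed from midranks, ties
  counting one half, and is *flagged undefined* (not silently 0.5) on a
  single-class fold.

## Training paradigm

**Pretraining** (defaults: masking probability p_m = 0.5, feature-loss
weight α = 2, batch 256, 30 epochs, Adam 2e-4): each mini-batch cell is
replaced, with probability p_m, by a value drawn from the same column
(per-feature independent permutation of the sample order — this preserves
every feature's marginal exactly; a whole-row single-permutation mode is
available since either reading of "shuffling the sample order" is
defensible).  One joint Bernoulli mask covers the n+m feature grid.  The
token-level interaction output (no pooling) feeds two linear heads: a
shared mask-detection head (d → 1 per token), and a feature-reconstruction
head consuming each token concatenated with its raw (unthresholded,
differentiable) mask logit — per-numerical-feature regression outputs,
per-categorical-feature class logits.  Reconstruction targets the
*original* uncorrupted value.  The loss `L_mask + α(MSE + mean CE)`
updates embedding, interaction layer and both heads; the supervised output
head receives no gradient.  Two config keys (`beta`, `gamma`) are carried
for config-file compatibility but enter no computation, as no equation
defines them.

**Fine-tuning**: the interaction layer (intra MLP + encoder stack;
`freeze_scope="interaction_layer"`, the default) is copied from the
checkpoint and frozen — an `encoder_only` scope exists because freezing
only the encoder stack is an equally defensible reading, and both are
tested.  A fresh embedding sized to the target schema and a fresh head are
trained by Adam (2e-4, batch 256) with early stopping on validation AUC
(patience 10, max 200 epochs; ties resolve to the earliest epoch, and the
best-epoch parameters are restored).  A single-class validation split
falls back to validation loss and flags the result.  Class imbalance is
deliberately *not* rebalanced — the paradigm itself is the remedy under
test — though a `pos_weight` option exists, default off.

**Warm-started embedding.** When target and corpus share a schema
(verified by fingerprint), the embedding may be copied from the checkpoint
instead of re-initialized (`warm_start_embedding=True`); it stays
trainable.  This matters at small fine-tuning budgets: a frozen encoder
expects tokens in the basis it was trained on, and a freshly initialized
embedding cannot re-align to that basis within the ~10² optimizer steps a
250-row table affords.  In a linear-probe comparison (5-fold logistic
regression on pooled representations of 250-row targets, five draws) the
pretrained encoder over a fresh random embedding was indistinguishable
from a random encoder, while the same encoder over its own warm-started
embedding probed ~0.10 AUC higher than random.  The same-schema transfer
experiments therefore warm-start; cross-schema transfer necessarily
re-initializes, which is also the package default.

**Mixup** (optional, numerical features only): batch rows are paired by a
seeded permutation; numerical features and labels are convex-combined
with λ ~ Beta(0.2, 0.2) while categorical features keep the anchor row's
categories (index mixtures are meaningless).  Labels are mixed — standard
Mixup — producing soft targets, which the fused BCE accepts; whether the
original recipe mixed labels on this task is not documented, so this
choice is flagged here.

## Evaluation protocol

`make_splits` plans k-fold CV repeated R times; per fold the non-test rows
are split so validation holds 20% of them, reproducing overall 72/18/10
train/validation/test fractions at k = 10.  Both splits stratify by label
when labels are present (with the 1:2–1:4 imbalance of the clinical
tables, unstratified 10-fold splits routinely produce single-class folds);
degenerate class counts fall back to unstratified splitting and leave a
warning on the plan rather than failing.  The harness standardizes
numerical columns with *training-fold* statistics only (z-score; the
choice is exposed as none|zscore since the original preprocessing is
undocumented), trains with early stopping on the fold's validation rows,
and never lets test rows touch any training decision — a leakage test
corrupts test labels and asserts the trained model is unchanged.  Reports
carry per-fold metrics, their mean ± sd, and a pooled-prediction AUC side
by side (whether published figures average per-fold metrics or pool
predictions is ambiguous; both are reported).

## Synthetic data model

The generator emulates the *shapes* of the study tables — a large balanced
mixed-type pretraining corpus (Covertype-like; descriptions of that corpus
give either 10 numerical + 44 categorical columns or the reverse, so both
counts are plain parameters)
and small imbalanced targets (~250 rows, 6 numerical + 8 categorical
columns, positive fraction 1/3, matching the larger of the two clinical
registries) — with a single planted-signal knob:

- label y ~ Bernoulli(positive_fraction);
- numerical feature j | y: Gaussian with class-mean gap
  `signal_strength · noise_sd / √n`, so the numerical block's total
  Mahalanobis separation is exactly `signal_strength`;
- categorical feature j | y: multinomial whose log-probabilities are
  tilted by `±(signal_strength/√m)/2` along a fixed ±1 contrast around a
  random base distribution.

`signal_strength = 0` makes every feature exactly independent of the
label (null-calibration tests); `signal_strength = 3` with both blocks is
linearly separable to >0.95 training accuracy at 2000 rows (a tested
ceiling).  What the generator does **not** model: feature-feature
dependence beyond the shared class, missing-not-at-random patterns,
ordinal severity scores, measurement noise heterogeneity, or covariate
shift between corpus and target.  Passing tests therefore demonstrate the
machinery and the direction of the transfer effect under clean conditions,
not clinical performance.

## Numerical core

No GPU tensor framework is used: a minimal reverse-mode automatic
differentiation engine over float64 NumPy arrays (`tabtransfer.autodiff`)
provides the ~20 primitives the model needs, plus Adam.  Every primitive
and the full model loss are gradient-checked against central finite
differences (tolerance 1e-4 relative).  Numerically sensitive pieces use
stable forms: fused `softplus(z) − y·z` for BCE (finite to |z| = 1e4, a
tested contract), max-shifted `log_softmax`, LayerNorm with ε = 1e-5.
Parameter initialization is seeded Kaiming-uniform (bound √(3/fan_in));
LayerNorm gains start at 1, biases at 0.  Seeds are split by purpose
(init, mask, shuffle, batch order, dropout) via `SeedSequence`, so every
run is bit-reproducible from one integer.

## Desk-scale experiment sizes

The packaged experiments (`tabtransfer.experiments`) run the full pipeline
at reduced size — d = 32, 4 heads, 2 encoder blocks — chosen so the whole
suite completes in minutes on one CPU while preserving every structural
property of the full configuration (d = 192, 8 heads, 3 blocks):

- *learnability*: 2000 rows, signal 3, end-to-end; best validation AUC.
- *paradigm*: one 5000-row balanced same-schema corpus, pretrained 30
  epochs; three fresh 250-row 1:2-imbalanced targets, each evaluated by
  full 10-fold CV with 72/18/10 splits, giving 30 paired training runs per
  arm (frozen-transfer fine-tune with warm-started embedding vs
  end-to-end) on shared split plans and seeds.  The claim checked is
  directional — mean test AUC of pretrain+fine-tune ≥ end-to-end — not any
  published figure, which came from real registries at full model size.
- *null calibration*: 120 zero-signal rows, 10-fold × 3 repeats, aggregate
  AUC inside [0.35, 0.65].

One optimization setting is re-sized for these experiments, identically in
both arms.  A 250-row target leaves a 180-row training split, so at batch
size 256 an "epoch" is a single full-batch Adam step; the package default
learning rate of 2e-4 — appropriate for corpora that take hundreds of
steps per epoch — then cannot fit even the linear output head within a
few-hundred-epoch budget, and the shortfall penalizes the frozen-encoder
arm hardest (it has the fewest trainable directions, while linear probes
show its representations support ~0.9 AUC).  The experiments therefore
train both arms with learning rate 2e-3, at most 300 epochs, and early
stopping patience 30; package-wide defaults keep the published values.

## Known limitations

- The paradigm comparison is stochastic; even averaged over 30 paired
  25-row test folds its per-seed mean difference carries a standard error
  of roughly one AUC point, so individual seeds can understate (or
  overstate) the average gain, and near-zero differences are expected at
  some seeds.
- Cross-schema transfer currently re-initializes the embedding; no
  column-matching or embedding-alignment scheme is attempted, and at
  desk-scale budgets cross-schema gains are accordingly not claimed.
- Only binary labels, row-wise deletion for missing data (no imputation),
  and dense attention (t = n + m is small for tables) are supported.
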