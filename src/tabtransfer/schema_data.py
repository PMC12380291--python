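"""Dataset schema, table I/O, label derivation, preprocessing and splits.

Tabular clinical datasets mix numerical and categorical columns.  A
:class:`FeatureSchema` declares, once, which columns are which (and each
categorical column's vocabulary); every other module trusts it as the single
source of truth for the feature counts ``n`` (numerical), ``m``
(categorical) and the total category count ``S``.

The module also provides the synthetic fixture generator used throughout
the test suite: class-conditional Gaussian numerical features and
class-conditional multinomial categorical features whose separation scales
with a single ``signal_strength`` knob, so that ``signal_strength = 0``
yields label-independent features and large values yield a linearly
separable table.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split

__all__ = [
    "SchemaError",
    "ParseError",
    "EmptyDatasetError",
    "FeatureSchema",
    "TabularDataset",
    "SplitPlan",
    "SyntheticSpec",
    "load_table",
    "write_table",
    "drop_missing",
    "derive_stroke_label",
    "standardize_numerical",
    "make_splits",
    "generate_synthetic",
    "covertype_like_spec",
    "stroke_target_like_spec",
]

MISSING_CAT = -1  # sentinel index for a missing categorical cell


class SchemaError(ValueError):
    """A table does not match its declared schema."""


class ParseError(ValueError):
    """A cell could not be parsed as its declared kind."""


class EmptyDatasetError(ValueError):
    """An operation produced a dataset with zero rows."""


@dataclass
class FeatureSchema:
    """Names, order and kinds of the columns of one tabular dataset.

    Parameters
    ----------
    numerical_names, categorical_names
        Ordered column names of each kind.  Feature order is fixed by the
        schema: numerical block first, then categorical.
    vocab
        For each categorical column, the ordered list of category labels.
        Category *i* of a feature maps to index *i*; with
        ``unknown_policy="unknown"`` one extra reserved index per feature
        absorbs unseen categories at inference time.
    label_name
        Name of the binary label column, or ``None`` for unlabelled tables.
    unknown_policy
        ``"strict"`` rejects categories outside the vocabulary;
        ``"unknown"`` maps them to the reserved index.
    missing_values
        Cell strings (besides genuinely empty cells) read as missing,
        e.g. a site-specific sentinel like ``"-99"``.
    """

    numerical_names: tuple[str, ...]
    categorical_names: tuple[str, ...]
    vocab: dict[str, tuple[str, ...]]
    label_name: str | None = None
    unknown_policy: str = "strict"
    missing_values: tuple[str, ...] = ("", "NA", "NaN", "nan", "null")

    def __post_init__(self):
        self.numerical_names = tuple(self.numerical_names)
        self.categorical_names = tuple(self.categorical_names)
        self.vocab = {k: tuple(str(v) for v in vs) for k, vs in self.vocab.items()}
        if self.n + self.m < 1:
            raise SchemaError("schema needs at least one feature column")
        all_names = list(self.numerical_names) + list(self.categorical_names)
        if self.label_name is not None:
            all_names.append(self.label_name)
        if len(set(all_names)) != len(all_names):
            raise SchemaError("duplicate column name in schema")
        for name in self.categorical_names:
            if name not in self.vocab:
                raise SchemaError(f"categorical column {name!r} has no vocabulary")
            if len(self.vocab[name]) == 0:
                raise SchemaError(f"categorical column {name!r} has empty vocabulary")
        if self.unknown_policy not in ("strict", "unknown"):
            raise SchemaError(f"unknown_policy {self.unknown_policy!r} invalid")
        self.missing_values = tuple(str(v) for v in self.missing_values)

    def is_missing(self, value) -> bool:
        """Is a raw cell one of the schema's missing sentinels?"""
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return True
        return str(value).strip() in self.missing_values

    # -- derived sizes -------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.numerical_names)

    @property
    def m(self) -> int:
        return len(self.categorical_names)

    def cardinality(self, name: str) -> int:
        extra = 1 if self.unknown_policy == "unknown" else 0
        return len(self.vocab[name]) + extra

    @property
    def cardinalities(self) -> tuple[int, ...]:
        return tuple(self.cardinality(c) for c in self.categorical_names)

    @property
    def S(self) -> int:
        """Total category count across all categorical features."""
        return int(sum(self.cardinalities))

    @property
    def offsets(self) -> np.ndarray:
        """Row offset of each categorical feature into the flat lookup table."""
        return np.concatenate([[0], np.cumsum(self.cardinalities)[:-1]]).astype(int)

    def unknown_index(self, name: str) -> int:
        if self.unknown_policy != "unknown":
            raise SchemaError("schema has no reserved unknown index")
        return len(self.vocab[name])

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "numerical": list(self.numerical_names),
            "categorical": list(self.categorical_names),
            "vocab": {k: list(v) for k, v in self.vocab.items()},
            "label": self.label_name,
            "unknown_policy": self.unknown_policy,
            "missing_values": list(self.missing_values),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSchema":
        return cls(
            numerical_names=tuple(d.get("numerical", ())),
            categorical_names=tuple(d.get("categorical", ())),
            vocab={k: tuple(v) for k, v in d.get("vocab", {}).items()},
            label_name=d.get("label"),
            unknown_policy=d.get("unknown_policy", "strict"),
            missing_values=tuple(
                d.get("missing_values", ("", "NA", "NaN", "nan", "null"))
            ),
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "FeatureSchema":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def fingerprint(self) -> str:
        """Stable hash of column names + vocabularies; guards checkpoints."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class TabularDataset:
    """Row-major encoded table: real block, integer-coded categorical block.

    Missing cells are ``NaN`` in ``X_num``/``y`` and :data:`MISSING_CAT` in
    ``X_cat`` until :func:`drop_missing` removes their rows.
    """

    schema: FeatureSchema
    X_num: np.ndarray  # (k, n) float
    X_cat: np.ndarray  # (k, m) int
    y: np.ndarray | None = None  # (k,) float with {0,1} (NaN = missing)

    def __post_init__(self):
        self.X_num = np.asarray(self.X_num, dtype=np.float64).reshape(-1, self.schema.n)
        self.X_cat = np.asarray(self.X_cat, dtype=np.int64).reshape(-1, self.schema.m)
        if self.X_num.shape[0] != self.X_cat.shape[0]:
            raise SchemaError("numerical and categorical blocks disagree on row count")
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=np.float64).reshape(-1)
            if self.y.shape[0] != self.X_num.shape[0]:
                raise SchemaError("label vector length mismatch")
        bad = (self.X_cat != MISSING_CAT) & (
            (self.X_cat < 0) | (self.X_cat >= np.array(self.schema.cardinalities or [1]))
        )
        if self.schema.m and bad.any():
            raise SchemaError("categorical index out of range for its vocabulary")

    @property
    def k(self) -> int:
        return self.X_num.shape[0]

    def subset(self, indices) -> "TabularDataset":
        idx = np.asarray(indices, dtype=int)
        return TabularDataset(
            schema=self.schema,
            X_num=self.X_num[idx],
            X_cat=self.X_cat[idx],
            y=None if self.y is None else self.y[idx],
        )

    def copy(self) -> "TabularDataset":
        return TabularDataset(
            schema=self.schema,
            X_num=self.X_num.copy(),
            X_cat=self.X_cat.copy(),
            y=None if self.y is None else self.y.copy(),
        )

    def labels_int(self) -> np.ndarray:
        if self.y is None:
            raise SchemaError("dataset has no labels")
        if np.isnan(self.y).any():
            raise SchemaError("dataset has missing labels; drop_missing first")
        return self.y.astype(int)


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def load_table(path, schema: FeatureSchema) -> TabularDataset:
    """Read a CSV/TSV with a header into an encoded :class:`TabularDataset`.

    Numerical columns are parsed as reals, categorical values mapped to
    vocabulary indices (per the schema's ``unknown_policy``), and the label
    column, if declared, coerced to {0,1}.  Row order is preserved; missing
    cells survive as sentinels until :func:`drop_missing`.
    """
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=True)
    needed = list(schema.numerical_names) + list(schema.categorical_names)
    for col in needed:
        if col not in df.columns:
            raise SchemaError(f"column {col!r} required by schema is missing")
    k = len(df)

    X_num = np.full((k, schema.n), np.nan)
    for j, col in enumerate(schema.numerical_names):
        raw = df[col]
        missing = raw.apply(schema.is_missing).to_numpy()
        parsed = pd.to_numeric(raw, errors="coerce").to_numpy()
        bad = np.isnan(parsed) & ~missing
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ParseError(
                f"unparsable numerical cell at row {row}, column {col!r}: "
                f"{raw.iloc[row]!r}"
            )
        X_num[:, j] = np.where(missing, np.nan, parsed)

    X_cat = np.full((k, schema.m), MISSING_CAT, dtype=np.int64)
    for j, col in enumerate(schema.categorical_names):
        mapping = {v: i for i, v in enumerate(schema.vocab[col])}
        raw = df[col]
        for row, value in enumerate(raw):
            if schema.is_missing(value):
                continue
            value = str(value)
            if value in mapping:
                X_cat[row, j] = mapping[value]
            elif schema.unknown_policy == "unknown":
                X_cat[row, j] = schema.unknown_index(col)
            else:
                raise SchemaError(
                    f"category {value!r} at row {row} not in vocabulary of {col!r}"
                )

    y = None
    if schema.label_name is not None and schema.label_name in df.columns:
        raw = df[schema.label_name]
        missing = raw.apply(schema.is_missing).to_numpy()
        parsed = pd.to_numeric(raw, errors="coerce").to_numpy()
        valid = ~missing
        if np.isnan(parsed[valid]).any() or not np.isin(
            parsed[valid], (0.0, 1.0)
        ).all():
            raise ParseError(f"label column {schema.label_name!r} must be binary")
        y = np.where(missing, np.nan, parsed)

    return TabularDataset(schema=schema, X_num=X_num, X_cat=X_cat, y=y)


def write_table(dataset: TabularDataset, path) -> None:
    """Write a dataset back to CSV/TSV with original category labels."""
    schema = dataset.schema
    data: dict[str, object] = {}
    for j, col in enumerate(schema.numerical_names):
        data[col] = dataset.X_num[:, j]
    for j, col in enumerate(schema.categorical_names):
        labels = list(schema.vocab[col])
        if schema.unknown_policy == "unknown":
            labels.append("__unknown__")
        column = []
        for idx in dataset.X_cat[:, j]:
            column.append("" if idx == MISSING_CAT else labels[idx])
        data[col] = column
    if dataset.y is not None and schema.label_name is not None:
        data[schema.label_name] = [
            "" if np.isnan(v) else int(v) for v in dataset.y
        ]
    pd.DataFrame(data).to_csv(path, sep=_sep_for(path), index=False)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def drop_missing(dataset: TabularDataset) -> TabularDataset:
    """Discard every row with a missing feature or label cell.

    Mirrors the preprocessing rule used for the clinical tables: rows are
    dropped, never imputed.  Relative row order is preserved.
    """
    keep = np.ones(dataset.k, dtype=bool)
    if dataset.schema.n:
        keep &= ~np.isnan(dataset.X_num).any(axis=1)
    if dataset.schema.m:
        keep &= (dataset.X_cat != MISSING_CAT).all(axis=1)
    if dataset.y is not None:
        keep &= ~np.isnan(dataset.y)
    if not keep.any():
        raise EmptyDatasetError("all rows contain missing values")
    return dataset.subset(np.flatnonzero(keep))


def derive_stroke_label(pre_nihss: int, post_nihss: int) -> int:
    """Binary thrombolysis-benefit label from NIHSS scores.

    A patient counts as positive when the NIHSS severity score drops by four
    points or more after thrombolysis.  Both scores must lie in the NIHSS
    range [0, 42].
    """
    for name, score in (("pre_nihss", pre_nihss), ("post_nihss", post_nihss)):
        if int(score) != score:
            raise ValueError(f"{name} must be an integer, got {score!r}")
        if not 0 <= score <= 42:
            raise ValueError(f"{name} out of NIHSS range [0, 42]: {score}")
    return int(pre_nihss - post_nihss >= 4)


def standardize_numerical(
    train: TabularDataset, apply_to: TabularDataset
) -> TabularDataset:
    """Z-score the numerical block of ``apply_to`` using train-split stats.

    Constant columns (zero standard deviation on the training split) map to
    zero.  The categorical block and labels are untouched.
    """
    if train.k < 2:
        raise ValueError("standardization needs at least 2 training rows")
    out = apply_to.copy()
    if train.schema.n == 0:
        return out
    mean = train.X_num.mean(axis=0)
    sd = train.X_num.std(axis=0)
    scaled = np.where(sd > 0, (apply_to.X_num - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    out.X_num = scaled
    return out


# ---------------------------------------------------------------------------
# split planning
# ---------------------------------------------------------------------------


@dataclass
class SplitPlan:
    """Explicit (train, val, test) index triples for repeated k-fold CV."""

    folds: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    k_folds: int
    repeats: int
    seed: int
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "k_folds": self.k_folds,
            "repeats": self.repeats,
            "seed": self.seed,
            "warnings": self.warnings,
            "folds": [
                {"train": tr.tolist(), "val": va.tolist(), "test": te.tolist()}
                for tr, va, te in self.folds
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "SplitPlan":
        payload = json.loads(Path(path).read_text())
        folds = [
            (
                np.asarray(f["train"], dtype=int),
                np.asarray(f["val"], dtype=int),
                np.asarray(f["test"], dtype=int),
            )
            for f in payload["folds"]
        ]
        return cls(
            folds=folds,
            k_folds=payload["k_folds"],
            repeats=payload["repeats"],
            seed=payload["seed"],
            warnings=payload.get("warnings", []),
        )


def _derived_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


def make_splits(
    n_rows: int,
    k_folds: int,
    repeats: int,
    val_fraction_of_train: float = 0.20,
    seed: int = 0,
    labels: Sequence[int] | None = None,
) -> SplitPlan:
    """Plan repeated k-fold CV with a validation carve-out of the train part.

    Per repeat the rows are shuffled (seeded) into ``k_folds`` test folds;
    the remaining rows of each fold are split into train/validation so that
    validation holds ``val_fraction_of_train`` of the non-test rows.  The
    default 0.20 of the 90% non-test rows reproduces overall 72/18/10
    train/validation/test fractions for 10 folds.  When ``labels`` are
    supplied both splits are stratified; degenerate label counts fall back
    to unstratified splitting and leave a warning on the plan.
    """
    if not (n_rows >= k_folds >= 2):
        raise ValueError("need n_rows >= k_folds >= 2")
    if not 0 < val_fraction_of_train < 1:
        raise ValueError("val_fraction_of_train must lie in (0, 1)")
    labels_arr = None if labels is None else np.asarray(labels, dtype=int)
    if labels_arr is not None and labels_arr.shape[0] != n_rows:
        raise ValueError("labels length must equal n_rows")

    folds: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    warnings: list[str] = []
    rows = np.arange(n_rows)
    for r in range(repeats):
        rs = _derived_seed(seed, r)
        stratify = labels_arr is not None
        if stratify and np.bincount(labels_arr).min() < k_folds:
            warnings.append(
                f"repeat {r}: a class has fewer members than k_folds; "
                "fold assignment is unstratified"
            )
            stratify = False
        if stratify:
            splitter = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=rs)
            split_iter = splitter.split(rows, labels_arr)
        else:
            splitter = KFold(n_splits=k_folds, shuffle=True, random_state=rs)
            split_iter = splitter.split(rows)
        for f, (non_test, test) in enumerate(split_iter):
            strat_y = None
            if labels_arr is not None:
                counts = np.bincount(labels_arr[non_test], minlength=2)
                if counts.min() >= 2:
                    strat_y = labels_arr[non_test]
                else:
                    warnings.append(
                        f"repeat {r} fold {f}: non-test rows nearly single-class; "
                        "validation carve-out is unstratified"
                    )
                if counts.min() == 0:
                    warnings.append(
                        f"repeat {r} fold {f}: zero positives or negatives "
                        "outside the test fold"
                    )
            train_idx, val_idx = train_test_split(
                non_test,
                test_size=val_fraction_of_train,
                random_state=_derived_seed(seed, r, f),
                stratify=strat_y,
            )
            folds.append(
                (
                    np.sort(train_idx).astype(int),
                    np.sort(val_idx).astype(int),
                    np.sort(test).astype(int),
                )
            )
    return SplitPlan(
        folds=folds, k_folds=k_folds, repeats=repeats, seed=seed, warnings=warnings
    )


# ---------------------------------------------------------------------------
# synthetic fixture generator
# ---------------------------------------------------------------------------


@dataclass
class SyntheticSpec:
    """Shape and signal parameters for one synthetic table.

    ``signal_strength`` is the total Mahalanobis-style separation planted in
    each feature block: every numerical feature's class-conditional means
    differ by ``signal_strength * noise_sd / sqrt(n_numerical)`` so the
    numerical block alone carries separation ``signal_strength``;
    categorical class-conditional multinomials are tilted in log-space by
    ``signal_strength / sqrt(n_categorical)`` per feature.  Zero signal
    makes every feature independent of the label.
    """

    n_rows: int
    n_numerical: int
    n_categorical: int
    categories_per_feature: int = 3
    positive_fraction: float = 0.5
    signal_strength: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_rows < 1:
            raise ValueError("n_rows must be positive")
        if self.n_numerical + self.n_categorical < 1:
            raise ValueError("need at least one feature")
        if not 0 < self.positive_fraction < 1:
            raise ValueError("positive_fraction must lie in (0, 1)")
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be >= 0")
        if self.categories_per_feature < 2 and self.n_categorical > 0:
            raise ValueError("categorical features need >= 2 categories")


def covertype_like_spec(n_rows: int = 20000, seed: int = 0, **kw) -> SyntheticSpec:
    """A large, class-balanced pretraining corpus shaped like a cartographic
    cover-type table: ten numerical attributes plus 44 binary categorical
    attributes (wilderness-area / soil-type indicator style)."""
    kw.setdefault("n_numerical", 10)
    kw.setdefault("n_categorical", 44)
    kw.setdefault("categories_per_feature", 2)
    kw.setdefault("positive_fraction", 0.5)
    kw.setdefault("signal_strength", 3.0)
    return SyntheticSpec(n_rows=n_rows, seed=seed, **kw)


def stroke_target_like_spec(n_rows: int = 250, seed: int = 0, **kw) -> SyntheticSpec:
    """A small, imbalanced downstream table shaped like the stroke prognosis
    registries: ~14 mixed columns, positive:negative about 1:2."""
    kw.setdefault("n_numerical", 6)
    kw.setdefault("n_categorical", 8)
    kw.setdefault("categories_per_feature", 3)
    kw.setdefault("positive_fraction", 1 / 3)
    kw.setdefault("signal_strength", 1.5)
    return SyntheticSpec(n_rows=n_rows, seed=seed, **kw)


def _schema_for_spec(spec: SyntheticSpec) -> FeatureSchema:
    return FeatureSchema(
        numerical_names=tuple(f"num_{i}" for i in range(spec.n_numerical)),
        categorical_names=tuple(f"cat_{i}" for i in range(spec.n_categorical)),
        vocab={
            f"cat_{i}": tuple(f"c{j}" for j in range(spec.categories_per_feature))
            for i in range(spec.n_categorical)
        },
        label_name="label",
    )


def generate_synthetic(spec: SyntheticSpec) -> TabularDataset:
    """Draw a labelled table from the class-conditional generative model.

    Labels are Bernoulli(``positive_fraction``); numerical features are
    class-conditional Gaussians, categorical features class-conditional
    multinomials, both separated per :class:`SyntheticSpec`.  Fully
    determined by ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    schema = _schema_for_spec(spec)
    k, n, m = spec.n_rows, spec.n_numerical, spec.n_categorical
    y = (rng.random(k) < spec.positive_fraction).astype(np.float64)
    sign = np.where(y == 1, 0.5, -0.5)  # +delta/2 for positives

    if n:
        delta = spec.signal_strength * spec.noise_sd / np.sqrt(n)
        means = np.outer(sign, np.full(n, delta))
        X_num = rng.normal(loc=means, scale=spec.noise_sd)
    else:
        X_num = np.zeros((k, 0))

    X_cat = np.zeros((k, m), dtype=np.int64)
    if m:
        eps = spec.signal_strength / np.sqrt(m)
        C = spec.categories_per_feature
        contrast = np.where(np.arange(C) % 2 == 0, 1.0, -1.0)
        contrast -= contrast.mean()
        for j in range(m):
            base = rng.normal(0.0, 0.5, size=C)
            logits = base[None, :] + np.outer(sign * eps, contrast)
            probs = np.exp(logits - logits.max(axis=1, keepdims=True))
            probs /= probs.sum(axis=1, keepdims=True)
            u = rng.random(k)
            X_cat[:, j] = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)

    return TabularDataset(schema=schema, X_num=X_num, X_cat=X_cat, y=y)
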