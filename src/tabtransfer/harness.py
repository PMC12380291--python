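"""Repeated cross-validated evaluation harness.

Reproduces the experimental protocol structurally: k-fold CV repeated R
times with a 72/18/10 train/validation/test split per fold (for k=10 and a
0.20 validation carve-out), stratified by label.  Per fold the harness
standardizes numerical features on the fold's training rows only, builds a
fresh model (or transfers a pretrained checkpoint with the interaction
layer frozen), trains with early stopping on the fold's validation rows,
scores the untouched test rows, and records the five metrics.  Aggregates
are per-fold means and standard deviations; a pooled-prediction AUC over
all test scores is reported alongside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .finetune import TrainConfig, predict, train_supervised, transfer_and_freeze
from .head_metrics import UndefinedMetricError, auc, confusion, metrics_from_confusion
from .interaction import InteractionConfig
from .model import Checkpoint, init_model_params
from .schema_data import SplitPlan, TabularDataset, standardize_numerical

__all__ = ["FoldRecord", "EvalReport", "run_cv", "compare_paradigms"]

METRICS = ("acc", "pre", "rcl", "f1", "auc")


@dataclass
class FoldRecord:
    fold: int
    repeat: int
    acc: float
    pre: float
    rcl: float
    f1: float
    auc: float
    auc_defined: bool
    best_epoch: int
    seed: int
    error: str | None = None


@dataclass
class EvalReport:
    records: list[FoldRecord]
    aggregates: dict[str, dict[str, float]]
    pooled_auc: float
    config_echo: dict

    def to_dict(self) -> dict:
        return {
            "records": [r.__dict__ for r in self.records],
            "aggregates": self.aggregates,
            "pooled_auc": self.pooled_auc,
            "config_echo": self.config_echo,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_csv(self, path) -> None:
        pd.DataFrame([r.__dict__ for r in self.records]).to_csv(path, index=False)

    def mean(self, metric: str) -> float:
        return self.aggregates[metric]["mean"]


def _aggregate(records: list[FoldRecord]) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for metric in METRICS:
        values = [getattr(r, metric) for r in records if r.error is None]
        if metric == "auc":
            values = [
                r.auc for r in records if r.error is None and r.auc_defined
            ]
        arr = np.asarray(values, dtype=np.float64)
        out[metric] = {
            "mean": float(arr.mean()) if arr.size else float("nan"),
            "std": float(arr.std()) if arr.size else float("nan"),
            "n_folds": int(arr.size),
        }
    return out


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("tabtransfer")
    except PackageNotFoundError:  # pragma: no cover - not installed
        return "unknown"


def _fold_seed(base_seed: int, fold_index: int) -> int:
    return int(
        np.random.SeedSequence([base_seed, fold_index]).generate_state(1)[0] % (2**31)
    )


def run_cv(
    dataset: TabularDataset,
    plan: SplitPlan,
    train_config: TrainConfig,
    int_config: InteractionConfig,
    checkpoint: Checkpoint | None = None,
) -> EvalReport:
    """Evaluate one training arm over every fold of a split plan.

    With a ``checkpoint`` the model per fold is rebuilt by
    :func:`~tabtransfer.finetune.transfer_and_freeze` under
    ``train_config.freeze_scope``; otherwise a fresh model is initialized
    and trained end-to-end.  Fully reproducible from (dataset, plan,
    configs): per-fold seeds derive from ``train_config.seed`` and the fold
    index.  A failed fold is recorded with its error, not dropped.
    """
    records: list[FoldRecord] = []
    all_scores: list[np.ndarray] = []
    all_labels: list[np.ndarray] = []
    k = plan.k_folds
    for fold_index, (train_idx, val_idx, test_idx) in enumerate(plan.folds):
        seed = _fold_seed(train_config.seed, fold_index)
        repeat, fold = divmod(fold_index, k)
        try:
            train_raw = dataset.subset(train_idx)
            val = standardize_numerical(train_raw, dataset.subset(val_idx))
            test = standardize_numerical(train_raw, dataset.subset(test_idx))
            train = standardize_numerical(train_raw, train_raw)

            if checkpoint is not None:
                model = transfer_and_freeze(
                    checkpoint,
                    dataset.schema,
                    freeze_scope=train_config.freeze_scope,
                    pooling=int_config.pooling,
                    seed=seed,
                    warm_start_embedding=train_config.warm_start_embedding,
                )
            else:
                model = init_model_params(dataset.schema, int_config, seed=seed)
            fold_config = TrainConfig(**{**train_config.to_dict(), "seed": seed})
            result = train_supervised(train, val, model, fold_config)

            scores = predict(test, result.model)
            y_test = test.labels_int()
            preds = (scores >= 0.5).astype(int)  # matches classify() at 0.5
            acc, pre, rcl, f1 = metrics_from_confusion(confusion(y_test, preds))
            try:
                fold_auc = auc(scores, y_test)
                auc_defined = True
            except UndefinedMetricError:
                fold_auc = float("nan")
                auc_defined = False
            records.append(
                FoldRecord(
                    fold=fold, repeat=repeat, acc=acc, pre=pre, rcl=rcl, f1=f1,
                    auc=fold_auc, auc_defined=auc_defined,
                    best_epoch=result.best_epoch, seed=seed,
                )
            )
            all_scores.append(scores)
            all_labels.append(y_test)
        except Exception as exc:  # a failed fold is recorded, not silently dropped
            records.append(
                FoldRecord(
                    fold=fold, repeat=repeat, acc=float("nan"), pre=float("nan"),
                    rcl=float("nan"), f1=float("nan"), auc=float("nan"),
                    auc_defined=False, best_epoch=-1, seed=seed, error=str(exc),
                )
            )
    pooled = float("nan")
    if all_scores:
        try:
            pooled = auc(np.concatenate(all_scores), np.concatenate(all_labels))
        except UndefinedMetricError:
            pass
    return EvalReport(
        records=records,
        aggregates=_aggregate(records),
        pooled_auc=pooled,
        config_echo={
            "version": _package_version(),
            "train": train_config.to_dict(),
            "interaction": int_config.to_dict(),
            "plan": {"k_folds": plan.k_folds, "repeats": plan.repeats,
                     "seed": plan.seed, "warnings": plan.warnings},
            "pretrained": checkpoint is not None,
        },
    )


def compare_paradigms(
    dataset: TabularDataset,
    plan: SplitPlan,
    train_config: TrainConfig,
    int_config: InteractionConfig,
    checkpoint: Checkpoint,
) -> dict:
    """Paired comparison of the three training arms on identical folds.

    Arms: plain end-to-end training ("sgd"), end-to-end with Mixup
    ("sgd_mixup"), and pretrained-transfer fine-tuning ("pt_ft").  All arms
    share the same SplitPlan (hence identical test folds), so per-fold AUC
    differences are paired.
    """
    base = train_config.to_dict()
    arms = {
        "sgd": (TrainConfig(**{**base, "freeze_scope": "none",
                               "mixup_enabled": False}), None),
        "sgd_mixup": (TrainConfig(**{**base, "freeze_scope": "none",
                                     "mixup_enabled": True}), None),
        "pt_ft": (TrainConfig(**{**base, "mixup_enabled": False}), checkpoint),
    }
    reports = {
        name: run_cv(dataset, plan, cfg, int_config, ckpt)
        for name, (cfg, ckpt) in arms.items()
    }
    paired = {}
    for a, b in (("pt_ft", "sgd"), ("pt_ft", "sgd_mixup"), ("sgd_mixup", "sgd")):
        diffs = [
            ra.auc - rb.auc
            for ra, rb in zip(reports[a].records, reports[b].records)
            if ra.auc_defined and rb.auc_defined and ra.error is None and rb.error is None
        ]
        paired[f"{a}_minus_{b}"] = {
            "mean": float(np.mean(diffs)) if diffs else float("nan"),
            "per_fold": diffs,
        }
    return {"reports": reports, "paired_auc_differences": paired}
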