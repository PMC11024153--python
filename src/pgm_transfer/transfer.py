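"""Pretraining on a source dataset and frozen-extractor fine-tuning.

Validates transferability rankings at desk scale: the encoder is pretrained
on a source dataset (Adam, best-validation checkpoint), then transferred to
a target task with the feature extractor frozen bit-for-bit while a fresh
predictor head is trained from scratch.  Repeated fine-tuning runs are
aggregated into a mean +/- std of ROC-AUC (classification) or RMSE
(regression) on the scaffold-held-out test partition.

Defaults are desk-scale (30 epochs, small encoder);
``TrainConfig.full_scale()`` restores the full protocol (lr 1e-3, batch 32,
200 epochs, 5 runs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.metrics import roc_auc_score

from .data_io import MoleculeRecord, TaskSpec, featurize, scaffold_split
from .errors import ComparabilityError, ConfigurationError, EvaluationError, NumericError
from .model import (
    ModelConfig,
    ModelState,
    init_model,
    loss_and_gradients,
    make_batch,
    _forward,
)

logger = logging.getLogger(__name__)

_SEED_MOD = 2**31


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 30  # desk-scale default; the full protocol uses 200
    n_runs: int = 5
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)

    def __post_init__(self):
        if self.lr <= 0 or self.batch_size < 1 or self.max_epochs < 1 or self.n_runs < 1:
            raise ConfigurationError("lr, batch_size, max_epochs, n_runs must be positive")
        if len(self.seeds) != self.n_runs:
            raise ConfigurationError("len(seeds) must equal n_runs")

    @classmethod
    def full_scale(cls) -> "TrainConfig":
        """Full protocol: Adam lr 1e-3, batch 32, 200 epochs, 5 runs."""
        return cls(lr=1e-3, batch_size=32, max_epochs=200, n_runs=5, seeds=(0, 1, 2, 3, 4))


@dataclass
class TransferResult:
    metric_name: str  # "roc_auc" | "rmse"
    per_run: list[float]
    source_name: str
    target_name: str

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_run))

    @property
    def std(self) -> float:
        return float(np.std(self.per_run))

    def to_rows(self, seeds) -> list[dict]:
        rows = [
            {"source": self.source_name, "target": self.target_name,
             "run_seed": s, "metric": self.metric_name, "value": v}
            for s, v in zip(seeds, self.per_run)
        ]
        rows.append({"source": self.source_name, "target": self.target_name,
                     "run_seed": "aggregate", "metric": f"{self.metric_name}_mean_std",
                     "value": f"{self.mean:.6f}+/-{self.std:.6f}"})
        return rows


def evaluate(predictions, labels, observed, task: TaskSpec) -> float:
    """Test metric over observed label cells.

    Classification: unweighted mean over subtasks of per-subtask ROC-AUC
    (subtasks with a single observed class are skipped and logged).
    Regression: RMSE over all observed cells.
    """
    def _as_cells(a, dtype):
        a = np.asarray(a, dtype=dtype)
        return a[:, None] if a.ndim == 1 else a  # 1-D input = single subtask

    predictions = _as_cells(predictions, np.float64)
    labels = _as_cells(labels, np.float64)
    observed = _as_cells(observed, bool)
    if task.task_type == "regression":
        if not observed.any():
            raise EvaluationError("no observed cells to score")
        diff = (predictions - labels)[observed]
        return float(np.sqrt(np.mean(diff**2)))
    aucs = []
    for j in range(labels.shape[1]):
        m = observed[:, j]
        y = labels[m, j]
        if m.sum() == 0 or len(np.unique(y)) < 2:
            logger.info("subtask %d skipped: fewer than two observed classes", j)
            continue
        aucs.append(roc_auc_score(y, predictions[m, j]))
    if not aucs:
        raise EvaluationError("every subtask had a single observed class")
    return float(np.mean(aucs))


class Adam:
    """Adam optimizer over a named-parameter dict (no weight decay)."""

    def __init__(self, names, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.names = list(names)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for n in self.names:
            g = grads[n]
            self.m[n] = b1 * self.m.get(n, 0.0) + (1 - b1) * g
            self.v[n] = b2 * self.v.get(n, 0.0) + (1 - b2) * g * g
            mhat = self.m[n] / (1 - b1**self.t)
            vhat = self.v[n] / (1 - b2**self.t)
            params[n] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _predict(state: ModelState, graphs, batch_size=256) -> np.ndarray:
    outs = []
    for start in range(0, len(graphs), batch_size):
        chunk = graphs[start:start + batch_size]
        batch = make_batch(chunk, np.zeros((len(chunk), state.config.predictor_out)),
                           np.ones((len(chunk), state.config.predictor_out), dtype=bool))
        logits, _ = _forward(state, batch)
        outs.append(logits)
    return np.concatenate(outs)


def _metric_better(metric_name: str, a: float, b: float) -> bool:
    return a > b if metric_name == "roc_auc" else a < b


class GraphPropertyPredictor(BaseEstimator):
    """Trainable molecular property model (encoder + predictor head).

    ``fit`` scaffold-splits the records 8:1:1, trains with Adam on the train
    partition, and keeps the checkpoint with the best validation metric.
    With ``freeze_extractor=True`` and an ``init_state``, the encoder is
    taken from ``init_state`` and left bit-identical while only the
    predictor head (re-initialized from ``seed``) is trained — the transfer
    fine-tuning regime.

    Attributes
    ----------
    state_ : ModelState               best-validation checkpoint
    final_state_ : ModelState         state after the last epoch
    val_metric_ : float               validation metric of ``state_``
    test_metric_ : float              its metric on the held-out test split
    metric_name_ : str                "roc_auc" or "rmse"
    """

    def __init__(self, model_config: ModelConfig | None = None, lr: float = 1e-3,
                 batch_size: int = 32, max_epochs: int = 30, seed: int = 0,
                 freeze_extractor: bool = False, init_state: ModelState | None = None,
                 split_seed: int = 0, max_train: int | None = None):
        self.model_config = model_config
        self.lr = lr
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.seed = seed
        self.freeze_extractor = freeze_extractor
        self.init_state = init_state
        self.split_seed = split_seed
        self.max_train = max_train

    def fit(self, records: list[MoleculeRecord], task: TaskSpec):
        model_config = self.model_config or ModelConfig()
        cfg = replace(model_config, predictor_out=task.n_subtasks,
                      init_seed=self.seed % _SEED_MOD)
        state = init_model(cfg)
        if self.init_state is not None:
            donor = self.init_state
            if donor.config.encoder != cfg.encoder or \
                    donor.config.hidden_width != cfg.hidden_width or \
                    donor.config.encoder_depth != cfg.encoder_depth:
                raise ComparabilityError("init_state encoder shape does not match model_config")
            for n in state.extractor_names:
                state.params[n] = donor.params[n].copy()
        trained = state.predictor_names if self.freeze_extractor else list(state.params)
        frozen_hash = None
        if self.freeze_extractor:
            frozen_hash = _extractor_digest(state)

        train_idx, valid_idx, test_idx = scaffold_split(records, seed=self.split_seed)
        if self.max_train is not None and len(train_idx) > self.max_train:
            # data-poor target regime: train on a seeded subsample of the
            # train partition, but keep validation/test partitions intact
            sub_rng = np.random.default_rng(
                np.random.SeedSequence([self.seed % _SEED_MOD, 417]))
            train_idx = sorted(sub_rng.choice(train_idx, size=self.max_train,
                                              replace=False).tolist())
        graphs = [featurize(r) for r in records]
        labels = np.stack([r.labels for r in records])
        observed = np.stack([r.observed for r in records])
        metric_name = "roc_auc" if task.task_type == "classification" else "rmse"

        opt = Adam(trained, lr=self.lr)
        rng = np.random.default_rng(np.random.SeedSequence([self.seed % _SEED_MOD, 9173]))
        best_state, best_val = None, None
        for epoch in range(self.max_epochs):
            order = rng.permutation(train_idx)
            for start in range(0, len(order), self.batch_size):
                idx = order[start:start + self.batch_size]
                if not observed[idx].any():
                    continue
                batch = make_batch([graphs[i] for i in idx], labels[idx], observed[idx])
                loss, grads = loss_and_gradients(state, batch, task)
                if not np.isfinite(loss):
                    raise NumericError(f"training diverged at epoch {epoch}")
                opt.step(state.params, grads)
            val = self._safe_metric(state, graphs, labels, observed, valid_idx, task)
            if val is not None and (best_val is None or _metric_better(metric_name, val, best_val)):
                best_val, best_state = val, state.copy()
        if best_state is None:  # validation never scoreable: fall back to last state
            best_state, best_val = state.copy(), float("nan")
        if self.freeze_extractor and _extractor_digest(best_state) != frozen_hash:
            raise NumericError("frozen extractor changed during fine-tuning")
        self.state_ = best_state
        self.final_state_ = state
        self.val_metric_ = best_val
        self.metric_name_ = metric_name
        # None when the test partition has a single observed class everywhere
        self.test_metric_ = self._safe_metric(
            best_state, graphs, labels, observed, test_idx, task)
        self.split_ = (train_idx, valid_idx, test_idx)
        return self

    def predict(self, records: list[MoleculeRecord]) -> np.ndarray:
        """Raw model outputs (logits for classification)."""
        return _predict(self.state_, [featurize(r) for r in records])

    @staticmethod
    def _safe_metric(state, graphs, labels, observed, idx, task):
        if not len(idx):
            return None
        preds = _predict(state, [graphs[i] for i in idx])
        try:
            return evaluate(preds, labels[idx], observed[idx], task)
        except EvaluationError:
            return None


def _extractor_digest(state: ModelState) -> bytes:
    import hashlib

    h = hashlib.sha256()
    for n in state.extractor_names:
        h.update(np.ascontiguousarray(state.params[n]).tobytes())
    return h.digest()


def pretrain(records, task: TaskSpec, model_config: ModelConfig,
             train_config: TrainConfig, seed: int | None = None) -> ModelState:
    """Train the full model on the source dataset; return the checkpoint
    with the best validation metric."""
    seed = train_config.seeds[0] if seed is None else seed
    est = GraphPropertyPredictor(
        model_config=model_config, lr=train_config.lr,
        batch_size=train_config.batch_size, max_epochs=train_config.max_epochs,
        seed=seed, split_seed=seed,
    )
    return est.fit(records, task).state_


def finetune(pretrained: ModelState, records, task: TaskSpec,
             train_config: TrainConfig, source_name: str = "source",
             target_name: str = "target", max_train: int | None = None) -> TransferResult:
    """Fine-tune on the target with the extractor frozen.

    For each run seed, the predictor head is re-initialized and trained from
    scratch on the target train partition; the extractor stays bit-identical
    to the pretrained one.  Each run uses its own seeded scaffold split, and
    the best-validation checkpoint is scored on the test partition.
    ``max_train`` caps the number of target training molecules (the
    data-poor regime where transfer learning is actually needed).
    """
    per_run = []
    metric_name = None
    for run_seed in train_config.seeds:
        est = GraphPropertyPredictor(
            model_config=pretrained.config, lr=train_config.lr,
            batch_size=train_config.batch_size, max_epochs=train_config.max_epochs,
            seed=run_seed, split_seed=run_seed,
            freeze_extractor=True, init_state=pretrained, max_train=max_train,
        )
        est.fit(records, task)
        if est.test_metric_ is None:
            raise EvaluationError(
                f"run seed {run_seed}: target test partition could not be scored")
        per_run.append(est.test_metric_)
        metric_name = est.metric_name_
    return TransferResult(metric_name=metric_name, per_run=per_run,
                          source_name=source_name, target_name=target_name)
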