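"""Per-fold model training with the LOSO protocol.

Training follows the regime: Adam (learning rate 1e-3), batch size 16, MSE
loss, at most 150 epochs with early stopping after 20 epochs without a
validation-loss improvement of at least 1e-4, restoring the best weights.
Validation for early stopping holds out one randomly chosen (seeded) training
subject, mirroring the subject-level separation of LOSO itself. Labels are
z-scored on the training split and predictions are mapped back to original
units, a pure conditioning choice that leaves reported metrics on the bpm /
kcal/min scale.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .channels import PhysioStream, SensorRecording
from .model import DenseNetConfig, EstimatorNet, extract_attention_weights
from .nn.autodiff import Tensor
from .preprocessing import (
    StandardizationStats,
    WindowedSample,
    apply_standardizer,
    build_loso_folds,
    extract_windows,
    fit_standardizer,
    stack_windows,
)

logger = logging.getLogger(__name__)

CHECKPOINT_SCHEMA = "insolenet-checkpoint-1"


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 16
    max_epochs: int = 150
    early_stop_patience: int = 20
    min_delta: float = 1e-4  # improvement threshold for "significant"
    target: str = "ee"  # "ee" (kcal/min) or "hr" (bpm)
    attention_enabled: bool = True
    seed: int = 0
    validation_scheme: str = "holdout_subject"  # or "holdout_fraction"
    val_fraction: float = 0.1
    hidden_size: int = 32
    densenet: DenseNetConfig = field(default_factory=DenseNetConfig)
    window_s: float = 10.0
    hop_s: float = 1.0
    standardize_labels: bool = True

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.early_stop_patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
        if self.target not in ("hr", "ee"):
            raise ValueError("target must be 'hr' or 'ee'")


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params, lr: float):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainedModel:
    """A fitted network plus the label scaling needed to invert predictions."""

    net: EstimatorNet
    y_mean: float
    y_std: float
    config: TrainConfig
    best_epoch: int
    history: dict


@dataclass
class FoldResult:
    test_subject: str
    y_true: np.ndarray
    y_pred: np.ndarray
    att_matrix: np.ndarray | None  # (n_test_windows, 20), None when ablated
    best_epoch: int
    history: dict
    stats: StandardizationStats
    model: TrainedModel | None = None


def _mse(model: EstimatorNet, x: np.ndarray, y: np.ndarray,
         batch_size: int = 64) -> float:
    model.set_training(False)
    errs = []
    for a in range(0, len(x), batch_size):
        pred, _ = model.forward(Tensor(x[a : a + batch_size]))
        errs.append((pred.data - y[a : a + batch_size]) ** 2)
    return float(np.concatenate(errs).mean())


def train_fold(
    train_windows: list[WindowedSample],
    config: TrainConfig,
    val_windows: list[WindowedSample] | None = None,
) -> TrainedModel:
    """Train one model on the given windows; returns the best-epoch weights."""
    rng = np.random.default_rng(config.seed)
    if val_windows is None:
        subjects = sorted({w.subject_id for w in train_windows})
        if config.validation_scheme == "holdout_subject":
            if len(subjects) < 2:
                raise ValueError(
                    "holdout_subject validation needs >= 2 training subjects"
                )
            val_subject = subjects[int(rng.integers(len(subjects)))]
            val_windows = [w for w in train_windows if w.subject_id == val_subject]
            train_windows = [w for w in train_windows if w.subject_id != val_subject]
            logger.info("validation subject: %s", val_subject)
        else:  # holdout_fraction
            idx = rng.permutation(len(train_windows))
            n_val = max(1, int(round(config.val_fraction * len(train_windows))))
            val_windows = [train_windows[i] for i in idx[:n_val]]
            train_windows = [train_windows[i] for i in idx[n_val:]]
    if not val_windows:
        raise ValueError("validation set is empty")
    if not train_windows:
        raise ValueError("training set is empty")

    x_tr, y_tr = stack_windows(train_windows, config.target)
    x_va, y_va = stack_windows(val_windows, config.target)
    if config.standardize_labels:
        y_mean = float(y_tr.mean())
        y_std = float(y_tr.std()) or 1.0
    else:
        y_mean, y_std = 0.0, 1.0
    z_tr = (y_tr - y_mean) / y_std
    z_va = (y_va - y_mean) / y_std

    net = EstimatorNet(
        seed=config.seed,
        densenet=config.densenet,
        hidden_size=config.hidden_size,
        attention_enabled=config.attention_enabled,
    )
    opt = Adam(net.parameters(), config.learning_rate)
    best_val = np.inf
    best_state = net.state_dict()
    best_epoch = 0
    wait = 0
    history = {"train_loss": [], "val_loss": []}
    n = len(train_windows)
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        net.set_training(True)
        batch_losses = []
        for a in range(0, n, config.batch_size):
            sel = order[a : a + config.batch_size]
            net.zero_grad()
            pred, _ = net.forward(Tensor(x_tr[sel]))
            loss = ((pred - Tensor(z_tr[sel])) ** 2.0).mean()
            loss.backward()
            opt.step()
            batch_losses.append(float(loss.data))
        val_loss = _mse(net, x_va, z_va)
        history["train_loss"].append(float(np.mean(batch_losses)))
        history["val_loss"].append(val_loss)
        logger.info("epoch %d: train %.5f val %.5f", epoch,
                    history["train_loss"][-1], val_loss)
        if best_val - val_loss >= config.min_delta:
            best_val = val_loss
            best_state = net.state_dict()
            best_epoch = epoch
            wait = 0
        else:
            wait += 1
            if wait >= config.early_stop_patience:
                logger.info("early stop at epoch %d (best %d)", epoch, best_epoch)
                break
    net.load_state_dict(best_state)
    return TrainedModel(net, y_mean, y_std, config, best_epoch, history)


def predict(model: TrainedModel, windows: list[WindowedSample],
            batch_size: int = 64) -> np.ndarray:
    """One scalar prediction per window, in label units, order preserved."""
    if not windows:
        return np.zeros(0)
    x, _ = stack_windows(windows, model.config.target)
    model.net.set_training(False)
    out = []
    for a in range(0, len(x), batch_size):
        pred, _ = model.net.forward(Tensor(x[a : a + batch_size]))
        out.append(pred.data)
    return np.concatenate(out) * model.y_std + model.y_mean


def run_loso(
    cohort: list[tuple[SensorRecording, PhysioStream]],
    config: TrainConfig,
    max_folds: int | None = None,
    keep_models: bool = False,
) -> list[FoldResult]:
    """LOSO cross-validation over a cohort of (recording, labels) pairs.

    For every fold the channel standardizer and the early-stopping validation
    split are fitted on training subjects only; the held-out subject's windows
    are never seen before testing. ``max_folds`` limits the number of folds
    actually trained (for scaled-down runs); folds are taken in subject order.
    """
    if len(cohort) < 3:
        raise ValueError("LOSO with subject-level validation needs >= 3 subjects")
    by_id = {rec.subject_id: (rec, stream) for rec, stream in cohort}
    folds = build_loso_folds([rec.subject_id for rec, _ in cohort])
    if max_folds is not None:
        folds = folds[:max_folds]
    results: list[FoldResult] = []
    for train_ids, test_id in folds:
        stats = fit_standardizer([by_id[s][0] for s in train_ids])
        train_windows: list[WindowedSample] = []
        for s in train_ids:
            rec, stream = by_id[s]
            train_windows.extend(
                extract_windows(apply_standardizer(rec, stats), stream,
                                config.window_s, config.hop_s)
            )
        rec, stream = by_id[test_id]
        test_windows = extract_windows(apply_standardizer(rec, stats), stream,
                                       config.window_s, config.hop_s)
        trained = train_fold(train_windows, config)
        y_pred = predict(trained, test_windows)
        _, y_true = stack_windows(test_windows, config.target)
        att = (
            extract_attention_weights(trained.net, test_windows)
            if config.attention_enabled
            else None
        )
        results.append(
            FoldResult(
                test_subject=test_id,
                y_true=y_true,
                y_pred=y_pred,
                att_matrix=att,
                best_epoch=trained.best_epoch,
                history=trained.history,
                stats=stats,
                model=trained if keep_models else None,
            )
        )
    return results


def save_checkpoint(model: TrainedModel, path) -> None:
    """Single-file checkpoint: schema tag, config, seed and all tensors."""
    meta = {
        "schema": CHECKPOINT_SCHEMA,
        "config": _config_to_dict(model.config),
        "y_mean": model.y_mean,
        "y_std": model.y_std,
        "best_epoch": model.best_epoch,
        "seed": model.config.seed,
    }
    state = model.net.state_dict()
    np.savez(path, __meta__=json.dumps(meta), **state)


def load_checkpoint(path) -> TrainedModel:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        if meta.get("schema") != CHECKPOINT_SCHEMA:
            raise ValueError(f"unknown checkpoint schema: {meta.get('schema')}")
        state = {k: data[k] for k in data.files if k != "__meta__"}
    config = _config_from_dict(meta["config"])
    net = EstimatorNet(
        seed=config.seed,
        densenet=config.densenet,
        hidden_size=config.hidden_size,
        attention_enabled=config.attention_enabled,
    )
    net.load_state_dict(state)
    return TrainedModel(net, meta["y_mean"], meta["y_std"], config,
                        meta["best_epoch"], {})


def _config_to_dict(config: TrainConfig) -> dict:
    d = asdict(config)
    return d


def _config_from_dict(d: dict) -> TrainConfig:
    d = dict(d)
    d["densenet"] = DenseNetConfig(**d["densenet"])
    return TrainConfig(**d)
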