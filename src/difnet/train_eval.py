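"""Training loop, trial-level cross-validation and evaluation metrics.

Cross-validation is trial-level by default: folds partition 4-s epochs, not
subjects, so each subject's trials span the training, validation and test
partitions.  A subject-disjoint mode and a per-subject finetuning split
(80/20) are also provided.  Demographic min/max statistics are always fitted
on the training partition of each fold and applied frozen elsewhere.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .model import DIFNet, normalize_demographics
from .nn import Adam, cross_entropy
from .preprocess import EpochSet

__all__ = [
    "TrainConfig",
    "ConfusionMatrix",
    "MetricsReport",
    "FoldPlan",
    "make_folds",
    "train",
    "evaluate",
    "compute_metrics",
    "crossval",
    "compare_variants",
]


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 200
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if min(self.learning_rate, self.batch_size, self.epochs) <= 0:
            raise ValueError("learning_rate, batch_size and epochs must be positive")
        if not 0 <= self.val_fraction < 1:
            raise ValueError("val_fraction must be in [0, 1)")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray
                         ) -> "ConfusionMatrix":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        )


@dataclass
class MetricsReport:
    accuracy: float
    precision: float | None
    recall: float | None
    f1: float | None
    kappa: float
    undefined: list[str] = field(default_factory=list)
    confusion: ConfusionMatrix | None = None

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "kappa": self.kappa,
            "undefined": self.undefined,
        }


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, precision, recall, F1 and Cohen's kappa from counts.

    Kappa uses the chance agreement from the confusion-matrix margins,
    P_e = [(TP+FP)(TP+FN) + (FN+TN)(FP+TN)] / N^2, so kappa stays in
    [-1, 1].  Zero-denominator metrics are reported as None and flagged,
    never silently coerced to 0.
    """
    n = cm.total
    undefined: list[str] = []
    accuracy = (cm.tp + cm.tn) / n
    precision = cm.tp / (cm.tp + cm.fp) if cm.tp + cm.fp else None
    recall = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else None
    if precision is None:
        undefined.append("precision")
    if recall is None:
        undefined.append("recall")
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
        undefined.append("f1")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    p_e = ((cm.tp + cm.fp) * (cm.tp + cm.fn)
           + (cm.fn + cm.tn) * (cm.fp + cm.tn)) / n**2
    kappa = 0.0 if p_e == 1.0 else (accuracy - p_e) / (1.0 - p_e)
    return MetricsReport(accuracy=accuracy, precision=precision, recall=recall,
                         f1=f1, kappa=kappa, undefined=undefined, confusion=cm)


# --------------------------------------------------------------------------
# fold construction
# --------------------------------------------------------------------------

@dataclass
class FoldPlan:
    k: int
    mode: str
    seed: int
    assignments: np.ndarray                 # fold index per epoch (trial modes)
    finetune_splits: dict | None = None     # subject -> (train_idx, test_idx)

    def fold_indices(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        test = np.flatnonzero(self.assignments == fold)
        train = np.flatnonzero((self.assignments != fold)
                               & (self.assignments >= 0))
        return train, test

    def plan_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.mode.encode())
        h.update(self.assignments.tobytes())
        if self.finetune_splits:
            for subj in sorted(self.finetune_splits):
                tr, te = self.finetune_splits[subj]
                h.update(subj.encode())
                h.update(np.asarray(tr).tobytes())
                h.update(np.asarray(te).tobytes())
        return h.hexdigest()[:16]


def make_folds(epochs: EpochSet, k: int = 10, mode: str = "trial_level",
               seed: int = 0, finetune_fraction: float = 0.8,
               chronological: bool = True) -> FoldPlan:
    """Assign trials to folds.

    ``trial_level``: class-stratified random assignment of individual trials
    (each subject's trials spread across folds).  ``blocked``: each subject's
    trials are cut into k contiguous chronological blocks, block i going to
    fold i — every subject still spans all folds, but overlapping windows
    almost never straddle a fold boundary, which random assignment lets them
    do freely (a leakage path when windows overlap).  ``subject_disjoint``:
    whole subjects assigned to folds (no subject spans folds).
    ``subject_finetune``: per-subject train/test split, 80/20 by default,
    chronological unless ``chronological=False``.
    """
    n = epochs.n_epochs
    if mode not in ("trial_level", "blocked", "subject_disjoint",
                    "subject_finetune"):
        raise ValueError(f"unknown fold mode {mode!r}")
    rng = np.random.default_rng(seed)
    if mode == "subject_finetune":
        splits = {}
        for subj in np.unique(epochs.subject_ids):
            idx = np.flatnonzero(epochs.subject_ids == subj)
            if not chronological:
                idx = rng.permutation(idx)
            n_train = int(math.floor(finetune_fraction * len(idx)))
            splits[str(subj)] = (idx[:n_train], idx[n_train:])
        return FoldPlan(k=1, mode=mode, seed=seed,
                        assignments=np.zeros(n, dtype=np.int64),
                        finetune_splits=splits)
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} trials")
    assignments = np.empty(n, dtype=np.int64)
    if mode == "trial_level":
        for cls in np.unique(epochs.labels):
            idx = rng.permutation(np.flatnonzero(epochs.labels == cls))
            assignments[idx] = np.arange(len(idx)) % k
    elif mode == "blocked":
        # purge epochs whose windows reach back into the previous block:
        # with step S and window W, the first ceil(W/S)-1 epochs of each
        # later block share samples with the earlier block's last epoch
        purge = 0
        if epochs.window_samples and epochs.step_samples:
            purge = int(np.ceil(epochs.window_samples / epochs.step_samples)) - 1
        for subj in np.unique(epochs.subject_ids):
            idx = np.flatnonzero(epochs.subject_ids == subj)
            if len(idx) < k:
                raise ValueError(
                    f"subject {subj} has {len(idx)} trials, fewer than k={k}"
                )
            for fold, block in enumerate(np.array_split(idx, k)):
                assignments[block] = fold
                if fold > 0:
                    assignments[block[:purge]] = -1  # excluded from all folds
    else:  # subject_disjoint
        subjects = np.unique(epochs.subject_ids)
        if k > len(subjects):
            raise ValueError(f"cannot make {k} subject-disjoint folds from "
                             f"{len(subjects)} subjects")
        order = rng.permutation(subjects)
        fold_of = {s: i % k for i, s in enumerate(order)}
        assignments = np.array([fold_of[s] for s in epochs.subject_ids])
    return FoldPlan(k=k, mode=mode, seed=seed, assignments=assignments)


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

def _as_batch_input(data: np.ndarray) -> np.ndarray:
    # (n, C, T) -> (n, 1, C, T): the multiscale block expects an explicit
    # leading feature-map axis.
    return data[:, None, :, :]


def train(model: DIFNet, x: np.ndarray, y: np.ndarray,
          demo: np.ndarray | None, cfg: TrainConfig,
          x_val: np.ndarray | None = None, y_val: np.ndarray | None = None,
          demo_val: np.ndarray | None = None) -> dict:
    """Fit with Adam + cross-entropy; keeps the parameters of the epoch with
    the highest validation accuracy (training accuracy when no validation
    set is supplied).  Returns the history dict."""
    if len(x) < 1:
        raise ValueError("need at least one training sample")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    history = {"loss": [], "accuracy": [], "val_accuracy": []}
    best = (-np.inf, None, -1)
    n = len(x)
    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(n)
        losses, hits = [], 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start: start + cfg.batch_size]
            xb = _as_batch_input(x[idx])
            logits = model.forward(xb, None if demo is None else demo[idx])
            loss = cross_entropy(logits, y[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}; lower the learning rate"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            hits += int((logits.data.argmax(axis=1) == y[idx]).sum())
        train_acc = hits / n
        history["loss"].append(float(np.mean(losses)))
        history["accuracy"].append(train_acc)
        if x_val is not None and len(x_val):
            val_acc = float(
                (predict(model, x_val, demo_val) == y_val).mean()
            )
        else:
            val_acc = train_acc
        history["val_accuracy"].append(val_acc)
        if val_acc > best[0]:
            best = (val_acc, model.state(), epoch)
    if best[1] is not None:
        model.load_state(best[1])
    history["best_epoch"] = best[2]
    history["best_val_accuracy"] = best[0]
    return history


def predict(model: DIFNet, x: np.ndarray,
            demo: np.ndarray | None = None) -> np.ndarray:
    model.eval()
    preds = []
    for start in range(0, len(x), 256):
        xb = _as_batch_input(x[start: start + 256])
        db = None if demo is None else demo[start: start + 256]
        preds.append(model.forward(xb, db).data.argmax(axis=1))
    return np.concatenate(preds)


def evaluate(model: DIFNet, x: np.ndarray, y: np.ndarray,
             demo: np.ndarray | None = None) -> MetricsReport:
    cm = ConfusionMatrix.from_predictions(y, predict(model, x, demo))
    return compute_metrics(cm)


# --------------------------------------------------------------------------
# cross-validation
# --------------------------------------------------------------------------

def _stratified_val_split(y: np.ndarray, fraction: float,
                          rng: np.random.Generator
                          ) -> tuple[np.ndarray, np.ndarray]:
    train_idx, val_idx = [], []
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        n_val = int(round(fraction * len(idx)))
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(val_idx))


def crossval(model_factory, epochs: EpochSet, plan: FoldPlan,
             cfg: TrainConfig, indicator_columns: list[str] | None = None
             ) -> dict:
    """K-fold cross-validation with an inner stratified validation split.

    ``model_factory(seed)`` must return a fresh model.  Demographic min/max
    statistics are fitted per fold on its training partition.  Returns
    per-fold reports, fold-wise accuracy vector (for paired comparisons),
    aggregate mean/sd and the plan hash binding results to the fold plan.
    """
    if len(plan.assignments) != epochs.n_epochs:
        raise ValueError("fold plan does not match epoch set")
    indicator_columns = indicator_columns or []
    reports: list[MetricsReport] = []
    histories = []
    for fold in range(plan.k):
        train_all, test_idx = plan.fold_indices(fold)
        rng = np.random.default_rng(cfg.seed * 10_000 + fold)
        tr_rel, val_rel = _stratified_val_split(
            epochs.labels[train_all], cfg.val_fraction, rng
        )
        train_idx = train_all[tr_rel]
        val_idx = train_all[val_rel]
        if indicator_columns:
            demo_train, stats_ = normalize_demographics(
                epochs.demographics.iloc[train_idx], indicator_columns
            )
            demo_val, _ = normalize_demographics(
                epochs.demographics.iloc[val_idx], indicator_columns, stats_
            ) if len(val_idx) else (None, None)
            demo_test, _ = normalize_demographics(
                epochs.demographics.iloc[test_idx], indicator_columns, stats_
            )
        else:
            demo_train = demo_val = demo_test = None
        model = model_factory(cfg.seed * 10_000 + fold)
        fold_cfg = TrainConfig(learning_rate=cfg.learning_rate,
                               batch_size=cfg.batch_size, epochs=cfg.epochs,
                               val_fraction=cfg.val_fraction,
                               seed=cfg.seed * 10_000 + fold)
        history = train(
            model, epochs.data[train_idx], epochs.labels[train_idx],
            demo_train, fold_cfg,
            x_val=epochs.data[val_idx] if len(val_idx) else None,
            y_val=epochs.labels[val_idx] if len(val_idx) else None,
            demo_val=demo_val,
        )
        reports.append(evaluate(model, epochs.data[test_idx],
                                epochs.labels[test_idx], demo_test))
        histories.append(history)
    accs = np.array([r.accuracy for r in reports])
    kappas = np.array([r.kappa for r in reports])
    return {
        "fold_reports": reports,
        "fold_accuracies": accs,
        "fold_kappas": kappas,
        "mean_accuracy": float(accs.mean()),
        "sd_accuracy": float(accs.std(ddof=1)) if plan.k > 1 else 0.0,
        "mean_kappa": float(kappas.mean()),
        "plan_hash": plan.plan_hash(),
        "histories": histories,
    }


def compare_variants(acc_a: np.ndarray, acc_b: np.ndarray) -> float:
    """Two-sided paired t-test on fold-wise accuracy vectors.

    Identical vectors (zero paired difference everywhere) return p = 1.0,
    the convention for "no evidence of any difference".
    """
    acc_a = np.asarray(acc_a, dtype=np.float64)
    acc_b = np.asarray(acc_b, dtype=np.float64)
    if acc_a.shape != acc_b.shape:
        raise ValueError("fold vectors must be paired (equal length)")
    if len(acc_a) < 2:
        raise ValueError("need at least two folds for a paired test")
    diff = acc_a - acc_b
    if np.allclose(diff, 0.0):
        return 1.0
    _, p = sps.ttest_rel(acc_a, acc_b)
    return float(p)


def save_report(report: dict, path) -> None:
    """JSON dump of a crossval result (numpy types coerced)."""
    payload = {
        "fold_reports": [r.as_dict() for r in report["fold_reports"]],
        "fold_accuracies": report["fold_accuracies"].tolist(),
        "mean_accuracy": report["mean_accuracy"],
        "sd_accuracy": report["sd_accuracy"],
        "mean_kappa": report["mean_kappa"],
        "plan_hash": report["plan_hash"],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
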