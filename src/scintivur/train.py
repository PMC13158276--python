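"""Training and validation protocol.

The cohort is split at the patient level into a development cohort (90%)
and an independent test cohort (10%); 10-fold cross-validation runs inside
the development cohort so every development patient is validation data
exactly once. Each fold trains on severe-side inputs with augmentation
(AdamW, cross-entropy, batch size 3) and is early-stopped when the
validation metric fails to improve for `patience` consecutive epochs;
validation is evaluated under both the severe-side and bilateral settings.
Test patients never contribute a gradient or an early-stopping signal.

Everything is seeded: the per-fold seed is ``global seed + fold index``, so
folds are reproducible independently of the order they are trained in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from skimage import transform as _sktransform

from . import metrics as _metrics
from .nn import AdamW, bce_with_logits, cross_entropy
from .nn.autograd import default_dtype
from .net import GatedSwinClassifier, NetConfig, build_model
from .phantom import ScintiScan
from .preprocess import KidneyROI, PreprocessConfig, augment, normalise, preprocess_scan
from .sideselect import SideDecision, select_severe_side

__all__ = [
    "SplitPlan",
    "TrainConfig",
    "FoldRun",
    "PatientRecord",
    "make_splits",
    "early_stop_epoch",
    "EarlyStopper",
    "build_dataset",
    "train_fold",
    "evaluate_patients",
    "run_cross_validation",
]


# ---------------------------------------------------------------------------
# splits


@dataclass(frozen=True)
class SplitPlan:
    dev_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    folds: tuple[tuple[str, ...], ...]
    seed: int

    def __post_init__(self) -> None:
        dev, test = set(self.dev_ids), set(self.test_ids)
        if dev & test:
            raise ValueError("development and test cohorts overlap")
        fold_union: set[str] = set()
        for f in self.folds:
            if fold_union & set(f):
                raise ValueError("folds are not pairwise disjoint")
            fold_union |= set(f)
        if fold_union != dev:
            raise ValueError("folds must partition the development cohort")

    def train_ids(self, fold_index: int) -> tuple[str, ...]:
        return tuple(
            pid for i, f in enumerate(self.folds) if i != fold_index for pid in f
        )


def make_splits(
    manifest, seed: int, test_frac: float = 0.1, n_folds: int = 10
) -> SplitPlan:
    """Patient-level 9:1 development/test split plus k equal folds.

    Fold sizes differ by at most one; reproducible for a fixed seed.
    """
    ids = [str(p) for p in manifest["patient_id"]]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient ids in manifest")
    if len(ids) < 20:
        raise ValueError("need at least 20 patients to split")
    rng = np.random.default_rng([seed, 0x5B117])
    order = list(np.array(ids)[rng.permutation(len(ids))])
    n_test = int(round(len(ids) * test_frac))
    test = tuple(order[:n_test])
    dev = order[n_test:]
    folds = tuple(tuple(f) for f in np.array_split(np.array(dev), n_folds))
    return SplitPlan(dev_ids=tuple(dev), test_ids=test, folds=folds, seed=seed)


# ---------------------------------------------------------------------------
# early stopping


def early_stop_epoch(history: Sequence[float], patience: int) -> tuple[int | None, int]:
    """First epoch at which `patience` consecutive non-improvements occur.

    Epochs are 1-based. Returns ``(stop_epoch or None, best_epoch)``;
    improvement means strictly exceeding the running best.
    """
    if not len(history):
        raise ValueError("history must be non-empty")
    best = history[0]
    best_epoch = 1
    streak = 0
    for i, v in enumerate(list(history)[1:], start=2):
        if v > best:
            best, best_epoch, streak = v, i, 0
        else:
            streak += 1
            if streak >= patience:
                return i, best_epoch
    return None, best_epoch


class EarlyStopper:
    """Streaming early stopping on (metric, -loss) with strict improvement."""

    def __init__(self, patience: int):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.best_key: tuple[float, float] | None = None
        self.best_epoch = 0
        self.streak = 0

    def update(self, epoch: int, metric: float, loss: float = 0.0) -> tuple[bool, bool]:
        """Returns (improved, should_stop) after this epoch's validation."""
        key = (metric, -loss)
        if self.best_key is None or key > self.best_key:
            self.best_key, self.best_epoch, self.streak = key, epoch, 0
            return True, False
        self.streak += 1
        return False, self.streak >= self.patience


# ---------------------------------------------------------------------------
# dataset assembly


@dataclass
class PatientRecord:
    patient_id: str
    label: int
    grade_left: int
    grade_right: int
    roi_left: KidneyROI
    roi_right: KidneyROI
    decision: SideDecision

    @property
    def severe_roi(self) -> KidneyROI:
        return self.roi_left if self.decision.chosen_side == "left" else self.roi_right


def build_dataset(
    scans: Iterable[ScintiScan],
    seed: int,
    preprocess_config: PreprocessConfig | None = None,
) -> dict[str, PatientRecord]:
    """Preprocess scans and apply severe-side selection; keyed by patient."""
    records: dict[str, PatientRecord] = {}
    for scan in scans:
        _, left, right = preprocess_scan(
            scan.image, patient_id=scan.patient_id, config=preprocess_config
        )
        decision = select_severe_side(
            scan.vur_grade_left,
            scan.vur_grade_right,
            left.mean_intensity,
            right.mean_intensity,
            scan.patient_id,
            seed,
        )
        records[scan.patient_id] = PatientRecord(
            patient_id=scan.patient_id,
            label=scan.label,
            grade_left=scan.vur_grade_left,
            grade_right=scan.vur_grade_right,
            roi_left=left,
            roi_right=right,
            decision=decision,
        )
    return records


# ---------------------------------------------------------------------------
# training


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-4
    weight_decay: float = 0.01
    batch_size: int = 3
    patience: int = 20
    max_epochs: int = 300
    loss: str = "cross_entropy"  # or "bce_logits"
    seed: int = 0
    setting: str = "severe"  # training always uses severe-side inputs
    augment: bool = True
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.patience < 1 or self.batch_size < 1:
            raise ValueError("patience and batch_size must be >= 1")
        if self.loss not in ("cross_entropy", "bce_logits"):
            raise ValueError(f"unknown loss {self.loss!r}")


@dataclass
class FoldRun:
    fold_index: int
    best_epoch: int
    stopped_epoch: int
    val_history: list[dict]
    state: dict[str, np.ndarray]
    net_config: NetConfig
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]

    def restore(self) -> GatedSwinClassifier:
        model = build_model(self.net_config)
        model.load_state_dict(self.state)
        return model


def _model_input(roi_image: np.ndarray, size: int) -> np.ndarray:
    if roi_image.shape != (size, size):
        roi_image = _sktransform.resize(
            roi_image, (size, size), order=1, preserve_range=True, anti_aliasing=False
        )
    return roi_image


def _norm_input(roi: KidneyROI, size: int) -> np.ndarray:
    """Normalise then resize to the model's input grid."""
    return _model_input(normalise(roi), size)


def evaluate_patients(
    model: GatedSwinClassifier,
    records: Sequence[PatientRecord],
    setting: str,
) -> dict[str, np.ndarray]:
    """Patient-level labels, scores and hard calls under one input setting.

    severe: the selected kidney's positive-class probability scores the
    patient. bilateral: both kidneys are scored separately; the patient is
    called positive iff either side is (logical OR), with the max side
    probability as the patient score.
    """
    size = model.config.img_size
    labels = np.array([r.label for r in records], dtype=int)
    if setting == "severe":
        batch = np.stack([_norm_input(r.severe_roi, size) for r in records])[:, None]
        probs = model.predict_proba(batch)
        preds = (probs >= 0.5).astype(int)
    elif setting == "bilateral":
        left = np.stack([_norm_input(r.roi_left, size) for r in records])[:, None]
        right = np.stack([_norm_input(r.roi_right, size) for r in records])[:, None]
        pl = model.predict_proba(left)
        pr = model.predict_proba(right)
        preds = np.array(
            [
                int(_metrics.aggregate_bilateral(a >= 0.5, b >= 0.5))
                for a, b in zip(pl, pr)
            ]
        )
        probs = np.maximum(pl, pr)
    else:
        raise ValueError(f"unknown setting {setting!r}")
    return {"labels": labels, "probs": probs, "preds": preds}


def train_fold(
    plan: SplitPlan,
    fold_index: int,
    dataset: Mapping[str, PatientRecord],
    net_config: NetConfig | None = None,
    train_config: TrainConfig | None = None,
) -> FoldRun:
    """Train one cross-validation fold on severe-side inputs.

    Validation runs each epoch on the held-out fold under both settings;
    early stopping monitors severe-side validation accuracy with ties
    broken by lower validation loss; the best epoch's weights are kept.
    """
    net_config = net_config or NetConfig()
    train_config = train_config or TrainConfig()
    val_ids = plan.folds[fold_index]
    if not val_ids:
        raise ValueError(f"fold {fold_index} is empty")
    train_ids = plan.train_ids(fold_index)
    forbidden = set(train_ids) & set(plan.test_ids)
    if forbidden:
        raise AssertionError(f"test patients leaked into training: {sorted(forbidden)}")
    fold_seed = train_config.seed + fold_index
    rng = np.random.default_rng([fold_seed, 0x7EA1])
    loss_fn = cross_entropy if train_config.loss == "cross_entropy" else bce_with_logits
    size = net_config.img_size

    dtype = np.float32 if train_config.dtype == "float32" else np.float64
    with default_dtype(dtype):
        model = build_model(net_config, seed=fold_seed)
        opt = AdamW(
            model.parameters(), lr=train_config.lr, weight_decay=train_config.weight_decay
        )
        stopper = EarlyStopper(train_config.patience)
        best_state = model.state_dict()
        history: list[dict] = []
        train_records = [dataset[pid] for pid in train_ids]
        val_records = [dataset[pid] for pid in val_ids]
        stopped_epoch = train_config.max_epochs
        for epoch in range(1, train_config.max_epochs + 1):
            order = rng.permutation(len(train_records))
            epoch_losses = []
            for start in range(0, len(order), train_config.batch_size):
                chunk = [train_records[i] for i in order[start : start + train_config.batch_size]]
                imgs = []
                for rec in chunk:
                    roi = augment(
                        rec.severe_roi,
                        seed=int(rng.integers(0, 2**31 - 1)),
                        enabled=train_config.augment,
                    )
                    imgs.append(_norm_input(roi, size))
                batch = np.stack(imgs)[:, None]
                targets = np.array([rec.label for rec in chunk], dtype=int)
                logits = model(batch)
                loss = loss_fn(logits, targets)
                model.zero_grad()
                loss.backward()
                opt.step()
                epoch_losses.append(float(loss.data))
            sev = evaluate_patients(model, val_records, "severe")
            bil = evaluate_patients(model, val_records, "bilateral")
            val_loss = float(
                cross_entropy_np(sev["probs"], sev["labels"])
            )
            entry = {
                "epoch": epoch,
                "train_loss": float(np.mean(epoch_losses)),
                "val_loss": val_loss,
                "val_acc_severe": float(np.mean(sev["preds"] == sev["labels"])),
                "val_acc_bilateral": float(np.mean(bil["preds"] == bil["labels"])),
            }
            history.append(entry)
            improved, stop = stopper.update(
                epoch, entry["val_acc_severe"], entry["val_loss"]
            )
            if improved:
                best_state = model.state_dict()
            if stop:
                stopped_epoch = epoch
                break
    return FoldRun(
        fold_index=fold_index,
        best_epoch=stopper.best_epoch,
        stopped_epoch=stopped_epoch,
        val_history=history,
        state=best_state,
        net_config=net_config,
        train_ids=tuple(train_ids),
        val_ids=tuple(val_ids),
    )


def cross_entropy_np(probs: np.ndarray, labels: np.ndarray, eps: float = 1e-12) -> float:
    """Binary cross-entropy of positive-class probabilities (plain numpy)."""
    p = np.clip(probs, eps, 1.0 - eps)
    return float(-np.mean(labels * np.log(p) + (1 - labels) * np.log(1 - p)))


def run_cross_validation(
    plan: SplitPlan,
    dataset: Mapping[str, PatientRecord],
    net_config: NetConfig | None = None,
    train_config: TrainConfig | None = None,
    folds: Sequence[int] | None = None,
) -> dict:
    """Train the requested folds and evaluate each on the test cohort.

    Returns fold runs, per-fold test metrics under both settings, the
    fold-averaged confusion matrices, and t-based 95% CIs of the per-fold
    metric estimates.
    """
    net_config = net_config or NetConfig()
    train_config = train_config or TrainConfig()
    fold_list = list(folds) if folds is not None else list(range(len(plan.folds)))
    runs = [train_fold(plan, i, dataset, net_config, train_config) for i in fold_list]
    test_records = [dataset[pid] for pid in plan.test_ids]
    out: dict = {"runs": runs, "test": {}}
    for setting in ("severe", "bilateral"):
        per_fold_metrics = []
        cms = []
        with default_dtype(np.float32 if train_config.dtype == "float32" else np.float64):
            for run in runs:
                model = run.restore()
                ev = evaluate_patients(model, test_records, setting)
                cm = _metrics.ConfusionMatrix.from_predictions(ev["labels"], ev["preds"])
                ms = _metrics.compute_metrics(cm)
                entry = {
                    "accuracy": ms.accuracy,
                    "sensitivity": ms.sensitivity,
                    "specificity": ms.specificity,
                }
                try:
                    entry["auc"] = _metrics.roc_auc(ev["probs"], ev["labels"])
                except ValueError:
                    entry["auc"] = float("nan")
                per_fold_metrics.append(entry)
                cms.append(cm)
        avg_cm = _metrics.ConfusionMatrix.average(cms)
        aggregates = {}
        if len(runs) >= 2:
            for key in per_fold_metrics[0]:
                vals = [m[key] for m in per_fold_metrics]
                if not any(np.isnan(vals)):
                    aggregates[key] = _metrics.aggregate_folds(vals)
        out["test"][setting] = {
            "per_fold": per_fold_metrics,
            "avg_confusion": avg_cm,
            "avg_metrics": _metrics.compute_metrics(avg_cm),
            "aggregates": aggregates,
        }
    return out
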