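"""End-to-end pipeline orchestration.

Stages: phantom -> preprocess -> sideselect -> qc -> train -> eval ->
report, driven by one serialisable config with a single global seed from
which every stage seed derives. Each stage reads only on-disk artefacts of
earlier stages, is deterministic given identical inputs and seeds, and
registers its outputs (with content hashes) in an artefact manifest, so a
rerun with an unchanged config reproduces identical hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import metrics as _metrics
from .net import NetConfig
from .phantom import (
    PhantomConfig,
    STRONG_GRADE_P,
    generate_cohort,
    strong_effect_config,
    write_cohort,
)
from .preprocess import KidneyROI, preprocess_scan
from .qc import qc_metrics, shift_tests, shift_tests_frame
from .sideselect import select_severe_side
from .train import (
    PatientRecord,
    SplitPlan,
    TrainConfig,
    evaluate_patients,
    make_splits,
    train_fold,
)
from .nn.autograd import default_dtype
from .net import build_model

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

STAGES = ("phantom", "preprocess", "sideselect", "qc", "train", "eval", "report")


@dataclass
class RunConfig:
    """One file controls the whole run; seeds derive from `global_seed`."""

    workdir: str = "runs/default"
    global_seed: int = 0
    # phantom section
    n_patients: int = 60
    prevalence: float = 0.5
    strong_effect: bool = True
    phantom_overrides: dict = field(default_factory=dict)
    # split / training section
    n_folds: int = 5
    test_frac: float = 0.1
    folds_to_run: list[int] = field(default_factory=lambda: [0])
    net: dict = field(default_factory=lambda: {"img_size": 128, "window_size": 4})
    train: dict = field(default_factory=lambda: {"max_epochs": 12, "patience": 12})
    qc_alpha: float = 0.05

    def phantom_config(self) -> PhantomConfig:
        base = strong_effect_config() if self.strong_effect else PhantomConfig()
        return dataclasses.replace(base, **self.phantom_overrides)

    def net_config(self) -> NetConfig:
        return NetConfig(**self.net)

    def train_config(self) -> TrainConfig:
        return TrainConfig(seed=self.global_seed, **self.train)

    def split_plan(self, manifest: pd.DataFrame) -> SplitPlan:
        return make_splits(
            manifest, seed=self.global_seed, test_frac=self.test_frac, n_folds=self.n_folds
        )

    # serialisation ------------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Run:
    def __init__(self, config: RunConfig):
        self.config = config
        self.workdir = Path(config.workdir)
        self.workdir.mkdir(parents=True, exist_ok=True)
        self.artefacts: dict[str, str] = {}

    def register(self, *paths: Path) -> None:
        for p in paths:
            self.artefacts[str(p.relative_to(self.workdir))] = _sha256(p)

    def require(self, path: Path, producer: str) -> Path:
        if not path.exists():
            raise FileNotFoundError(
                f"missing artefact {path}; run the '{producer}' stage first"
            )
        return path

    # -- stages ----------------------------------------------------------
    def phantom(self) -> None:
        cfg = self.config
        scans, manifest = generate_cohort(
            cfg.phantom_config(),
            cfg.n_patients,
            cfg.prevalence,
            seed=cfg.global_seed,
            grade_distribution=STRONG_GRADE_P if cfg.strong_effect else None,
        )
        out = self.workdir / "images"
        manifest_path = write_cohort(scans, manifest, out)
        self.register(manifest_path, *sorted(out.glob("*.png")))

    def _manifest(self) -> pd.DataFrame:
        path = self.require(self.workdir / "images" / "manifest.csv", "phantom")
        return pd.read_csv(path)

    def preprocess(self) -> None:
        manifest = self._manifest()
        roi_dir = self.workdir / "rois"
        roi_dir.mkdir(exist_ok=True)
        rows = []
        for rec in manifest.itertuples():
            image = np.asarray(Image.open(self.workdir / "images" / rec.image_path))
            crop, left, right = preprocess_scan(image, patient_id=rec.patient_id)
            for roi in (left, right):
                Image.fromarray(np.clip(np.rint(roi.image), 0, 255).astype(np.uint8)).save(
                    roi_dir / f"{rec.patient_id}_{roi.side}.png"
                )
            rows.append(
                {
                    "patient_id": rec.patient_id,
                    "otsu_level": crop.otsu_level,
                    "midline_column": crop.midline_column,
                    "crop_top": crop.crop_box[0],
                    "crop_left": crop.crop_box[1],
                    "crop_height": crop.crop_box[2],
                    "crop_width": crop.crop_box[3],
                    "mean_left": left.mean_intensity,
                    "mean_right": right.mean_intensity,
                }
            )
        log_path = self.workdir / "preprocess_log.csv"
        pd.DataFrame(rows).to_csv(log_path, index=False)
        self.register(log_path, *sorted(roi_dir.glob("*.png")))

    def sideselect(self) -> None:
        manifest = self._manifest().set_index("patient_id")
        log = pd.read_csv(
            self.require(self.workdir / "preprocess_log.csv", "preprocess")
        ).set_index("patient_id")
        rows = []
        for pid, rec in log.iterrows():
            m = manifest.loc[pid]
            d = select_severe_side(
                int(m.vur_grade_left),
                int(m.vur_grade_right),
                float(rec.mean_left),
                float(rec.mean_right),
                str(pid),
                seed=self.config.global_seed,
            )
            rows.append(d.__dict__)
        path = self.workdir / "side_decisions.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        self.register(path)

    def qc(self) -> None:
        manifest = self._manifest()
        plan = self.config.split_plan(manifest)
        split_of = {pid: "test" for pid in plan.test_ids}
        for i, fold in enumerate(plan.folds):
            for pid in fold:
                split_of[pid] = "val" if i == 0 else "train"
        records = {"train": [], "val": [], "test": []}
        rows = []
        for rec in manifest.itertuples():
            path = self.workdir / "images" / rec.image_path
            r = qc_metrics(
                np.asarray(Image.open(path)),
                path.stat().st_size,
                split=split_of[rec.patient_id],
            )
            records[r.split].append(r)
            rows.append({"patient_id": rec.patient_id, **r.__dict__})
        qc_path = self.workdir / "qc_records.csv"
        pd.DataFrame(rows).to_csv(qc_path, index=False)
        results = shift_tests(
            records["train"], records["test"], val=records["val"], alpha=self.config.qc_alpha
        )
        shift_path = self.workdir / "shift_tests.csv"
        shift_tests_frame(results).to_csv(shift_path, index=False)
        self.register(qc_path, shift_path)

    def _dataset(self) -> dict[str, PatientRecord]:
        manifest = self._manifest().set_index("patient_id")
        log = pd.read_csv(
            self.require(self.workdir / "preprocess_log.csv", "preprocess")
        ).set_index("patient_id")
        decisions = pd.read_csv(
            self.require(self.workdir / "side_decisions.csv", "sideselect")
        ).set_index("patient_id")
        from .sideselect import SideDecision

        dataset = {}
        for pid, m in manifest.iterrows():
            rois = {}
            for side in ("left", "right"):
                img = np.asarray(
                    Image.open(self.workdir / "rois" / f"{pid}_{side}.png")
                ).astype(float)
                rois[side] = KidneyROI(
                    side=side,
                    image=img,
                    mean_intensity=float(log.loc[pid, f"mean_{side}"]),
                    patient_id=str(pid),
                )
            d = decisions.loc[pid]
            dataset[str(pid)] = PatientRecord(
                patient_id=str(pid),
                label=int(m.label),
                grade_left=int(m.vur_grade_left),
                grade_right=int(m.vur_grade_right),
                roi_left=rois["left"],
                roi_right=rois["right"],
                decision=SideDecision(str(pid), str(d.chosen_side), str(d.rule_fired)),
            )
        return dataset

    def train(self) -> None:
        cfg = self.config
        manifest = self._manifest()
        plan = cfg.split_plan(manifest)
        dataset = self._dataset()
        ckpt_dir = self.workdir / "checkpoints"
        ckpt_dir.mkdir(exist_ok=True)
        log_paths = []
        for fold in cfg.folds_to_run:
            run = train_fold(plan, fold, dataset, cfg.net_config(), cfg.train_config())
            np.savez(ckpt_dir / f"fold{fold}.npz", **run.state)
            log = {
                "fold_index": run.fold_index,
                "best_epoch": run.best_epoch,
                "stopped_epoch": run.stopped_epoch,
                "train_ids": list(run.train_ids),
                "val_ids": list(run.val_ids),
                "history": run.val_history,
            }
            p = self.workdir / f"fold{fold}_log.json"
            p.write_text(json.dumps(log, indent=2))
            log_paths.append(p)
        self.register(*log_paths)

    def eval(self) -> None:
        cfg = self.config
        manifest = self._manifest()
        plan = cfg.split_plan(manifest)
        dataset = self._dataset()
        test_records = [dataset[pid] for pid in plan.test_ids]
        results: dict = {"settings": {}}
        roc_rows = []
        cms = {}
        with default_dtype(np.float32 if cfg.train_config().dtype == "float32" else np.float64):
            models = []
            for fold in cfg.folds_to_run:
                path = self.require(
                    self.workdir / "checkpoints" / f"fold{fold}.npz", "train"
                )
                model = build_model(cfg.net_config())
                with np.load(path) as data:
                    model.load_state_dict({k: data[k] for k in data.files})
                models.append((fold, model))
            for setting in ("severe", "bilateral"):
                per_fold = []
                fold_cms = []
                for fold, model in models:
                    ev = evaluate_patients(model, test_records, setting)
                    cm = _metrics.ConfusionMatrix.from_predictions(ev["labels"], ev["preds"])
                    fold_cms.append(cm)
                    entry = {"fold": fold, "accuracy": float(np.mean(ev["preds"] == ev["labels"]))}
                    try:
                        entry["auc"] = _metrics.roc_auc(ev["probs"], ev["labels"])
                    except ValueError:
                        entry["auc"] = float("nan")
                    per_fold.append(entry)
                    order = np.argsort(-ev["probs"])
                    for rank in order:
                        roc_rows.append(
                            {
                                "setting": setting,
                                "fold": fold,
                                "score": float(ev["probs"][rank]),
                                "label": int(ev["labels"][rank]),
                            }
                        )
                avg = _metrics.ConfusionMatrix.average(fold_cms)
                cms[setting] = avg
                ms = _metrics.compute_metrics(avg)
                results["settings"][setting] = {
                    "per_fold": per_fold,
                    "avg_confusion": {"tn": avg.tn, "fp": avg.fp, "fn": avg.fn, "tp": avg.tp},
                    "avg_metrics": {
                        k: (None if np.isnan(v) else round(v, 4))
                        for k, v in ms.__dict__.items()
                    },
                }
        metrics_path = self.workdir / "metrics.json"
        metrics_path.write_text(json.dumps(results, indent=2))
        roc_path = self.workdir / "roc_points.csv"
        pd.DataFrame(roc_rows).to_csv(roc_path, index=False)
        self.register(metrics_path, roc_path)

    def report(self) -> None:
        metrics_json = json.loads(
            self.require(self.workdir / "metrics.json", "eval").read_text()
        )
        model_cms = {
            f"Model ({name}-side)": _metrics.ConfusionMatrix(**s["avg_confusion"])
            for name, s in metrics_json["settings"].items()
        }
        table = _metrics.clinician_report(model_cm_by_setting=model_cms)
        path = self.workdir / "clinician_comparison.csv"
        table.to_csv(path)
        self.register(path)


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> dict[str, str]:
    """Execute the requested stages in dependency order.

    Returns the artefact manifest (relative path -> sha256), also written
    to ``workdir/artefacts.json``.
    """
    requested = list(stages) if stages else list(STAGES)
    unknown = set(requested) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    run = _Run(config)
    for stage in STAGES:
        if stage not in requested:
            continue
        t0 = time.time()
        getattr(run, stage)()
        print(f"[scintivur] stage {stage:<10s} done in {time.time() - t0:6.1f}s")
    manifest_path = run.workdir / "artefacts.json"
    manifest_path.write_text(json.dumps(run.artefacts, indent=2, sort_keys=True))
    config.to_yaml(run.workdir / "config.yaml")
    return run.artefacts
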