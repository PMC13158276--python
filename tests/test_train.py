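"""Split plan, early stopping and fold training: protocol invariants."""

import numpy as np
import pandas as pd
import pytest

from scintivur.net import NetConfig
from scintivur.phantom import STRONG_GRADE_P, generate_cohort, strong_effect_config
from scintivur.train import (
    EarlyStopper,
    SplitPlan,
    TrainConfig,
    build_dataset,
    early_stop_epoch,
    evaluate_patients,
    make_splits,
    train_fold,
)


def _manifest(n):
    return pd.DataFrame({"patient_id": [f"P{i:04d}" for i in range(n)]})


class TestMakeSplits:
    def test_clinical_cohort_sizes(self):
        plan = make_splits(_manifest(346), seed=0)
        assert len(plan.test_ids) in (34, 35)
        assert len(plan.dev_ids) + len(plan.test_ids) == 346
        sizes = sorted(len(f) for f in plan.folds)
        assert len(plan.folds) == 10
        assert sizes[-1] - sizes[0] <= 1
        assert all(31 <= s <= 32 for s in sizes)

    def test_every_dev_patient_in_exactly_one_fold(self):
        plan = make_splits(_manifest(101), seed=3, n_folds=10)
        seen = [pid for fold in plan.folds for pid in fold]
        assert sorted(seen) == sorted(plan.dev_ids)
        assert len(seen) == len(set(seen))

    def test_seed_contract(self):
        a = make_splits(_manifest(60), seed=0, n_folds=5)
        b = make_splits(_manifest(60), seed=0, n_folds=5)
        c = make_splits(_manifest(60), seed=1, n_folds=5)
        assert a == b
        assert a.test_ids != c.test_ids

    def test_duplicate_ids_rejected(self):
        bad = pd.DataFrame({"patient_id": ["a"] * 10 + ["b"] * 15})
        with pytest.raises(ValueError, match="duplicate"):
            make_splits(bad, seed=0)

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError, match="at least 20"):
            make_splits(_manifest(19), seed=0)

    def test_overlapping_plan_rejected_by_invariants(self):
        with pytest.raises(ValueError, match="overlap"):
            SplitPlan(dev_ids=("a", "b"), test_ids=("b",), folds=(("a", "b"),), seed=0)


class TestEarlyStopping:
    def test_strictly_improving_never_stops(self):
        stop, best = early_stop_epoch(list(range(50)), patience=20)
        assert stop is None and best == 50

    def test_flat_after_first_epoch_stops_at_21(self):
        stop, best = early_stop_epoch([1.0] + [0.5] * 40, patience=20)
        assert stop == 21 and best == 1

    def test_sawtooth_counter_resets_on_new_best(self):
        history = [0.5] * 14 + [0.9] + [0.6] * 30  # new best at epoch 15
        stop, best = early_stop_epoch(history, patience=20)
        assert best == 15
        assert stop == 35  # no earlier than best + patience

    def test_streaming_stopper_matches_pure_function(self, rng):
        history = list(rng.uniform(size=60))
        stop, best = early_stop_epoch(history, patience=7)
        stopper = EarlyStopper(patience=7)
        stopped_at = None
        for epoch, v in enumerate(history, start=1):
            _, should_stop = stopper.update(epoch, v)
            if should_stop:
                stopped_at = epoch
                break
        assert stopped_at == stop
        if stop is not None:
            assert stopper.best_epoch == best

    def test_tie_broken_by_lower_loss(self):
        s = EarlyStopper(patience=5)
        s.update(1, 0.8, loss=0.6)
        improved, _ = s.update(2, 0.8, loss=0.5)
        assert improved and s.best_epoch == 2
        improved, _ = s.update(3, 0.8, loss=0.55)
        assert not improved


@pytest.fixture(scope="module")
def tiny_study():
    scans, manifest = generate_cohort(
        strong_effect_config(), 24, 0.5, seed=8, grade_distribution=STRONG_GRADE_P
    )
    dataset = build_dataset(scans, seed=8)
    plan = make_splits(manifest, seed=8, n_folds=3)
    net = NetConfig(img_size=64, window_size=4, embed_dim=8, num_heads=(1, 2, 4, 8))
    return dataset, plan, net


class TestTrainFold:
    def test_runs_and_logs_history(self, tiny_study):
        dataset, plan, net = tiny_study
        tc = TrainConfig(seed=0, max_epochs=2, patience=2)
        run = train_fold(plan, 0, dataset, net, tc)
        assert len(run.val_history) == 2
        assert run.best_epoch <= run.stopped_epoch <= run.best_epoch + tc.patience
        assert set(run.val_history[0]) >= {
            "epoch",
            "train_loss",
            "val_loss",
            "val_acc_severe",
            "val_acc_bilateral",
        }

    def test_no_test_patient_contributes_to_training(self, tiny_study):
        dataset, plan, net = tiny_study
        tc = TrainConfig(seed=0, max_epochs=1, patience=1)
        for fold in range(len(plan.folds)):
            run = train_fold(plan, fold, dataset, net, tc)
            assert not set(run.train_ids) & set(plan.test_ids)
            assert not set(run.val_ids) & set(plan.test_ids)
            assert not set(run.train_ids) & set(run.val_ids)

    def test_identical_seeds_give_identical_first_epoch(self, tiny_study):
        dataset, plan, net = tiny_study
        tc = TrainConfig(seed=4, max_epochs=1, patience=1)
        a = train_fold(plan, 0, dataset, net, tc)
        b = train_fold(plan, 0, dataset, net, tc)
        assert a.val_history[0]["train_loss"] == b.val_history[0]["train_loss"]
        assert a.val_history[0]["val_acc_severe"] == b.val_history[0]["val_acc_severe"]

    def test_folds_are_order_independent(self, tiny_study):
        dataset, plan, net = tiny_study
        tc = TrainConfig(seed=4, max_epochs=1, patience=1)
        fresh = train_fold(plan, 1, dataset, net, tc)
        train_fold(plan, 0, dataset, net, tc)  # interleave another fold
        again = train_fold(plan, 1, dataset, net, tc)
        assert fresh.val_history == again.val_history

    def test_bilateral_evaluation_is_logical_or(self, tiny_study):
        dataset, plan, net = tiny_study
        tc = TrainConfig(seed=0, max_epochs=1, patience=1)
        run = train_fold(plan, 0, dataset, net, tc)
        model = run.restore()
        records = [dataset[pid] for pid in plan.test_ids]
        from scintivur.train import _norm_input

        bil = evaluate_patients(model, records, "bilateral")
        left = model.predict_proba(
            np.stack([_norm_input(r.roi_left, 64) for r in records])[:, None]
        )
        right = model.predict_proba(
            np.stack([_norm_input(r.roi_right, 64) for r in records])[:, None]
        )
        expected = ((left >= 0.5) | (right >= 0.5)).astype(int)
        assert np.array_equal(bil["preds"], expected)

    def test_empty_fold_rejected(self, tiny_study):
        dataset, plan, net = tiny_study
        merged = plan.folds[-2] + plan.folds[-1]  # keep the partition intact
        bad = SplitPlan(
            dev_ids=plan.dev_ids,
            test_ids=plan.test_ids,
            folds=plan.folds[:-2] + (merged, ()),
            seed=plan.seed,
        )
        with pytest.raises(ValueError, match="empty"):
            train_fold(bad, len(bad.folds) - 1, dataset, net)
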