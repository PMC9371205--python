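"""Classifier architecture, learning-rate schedule, subject-wise splits,
training behaviour and sequence prediction."""

import numpy as np
import pytest

from swimlap.activities import ImuRecording
from swimlap.classifier import (
    ModelConfig,
    TABLE_PARAM_COUNTS,
    TrainingConfig,
    bidirectional_param_count,
    build_model,
    lr_schedule,
    split_hoscv,
    train,
)
from swimlap.preprocess import ChannelScaler
from swimlap.windowing import WindowBatch


def _toy_batch(n=200, seed=0):
    """Separable 8-class windows: class-dependent offset on one channel."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 8, size=n)
    x = rng.normal(0, 0.1, size=(n, 6, 90)).astype(np.float32)
    for i in range(n):
        x[i, y[i] % 6, :] += 3.0 + y[i]
    return WindowBatch(x, frame_index=np.arange(n), targets=y)


def _no_dropout_cfg():
    return ModelConfig(dropout=0.0, recurrent_dropout=0.0, dense_dropout=0.0)


class TestArchitecture:
    def test_strict_build_reproduces_reference_counts(self):
        clf = build_model(strict_paper=True)
        assert tuple(clf.layer_param_counts()) == TABLE_PARAM_COUNTS

    def test_recurrent_counts_match_closed_form(self):
        clf = build_model()
        dims = [(64, 90), (32, 128), (16, 64), (16, 32)]
        for count, (u, d) in zip(clf.layer_param_counts(), dims):
            assert count == bidirectional_param_count(u, d)

    def test_strict_build_rejects_deviating_layout(self):
        with pytest.raises(ValueError, match="strict_paper"):
            build_model(ModelConfig(layout="frames_as_time"), strict_paper=True)

    def test_strict_build_rejects_wrong_units(self):
        with pytest.raises(ValueError, match="strict_paper"):
            build_model(ModelConfig(units=(64, 32, 16)), strict_paper=True)


class TestLrSchedule:
    def test_initial_value(self):
        assert lr_schedule(0) == pytest.approx(1e-3)

    def test_non_increasing(self):
        vals = [lr_schedule(e) for e in range(15)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_closed_form_at_epoch_10(self):
        assert lr_schedule(10) == pytest.approx(1e-3 * 800 ** (-0.1))

    def test_negative_epoch_rejected(self):
        with pytest.raises(ValueError):
            lr_schedule(-1)


class _Sess:
    def __init__(self, subject_id):
        self.subject_id = subject_id


class TestSplit:
    def test_subjects_disjoint_and_union_complete(self):
        sessions = [_Sess(f"S{i:02d}") for i in range(10)]
        tr, va, te = split_hoscv(sessions, seed=3)
        ids = lambda xs: {s.subject_id for s in xs}
        assert ids(va).isdisjoint(ids(te))
        assert ids(tr).isdisjoint(ids(va) | ids(te))
        assert ids(tr) | ids(va) | ids(te) == ids(sessions)
        assert len(va) == len(te) == 1

    def test_deterministic_given_seed(self):
        sessions = [_Sess(f"S{i}") for i in range(8)]
        assert [s.subject_id for s in split_hoscv(sessions, seed=4)[2]] == [
            s.subject_id for s in split_hoscv(sessions, seed=4)[2]
        ]

    def test_single_holdout_subject_mode(self):
        sessions = [_Sess(f"S{i}") for i in range(5)]
        _, va, te = split_hoscv(sessions, seed=0, single_holdout_subject=True)
        assert va[0].subject_id == te[0].subject_id

    def test_fewer_than_three_subjects_rejected(self):
        with pytest.raises(ValueError, match="3 subjects"):
            split_hoscv([_Sess("a"), _Sess("b")], seed=0)


class TestTraining:
    def test_overfits_separable_toy_set(self):
        batch = _toy_batch()
        clf = build_model(_no_dropout_cfg(), seed=0, dtype=np.float32)
        train(clf, batch, None, TrainingConfig(epochs=30, seed=0))
        probs = clf.predict_proba_windows(batch)
        assert (probs.argmax(1) == batch.targets).mean() == 1.0
        # emitted labels equal training targets on the overfitted set
        assert np.array_equal(probs.argmax(1), batch.targets)

    def test_loss_decreases_over_training(self):
        batch = _toy_batch()
        clf = build_model(_no_dropout_cfg(), seed=1, dtype=np.float32)
        train(clf, batch, None, TrainingConfig(epochs=10, seed=1))
        h = clf.history["train_loss"]
        assert h[-1] < h[0]

    def test_training_is_deterministic(self):
        batch = _toy_batch(n=100)
        results = []
        for _ in range(2):
            clf = build_model(seed=5, dtype=np.float32)
            train(clf, batch, None, TrainingConfig(epochs=2, seed=5))
            results.append(clf.net.get_weights())
        for a, b in zip(*results):
            assert np.array_equal(a, b)

    def test_history_records_lr_and_val_accuracy(self):
        batch = _toy_batch(n=100)
        clf = build_model(_no_dropout_cfg(), seed=0, dtype=np.float32)
        train(clf, batch, batch, TrainingConfig(epochs=3, seed=0))
        assert clf.history["lr"][0] == pytest.approx(1e-3)
        assert len(clf.history["val_accuracy"]) == 3

    def test_untargeted_batch_rejected(self):
        batch = _toy_batch(n=64)
        batch.targets = None
        clf = build_model(seed=0)
        with pytest.raises(ValueError, match="targets"):
            train(clf, batch, None, TrainingConfig(epochs=1, seed=0))


class TestPredictSequence:
    def test_one_label_per_frame_and_valid_probabilities(self, rng):
        clf = build_model(seed=0, dtype=np.float32,
                          scaler=ChannelScaler(np.zeros(6), np.ones(6)))
        rec = ImuRecording(rng.normal(size=(230, 6)), sample_rate=50.0,
                           preprocessed=True)
        seq, probs = clf.predict_sequence(rec)
        assert seq.n_frames == 230
        assert seq.provenance == "raw_prediction"
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.array_equal(probs.argmax(axis=1), seq.labels)

    def test_raw_recording_is_preprocessed_internally(self, rng):
        scaler = ChannelScaler(np.zeros(6), np.ones(6))
        clf = build_model(seed=0, dtype=np.float32, scaler=scaler)
        rec = ImuRecording(rng.normal(size=(2800, 6)), sample_rate=280.0)
        seq, _ = clf.predict_sequence(rec)
        assert seq.n_frames == 500  # one label per 0.02 s of signal
        assert seq.sample_rate == 50.0
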