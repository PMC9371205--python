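"""End-to-end experiment drivers: cohort training under subject-wise
cross-validation and the benchmark utilities built on it.

``run_hoscv_experiment`` is the canonical desk-scale experiment: simulate a
cohort, hold one subject out for validation and another for testing, fit
the channel scaler on the training subjects only, train the classifier,
predict the held-out subject frame by frame, clean the prediction with the
minimum-duration filter, and score both the frame-wise classification and
the derived lap times against the simulator's ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .activities import ImuRecording, LabelSequence, N_CLASSES
from .agreement import AgreementReport, classification_report
from .classifier import (
    ModelConfig,
    SwimClassifier,
    TrainingConfig,
    build_model,
    split_hoscv,
    train,
)
from .label_filter import FilterPolicy, filter_predictions
from .laptimes import compute_lap_times, pair_lap_tables
from .preprocess import ChannelScaler, fit_scaler, preprocess
from .simulate import SessionPlan, SyntheticSession, generate_cohort, pace_ladder_block
from .windowing import WindowBatch, make_windows

__all__ = [
    "corrupt_labels",
    "resample_labels",
    "build_training_windows",
    "benchmark_filter_policy",
    "benchmark_cohort",
    "HoscvResult",
    "run_hoscv_experiment",
]


def benchmark_cohort(seed: int, n_subjects: int = 6) -> list[SyntheticSession]:
    """The desk-scale benchmark cohort: one pace-ladder block per technique
    (4 laps each, low -> maximal) per subject, with shortened rests.

    This condenses the full protocol to roughly six minutes of signal per
    subject while keeping every technique and all four pace levels."""
    from .activities import STROKES

    plan = SessionPlan([pace_ladder_block(t, rest_s=20.0) for t in STROKES])
    return generate_cohort(n_subjects, plan, seed=seed)


def benchmark_filter_policy() -> FilterPolicy:
    """Filter minima consistent with the simulator's phase durations.

    A minimum-duration threshold must undercut the shortest genuine phase
    the protocol can produce, otherwise the filter erases real segments
    (e.g. a maximal-pace turn) and merges laps. These minima sit at roughly
    half the shortest scheduled duration of each phase.
    """
    from .activities import ActivityClass as A

    return FilterPolicy(
        min_duration_s={
            A.WALLPUSH: 0.10, A.UNDERWATER: 0.50, A.TURN: 0.25, A.REST: 1.0,
            A.BUTTERFLY: 1.5, A.BACKSTROKE: 1.5, A.BREASTSTROKE: 1.5,
            A.FRONTCRAWL: 1.5,
        }
    )


def corrupt_labels(seq: LabelSequence, fraction: float, seed: int) -> LabelSequence:
    """Flip a random ``fraction`` of frames to a random wrong class —
    the standard corrupted-prediction fixture for filter benchmarks."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    labels = seq.labels.copy()
    n_bad = int(round(fraction * labels.size))
    idx = rng.choice(labels.size, size=n_bad, replace=False)
    shift = rng.integers(1, N_CLASSES, size=n_bad)
    labels[idx] = (labels[idx] + shift) % N_CLASSES
    return LabelSequence(labels, sample_rate=seq.sample_rate, provenance="raw_prediction")


def resample_labels(seq: LabelSequence, target_rate: float) -> LabelSequence:
    """Nearest-frame label resampling (e.g. 280 Hz ground truth onto the
    50 Hz working grid)."""
    n_out = int(round(seq.n_frames * target_rate / seq.sample_rate))
    src = np.minimum(
        (np.arange(n_out) * seq.sample_rate / target_rate).astype(np.int64),
        seq.n_frames - 1,
    )
    return LabelSequence(seq.labels[src], sample_rate=target_rate, provenance=seq.provenance)


def build_training_windows(
    sessions: list[SyntheticSession],
    scaler: ChannelScaler,
    stride: int = 1,
    layout: str = "paper",
) -> WindowBatch:
    """Preprocess each session, align its ground truth to the working rate
    and stack the windows of all sessions into one batch."""
    tensors, targets, frames = [], [], []
    for s in sessions:
        rec = preprocess(s.recording, scaler)
        lab = resample_labels(s.labels, rec.sample_rate)
        if lab.n_frames != rec.n_frames:
            lab = LabelSequence(
                np.resize(lab.labels, rec.n_frames),
                sample_rate=rec.sample_rate, provenance=lab.provenance,
            )
        b = make_windows(rec, lab, stride=stride, pad_edges=True, layout=layout)
        tensors.append(b.tensor)
        targets.append(b.targets)
        frames.append(b.frame_index)
    return WindowBatch(
        np.concatenate(tensors),
        frame_index=np.concatenate(frames),
        targets=np.concatenate(targets),
        layout=layout,
    )


@dataclass
class HoscvResult:
    classifier: SwimClassifier
    test_subject: str
    report_raw: object
    report_filtered: object
    lap_agreement: AgreementReport | None
    n_laps_pred: int
    n_laps_true: int
    predicted: LabelSequence = field(repr=False, default=None)
    filtered: LabelSequence = field(repr=False, default=None)

    @property
    def weighted_f1_raw(self) -> float:
        return self.report_raw.weighted_f1

    @property
    def weighted_f1_filtered(self) -> float:
        return self.report_filtered.weighted_f1


def run_hoscv_experiment(
    cohort: list[SyntheticSession],
    seed: int = 0,
    epochs: int = 10,
    stride: int = 1,
    model_config: ModelConfig | None = None,
    filter_policy: FilterPolicy | None = None,
    scaler_scope: str = "train",
    single_holdout_subject: bool = False,
    dtype=np.float32,
) -> HoscvResult:
    """Train and evaluate on a synthetic cohort with subject-wise splits.

    ``scaler_scope`` selects whether channel statistics pool over training
    subjects only (default, leakage-free) or over all subjects.
    """
    if scaler_scope not in ("train", "all"):
        raise ValueError("scaler_scope must be 'train' or 'all'")
    mcfg = model_config or ModelConfig()
    policy = filter_policy or benchmark_filter_policy()
    train_sessions, val_sessions, test_sessions = split_hoscv(
        cohort, seed=seed, single_holdout_subject=single_holdout_subject
    )
    scale_pool = cohort if scaler_scope == "all" else train_sessions
    # scaler statistics are computed on the filtered/resampled signal
    from .preprocess import butterworth_lowpass, resample_to

    conditioned = [resample_to(butterworth_lowpass(s.recording)) for s in scale_pool]
    scaler = fit_scaler(conditioned)

    train_batch = build_training_windows(train_sessions, scaler, stride=stride, layout=mcfg.layout)
    val_batch = build_training_windows(val_sessions, scaler, stride=max(stride, 4), layout=mcfg.layout)

    clf = build_model(mcfg, seed=seed, scaler=scaler, dtype=dtype)
    tcfg = TrainingConfig(epochs=epochs, seed=seed, stride=stride)
    train(clf, train_batch, val_batch, tcfg)

    test = test_sessions[0]
    rec50 = preprocess(test.recording, scaler)
    truth50 = resample_labels(test.labels, rec50.sample_rate)
    if truth50.n_frames != rec50.n_frames:
        truth50 = LabelSequence(
            np.resize(truth50.labels, rec50.n_frames),
            sample_rate=rec50.sample_rate, provenance="ground_truth",
        )
    pred, _ = clf.predict_sequence(rec50)
    filtered = filter_predictions(pred, policy)

    report_raw = classification_report(pred, truth50)
    report_filtered = classification_report(filtered, truth50)

    pred_laps = compute_lap_times(filtered, subject_id=test.subject_id)
    paired = pair_lap_tables(pred_laps, test.lap_table)
    lap_agreement = AgreementReport.compute(paired.pred_s, paired.ref_s) if paired.n >= 2 else None

    return HoscvResult(
        classifier=clf,
        test_subject=test.subject_id,
        report_raw=report_raw,
        report_filtered=report_filtered,
        lap_agreement=lap_agreement,
        n_laps_pred=len(pred_laps),
        n_laps_true=len(test.lap_table),
        predicted=pred,
        filtered=filtered,
    )
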