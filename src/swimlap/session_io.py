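"""On-disk artifacts: IMU CSV time series, label files, lap tables, reports
and model bundles.

All tabular formats are plain comma-separated UTF-8 with a mandatory header
row and '.' decimals. Label files come in two flavours: half-open interval
rows ``start_s,end_s,label`` (frames assigned as floor(start*rate) ..
floor(end*rate), which must tile the recording), or one class token per
frame. A trained model is persisted as a versioned bundle directory holding
the weight arrays, the architecture/training configuration and the channel
scaler, with a JSON metadata file recording the class vocabulary.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .activities import (
    ActivityClass,
    CHANNELS,
    ImuRecording,
    LabelSequence,
    Segment,
    labels_to_segments,
)
from .classifier import ModelConfig, SwimClassifier, TrainingConfig, build_model
from .laptimes import LapRecord
from .preprocess import ChannelScaler

__all__ = [
    "read_imu_csv",
    "write_imu_csv",
    "read_labels",
    "write_labels",
    "read_lap_table",
    "write_lap_table",
    "save_model",
    "load_model",
    "SessionBundle",
]

BUNDLE_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# IMU time series

def write_imu_csv(rec: ImuRecording, path, include_time: bool = True) -> None:
    df = pd.DataFrame(rec.samples, columns=list(CHANNELS))
    if include_time:
        df.insert(0, "time_s", rec.times())
    df.to_csv(path, index=False, float_format="%.9f")


def read_imu_csv(
    path,
    sample_rate: float | None = None,
    subject_id: str = "S00",
    session_id: str = "sess0",
    preprocessed: bool = False,
) -> ImuRecording:
    """Read a 6-channel CSV. The rate comes from a ``time_s`` column when
    present (time stamps must be uniform to 1e-6 s), else from the
    ``sample_rate`` argument."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty IMU file: {path}") from None
    if df.empty:
        raise ValueError(f"IMU file has no rows: {path}")
    missing = [c for c in CHANNELS if c not in df.columns]
    if missing:
        raise ValueError(f"missing channel column(s): {', '.join(missing)}")
    if "time_s" in df.columns:
        t = df["time_s"].to_numpy(dtype=float)
        if t.size > 1:
            dt = np.diff(t)
            if np.max(np.abs(dt - dt.mean())) > 1e-6:
                raise ValueError("non-uniform time stamps (tolerance 1e-6 s)")
            rate = 1.0 / dt.mean()
        elif sample_rate is None:
            raise ValueError("single-row file needs an explicit sample_rate")
        else:
            rate = sample_rate
    elif sample_rate is not None:
        rate = sample_rate
    else:
        raise ValueError("file has no time_s column; pass sample_rate explicitly")
    samples = df[list(CHANNELS)].to_numpy(dtype=float)
    return ImuRecording(
        samples, sample_rate=float(rate), subject_id=subject_id,
        session_id=session_id, preprocessed=preprocessed,
    )


# ---------------------------------------------------------------------------
# label files

def write_labels(seq: LabelSequence, path, as_intervals: bool = True) -> None:
    if as_intervals:
        rows = [
            {
                "start_s": s.start_frame / seq.sample_rate,
                "end_s": s.end_frame / seq.sample_rate,
                "label": s.activity.short,
            }
            for s in labels_to_segments(seq)
        ]
        pd.DataFrame(rows).to_csv(path, index=False, float_format="%.9f")
    else:
        pd.DataFrame({"label": [ActivityClass(c).short for c in seq.labels]}).to_csv(
            path, index=False
        )


def read_labels(path, rate: float, provenance: str = "ground_truth") -> LabelSequence:
    """Read either interval rows or a per-frame token column into a
    full-coverage per-frame sequence at ``rate``."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty label file: {path}") from None
    if {"start_s", "end_s", "label"}.issubset(df.columns):
        segs = []
        for _, row in df.iterrows():
            start = int(np.floor(float(row["start_s"]) * rate + 1e-9))
            end = int(np.floor(float(row["end_s"]) * rate + 1e-9))
            segs.append(Segment(ActivityClass.from_token(row["label"]), start, end))
        expected = 0
        for s in segs:
            if s.start_frame != expected:
                raise ValueError(
                    f"label intervals must tile without gaps; gap before {s.start_frame / rate:.3f} s"
                )
            expected = s.end_frame
        labels = np.concatenate(
            [np.full(s.n_frames, int(s.activity), dtype=np.int64) for s in segs]
        )
    elif "label" in df.columns:
        labels = np.array(
            [int(ActivityClass.from_token(tok)) for tok in df["label"]], dtype=np.int64
        )
    else:
        raise ValueError("label file needs either (start_s,end_s,label) or a label column")
    return LabelSequence(labels, sample_rate=rate, provenance=provenance)


# ---------------------------------------------------------------------------
# lap tables

_LAP_COLUMNS = [
    "subject", "session", "block_index", "lap_index", "technique",
    "lap_type", "start_s", "end_s", "duration_s",
]


def write_lap_table(laps: list[LapRecord], path) -> None:
    """Lap table CSV; durations keep >= 4 decimals so the 0.02 s working
    resolution survives a round trip."""
    rows = [
        {
            "subject": lap.subject_id, "session": lap.session_id,
            "block_index": lap.block_index, "lap_index": lap.lap_index,
            "technique": lap.technique.short, "lap_type": lap.lap_type,
            "start_s": lap.start_s, "end_s": lap.end_s,
            "duration_s": lap.duration_s,
        }
        for lap in laps
    ]
    df = pd.DataFrame(rows, columns=_LAP_COLUMNS)
    df.to_csv(path, index=False, float_format="%.6f")


def read_lap_table(path, sample_rate: float = 50.0) -> list[LapRecord]:
    df = pd.read_csv(path)
    laps = []
    for _, row in df.iterrows():
        start = int(round(float(row["start_s"]) * sample_rate))
        end = int(round(float(row["end_s"]) * sample_rate))
        laps.append(
            LapRecord(
                technique=ActivityClass.from_token(row["technique"]),
                lap_type=str(row["lap_type"]),
                start_frame=start, end_frame=end, sample_rate=sample_rate,
                block_index=int(row["block_index"]), lap_index=int(row["lap_index"]),
                subject_id="" if pd.isna(row["subject"]) else str(row["subject"]),
                session_id="" if pd.isna(row["session"]) else str(row["session"]),
            )
        )
    return laps


# ---------------------------------------------------------------------------
# model bundles

def save_model(clf: SwimClassifier, bundle_dir) -> Path:
    """Persist weights + configs + scaler as a versioned bundle directory."""
    d = Path(bundle_dir)
    d.mkdir(parents=True, exist_ok=True)
    weights = clf.net.get_weights()
    np.savez(d / "weights.npz", **{f"w{i:03d}": w for i, w in enumerate(weights)})
    meta = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "classes": {c.name: int(c) for c in ActivityClass},
        "model_config": dataclasses.asdict(clf.config),
        "training_config": (
            dataclasses.asdict(clf.training_config) if clf.training_config else None
        ),
        "history": clf.history,
        "scaler": clf.scaler.to_dict() if clf.scaler else None,
    }
    (d / "bundle.json").write_text(json.dumps(meta, indent=2))
    return d


def load_model(bundle_dir) -> SwimClassifier:
    d = Path(bundle_dir)
    meta = json.loads((d / "bundle.json").read_text())
    if meta["format_version"] != BUNDLE_FORMAT_VERSION:
        raise ValueError(f"unsupported bundle format {meta['format_version']}")
    mc = meta["model_config"]
    mc["units"] = tuple(mc["units"])
    cfg = ModelConfig(**mc)
    clf = build_model(cfg, seed=0)
    with np.load(d / "weights.npz") as z:
        weights = [z[k] for k in sorted(z.files)]
    clf.net.set_weights(weights)
    if meta.get("scaler"):
        clf.scaler = ChannelScaler.from_dict(meta["scaler"])
    if meta.get("training_config"):
        clf.training_config = TrainingConfig(**meta["training_config"])
    clf.history = meta.get("history", {})
    return clf


# ---------------------------------------------------------------------------
# bundles of session files

@dataclasses.dataclass
class SessionBundle:
    """Paths of one session's artifacts plus its metadata."""

    recording_path: Path
    label_path: Path | None = None
    lap_table_path: Path | None = None
    subject_id: str = "S00"
    session_id: str = "sess0"
    sample_rate: float = 280.0

    def load(self):
        rec = read_imu_csv(
            self.recording_path, sample_rate=self.sample_rate,
            subject_id=self.subject_id, session_id=self.session_id,
        )
        if abs(rec.sample_rate - self.sample_rate) > 1e-6 * self.sample_rate:
            raise ValueError(
                f"declared rate {self.sample_rate} Hz does not match file "
                f"({rec.sample_rate:.6f} Hz)"
            )
        labels = (
            read_labels(self.label_path, rate=rec.sample_rate)
            if self.label_path
            else None
        )
        laps = (
            read_lap_table(self.lap_table_path, sample_rate=rec.sample_rate)
            if self.lap_table_path
            else None
        )
        return rec, labels, laps
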