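"""Sliding-window segmentation into the classifier's 3-D input tensor.

A window spans 90 frames of the 50 Hz working-rate signal (1.8 s) and is
labelled with the class of its median frame, index 45 of 0..89. With edge
padding enabled (boundary frames replicated) every frame of the recording
receives exactly one window centred on it, so the classifier can emit a
prediction at every 0.02 s time step.

Tensor layout: the default ``layout="paper"`` feeds the recurrent network
with the 6 IMU channels as the sequence axis and the 90-frame window as the
per-step feature vector — the only layout consistent with the published
per-layer parameter counts of the reference architecture. The conventional
alternative (90 time steps of 6 features) is available as
``layout="frames_as_time"`` but produces a different parameter budget.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .activities import ImuRecording, LabelSequence, N_CLASSES

__all__ = ["WindowBatch", "make_windows", "shuffle_windows", "WINDOW_FRAMES", "MEDIAN_INDEX"]

WINDOW_FRAMES = 90
MEDIAN_INDEX = 45  # 0-based index of the median frame in a 90-frame window

LAYOUTS = ("paper", "frames_as_time")


@dataclass
class WindowBatch:
    """A stack of windows ready for the network.

    tensor: (n, 6, 90) for layout "paper" or (n, 90, 6) for
    "frames_as_time"; targets: class code of each window's median frame
    (None for unlabeled data); frame_index: the median (centre) frame of
    each window in the source recording's frame numbering.
    """

    tensor: np.ndarray
    frame_index: np.ndarray
    targets: np.ndarray | None = None
    layout: str = "paper"
    window_length: int = WINDOW_FRAMES

    def __post_init__(self) -> None:
        if self.layout not in LAYOUTS:
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.tensor.ndim != 3 or self.tensor.shape[0] < 1:
            raise ValueError("tensor must be (n >= 1, steps, features)")
        if self.targets is not None:
            self.targets = np.asarray(self.targets, dtype=np.int64)
            if self.targets.shape != (self.tensor.shape[0],):
                raise ValueError("targets must be one code per window")
            if self.targets.size and (
                self.targets.min() < 0 or self.targets.max() >= N_CLASSES
            ):
                raise ValueError("target codes must lie in 0..7")

    @property
    def n_windows(self) -> int:
        return self.tensor.shape[0]


def make_windows(
    rec: ImuRecording,
    labels: LabelSequence | None = None,
    stride: int = 1,
    pad_edges: bool = True,
    window: int = WINDOW_FRAMES,
    layout: str = "paper",
    dtype=np.float32,
) -> WindowBatch:
    """Cut a preprocessed recording into overlapping windows.

    With ``pad_edges`` the first/last ``window//2`` frames are replicated so
    a window exists centred on every stride-th frame; without padding,
    windows start at frames 0, stride, ... up to ``frames - window``.
    """
    if labels is not None and labels.n_frames != rec.n_frames:
        raise ValueError("labels must have one entry per recording frame")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    center = window // 2  # index of the median frame within a window
    x = rec.samples
    n = rec.n_frames
    if pad_edges:
        x = np.pad(x, ((center, window - center - 1), (0, 0)), mode="edge")
        centers = np.arange(0, n, stride)
    else:
        if n < window:
            raise ValueError(
                f"recording of {n} frames is shorter than one {window}-frame window"
            )
        centers = np.arange(center, n - (window - center - 1), stride)
    starts = centers - center if not pad_edges else centers
    # sliding_window_view gives (n - window + 1, window, 6) views; index the
    # needed starts then copy into the requested layout.
    view = np.lib.stride_tricks.sliding_window_view(x, window, axis=0)
    # view shape: (num_positions, 6, window)
    wins = view[starts]  # (n_windows, 6, window)
    if layout == "paper":
        tensor = np.ascontiguousarray(wins, dtype=dtype)
    elif layout == "frames_as_time":
        tensor = np.ascontiguousarray(np.swapaxes(wins, 1, 2), dtype=dtype)
    else:
        raise ValueError(f"unknown layout {layout!r}")
    targets = None
    if labels is not None:
        targets = labels.labels[centers]
    return WindowBatch(tensor, frame_index=centers, targets=targets, layout=layout, window_length=window)


def shuffle_windows(batch: WindowBatch, seed: int) -> WindowBatch:
    """Deterministically permute windows and targets by the same permutation."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(batch.n_windows)
    return WindowBatch(
        batch.tensor[perm],
        frame_index=batch.frame_index[perm],
        targets=None if batch.targets is None else batch.targets[perm],
        layout=batch.layout,
        window_length=batch.window_length,
    )
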