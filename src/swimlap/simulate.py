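"""Synthetic labeled swimming sessions from a sacrum-mounted IMU.

Real pool sessions follow a rigid phase grammar: each exercise block starts
with a wall push, continues through an underwater glide into stroking, laps
are separated by turns (each followed by a glide, and optionally a new wall
push), and every block ends in rest. The generator emits, per session:

* a raw 280 Hz 6-channel recording (accelerometer in g, gyroscope in deg/s),
* the per-frame ground-truth activity labels aligned to it, and
* the true lap table (technique, START/MIDDLE/END type, boundary frames)
  computed from the phase schedule with the same anchor conventions the
  lap-timing module applies to label sequences.

Signal primitives are deliberately simple — per-phase orientation baselines
(gravity flips sign on the posterior axis between prone and supine strokes),
technique-specific harmonic oscillations, a half-sine acceleration impulse
for wall pushes and a gyroscope burst for turns, plus Gaussian (optionally
AR(1)-coloured) noise. They make the eight classes statistically separable
and spectrally plausible; no biomechanical fidelity is claimed. Pace scales
stroke frequency and amplitude up and phase durations down, emulating a
swimmer accelerating across repeats. Subjects differ by amplitude and
stroke-frequency scale factors, giving inter-subject variability.

All randomness flows from explicit integer seeds; identical inputs produce
bit-identical sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .activities import (
    ActivityClass,
    ImuRecording,
    LabelSequence,
    STROKES,
    labels_to_segments,
)
from .laptimes import LapRecord

__all__ = [
    "PhaseModel",
    "NoiseModel",
    "SubjectProfile",
    "Block",
    "SessionPlan",
    "SyntheticSession",
    "PACE_LEVELS",
    "default_phase_models",
    "medley_block",
    "pace_ladder_block",
    "protocol_plan",
    "generate_session",
    "generate_cohort",
    "check_grammar",
]

RAW_RATE = 280.0

PACE_LEVELS = ("low", "moderate", "high", "maximal")

#: Pace multipliers relative to moderate: phase durations shrink while
#: stroke frequency and movement amplitude grow as the swimmer speeds up.
PACE_DURATION_MULT = {"low": 1.15, "moderate": 1.0, "high": 0.90, "maximal": 0.82}
PACE_FREQ_MULT = {"low": 0.90, "moderate": 1.0, "high": 1.10, "maximal": 1.20}
PACE_AMP_MULT = {"low": 0.90, "moderate": 1.0, "high": 1.10, "maximal": 1.20}

_PRONE = np.array([0.05, 0.0, 0.95, 0.0, 0.0, 0.0])
_SUPINE = np.array([0.05, 0.0, -0.95, 0.0, 0.0, 0.0])
_STANDING = np.array([0.98, 0.0, 0.05, 0.0, 0.0, 0.0])


@dataclass
class PhaseModel:
    """Signal primitive for one activity class.

    Channel order everywhere is (ax, ay, az, gx, gy, gz). ``amplitudes``
    are oscillation amplitudes (g or deg/s), ``harmonics`` weight integer
    multiples of ``base_freq_hz``, ``impulse`` is a half-sine magnitude on
    the cranial acceleration axis (wall push), ``burst`` a half-sine
    rotation magnitude on the gyroscope (turn), ``decay_per_s`` an
    exponential amplitude decay across the phase (underwater glide).
    """

    activity: ActivityClass
    duration_range_s: tuple[float, float]
    base_freq_hz: float = 0.0
    amplitudes: np.ndarray = field(default_factory=lambda: np.zeros(6))
    harmonics: tuple[tuple[int, float], ...] = ((1, 1.0),)
    baseline: np.ndarray = field(default_factory=lambda: _PRONE.copy())
    impulse: float = 0.0
    burst: float = 0.0
    decay_per_s: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.duration_range_s
        if lo <= 0 or hi < lo:
            raise ValueError("duration range must satisfy 0 < min <= max")
        if self.base_freq_hz < 0:
            raise ValueError("base frequency must be >= 0")
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.baseline = np.asarray(self.baseline, dtype=float)


@dataclass
class NoiseModel:
    """Additive sensor noise: white Gaussian per channel, optional AR(1)
    colouring and optional slow gyroscope drift (off by default)."""

    accel_sd_g: float = 0.05
    gyro_sd_dps: float = 5.0
    ar_coef: float = 0.0
    gyro_drift_dps_per_min: float = 0.0

    def __post_init__(self) -> None:
        if self.accel_sd_g < 0 or self.gyro_sd_dps < 0:
            raise ValueError("noise sd must be >= 0")
        if not 0.0 <= self.ar_coef < 1.0:
            raise ValueError("AR(1) coefficient must lie in [0, 1)")

    @property
    def sds(self) -> np.ndarray:
        return np.array([self.accel_sd_g] * 3 + [self.gyro_sd_dps] * 3)


def default_phase_models() -> dict[ActivityClass, PhaseModel]:
    """Placeholder primitives per phase; every value is config-overridable."""
    A = ActivityClass
    return {
        A.WALLPUSH: PhaseModel(A.WALLPUSH, (0.25, 0.45), impulse=1.3),
        A.UNDERWATER: PhaseModel(
            A.UNDERWATER, (2.0, 3.5), base_freq_hz=2.0,
            amplitudes=np.array([0.05, 0.0, 0.30, 0.0, 60.0, 0.0]),
            decay_per_s=0.5,
        ),
        A.BUTTERFLY: PhaseModel(
            A.BUTTERFLY, (14.0, 18.0), base_freq_hz=0.9,
            amplitudes=np.array([0.30, 0.05, 0.50, 5.0, 80.0, 5.0]),
            harmonics=((1, 1.0), (2, 0.5)),
        ),
        A.BACKSTROKE: PhaseModel(
            A.BACKSTROKE, (14.0, 18.0), base_freq_hz=0.7,
            amplitudes=np.array([0.10, 0.20, 0.15, 90.0, 10.0, 10.0]),
            baseline=_SUPINE.copy(),
        ),
        A.BREASTSTROKE: PhaseModel(
            A.BREASTSTROKE, (15.0, 19.0), base_freq_hz=0.55,
            amplitudes=np.array([0.45, 0.05, 0.25, 5.0, 45.0, 5.0]),
            harmonics=((1, 1.0), (2, 0.7)),
        ),
        A.FRONTCRAWL: PhaseModel(
            A.FRONTCRAWL, (13.0, 17.0), base_freq_hz=0.75,
            amplitudes=np.array([0.12, 0.25, 0.08, 70.0, 10.0, 10.0]),
            harmonics=((1, 1.0), (2, 0.3)),
        ),
        A.TURN: PhaseModel(A.TURN, (0.6, 1.0), burst=250.0),
        A.REST: PhaseModel(A.REST, (10.0, 10.0), baseline=_STANDING.copy()),
    }


@dataclass
class SubjectProfile:
    """Per-swimmer scale factors: movement amplitude, stroke frequency, and
    how strongly each pace level shortens phase durations."""

    subject_id: str = "S00"
    amplitude_scale: float = 1.0
    frequency_scale: float = 1.0
    pace_duration_mult: dict[str, float] = field(
        default_factory=lambda: dict(PACE_DURATION_MULT)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_scale <= 0 or self.frequency_scale <= 0:
            raise ValueError("scale factors must be > 0")
        mults = [self.pace_duration_mult[p] for p in PACE_LEVELS]
        if not all(a > b for a, b in zip(mults, mults[1:])):
            raise ValueError(
                "pace duration multipliers must strictly decrease from low to maximal"
            )


@dataclass
class Block:
    """One exercise block: an ordered list of (technique, pace) laps,
    terminated by a rest of ``rest_s`` seconds."""

    laps: list[tuple[ActivityClass, str]]
    rest_s: float = 60.0

    def __post_init__(self) -> None:
        if not self.laps:
            raise ValueError("block must contain at least one lap")
        for tech, pace in self.laps:
            if not ActivityClass(tech).is_stroke:
                raise ValueError(f"{ActivityClass(tech).name} is not a stroke technique")
            if pace not in PACE_LEVELS:
                raise ValueError(f"unknown pace level {pace!r}")
        if self.rest_s <= 0:
            raise ValueError("rest duration must be > 0")

    @classmethod
    def uniform(cls, technique: ActivityClass, n_laps: int, pace: str = "moderate",
                rest_s: float = 60.0) -> "Block":
        return cls([(technique, pace)] * n_laps, rest_s=rest_s)


def medley_block(pace: str = "moderate", rest_s: float = 60.0) -> Block:
    """One 4-lap medley in conventional order (BU, BA, BR, FR)."""
    return Block([(t, pace) for t in STROKES], rest_s=rest_s)


def pace_ladder_block(technique: ActivityClass, rest_s: float = 180.0) -> Block:
    """Four laps of one technique at increasing pace (low -> maximal)."""
    return Block([(technique, p) for p in PACE_LEVELS], rest_s=rest_s)


@dataclass
class SessionPlan:
    """Ordered exercise blocks plus session-wide generation options."""

    blocks: list[Block]
    post_turn_wallpush: bool = False
    phase_models: dict[ActivityClass, PhaseModel] = field(
        default_factory=default_phase_models
    )
    noise: NoiseModel = field(default_factory=NoiseModel)
    sample_rate: float = RAW_RATE

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("session plan must contain at least one block")


def protocol_plan() -> SessionPlan:
    """The default full-session structure: three moderate-pace medleys with
    short rests, then one pace-ladder 100 m per technique with long rests."""
    blocks = [medley_block(rest_s=60.0) for _ in range(3)]
    blocks += [pace_ladder_block(t, rest_s=180.0) for t in STROKES]
    return SessionPlan(blocks)


@dataclass
class SyntheticSession:
    recording: ImuRecording
    labels: LabelSequence
    lap_table: list[LapRecord]
    profile: SubjectProfile
    plan: SessionPlan

    @property
    def subject_id(self) -> str:
        return self.recording.subject_id


# ---------------------------------------------------------------------------
# signal synthesis

_CHANNEL_PHASE = np.arange(6) * (np.pi / 3.0)  # fixed per-channel phase offsets


def _phase_signal(model: PhaseModel, n: int, fs: float, profile: SubjectProfile,
                  pace: str, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n) / fs
    dur = n / fs
    out = np.tile(model.baseline, (n, 1))
    freq = model.base_freq_hz * profile.frequency_scale * PACE_FREQ_MULT[pace]
    amp = model.amplitudes * profile.amplitude_scale * PACE_AMP_MULT[pace]
    if freq > 0 and np.any(amp > 0):
        envelope = (
            np.exp(-model.decay_per_s * t)[:, None]
            if model.decay_per_s > 0
            else np.ones((n, 1))
        )
        phase0 = rng.uniform(0, 2 * np.pi)
        for k, w in model.harmonics:
            osc = np.sin(2 * np.pi * k * freq * t[:, None] + phase0 + _CHANNEL_PHASE)
            out += (w * amp) * osc * envelope
    if model.impulse > 0:
        out[:, 0] += model.impulse * profile.amplitude_scale * np.sin(np.pi * t / dur)
    if model.burst > 0:
        half = model.burst * profile.amplitude_scale * np.sin(np.pi * t / dur)
        out[:, 5] += half
        out[:, 3] += 0.4 * half
    return out


def _draw_duration(model: PhaseModel, rng: np.random.Generator,
                   dur_mult: float = 1.0) -> float:
    lo, hi = model.duration_range_s
    return rng.uniform(lo, hi) * dur_mult


# ---------------------------------------------------------------------------
# schedule construction

def _build_schedule(plan: SessionPlan, profile: SubjectProfile,
                    rng: np.random.Generator):
    """Lay out the session phase by phase.

    Returns (schedule, lap_rows): the schedule is a list of
    (activity, n_frames, pace) tuples; lap_rows are
    (block_index, technique, lap_type, start_frame, end_frame) computed from
    the boundary-anchor conventions during layout.
    """
    fs = plan.sample_rate
    pm = plan.phase_models
    A = ActivityClass
    schedule: list[tuple[ActivityClass, int, str]] = []
    lap_rows = []
    frame = 0

    def emit(activity: ActivityClass, dur_s: float, pace: str) -> tuple[int, int]:
        nonlocal frame
        n = max(1, int(round(dur_s * fs)))
        schedule.append((activity, n, pace))
        start = frame
        frame += n
        return start, frame

    for bi, block in enumerate(plan.blocks):
        first_pace = block.laps[0][1]
        dm = profile.pace_duration_mult
        _, wp_end = emit(A.WALLPUSH, _draw_duration(pm[A.WALLPUSH], rng, dm[first_pace]), first_pace)
        emit(A.UNDERWATER, _draw_duration(pm[A.UNDERWATER], rng, dm[first_pace]), first_pace)
        anchors = [wp_end]  # wallpush_end opens the first lap
        for li, (tech, pace) in enumerate(block.laps):
            emit(tech, _draw_duration(pm[tech], rng, dm[pace]), pace)
            last = li == len(block.laps) - 1
            if last:
                break
            next_pace = block.laps[li + 1][1]
            tu_start, tu_end = emit(A.TURN, _draw_duration(pm[A.TURN], rng, dm[next_pace]), next_pace)
            if plan.post_turn_wallpush:
                _, pwp_end = emit(A.WALLPUSH, _draw_duration(pm[A.WALLPUSH], rng, dm[next_pace]), next_pace)
                un_start, _ = emit(A.UNDERWATER, _draw_duration(pm[A.UNDERWATER], rng, dm[next_pace]), next_pace)
            else:
                pwp_end = None
                un_start, _ = emit(A.UNDERWATER, _draw_duration(pm[A.UNDERWATER], rng, dm[next_pace]), next_pace)
            # boundary anchor: technique-specific convention
            if tech in (A.BUTTERFLY, A.BREASTSTROKE):
                anchors.append(tu_start)
            else:  # front crawl / backstroke
                anchors.append(pwp_end if pwp_end is not None else un_start)
        rs_start, _ = emit(A.REST, block.rest_s, "moderate")
        anchors.append(rs_start)
        n_laps = len(anchors) - 1
        for k in range(n_laps):
            if k == n_laps - 1:
                lap_type = "END"
            elif k == 0:
                lap_type = "START"
            else:
                lap_type = "MIDDLE"
            lap_rows.append((bi, block.laps[k][0], lap_type, anchors[k], anchors[k + 1]))
    return schedule, lap_rows


def generate_session(
    plan: SessionPlan,
    profile: SubjectProfile,
    seed: int,
    session_id: str = "sess0",
) -> SyntheticSession:
    """Generate one labeled session; bit-identical for identical inputs."""
    rng = np.random.default_rng(seed)
    fs = plan.sample_rate
    schedule, lap_rows = _build_schedule(plan, profile, rng)
    n_total = sum(n for _, n, _ in schedule)
    samples = np.empty((n_total, 6))
    labels = np.empty(n_total, dtype=np.int64)
    pos = 0
    for activity, n, pace in schedule:
        samples[pos : pos + n] = _phase_signal(
            plan.phase_models[activity], n, fs, profile, pace, rng
        )
        labels[pos : pos + n] = int(activity)
        pos += n
    noise = rng.normal(0.0, 1.0, size=(n_total, 6)) * plan.noise.sds
    if plan.noise.ar_coef > 0:
        from scipy.signal import lfilter

        noise = lfilter([1.0], [1.0, -plan.noise.ar_coef], noise, axis=0)
    samples += noise
    if plan.noise.gyro_drift_dps_per_min > 0:
        drift = plan.noise.gyro_drift_dps_per_min * (np.arange(n_total) / fs / 60.0)
        samples[:, 3:] += drift[:, None]
    rec = ImuRecording(
        samples, sample_rate=fs, subject_id=profile.subject_id,
        session_id=session_id, preprocessed=False,
    )
    seq = LabelSequence(labels, sample_rate=fs, provenance="ground_truth")
    lap_table = [
        LapRecord(
            technique=tech, lap_type=lap_type, start_frame=a, end_frame=b,
            sample_rate=fs, block_index=bi, lap_index=i,
            subject_id=profile.subject_id, session_id=session_id,
        )
        for i, (bi, tech, lap_type, a, b) in enumerate(lap_rows)
    ]
    return SyntheticSession(rec, seq, lap_table, profile, plan)


def generate_cohort(
    n_subjects: int,
    plan_template: SessionPlan | None = None,
    seed: int = 0,
) -> list[SyntheticSession]:
    """One session per subject, with reproducibly drawn subject profiles.

    Subjects differ in amplitude and stroke-frequency scales (inter-subject
    variability); each session follows the plan template, which by default
    spans all four pace levels (intra-subject variability).
    """
    if n_subjects < 3:
        raise ValueError("cohort needs at least 3 subjects for subject-wise splits")
    plan = plan_template or protocol_plan()
    rng = np.random.default_rng(seed)
    sessions = []
    for i in range(n_subjects):
        mults = {
            p: PACE_DURATION_MULT[p] * rng.uniform(0.98, 1.02) for p in PACE_LEVELS
        }
        vals = sorted((mults[p] for p in PACE_LEVELS), reverse=True)
        mults = dict(zip(PACE_LEVELS, vals))
        profile = SubjectProfile(
            subject_id=f"S{i + 1:02d}",
            amplitude_scale=float(rng.uniform(0.8, 1.25)),
            frequency_scale=float(rng.uniform(0.85, 1.15)),
            pace_duration_mult=mults,
            seed=int(rng.integers(2**31)),
        )
        sessions.append(
            generate_session(plan, profile, seed=profile.seed, session_id=f"sess{i}")
        )
    return sessions


def check_grammar(seq: LabelSequence) -> bool:
    """True when the session's segments obey the block grammar
    WP UN stroke (TU [WP] UN stroke)* RS, with optional leading/trailing rest."""
    A = ActivityClass
    kinds = [s.activity for s in labels_to_segments(seq)]
    i, n = 0, len(kinds)
    while i < n and kinds[i] == A.REST:
        i += 1
    while i < n:
        if kinds[i] != A.WALLPUSH:
            return False
        i += 1
        if i >= n or kinds[i] != A.UNDERWATER:
            return False
        i += 1
        if i >= n or not kinds[i].is_stroke:
            return False
        i += 1
        while i < n and kinds[i] == A.TURN:
            i += 1
            if i < n and kinds[i] == A.WALLPUSH:
                i += 1
            if i >= n or kinds[i] != A.UNDERWATER:
                return False
            i += 1
            if i >= n or not kinds[i].is_stroke:
                return False
            i += 1
        if i >= n or kinds[i] != A.REST:
            return False
        i += 1
    return True
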