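"""Synthetic session generator: determinism, phase grammar, spectral
signatures and lap-table consistency."""

import numpy as np
import pytest

from swimlap.activities import ActivityClass, STROKES, labels_to_segments
from swimlap.laptimes import compute_lap_times
from swimlap.simulate import (
    Block,
    NoiseModel,
    SessionPlan,
    SubjectProfile,
    check_grammar,
    default_phase_models,
    generate_cohort,
    generate_session,
    medley_block,
    pace_ladder_block,
    protocol_plan,
)

from conftest import short_phase_models, short_plan

A = ActivityClass


class TestDeterminism:
    def test_same_inputs_bit_identical(self):
        plan = short_plan()
        prof = SubjectProfile("S01", amplitude_scale=1.1)
        s1 = generate_session(plan, prof, seed=9)
        s2 = generate_session(plan, prof, seed=9)
        assert np.array_equal(s1.recording.samples, s2.recording.samples)
        assert np.array_equal(s1.labels.labels, s2.labels.labels)
        assert [(l.start_frame, l.end_frame) for l in s1.lap_table] == [
            (l.start_frame, l.end_frame) for l in s2.lap_table
        ]

    def test_cohort_reproducible(self):
        c1 = generate_cohort(3, short_plan(), seed=4)
        c2 = generate_cohort(3, short_plan(), seed=4)
        for a, b in zip(c1, c2):
            assert np.array_equal(a.recording.samples, b.recording.samples)


class TestStructure:
    def test_four_lap_block_typed_start_middle_middle_end(self):
        plan = short_plan(laps_per_block=4)
        s = generate_session(plan, SubjectProfile("S01"), seed=0)
        assert [l.lap_type for l in s.lap_table] == ["START", "MIDDLE", "MIDDLE", "END"]
        assert all(l.technique == A.FRONTCRAWL for l in s.lap_table)

    def test_zero_block_plan_rejected(self):
        with pytest.raises(ValueError, match="at least one block"):
            SessionPlan([])

    def test_labels_and_recording_aligned(self, micro_session):
        assert micro_session.labels.n_frames == micro_session.recording.n_frames
        assert micro_session.labels.sample_rate == micro_session.recording.sample_rate

    def test_grammar_on_random_plans(self):
        rng = np.random.default_rng(17)
        pm = short_phase_models()
        for i in range(100):
            n_blocks = int(rng.integers(1, 4))
            blocks = []
            for _ in range(n_blocks):
                tech = STROKES[int(rng.integers(4))]
                blocks.append(Block.uniform(tech, int(rng.integers(1, 4)), rest_s=3.0))
            plan = SessionPlan(
                blocks, phase_models=pm,
                post_turn_wallpush=bool(rng.integers(2)),
            )
            s = generate_session(plan, SubjectProfile("S01"), seed=int(rng.integers(2**31)))
            assert check_grammar(s.labels), f"grammar violated on random plan {i}"

    def test_segment_boundaries_match_schedule_to_the_frame(self, micro_session):
        # every label transition is a genuine phase switch: segments decode
        # into the planned phase order for a 4-lap medley
        kinds = [s.activity for s in labels_to_segments(micro_session.labels)]
        expected = [A.WALLPUSH, A.UNDERWATER, A.BUTTERFLY]
        for tech in (A.BACKSTROKE, A.BREASTSTROKE, A.FRONTCRAWL):
            expected += [A.TURN, A.UNDERWATER, tech]
        expected += [A.REST]
        assert kinds == expected


class TestSignals:
    def test_stroke_frequency_spectral_peak(self):
        # front crawl configured at 0.7 Hz: dominant gyro-x peak in [0.6, 0.8]
        pm = default_phase_models()
        pm[A.FRONTCRAWL].base_freq_hz = 0.7
        plan = SessionPlan([Block.uniform(A.FRONTCRAWL, 1, rest_s=5.0)],
                           phase_models=pm, noise=NoiseModel(accel_sd_g=0.01, gyro_sd_dps=1.0))
        s = generate_session(plan, SubjectProfile("S01"), seed=2)
        seg = next(x for x in labels_to_segments(s.labels) if x.activity == A.FRONTCRAWL)
        gx = s.recording.samples[seg.start_frame : seg.end_frame, 3]
        gx = gx - gx.mean()
        freqs = np.fft.rfftfreq(gx.size, d=1.0 / 280.0)
        power = np.abs(np.fft.rfft(gx)) ** 2
        peak = freqs[np.argmax(power)]
        assert 0.6 <= peak <= 0.8

    def test_backstroke_is_supine(self, micro_session):
        segs = labels_to_segments(micro_session.labels)
        ba = next(s for s in segs if s.activity == A.BACKSTROKE)
        az = micro_session.recording.samples[ba.start_frame : ba.end_frame, 2]
        assert az.mean() < -0.5  # gravity flips sign on the posterior axis


class TestCohort:
    def test_profiles_pairwise_distinct(self):
        cohort = generate_cohort(3, short_plan(), seed=0)
        scales = [(s.profile.amplitude_scale, s.profile.frequency_scale) for s in cohort]
        assert len(set(scales)) == 3

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="3 subjects"):
            generate_cohort(2, short_plan(), seed=0)

    def test_class_balance_rest_and_strokes_outnumber_wallpush(self):
        cohort = generate_cohort(3, short_plan(n_blocks=2, laps_per_block=3), seed=1)
        counts = np.zeros(8)
        for s in cohort:
            counts += np.bincount(s.labels.labels, minlength=8)
        wp = counts[int(A.WALLPUSH)]
        assert counts[int(A.REST)] > wp
        assert counts[int(A.FRONTCRAWL)] > wp


class TestLapTableOracle:
    @pytest.mark.parametrize("post_turn_wp", [False, True])
    def test_laptimes_from_ground_truth_match_generator_table(self, post_turn_wp):
        plan = SessionPlan(
            [medley_block(rest_s=10.0), pace_ladder_block(A.FRONTCRAWL, rest_s=10.0)],
            phase_models=short_phase_models(), post_turn_wallpush=post_turn_wp,
        )
        s = generate_session(plan, SubjectProfile("S03"), seed=21)
        derived = compute_lap_times(s.labels)
        assert len(derived) == len(s.lap_table)
        for d, t in zip(derived, s.lap_table):
            assert d.technique == t.technique
            assert d.lap_type == t.lap_type
            assert abs(d.start_frame - t.start_frame) <= 1
            assert abs(d.end_frame - t.end_frame) <= 1

    def test_protocol_plan_shape(self):
        plan = protocol_plan()
        assert len(plan.blocks) == 7  # 3 medleys + 4 pace ladders
        assert sum(len(b.laps) for b in plan.blocks) == 28
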