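"""Shared fixtures: small synthetic sessions and cohorts.

Unit-test fixtures use deliberately short phase durations so each test
stays fast; the acceptance suite uses protocol-scale sessions.
"""

from __future__ import annotations

import numpy as np
import pytest

from swimlap.activities import ActivityClass, STROKES
from swimlap.simulate import (
    Block,
    SessionPlan,
    SubjectProfile,
    default_phase_models,
    generate_session,
    medley_block,
)


def short_phase_models():
    """Phase models with stroke bouts shortened to a few seconds."""
    pm = default_phase_models()
    for s in STROKES:
        pm[s].duration_range_s = (4.0, 6.0)
    pm[ActivityClass.UNDERWATER].duration_range_s = (1.5, 2.0)
    return pm


def short_plan(n_blocks: int = 1, laps_per_block: int = 2, rest_s: float = 5.0,
               technique: ActivityClass = ActivityClass.FRONTCRAWL,
               post_turn_wallpush: bool = False) -> SessionPlan:
    blocks = [
        Block.uniform(technique, laps_per_block, rest_s=rest_s)
        for _ in range(n_blocks)
    ]
    return SessionPlan(blocks, phase_models=short_phase_models(),
                       post_turn_wallpush=post_turn_wallpush)


@pytest.fixture(scope="session")
def micro_session():
    """One short medley session (4 laps, ~30 s of swimming)."""
    plan = SessionPlan([medley_block(rest_s=8.0)], phase_models=short_phase_models())
    return generate_session(plan, SubjectProfile("S01"), seed=42)


@pytest.fixture(scope="session")
def fr_session():
    """A 4-lap front-crawl block with realistic phase durations."""
    plan = SessionPlan([Block.uniform(ActivityClass.FRONTCRAWL, 4, rest_s=15.0)])
    return generate_session(plan, SubjectProfile("S02"), seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
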