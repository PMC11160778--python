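import numpy as np
import pandas as pd
import pytest

from oddsearch import GenerativeParams, generate_session


def make_session(colors=None, quads=None, outcomes=None, pts=None,
                 subject="s", session="sess0"):
    """Build a minimal ordered trial table from explicit per-trial values.

    Any unspecified attribute is filled with a constant; ``outcomes`` fixes
    ``correct`` by setting the choice quadrant to match (or not) the target.
    """
    n = max(len(x) for x in (colors, quads, outcomes, pts) if x is not None)
    colors = list(colors) if colors is not None else ["red"] * n
    quads = list(quads) if quads is not None else ["right"] * n
    outcomes = list(outcomes) if outcomes is not None else [True] * n
    pts = list(pts) if pts is not None else [200.0] * n
    other = {"right": "up", "up": "left", "left": "down", "down": "right"}
    choice = [q if ok else other[q] for q, ok in zip(quads, outcomes)]
    gap = [50.0] * n
    rt = [g + p for g, p in zip(gap, pts)]
    return pd.DataFrame({
        "subject_id": subject, "session_id": session,
        "trial_index": np.arange(n),
        "gap_ms": gap, "rt_ms": rt, "pt_ms": pts,
        "target_color": colors, "target_quadrant": quads,
        "choice_quadrant": choice,
        "correct": list(outcomes),
        "target_x_deg": np.nan, "target_y_deg": np.nan,
    })


def random_session(rng, n, session="r0"):
    colors = rng.choice(["red", "green"], n)
    quads = rng.choice(["right", "up", "left", "down"], n)
    outcomes = rng.random(n) < 0.6
    pts = rng.uniform(-50, 400, n)
    return make_session(colors, quads, outcomes, pts, session=session)


@pytest.fixture(scope="session")
def history_free_trials():
    """50k-trial history-free session shared across read-only tests."""
    params = GenerativeParams(n_trials=50_000, seed=101).history_free()
    trials, _ = generate_session(params)
    return trials


@pytest.fixture(scope="session")
def default_trials():
    """30k trials with the default history couplings."""
    params = GenerativeParams(n_trials=30_000, seed=202)
    trials, _ = generate_session(params)
    return trials
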