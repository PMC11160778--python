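import numpy as np
import pandas as pd
import pytest

from oddsearch import (classify_color_history, classify_history,
                       classify_joint_history, classify_location_history,
                       classify_outcome_history, classify_single_event,
                       enumerate_sequences, sequence_labels)
from oddsearch.history import single_event_name

from conftest import make_session, random_session
from oracles import brute_run_label, brute_sequence_label, brute_single_event


class TestColorHistory:

    def test_homogeneous_repeat_is_member_at_all_shallower_depths(self):
        trials = make_session(colors=["red", "red", "red"])
        assert classify_color_history(trials, 2).iloc[-1] == "S"
        assert classify_color_history(trials, 1).iloc[-1] == "S"

    def test_switch_is_1d(self):
        for colors in (["green", "red"], ["red", "green"]):
            trials = make_session(colors=colors)
            assert classify_color_history(trials, 1).iloc[-1] == "D"

    def test_first_trial_has_no_history(self):
        trials = make_session(colors=["red", "green", "red"])
        for n in (1, 2, 3):
            assert classify_color_history(trials, n).iloc[0] is None

    def test_mixed_run_is_neither(self):
        trials = make_session(colors=["red", "green", "red"])
        assert classify_color_history(trials, 2).iloc[-1] is None


class TestLocationHistory:

    @pytest.mark.parametrize("quads, N, expected", [
        (["up", "right"], 1, "D"),
        (["left", "down", "right"], 2, "D"),    # predecessors may differ
        (["down", "down", "down"], 2, "S"),
        (["up", "up", "left"], 2, "D"),         # repeats among predecessors ok
    ])
    def test_examples(self, quads, N, expected):
        trials = make_session(quads=quads)
        assert classify_location_history(trials, N).iloc[-1] == expected

    def test_depth1_is_exhaustive_dichotomy(self):
        rng = np.random.default_rng(1)
        trials = random_session(rng, 40)
        labels = classify_location_history(trials, 1)
        assert labels.iloc[0] is None
        assert labels.iloc[1:].isin(["S", "D"]).all()


class TestOutcomeHistory:

    @pytest.mark.parametrize("outcomes, N, expected", [
        ([True, True], 1, "C"),
        ([False, False, True], 2, "E"),
        ([True, False, True], 2, None),
    ])
    def test_examples(self, outcomes, N, expected):
        trials = make_session(outcomes=outcomes)
        assert classify_outcome_history(trials, N).iloc[-1] == expected


class TestJointHistory:

    def test_same_color_after_reward(self):
        trials = make_session(colors=["red", "red"], outcomes=[True, True])
        joint = classify_joint_history(trials, ("color", "outcome"), 1)
        assert joint.iloc[-1] == "SC"

    def test_different_color_after_error(self):
        trials = make_session(colors=["red", "green"], outcomes=[False, True])
        joint = classify_joint_history(trials, ("color", "outcome"), 1)
        assert joint.iloc[-1] == "DE"

    def test_triple_label(self):
        trials = make_session(colors=["red", "red"], quads=["up", "up"],
                              outcomes=[True, True])
        joint = classify_joint_history(
            trials, ("color", "location", "outcome"), 1)
        assert joint.iloc[-1] == "SSC"

    def test_any_inhomogeneous_dimension_voids_the_label(self):
        trials = make_session(colors=["red", "red", "red"],
                              outcomes=[True, False, True])
        joint = classify_joint_history(trials, ("color", "outcome"), 2)
        assert joint.iloc[-1] is None

    def test_rejects_empty_dims(self):
        trials = make_session(colors=["red", "red"])
        with pytest.raises(ValueError):
            classify_joint_history(trials, (), 1)


class TestSingleEvent:

    def test_lagged_color_repeat(self):
        colors = ["red", "green", "green", "green", "green", "red"]
        trials = make_session(colors=colors)
        member = classify_single_event(trials, "color", "S", lag=5)
        assert member.iloc[-1]
        assert single_event_name("S", 5) == "1S4x"

    def test_lagged_location_switch(self):
        trials = make_session(quads=["up", "left", "right", "down"])
        member = classify_single_event(trials, "location", "D", lag=3)
        assert member.iloc[-1]
        assert single_event_name("D", 3) == "1D2x"

    def test_lag1_reduces_to_depth1_run(self):
        rng = np.random.default_rng(7)
        trials = random_session(rng, 60)
        for dim in ("color", "location"):
            run = classify_history(trials, dim, 1)
            for rel in ("S", "D"):
                member = classify_single_event(trials, dim, rel, lag=1)
                assert (member.to_numpy()
                        == (run == rel).to_numpy()).all()

    def test_lag_validation(self):
        trials = make_session(colors=["red", "red"])
        with pytest.raises(ValueError):
            classify_single_event(trials, "color", "S", lag=0)


class TestEnumeration:

    def test_pair_counts_and_depth1_labels(self):
        labels = enumerate_sequences(("color", "location"), 1)
        assert sorted(labels) == ["DD", "DS", "SD", "SS"]
        assert len(enumerate_sequences(("color", "location"), 2)) == 16
        assert len(enumerate_sequences(("color", "location", "outcome"), 1)) == 8

    def test_sequence_labels_live_in_the_enumeration(self):
        rng = np.random.default_rng(8)
        trials = random_session(rng, 50)
        for H in (1, 2):
            labs = sequence_labels(trials, ("color", "location"), H)
            universe = set(enumerate_sequences(("color", "location"), H))
            assert set(labs.dropna()) <= universe


class TestAgainstBruteForce:
    """Oracle equivalence on random multi-session data."""

    DIM_COL = {"color": "target_color", "location": "target_quadrant",
               "outcome": "correct"}

    def _sessions(self, seed, n_sessions=40):
        rng = np.random.default_rng(seed)
        return [random_session(rng, int(rng.integers(1, 51)), session=f"r{i}")
                for i in range(n_sessions)]

    def test_run_mode_matches(self):
        sessions = self._sessions(10)
        trials = pd.concat(sessions, ignore_index=True)
        for dim in ("color", "location", "outcome"):
            for N in (1, 2, 3, 4):
                got = classify_history(trials, dim, N).to_numpy()
                expected = []
                for s in sessions:
                    vals = list(s[self.DIM_COL[dim]])
                    expected += [brute_run_label(vals, i, N, dim)
                                 for i in range(len(vals))]
                assert list(got) == expected, (dim, N)

    def test_sequence_mode_matches(self):
        sessions = self._sessions(11)
        trials = pd.concat(sessions, ignore_index=True)
        dims = ("color", "location", "outcome")
        for H in (1, 2, 3):
            got = sequence_labels(trials, dims, H).to_numpy()
            expected = []
            for s in sessions:
                vl = {d: list(s[self.DIM_COL[d]]) for d in dims}
                expected += [brute_sequence_label(vl, dims, i, H)
                             for i in range(len(s))]
            assert list(got) == expected, H

    def test_single_event_matches(self):
        sessions = self._sessions(12)
        trials = pd.concat(sessions, ignore_index=True)
        for dim in ("color", "location"):
            for rel in ("S", "D"):
                for lag in (1, 2, 5):
                    got = classify_single_event(trials, dim, rel, lag)
                    expected = []
                    for s in sessions:
                        vals = list(s[self.DIM_COL[dim]])
                        expected += [brute_single_event(vals, i, lag, rel)
                                     for i in range(len(vals))]
                    assert list(got.to_numpy()) == expected


class TestInvariants:

    def test_nesting_and_disjointness(self):
        rng = np.random.default_rng(13)
        trials = random_session(rng, 200)
        for dim in ("color", "location", "outcome"):
            prev = None
            for N in (1, 2, 3):
                lab = classify_history(trials, dim, N)
                a, b = ("C", "E") if dim == "outcome" else ("S", "D")
                assert not ((lab == a) & (lab == b)).any()
                if prev is not None:
                    # membership at depth N+1 implies membership at depth N
                    assert ((lab.notna()) <= (prev.notna())).all()
                    assert (lab.dropna() == prev[lab.notna()]).all()
                prev = lab

    def test_session_order_invariance(self):
        rng = np.random.default_rng(14)
        sessions = [random_session(rng, 30, session=f"r{i}") for i in range(4)]
        fwd = pd.concat(sessions, ignore_index=True)
        rev = pd.concat(sessions[::-1], ignore_index=True)
        lab_f = classify_history(fwd, "color", 2)
        lab_r = classify_history(rev, "color", 2)
        key = ["session_id", "trial_index"]
        merged = pd.DataFrame({"f": lab_f.values}, index=pd.MultiIndex.from_frame(fwd[key]))
        merged_r = pd.DataFrame({"r": lab_r.values}, index=pd.MultiIndex.from_frame(rev[key]))
        joined = merged.join(merged_r)
        assert (joined["f"].fillna("-") == joined["r"].fillna("-")).all()
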