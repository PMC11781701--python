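"""Evaluation machinery: system accuracy, AUC, fold bookkeeping, window
accounting, and pseudo-online scoring with oracle decision streams."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brakesense.data import labels_of
from brakesense.evaluate import (
    PseudoOnlineConfig,
    n_windows,
    pairwise_auc,
    score_window_decisions,
    stratified_folds,
    system_accuracy,
)
from brakesense.simulate import SimulationConfig, simulate_session


class TestSystemAccuracy:
    def test_perfect_detection(self):
        assert system_accuracy(0.0, 1.0, 1.0) == 1.0

    def test_worst_case(self):
        assert system_accuracy(1.0, 0.0, 0.0) == 0.0

    def test_forced_arithmetic(self):
        assert system_accuracy(0.03, 0.97, 0.94) == pytest.approx(0.96)

    def test_printed_form_available(self):
        assert system_accuracy(0.0, 1.0, 1.0, printed_form=True) == pytest.approx(1 / 3)

    def test_strict_monotonicity_on_grid(self):
        grid = np.linspace(0.0, 1.0, 11)
        for fal in grid[:-1]:
            for h in grid[:-1]:
                assert system_accuracy(fal, h, 0.5) < system_accuracy(fal, h + 0.1, 0.5)
                assert system_accuracy(fal, 0.5, h) < system_accuracy(fal, 0.5, h + 0.1)
                assert system_accuracy(fal + 0.1, h, h) < system_accuracy(fal, h, h)

    def test_rates_validated(self):
        with pytest.raises(ValueError):
            system_accuracy(1.5, 0.5, 0.5)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1))
def test_system_accuracy_in_unit_interval(fal, he, hs):
    assert 0.0 <= system_accuracy(fal, he, hs) <= 1.0


class TestAuc:
    def test_perfect_separation(self):
        assert pairwise_auc(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, -1, -1])) == 1.0

    def test_printed_example_by_pair_counting(self):
        """pos {0.9, 0.8}, neg {0.7, 0.85}: 3 of 4 pos-neg pairs are ordered
        correctly."""
        scores = np.array([0.9, 0.8, 0.7, 0.85])
        labels = np.array([1, 1, -1, -1])
        assert pairwise_auc(scores, labels) == pytest.approx(3 / 4)

    def test_matches_bruteforce_pair_counting(self, rng):
        scores = rng.random(30)
        labels = np.where(rng.random(30) > 0.5, 1, -1)
        labels[:2] = [1, -1]
        pos, neg = scores[labels == 1], scores[labels == -1]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert pairwise_auc(scores, labels) == pytest.approx(wins / (len(pos) * len(neg)))

    def test_chance_level_for_independent_scores(self, rng):
        aucs = [
            pairwise_auc(rng.random(200), np.repeat([1, -1], 100)) for _ in range(20)
        ]
        assert abs(np.mean(aucs) - 0.5) < 0.03

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            pairwise_auc(np.array([0.1, 0.2]), np.array([1, 1]))


class TestFolds:
    def test_sixfold_stratification_contract(self, default_epochs):
        y = labels_of(default_epochs)
        folds = stratified_folds(y, 6, seed=0)
        for _, te in folds:
            assert len(te) == 15
            _, counts = np.unique(y[te], return_counts=True)
            assert counts.tolist() == [5, 5, 5]
        all_test = np.sort(np.concatenate([te for _, te in folds]))
        np.testing.assert_array_equal(all_test, np.arange(90))

    def test_class_smaller_than_folds_rejected(self):
        y = np.array(["a"] * 3 + ["b"] * 10)
        with pytest.raises(ValueError):
            stratified_folds(y, 6, seed=0)


def test_window_accounting():
    assert n_windows(10.0) == int(np.floor((10.0 - 1.0) / 0.06)) + 1
    assert n_windows(1.0) == 1
    assert n_windows(0.5) == 0


@pytest.fixture(scope="module")
def tiny_session():
    return simulate_session(SimulationConfig(seed=33, n_trials=6, n_hard_trials=3))


def _window_grid(session):
    fs = session.fs
    L = int(round(fs))
    step = int(round(0.06 * fs))
    ends = np.arange(L, session.n_samples + 1, step)
    return ends / fs


class TestOracleDecisionStreams:
    def test_always_normal_oracle(self, tiny_session):
        """A decoder that never alarms: no hits, no false alarms, Sa = 1/3."""
        t_end = _window_grid(tiny_session)
        decisions = np.full(len(t_end), "normal")
        m = score_window_decisions(tiny_session, t_end, decisions)
        assert m.hit_hard == 0.0 and m.hit_soft == 0.0 and m.fal == 0.0
        assert m.sa == pytest.approx(1 / 3)
        assert m.n_windows == len(t_end)

    def test_always_hard_oracle(self, tiny_session):
        """A decoder that always says hard: hits every hard event, misses all
        soft events, and every normal window is a false alarm."""
        t_end = _window_grid(tiny_session)
        decisions = np.full(len(t_end), "hard")
        m = score_window_decisions(tiny_session, t_end, decisions)
        assert m.hit_hard == 1.0
        assert m.hit_soft == 0.0
        assert m.fal == 1.0

    def test_hit_window_boundary(self, tiny_session):
        """Only windows ending within (stimulus, stimulus + 1.2 s] count."""
        ev = tiny_session.braking_events()[0]
        t_end = np.array([ev.stimulus_s - 0.01, ev.stimulus_s + 1.3])
        decisions = np.array([ev.kind, ev.kind])
        m = score_window_decisions(tiny_session, t_end, decisions)
        hit = m.hit_hard if ev.kind == "hard" else m.hit_soft
        assert hit == 0.0  # both windows fall outside the hit interval

    def test_advanced_time_uses_earliest_detection(self, tiny_session):
        ev = [e for e in tiny_session.braking_events() if e.kind == "hard"][0]
        t_end = np.array([ev.stimulus_s + 0.2, ev.stimulus_s + 0.4])
        decisions = np.array(["hard", "hard"])
        m = score_window_decisions(tiny_session, t_end, decisions)
        expected_ms = (ev.pedal_s - (ev.stimulus_s + 0.2)) * 1000.0
        # only this one event can be hit by these two windows
        assert m.at_hard_ms[0] == pytest.approx(expected_ms)

    def test_wrong_class_detection_is_not_a_false_positive(self, tiny_session):
        """A 'soft' decision during a hard event misses the event but does not
        enter the false-positive denominator."""
        ev = [e for e in tiny_session.braking_events() if e.kind == "hard"][0]
        t_end = np.array([ev.stimulus_s + 0.5])
        decisions = np.array(["soft"])
        m = score_window_decisions(tiny_session, t_end, decisions)
        assert m.hit_hard == 0.0
        assert m.n_normal_windows == 0 and m.fal == 0.0

    def test_no_events_session_reports_nan(self, caplog):
        session = simulate_session(
            SimulationConfig(seed=4, n_trials=2, n_hard_trials=0)
        )
        # strip the soft events to get a pure normal-driving session
        session.events = [e for e in session.events if e.kind == "trial_start"]
        t_end = _window_grid(session)
        with caplog.at_level("WARNING"):
            m = score_window_decisions(session, t_end, np.full(len(t_end), "normal"))
        assert np.isnan(m.hit_hard) and np.isnan(m.hit_soft) and np.isnan(m.sa)
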