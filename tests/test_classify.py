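import collections

import numpy as np
import pytest

from vsdd import (
    AnalysisConfig,
    BehaviorParams,
    NeuronParams,
    SlidingWindowSignalClassifier,
    simulate_behavior,
    simulate_neuron,
)
from vsdd.classify import (
    SignalSegment,
    WindowLabelSeries,
    classify_neuron,
    extract_segments,
    fit_single_predictor,
    mc_model_comparison,
    signal_latencies,
    transition_probabilities,
)
from vsdd.config import substream
from vsdd.exceptions import InsufficientDataError, ParameterError


class TestFitSinglePredictor:
    def test_exact_fit(self):
        V = np.arange(1.0, 7.0)
        b0, b1, r2, p = fit_single_predictor(V.copy(), V)
        assert b1 == pytest.approx(1.0)
        assert b0 == pytest.approx(0.0)
        assert r2 == pytest.approx(1.0)
        assert p == 0.0

    def test_constant_response(self):
        V = np.arange(1.0, 7.0)
        _, _, r2, p = fit_single_predictor(np.full(6, 3.0), V)
        assert r2 == 0.0 and p == 1.0

    def test_six_point_hand_oracle(self):
        # closed-form normal equations on the 6 points, computed independently
        F = np.array([2.0, 3.0, 5.0, 4.0, 6.0, 8.0])
        V = np.arange(1.0, 7.0)
        svv = np.sum((V - V.mean()) ** 2)
        svf = np.sum((V - V.mean()) * (F - F.mean()))
        sff = np.sum((F - F.mean()) ** 2)
        r2_hand = svf**2 / (svv * sff)
        assert r2_hand == pytest.approx(1083.0 / 1225.0)  # = 0.884081632653...
        b0, b1, r2, _ = fit_single_predictor(F, V)
        assert b1 == pytest.approx(svf / svv)
        assert r2 == pytest.approx(r2_hand)

    def test_constant_predictor_raises(self):
        with pytest.raises(ParameterError):
            fit_single_predictor(np.arange(6.0), np.full(6, 2.0))


class TestMcModelComparison:
    def _inputs(self, n=120, seed=0):
        rng = np.random.default_rng(seed)
        V = rng.integers(1, 7, n).astype(float)
        C = (V > 3.5).astype(float)
        flip = rng.random(n) < 0.2
        C[flip] = 1 - C[flip]
        baseline = rng.poisson(5, n).astype(float)
        return V, C, baseline

    def test_noise_free_value_signal(self):
        V, C, baseline = self._inputs()
        cfg = AnalysisConfig(n_shuffle=1000, seed=1)
        res = mc_model_comparison(V.copy(), V, C, baseline, cfg)
        assert res.exceed_count == 1000
        assert res.label == "value"

    def test_constant_rate_unlabeled(self):
        V, C, baseline = self._inputs()
        cfg = AnalysisConfig(n_shuffle=200, seed=2)
        res = mc_model_comparison(np.full(len(V), 7.0), V, C, baseline, cfg)
        assert res.dr2_obs == 0.0
        assert res.label == "none"

    def test_choice_signal_mirror(self):
        # F = 10*C with V independent of C: symmetric mirror of the value case
        rng = np.random.default_rng(3)
        n = 120
        V = rng.integers(1, 7, n).astype(float)
        C = (rng.random(n) < 0.5).astype(float)
        baseline = rng.poisson(5, n).astype(float)
        cfg = AnalysisConfig(n_shuffle=1000, seed=3)
        res = mc_model_comparison(10.0 * C, V, C, baseline, cfg)
        assert res.exceed_count == 0
        assert res.label == "choice"

    def test_constant_baseline_warns_and_labels_via_obs(self):
        V, C, _ = self._inputs()
        cfg = AnalysisConfig(n_shuffle=200, seed=4)
        with pytest.warns(RuntimeWarning, match="baseline"):
            res = mc_model_comparison(V.copy(), V, C, np.zeros(len(V)), cfg)
        assert res.exceed_count == 200  # dr2_obs > 0 beats an all-zero null

    def test_exceed_count_uniform_under_exchangeable_null(self):
        # with F itself exchangeable noise, exceed_count/n should be ~uniform
        rng = np.random.default_rng(5)
        cfg = AnalysisConfig(n_shuffle=200, seed=5)
        u = []
        for rep in range(200):
            V = rng.integers(1, 7, 60).astype(float)
            C = (rng.random(60) < 0.5).astype(float)
            F = rng.poisson(5, 60).astype(float)
            baseline = rng.poisson(5, 60).astype(float)
            res = mc_model_comparison(F, V, C, baseline,
                                      cfg, rng=substream(5, "t", rep))
            u.append(res.exceed_count / cfg.n_shuffle)
        from scipy.stats import kstest

        assert kstest(u, "uniform").pvalue > 0.01


def _series(labels, step=1):
    labels = np.asarray(labels)
    return WindowLabelSeries(
        neuron_id="n1",
        window_starts=np.arange(len(labels)) * step,
        labels=labels,
        dr2_obs=np.zeros(len(labels)),
        exceed_count=np.zeros(len(labels), int),
        fit_p_value=np.zeros(len(labels)),
        fit_p_choice=np.zeros(len(labels)),
        n_shuffle=1000,
    )


class TestExtractSegments:
    def test_forty_window_run_found(self):
        labels = ["none"] * 100 + ["value"] * 40 + ["none"] * 60
        segs = extract_segments(_series(labels), 40)
        assert len(segs) == 1
        assert segs[0].kind == "value"
        assert segs[0].latency_ms == 100.0

    def test_39_windows_insufficient(self):
        labels = ["none"] * 100 + ["value"] * 39 + ["none"] * 60
        assert extract_segments(_series(labels), 40) == []

    def test_two_runs_two_segments(self):
        labels = ["none"] * 50 + ["value"] * 50 + ["none"] * 300 + ["choice"] * 61
        segs = extract_segments(_series(labels), 40)
        assert [(s.kind, s.latency_ms) for s in segs] == [
            ("value", 50.0),
            ("choice", 400.0),
        ]


class TestTransitionProbabilities:
    def _seg(self, nid, kind, lat):
        return SignalSegment(neuron_id=nid, kind=kind, latency_ms=lat, end_ms=lat + 40)

    def test_counting(self):
        segs = [
            self._seg("a", "value", 200), self._seg("a", "choice", 500),
            self._seg("b", "value", 200), self._seg("b", "choice", 500),
            self._seg("c", "choice", 150), self._seg("c", "value", 400),
        ]
        table = transition_probabilities(segs)
        row = table[(table["from"] == "value") & (table["to"] == "choice")].iloc[0]
        assert row["n_both"] == 3
        assert row["p_forward"] == pytest.approx(2 / 3)
        assert row["p_backward"] == pytest.approx(1 / 3)

    def test_single_kind_neurons_empty(self):
        segs = [self._seg("a", "value", 100), self._seg("b", "choice", 300)]
        assert len(transition_probabilities(segs)) == 0

    def test_tie_counts_half(self):
        segs = [
            self._seg("a", "value", 300), self._seg("a", "choice", 300),
        ]
        table = transition_probabilities(segs)
        row = table.iloc[0]
        assert row["p_forward"] == pytest.approx(0.5)
        assert row["ties"] == 1


class TestSignalLatencies:
    def test_single_segment_identity(self):
        segs = [SignalSegment("a", "value", 120.0, 160.0)]
        lat, _ = signal_latencies(segs)
        assert list(lat["value"]) == [120.0]
        assert list(lat["choice"]) == []

    def test_empty_population(self):
        lat, tests = signal_latencies([])
        assert all(len(v) == 0 for v in lat.values())
        assert all(np.isnan(p) for p in tests.values())

    def test_release_alignment_subtracts_release(self):
        segs = [SignalSegment("a", "choice", 500.0, 600.0)]
        lat, _ = signal_latencies(
            segs, align="button_release", release_times={"a": 420.0}
        )
        assert list(lat["choice"]) == [80.0]


class TestClassifyNeuron:
    def test_pure_value_neuron_dominated_by_value_labels(self, desk_config):
        trials = simulate_behavior(BehaviorParams(n_trials=300), seed=21)
        params = NeuronParams(value_gain_hz=4.0, choice_gain_hz=0.0,
                              t_value_on_ms=100.0, t_switch_ms=1000.0)
        trains = simulate_neuron(params, trials, seed=21)
        series = classify_neuron(trains, trials, desk_config)
        late = series.labels[series.window_starts >= 100]
        counts = collections.Counter(late)
        assert counts["value"] / len(late) > 0.8

    def test_transition_neuron_value_then_choice(self, desk_config,
                                                 behavior_session, transition_neuron):
        series = classify_neuron(transition_neuron, behavior_session, desk_config)
        early = series.labels[
            (series.window_starts >= 150) & (series.window_starts < 350)
        ]
        late = series.labels[
            (series.window_starts >= 500) & (series.window_starts <= 850)
        ]
        assert collections.Counter(early).most_common(1)[0][0] == "value"
        assert collections.Counter(late).most_common(1)[0][0] == "choice"

    def test_too_few_trials_rejected(self, desk_config):
        trials = simulate_behavior(BehaviorParams(n_trials=5), seed=22)
        trains = simulate_neuron(NeuronParams(), trials, seed=22)
        with pytest.raises(InsufficientDataError):
            classify_neuron(trains, trials, desk_config)

    def test_label_exclusivity(self, desk_config, behavior_session, transition_neuron):
        series = classify_neuron(transition_neuron, behavior_session, desk_config)
        assert set(series.labels) <= {"value", "choice", "intermediate", "none"}

    def test_deterministic_given_seed(self, desk_config, behavior_session,
                                      transition_neuron):
        s1 = classify_neuron(transition_neuron, behavior_session, desk_config)
        s2 = classify_neuron(transition_neuron, behavior_session, desk_config)
        assert np.array_equal(s1.labels, s2.labels)
        assert np.array_equal(s1.exceed_count, s2.exceed_count)


class TestClassifierEstimator:
    def test_population_fit_segments_and_transitions(self, desk_config):
        trains, trials = [], []
        for j in range(6):
            t = simulate_behavior(
                BehaviorParams(n_trials=200), seed=j, session_id=f"s{j}"
            )
            trials.extend(t)
            trains.extend(
                simulate_neuron(NeuronParams(), t, seed=j, neuron_id=f"n{j}")
            )
        clf = SlidingWindowSignalClassifier(
            step_ms=desk_config.step_ms, n_shuffle=desk_config.n_shuffle, seed=0
        ).fit(trains, trials)
        assert set(clf.series_) == {f"n{j}" for j in range(6)}
        assert clf.counts_["value"] >= 5 and clf.counts_["choice"] >= 5
        row = clf.transitions_[
            (clf.transitions_["from"] == "value") & (clf.transitions_["to"] == "choice")
        ]
        assert len(row) == 1 and row.iloc[0]["p_forward"] >= 0.9
        assert np.median(clf.latencies_["value"]) < np.median(clf.latencies_["choice"])

    def test_sklearn_params_round_trip(self):
        clf = SlidingWindowSignalClassifier(step_ms=10, n_shuffle=200)
        params = clf.get_params()
        assert params["step_ms"] == 10
        clone = SlidingWindowSignalClassifier(**params)
        assert clone.get_params() == params
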