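"""Weighted objective, random search, and leave-two-out splits."""

from types import SimpleNamespace

import numpy as np
import pytest

from portalwatch.gru import RNNWeights, gru_step, l2_penalty
from portalwatch.metrics import MetricStream
from portalwatch.simulate import ErrorSpec, PatientCohortSpec, ValidationError
from portalwatch.training import (
    ObjectiveSpec,
    SearchConfig,
    TrainingCase,
    error_factor,
    importance_factor,
    make_splits,
    objective,
    output_penalty,
    random_search,
    segment_factor,
)


def case_from(values: np.ndarray, ranking: int = 0, pid: str = "P") -> TrainingCase:
    n = values.shape[0]
    stream = MetricStream(
        values=values,
        segment_map=np.arange(1, n + 1),
        patient_id=pid,
        error=ErrorSpec.none(),
        n_segments=n,
    )
    return TrainingCase(stream=stream, ranking=ranking, patient_id=pid)


class TestFactors:
    @pytest.mark.parametrize(
        "s,label,expected",
        [(1, "normal", 1.0), (162, "error", 1.0), (81, "error", 0.5), (162, "normal", 1 / 162)],
    )
    def test_segment_factor(self, s, label, expected):
        assert segment_factor(s, label) == pytest.approx(expected)

    def test_segment_factor_out_of_range(self):
        with pytest.raises(ValidationError):
            segment_factor(0, "normal")
        with pytest.raises(ValidationError):
            segment_factor(163, "error")

    def test_importance_and_error_factors(self):
        assert importance_factor("normal") == pytest.approx(1e-2)
        assert importance_factor("error") == pytest.approx(1e-6)
        assert error_factor(0) == 1.0
        assert error_factor(1) == 1.0  # 10^(1-1)
        assert error_factor(5) == pytest.approx(1e4)
        # the largest error carries the same combined case weight as a normal one
        assert importance_factor("error") * error_factor(5) == pytest.approx(
            importance_factor("normal")
        )

    def test_error_factor_invalid_ranking(self):
        with pytest.raises(ValidationError):
            error_factor(6)

    @pytest.mark.parametrize(
        "y,label,expected",
        [(-1.0, "normal", 0.0), (0.0, "normal", 1.0), (0.5, "error", 0.25), (1.0, "error", 0.0)],
    )
    def test_output_penalty(self, y, label, expected):
        assert output_penalty(y, label) == pytest.approx(expected)


class TestObjective:
    def test_zero_weights_single_normal_case(self):
        # y == 0 everywhere: sum_s 1e-2 * (163-s)/162 * 1 = 1e-2 * 81.5
        spec = ObjectiveSpec(lambda_l2=0.0)
        cases = [case_from(np.zeros((162, 4)))]
        assert objective(RNNWeights.zeros(), cases, spec) == pytest.approx(0.815, abs=1e-12)

    def test_zero_weights_rank5_error_matches_normal(self):
        spec = ObjectiveSpec(lambda_l2=0.0)
        err = [case_from(np.zeros((162, 4)), ranking=5)]
        assert objective(RNNWeights.zeros(), err, spec) == pytest.approx(0.815, abs=1e-12)

    def test_matches_nested_loop_oracle(self, rng):
        spec = ObjectiveSpec(lambda_l2=0.0, n_windows=12)
        cases = [
            case_from(rng.normal(0, 5, (12, 4)), ranking=r, pid=f"P{r}")
            for r in (0, 1, 2, 5)
        ]
        w = RNNWeights.random(rng)
        got = objective(w, cases, spec)

        total = 0.0
        for c in cases:
            label = c.effective_label(spec.relabel_rank1_as_normal)
            rank = c.ranking if label == "error" else 0
            hs = [np.zeros(l.n_units) for l in w.layers]
            for s in range(1, 13):
                inp = c.stream.values[s - 1] * spec.input_scale
                for k, layer in enumerate(w.layers):
                    hs[k] = gru_step(inp, hs[k], layer)
                    inp = hs[k]
                y = hs[-1][0]
                total += (
                    importance_factor(label, spec)
                    * error_factor(rank)
                    * segment_factor(s, label, 12)
                    * output_penalty(y, label)
                )
        assert got == pytest.approx(total, abs=1e-12)

    def test_objective_decomposes_into_sum_and_penalty(self, rng):
        cases = [case_from(rng.normal(0, 1, (20, 4)), ranking=3)]
        w = RNNWeights.random(rng)
        with_l2 = objective(w, cases, ObjectiveSpec(n_windows=20))
        without = objective(w, cases, ObjectiveSpec(n_windows=20, lambda_l2=0.0))
        assert with_l2 == pytest.approx(without + l2_penalty(w, 40.0))
        assert without >= 0

    def test_relabeling_only_changes_rank1_cases(self, rng):
        w = RNNWeights.random(rng)
        for rank, should_change in [(0, False), (1, True), (2, False), (5, False)]:
            cases = [case_from(rng.normal(0, 2, (15, 4)), ranking=rank)]
            on = objective(w, cases, ObjectiveSpec(n_windows=15, relabel_rank1_as_normal=True))
            off = objective(w, cases, ObjectiveSpec(n_windows=15, relabel_rank1_as_normal=False))
            assert (on != off) == should_change

    def test_stream_length_mismatch_rejected(self, rng):
        cases = [case_from(np.zeros((10, 4)))]
        with pytest.raises(ValidationError):
            objective(RNNWeights.zeros(), cases, ObjectiveSpec(n_windows=162))


class TestRandomSearch:
    def test_trace_non_increasing_and_improves(self, rng):
        spec = ObjectiveSpec(n_windows=20)
        cases = [
            case_from(rng.normal(0, 3, (20, 4)) + (5 if r else 0), ranking=r, pid=f"P{r}")
            for r in (0, 0, 4, 5)
        ]
        _, trace = random_search(cases, spec, SearchConfig(iterations=150, seed=3))
        assert len(trace) == 151
        assert np.all(np.diff(trace) <= 0)
        assert trace[-1] < trace[0]

    def test_zero_iterations_returns_initial_weights(self, rng):
        spec = ObjectiveSpec(n_windows=8)
        cases = [case_from(rng.normal(0, 1, (8, 4)))]
        search = SearchConfig(iterations=0, seed=11)
        w, trace = random_search(cases, spec, search)
        expected = RNNWeights.random(
            np.random.default_rng(11), search.init_scale, update_bias=search.init_update_bias
        )
        np.testing.assert_array_equal(w.to_vector(), expected.to_vector())
        assert len(trace) == 1

    def test_toy_problem_drives_output_to_off_state(self):
        # one normal case with constant input: the optimum is y -> -1
        stub = SimpleNamespace(values=np.ones((25, 1)))
        cases = [TrainingCase(stream=stub, ranking=0, patient_id="toy")]
        spec = ObjectiveSpec(n_windows=25, lambda_l2=0.0)
        from portalwatch.gru import forward

        w0, trace = random_search(
            cases, spec, SearchConfig(iterations=600, seed=5), topology=(1, 1)
        )
        y = forward(stub.values, w0, spec.input_scale)
        assert y.mean() < -0.5
        assert trace[-1] < 0.25 * trace[0]

    def test_reproducible_given_seed(self, rng):
        spec = ObjectiveSpec(n_windows=10)
        cases = [case_from(rng.normal(0, 2, (10, 4)), ranking=2)]
        w1, t1 = random_search(cases, spec, SearchConfig(iterations=50, seed=9))
        w2, t2 = random_search(cases, spec, SearchConfig(iterations=50, seed=9))
        np.testing.assert_array_equal(w1.to_vector(), w2.to_vector())
        np.testing.assert_array_equal(t1, t2)


class TestSplits:
    def test_nine_unique_splits(self):
        plan = make_splits(PatientCohortSpec())
        assert len(plan) == 9
        pairs = {(s.test_full, s.test_partial) for s in plan}
        assert len(pairs) == 9

    def test_training_sets_hold_two_of_each_group(self):
        cohort = PatientCohortSpec()
        for s in make_splits(cohort):
            full = [p for p in s.train_patients if p in cohort.full_error_patients]
            partial = [p for p in s.train_patients if p in cohort.partial_error_patients]
            assert len(full) == 2 and len(partial) == 2

    def test_each_patient_tested_three_times(self):
        from collections import Counter

        counts = Counter()
        for s in make_splits(PatientCohortSpec()):
            counts.update(s.test_patients)
        assert all(v == 3 for v in counts.values())

    def test_train_test_disjoint(self):
        for s in make_splits(PatientCohortSpec()):
            assert not set(s.test_patients) & set(s.train_patients)

    def test_wrong_cohort_shape_rejected(self):
        with pytest.raises(ValidationError):
            make_splits(PatientCohortSpec(("A", "B"), ("C", "D", "E")))
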