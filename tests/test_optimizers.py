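"""Optimizer engines: schedules, step directions, batching, rescue,
line search, and the run loops."""

import numpy as np
import pytest

import batchode as b
from batchode.optimizers import (
    LearningRateSchedule,
    apply_update,
    make_epoch_batches,
    run_fullbatch_reference,
)
from conftest import QuadraticObjective, ScriptedFailureObjective


class TestSchedules:
    def test_preset_endpoints(self):
        cases = {
            1: (1e0, 1e-3), 2: (1e-1, 1e-4), 3: (1e-2, 1e-5),
        }
        n = 100
        for i, (start, end) in cases.items():
            s = getattr(LearningRateSchedule, f"schedule_{i}")()
            assert s.eta(0, n) == pytest.approx(start, rel=1e-12)
            assert s.eta(n - 1, n) == pytest.approx(end, rel=1e-12)

    def test_constant_preset_is_1e_minus_3_everywhere(self):
        s = LearningRateSchedule.schedule_4()
        assert all(s.eta(r, 50) == 1e-3 for r in range(50))

    def test_geometric_midpoint(self):
        s = LearningRateSchedule("log_decreasing", 1e-1, 1e-5)
        assert s.eta(50, 101) == pytest.approx(1e-3, rel=1e-12)

    def test_monotone_non_increasing(self):
        s = LearningRateSchedule.schedule_2()
        etas = [s.eta(r, 200) for r in range(200)]
        assert all(a >= b_ for a, b_ in zip(etas, etas[1:]))

    def test_degenerate_single_step_returns_start(self):
        s = LearningRateSchedule.schedule_1()
        assert s.eta(0, 1) == 1.0

    def test_from_string_forms(self):
        assert LearningRateSchedule.from_string("log:0.5:0.005").eta(0, 10) == 0.5
        assert LearningRateSchedule.from_string("const:0.02").eta(5, 10) == 0.02
        assert LearningRateSchedule.from_string("schedule_3").eta_start == 1e-2
        with pytest.raises(ValueError):
            LearningRateSchedule.from_string("bogus")

    def test_suggested_schedule_targets_kappa(self):
        s = b.suggest_learning_rate(25, kappa=0.05)
        assert s.eta(0, 100) == pytest.approx(0.05)


def _reference_trajectory(name, gradients, eta=0.1):
    """Independent hand-coded recursions of the published update rules."""
    n = len(gradients[0])
    theta = np.zeros(n)
    out = []
    if name == "sgd":
        for g in gradients:
            theta = theta - eta * g
            out.append(theta.copy())
    elif name == "momentum":
        v = np.zeros(n)
        for g in gradients:
            v = 0.9 * v + g
            theta = theta - eta * v
            out.append(theta.copy())
    elif name == "rmsprop":
        a = np.zeros(n)
        for g in gradients:
            a = 0.9 * a + 0.1 * g * g
            theta = theta - eta * g / (np.sqrt(a) + 1e-8)
            out.append(theta.copy())
    elif name in ("adam", "adam-balanced"):
        r1, r2 = (0.9, 0.999) if name == "adam" else (0.9, 0.9)
        m = np.zeros(n)
        v = np.zeros(n)
        for t, g in enumerate(gradients, start=1):
            m = r1 * m + (1 - r1) * g
            v = r2 * v + (1 - r2) * g * g
            mh = m / (1 - r1 ** t)
            vh = v / (1 - r2 ** t)
            theta = theta - eta * mh / (np.sqrt(vh) + 1e-8)
            out.append(theta.copy())
    return np.array(out)


class TestStepDirections:
    @pytest.mark.parametrize("name", ["sgd", "momentum", "rmsprop", "adam", "adam-balanced"])
    def test_matches_hand_coded_recursion(self, name):
        rng = np.random.default_rng(11)
        gradients = [rng.normal(0, 1, 3) for _ in range(10)]
        opt = b.make_optimizer(name)
        opt.reset(3)
        bounds = b.ParameterSpace(["a", "b", "c"], lower=np.full(3, -1e6), upper=np.full(3, 1e6))
        theta = np.zeros(3)
        trace = []
        for g in gradients:
            delta = opt.direction(g)
            theta = apply_update(theta, delta, 0.1, bounds)
            trace.append(theta.copy())
        ref = _reference_trajectory(name, gradients, eta=0.1)
        assert np.allclose(np.array(trace), ref, rtol=0, atol=1e-12)

    @pytest.mark.parametrize("name", ["sgd", "momentum", "rmsprop", "adam"])
    def test_zero_gradient_zero_direction(self, name):
        opt = b.make_optimizer(name)
        opt.reset(4)
        assert np.allclose(opt.direction(np.zeros(4)), 0.0)

    def test_adam_first_step_magnitude(self):
        opt = b.Adam()
        opt.reset(1)
        delta = opt.direction(np.array([1.0]))
        assert delta[0] == pytest.approx(-1.0 / (1.0 + 1e-8), rel=1e-12)

    def test_adam_variants_differ_only_in_decay_rates(self):
        std, bal = b.make_optimizer("adam"), b.make_optimizer("adam-balanced")
        assert (std.rho1, std.rho2) == (0.9, 0.999)
        assert (bal.rho1, bal.rho2) == (0.9, 0.9)

    def test_adam_step_norm_approaches_sqrt_n_theta(self):
        # under a persistent constant gradient the bias-corrected update
        # converges to unit magnitude per coordinate
        n = 7
        opt = b.Adam.balanced()
        opt.reset(n)
        g = np.full(n, 3.21)
        eta = 0.05
        for _ in range(200):
            delta = opt.direction(g)
        assert np.linalg.norm(eta * delta) == pytest.approx(eta * np.sqrt(n), rel=0.05)


class TestApplyUpdate:
    def test_zero_delta_no_move(self, quadratic_bounds):
        th = np.array([0.5, -1.0, 2.0])
        assert np.array_equal(apply_update(th, np.zeros(3), 0.3, quadratic_bounds), th)

    def test_clipping_at_upper_bound(self, quadratic_bounds):
        th = np.array([2.9, 0.0, 0.0])
        out = apply_update(th, np.array([10.0, 0.0, 0.0]), 1.0, quadratic_bounds)
        assert out[0] == 3.0

    def test_step_scale_halves_step(self, quadratic_bounds):
        th = np.zeros(3)
        full = apply_update(th, np.ones(3), 0.2, quadratic_bounds, step_scale=1.0)
        half = apply_update(th, np.ones(3), 0.2, quadratic_bounds, step_scale=0.5)
        assert np.allclose(half, full / 2)


class TestEpochBatches:
    def test_partition_covers_all_ids(self):
        ids = [f"c{i}" for i in range(6)]
        batches = make_epoch_batches(ids, 2, np.random.default_rng(0))
        assert len(batches) == 3
        assert sorted(sum(batches, [])) == sorted(ids)
        assert all(len(set(bt)) == len(bt) for bt in batches)

    def test_remainder_batch_kept(self):
        batches = make_epoch_batches([f"c{i}" for i in range(7)], 3, np.random.default_rng(1))
        assert [len(bt) for bt in batches] == [3, 3, 1]

    def test_deterministic_under_seed(self):
        ids = [f"c{i}" for i in range(10)]
        b1 = make_epoch_batches(ids, 4, np.random.default_rng(5))
        b2 = make_epoch_batches(ids, 4, np.random.default_rng(5))
        assert b1 == b2

    def test_oversized_batch_warns_and_uses_full(self):
        with pytest.warns(UserWarning):
            batches = make_epoch_batches(["a", "b"], 5, np.random.default_rng(0))
        assert len(batches) == 1 and len(batches[0]) == 2


class TestRescueInterceptor:
    def _run(self, fail_calls, **kw):
        rng = np.random.default_rng(2)
        centers = {f"e{i}": rng.normal(0, 1, 2) for i in range(4)}
        obj = ScriptedFailureObjective(centers, fail_calls)
        bounds = b.ParameterSpace(["a", "b"], lower=np.full(2, -10.0), upper=np.full(2, 10.0))
        hist = b.run_minibatch(obj, bounds, np.zeros(2), algorithm="sgd",
                               schedule="const:0.05", batch_size=2, epochs=4,
                               seed=3, compute_final_metrics=False, **kw)
        return hist

    def test_no_failure_interceptor_inert(self):
        hist = self._run(())
        assert hist.termination == "completed"
        assert all(s == 1.0 for s in hist.step_scale_trace)
        assert not any(e[1].startswith("rescue") for e in hist.events)

    def test_single_failure_recovers_with_step_scale_dip(self):
        hist = self._run({3})
        assert hist.termination == "completed"
        scales = hist.step_scale_trace
        assert 0.5 in scales          # dip after the rescue
        i = scales.index(0.5)
        assert scales[i + 1] == 1.0   # restored within one later step
        kinds = [e[1] for e in hist.events]
        assert kinds.count("rescue_attempt") == 1

    def test_persistent_failure_exhausts_after_ten_attempts(self):
        hist = self._run(set(range(3, 100)))
        assert hist.termination == "rescue_exhausted"
        attempts = [e for e in hist.events if e[1] == "rescue_attempt"]
        assert len(attempts) == 10

    def test_failure_at_initial_point_terminates_immediately(self):
        hist = self._run({1})
        assert hist.termination == "initial_failure"
        assert len(hist.steps) == 0

    def test_rescue_disabled_stops_on_failure(self):
        hist = self._run({3}, rescue=False)
        assert hist.termination == "rescue_exhausted"

    def test_step_scale_never_exceeds_one(self):
        hist = self._run({3, 5})
        assert max(hist.step_scale_trace) <= 1.0


class TestLineSearch:
    def test_overlarge_step_backtracked_on_quadratic(self):
        # 1-D quadratic with a learning rate ~100x too large: the accepted
        # point must use a smaller step and decrease J
        obj = QuadraticObjective({"e0": np.array([1.0])})
        bounds = b.ParameterSpace(["a"], lower=np.array([-50.0]), upper=np.array([50.0]))
        hist = b.run_minibatch(obj, bounds, np.array([0.0]), algorithm="sgd",
                               schedule="const:100.0", batch_size=1, epochs=1,
                               seed=0, line_search=True, compute_final_metrics=False)
        # gradient at 0 is -1, full step would be +100 -> J skyrockets;
        # backtracking must keep the accepted point closer than the full step
        theta_acc = hist.final_theta[0]
        assert abs(theta_acc) < 100.0
        J0 = obj.evaluate(np.array([0.0])).J
        # exhausted searches accept the smallest trial; with safeguarded
        # backtracking the trial step is at most 0.25 of the full step
        assert abs(theta_acc) <= 25.0 + 1e-9
        assert len([e for e in hist.events if "line_search" in e[1]]) >= 1

    def test_decreasing_first_trial_accepted_with_full_step(self):
        obj = QuadraticObjective({"e0": np.array([1.0])})
        bounds = b.ParameterSpace(["a"], lower=np.array([-50.0]), upper=np.array([50.0]))
        hist = b.run_minibatch(obj, bounds, np.array([0.0]), algorithm="sgd",
                               schedule="const:0.5", batch_size=1, epochs=1,
                               seed=0, line_search=True, compute_final_metrics=False)
        # eta=0.5, g=-1: full step to 0.5 halves the distance, J decreases
        assert hist.final_theta[0] == pytest.approx(0.5)
        assert hist.n_obj_evals == 1  # single objective-only trial

    def test_at_most_three_trials(self):
        obj = QuadraticObjective({"e0": np.array([0.0])})
        bounds = b.ParameterSpace(["a"], lower=np.array([-50.0]), upper=np.array([50.0]))
        hist = b.run_minibatch(obj, bounds, np.array([1.0]), algorithm="sgd",
                               schedule="const:1000.0", batch_size=1, epochs=1,
                               seed=0, line_search=True, compute_final_metrics=False)
        assert hist.n_obj_evals <= 3


class TestRunLoops:
    def test_descent_on_decomposable_quadratic(self, quadratic_objective, quadratic_bounds):
        th0 = np.array([2.5, -2.5, 2.5])
        J0 = quadratic_objective.evaluate(th0).J
        for algo in ("sgd", "momentum", "rmsprop", "adam", "adam-balanced"):
            hist = b.run_minibatch(quadratic_objective, quadratic_bounds, th0,
                                   algorithm=algo, schedule="log:0.2:0.001",
                                   batch_size=2, epochs=30, seed=1)
            assert hist.final_metrics["J_full"] < J0

    def test_full_batch_size_reproduces_full_gradient_method(self,
                                                             quadratic_objective,
                                                             quadratic_bounds):
        th0 = np.array([1.0, -1.0, 0.5])
        epochs = 12
        hist = b.run_minibatch(quadratic_objective, quadratic_bounds, th0,
                               algorithm="adam", schedule="schedule_2",
                               batch_size=len(quadratic_objective.condition_ids),
                               epochs=epochs, seed=0, compute_final_metrics=False)
        # independent full-batch loop with the same eta sequence
        sched = LearningRateSchedule.schedule_2()
        opt = b.Adam()
        opt.reset(3)
        theta = th0.copy()
        js = []
        for r in range(epochs):
            val = quadratic_objective.evaluate(theta, None, with_gradient=True)
            js.append(val.J)
            delta = opt.direction(val.gradient)
            theta = apply_update(theta, delta, sched.eta(r, epochs), quadratic_bounds)
        assert np.array_equal(np.array(hist.j_trace), np.array(js))
        assert np.array_equal(hist.final_theta, theta)

    def test_fixed_seed_bit_identical_history(self, quadratic_objective, quadratic_bounds):
        runs = [b.run_minibatch(quadratic_objective, quadratic_bounds,
                                np.array([1.0, 1.0, 1.0]), algorithm="rmsprop",
                                schedule="schedule_2", batch_size=2, epochs=5, seed=9)
                for _ in range(2)]
        assert np.array_equal(runs[0].thetas(), runs[1].thetas())
        assert runs[0].j_trace == runs[1].j_trace

    def test_wall_time_limit_terminates(self, quadratic_objective, quadratic_bounds):
        hist = b.run_minibatch(quadratic_objective, quadratic_bounds, np.zeros(3),
                               algorithm="sgd", schedule="schedule_4", batch_size=1,
                               epochs=100000, seed=0, wall_time_limit_s=0.05,
                               compute_final_metrics=False)
        assert hist.termination == "wall_time"


class TestFullBatchReference:
    def test_converges_on_convex_quadratic(self, quadratic_objective, quadratic_bounds):
        hist = run_fullbatch_reference(quadratic_objective, quadratic_bounds,
                                       np.array([2.0, 2.0, 2.0]))
        centers = np.array([quadratic_objective.centers[c]
                            for c in quadratic_objective.condition_ids])
        assert np.allclose(hist.final_theta, centers.mean(axis=0), atol=1e-5)

    def test_history_schema_matches_minibatch(self, quadratic_objective, quadratic_bounds):
        h1 = run_fullbatch_reference(quadratic_objective, quadratic_bounds, np.zeros(3))
        h2 = b.run_minibatch(quadratic_objective, quadratic_bounds, np.zeros(3),
                             batch_size=2, epochs=2, seed=0)
        for attr in ("steps", "theta_trace", "j_trace", "final_theta",
                     "termination", "n_condition_sims", "final_metrics"):
            assert hasattr(h1, attr) and hasattr(h2, attr)

    def test_reaches_chi2_band_on_cascade_fixture(self, small_problem, small_objective):
        res = b.run_multistart(small_objective, small_problem.parameter_space,
                               n_starts=5, seed=4, runner=run_fullbatch_reference,
                               max_iterations=150)
        N = small_problem.n_records
        J_true = b.full_dataset_metrics(small_objective,
                                        small_problem.theta_true_log10())["J_full"]
        assert np.nanmin(res.final_values) <= J_true + 3 * np.sqrt(N / 2)


class TestMultiStart:
    def test_starts_inside_box_and_paired_across_settings(self,
                                                          quadratic_objective,
                                                          quadratic_bounds):
        r1 = b.run_multistart(quadratic_objective, quadratic_bounds, n_starts=8,
                              seed=3, batch_size=2, epochs=2,
                              compute_final_metrics=False)
        r2 = b.run_multistart(quadratic_objective, quadratic_bounds, n_starts=8,
                              seed=3, algorithm="sgd", batch_size=3, epochs=2,
                              compute_final_metrics=False)
        assert np.all(r1.starts >= quadratic_bounds.lower)
        assert np.all(r1.starts <= quadratic_bounds.upper)
        assert np.array_equal(r1.starts, r2.starts)

    def test_default_start_count_is_100(self, quadratic_objective, quadratic_bounds):
        import inspect

        sig = inspect.signature(b.run_multistart)
        assert sig.parameters["n_starts"].default == 100
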