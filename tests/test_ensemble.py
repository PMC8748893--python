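"""History ensembles: smoothing, cutoff admission, thinning, prediction
spread, covariance spectrum, output-sensitivity SVD."""

import numpy as np
import pytest

import batchode as b
from batchode.optimizers import OptimizationHistory


class TestSmoothing:
    def test_constant_trace_unchanged(self):
        tr = np.full(12, 4.2)
        assert np.allclose(b.smooth_history(tr, 4), tr)

    def test_single_step_is_identity(self):
        assert b.smooth_history(np.array([7.0]), 10)[0] == 7.0

    def test_scripted_trace_matches_hand_computed_means(self):
        tr = np.arange(10.0)
        out = b.smooth_history(tr, 4)  # half-window 2, truncated at ends
        expected = []
        for i in range(10):
            lo, hi = max(0, i - 2), min(10, i + 3)
            expected.append(tr[lo:hi].mean())
        assert np.allclose(out, expected)


def _history(j_steps, thetas, steps_per_epoch, start_id=0):
    h = OptimizationHistory(start_id=start_id, steps_per_epoch=steps_per_epoch)
    for r, (j, th) in enumerate(zip(j_steps, thetas)):
        h.record(r, r // steps_per_epoch, th, j, 1e-3, 1.0)
    h.final_theta = np.array(thetas[-1])
    h.final_metrics = {"J_full": float(j_steps[-1]) * steps_per_epoch}
    return h


class TestBuildEnsemble:
    def test_all_above_cutoff_gives_empty_ensemble(self):
        h = _history([10.0] * 6, [np.zeros(2)] * 6, 3)
        with pytest.warns(UserWarning):
            ens = b.build_ensemble([h], n_records=100, cutoff=0.01)
        assert len(ens) == 0

    def test_scripted_admission_matches_hand_enumeration(self):
        # steps_per_epoch=1 -> no smoothing window beyond the point itself
        n_records = 8
        j = np.array([16.0, 4.0, 1.0, 4.0, 16.0])  # rmse = sqrt(2J/8) = 2,1,.5,1,2
        thetas = [np.full(2, float(i)) for i in range(5)]
        h = _history(list(j), thetas, steps_per_epoch=1)
        ens = b.build_ensemble([h], n_records=n_records, cutoff_tolerance=0.10,
                               thinning_cap=None)
        # best rmse 0.5 -> cutoff 0.55: only the middle step admitted
        assert len(ens) == 1
        assert ens.members[0, 0] == 2.0
        # explicit looser cutoff admits the rmse=1 steps too
        ens2 = b.build_ensemble([h], n_records=n_records, cutoff=1.0, thinning_cap=None)
        assert len(ens2) == 3

    def test_thinning_cap_limits_members_per_epoch(self):
        thetas = [np.array([float(r), 0.0]) for r in range(40)]
        h = _history([1.0] * 40, thetas, steps_per_epoch=20)
        ens = b.build_ensemble([h], n_records=10, cutoff=np.inf, thinning_cap=5)
        # two epochs, cap 5 each
        assert len(ens) == 10
        epochs = [step // 20 for (_, step) in ens.provenance]
        assert epochs.count(0) == 5 and epochs.count(1) == 5

    def test_uncapped_thinning_is_identity(self):
        thetas = [np.array([float(r)]) for r in range(12)]
        h = _history([1.0] * 12, thetas, steps_per_epoch=4)
        ens = b.build_ensemble([h], n_records=6, cutoff=np.inf, thinning_cap=None)
        assert len(ens) == 12

    def test_admissibility_invariant(self):
        rng = np.random.default_rng(1)
        hists = [_history(list(rng.uniform(0.5, 5.0, 30)),
                          [rng.normal(size=3) for _ in range(30)], 6, start_id=i)
                 for i in range(3)]
        ens = b.build_ensemble(hists, n_records=60)
        assert np.all(ens.smoothed_values <= ens.cutoff + 1e-12)


class TestEnsemblePredict:
    def test_single_member_sd_zero(self, small_problem):
        th = small_problem.theta_true_log10()
        cids = sorted(small_problem.conditions)[:2]
        out = b.ensemble_predict(small_problem, th[None, :], cids)
        for cid in cids:
            assert np.allclose(out["sd"][cid], 0.0)
        assert out["n_failed"] == 0

    def test_two_member_mean_exact(self, small_problem):
        th = small_problem.theta_true_log10()
        members = np.stack([th, th + 0.1])
        cids = sorted(small_problem.conditions)[:1]
        out = b.ensemble_predict(small_problem, members, cids)
        y1 = b.ensemble_predict(small_problem, th[None, :], cids)["mean"][cids[0]]
        y2 = b.ensemble_predict(small_problem, (th + 0.1)[None, :], cids)["mean"][cids[0]]
        assert np.allclose(out["mean"][cids[0]], (y1 + y2) / 2)

    def test_duplicated_members_counted_as_listed(self, small_problem):
        th = small_problem.theta_true_log10()
        members = np.stack([th, th + 0.2, th + 0.2])
        cids = sorted(small_problem.conditions)[:1]
        out = b.ensemble_predict(small_problem, members, cids)
        # SD over members-as-listed differs from the deduplicated SD
        dedup = b.ensemble_predict(small_problem, np.stack([th, th + 0.2]), cids)
        assert not np.allclose(out["sd"][cids[0]], dedup["sd"][cids[0]])

    def test_top_k_selects_best_finals(self):
        hists = []
        for i, jf in enumerate([5.0, 1.0, 3.0, np.nan]):
            h = OptimizationHistory(start_id=i)
            h.final_theta = np.array([float(i)])
            h.final_metrics = {"J_full": jf}
            hists.append(h)
        top = b.top_k_ensemble(hists, k=2)
        assert list(top[:, 0]) == [1.0, 2.0]


class TestCovarianceSpectrum:
    def test_members_on_a_line_have_one_nonzero_eigenvalue(self):
        t = np.linspace(0, 1, 50)
        members = np.outer(t, np.array([1.0, 2.0, -1.0]))
        spec = b.covariance_spectrum(members)
        assert spec["eigenvalues"][0] > 1e-6
        assert np.allclose(spec["eigenvalues"][1:], 0.0, atol=1e-12)

    def test_isotropic_sample_has_flat_spectrum(self):
        rng = np.random.default_rng(5)
        spec = b.covariance_spectrum(rng.normal(0, 1, size=(1000, 5)))
        ev = spec["eigenvalues"]
        assert ev[0] / ev[-1] < 1.2 / 0.8

    def test_trace_identity_and_fraction_sum(self):
        rng = np.random.default_rng(0)
        members = rng.normal(0, 1, size=(40, 6)) * np.arange(1, 7)
        spec = b.covariance_spectrum(members)
        total = np.var(members, axis=0, ddof=1).sum()
        assert spec["total_variance"] == pytest.approx(total, rel=1e-10)
        assert spec["explained_variance"].sum() == pytest.approx(1.0, abs=1e-10)


class TestOutputSensitivitySVD:
    def test_linear_model_singular_values_match_hand_jacobian(self):
        # y(t) = exp(-k t); dy/dk-hat = -t exp(-kt) k ln10 at one time point:
        # a 1x1 sensitivity matrix whose SV is its absolute value
        import pandas as pd

        model = b.ODEModel.from_symbolic(states={"x": "1"}, parameters=["k"], inputs=["u"],
                                         rates={"x": "-k*x"}, observables={"y": "x"})
        conds = {"c0": b.Condition("c0", [0.0])}
        meas = pd.DataFrame({"observableId": ["y"], "simulationConditionId": ["c0"],
                             "time": [2.0], "measurement": [0.5], "noiseParameters": [1.0]})
        prob = b.CalibrationProblem(model=model, conditions=conds, measurements=meas,
                                    parameter_space=b.ParameterSpace(["k"]))
        k = 0.7
        out = b.output_sensitivity_svd(prob, np.array([[np.log10(k)]]))
        expected = abs(-2.0 * np.exp(-k * 2.0) * k * np.log(10))
        assert out["singular_values"][0] == pytest.approx(expected, rel=1e-5)
        assert out["numerical_rank"] == 1

    def test_duplicated_rate_parameter_reduces_numerical_rank(self):
        # two parameters entering only through their product cannot be
        # separated: the sensitivity matrix has rank n_theta - 1
        import pandas as pd

        model = b.ODEModel.from_symbolic(
            states={"x": "1"}, parameters=["k1", "k2"], inputs=["u"],
            rates={"x": "-k1*k2*x"}, observables={"y": "x"})
        conds = {"c0": b.Condition("c0", [0.0])}
        meas = pd.DataFrame({"observableId": ["y"] * 3, "simulationConditionId": ["c0"] * 3,
                             "time": [1.0, 2.0, 3.0], "measurement": [0.0] * 3,
                             "noiseParameters": [1.0] * 3})
        prob = b.CalibrationProblem(model=model, conditions=conds, measurements=meas,
                                    parameter_space=b.ParameterSpace(["k1", "k2"]))
        # the two sensitivity columns are mathematically identical but carry
        # integration error ~rtol, so the rank is counted at that accuracy
        out = b.output_sensitivity_svd(prob, np.log10([[0.8, 1.1], [1.3, 0.6]]),
                                       rtol=1e-8, atol=1e-14, rank_rtol=1e-6)
        assert out["numerical_rank"] < prob.model.n_theta

    def test_sv_count_bounded_by_matrix_dims(self, small_problem):
        th = small_problem.theta_true_log10()
        out = b.output_sensitivity_svd(small_problem, th[None, :],
                                       condition_ids=sorted(small_problem.conditions)[:2])
        assert len(out["singular_values"]) <= min(out["matrix_shape"])
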