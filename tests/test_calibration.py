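import numpy as np
import pytest

import cdkcycle.calibration as cal
from cdkcycle.calibration import (
    FitConfig,
    NON_CYCLING_PENALTY,
    SensitivityRanking,
    fit_report,
    objective_cost,
    optimize,
    rank_sensitivity,
    subspace_names,
)
from cdkcycle.params import PARAM_NAMES
from cdkcycle.synth import ReferenceDataset


class TestObjective:
    def test_self_match_cost_near_zero(self, params, model_ds):
        assert objective_cost(params, model_ds) < 1e-4

    def test_hand_arithmetic_on_toy_channels(self, params, model_ds, monkeypatch):
        # model cyclin A [0, 0.5, 1] against data [0, 0, 1]; cyclin B and
        # onset match exactly -> cost = MSE = 0.25/3
        grid = np.array([0.0, 0.5, 1.0])
        monkeypatch.setattr(
            cal, "_model_channels_on_grid",
            lambda p, g, rtol, atol: (np.array([0.0, 0.5, 1.0]),
                                      np.array([0.2, 0.4, 0.9]), 0.97))
        data = ReferenceDataset(times=grid,
                                cyclinA2=np.array([0.0, 0.0, 1.0]),
                                cyclinB1=np.array([0.2, 0.4, 0.9]),
                                PHH3=np.array([0.0, 0.0, 1.0]),
                                DNA=np.array([2.0, 3.0, 4.0]))
        # data PHH3 crosses 0.5 at the last grid point... use onset match
        monkeypatch.setattr(cal, "_data_onset", lambda d: 0.97)
        cost = objective_cost(params, data)
        assert cost == pytest.approx(0.25 / 3, rel=1e-12)

    def test_cost_increases_away_from_generating_value(self, params, model_ds):
        # 5-point sweep of one strongly identifiable constant
        costs = [objective_cost(params.with_overrides(
            {"k_se2f": params["k_se2f"] * f}), model_ds)
            for f in (0.7, 0.85, 1.0, 1.15, 1.3)]
        assert costs[2] == min(costs)
        assert costs[0] > costs[1] > costs[2] < costs[3] < costs[4]

    def test_non_cycling_returns_penalty_not_exception(self, params, model_ds):
        dead = params.with_overrides({"k_sb_basal": 0.0, "k_sb_e2f": 0.0,
                                      "k_sb_ab": 0.0, "k_sb_b": 0.0})
        assert objective_cost(dead, model_ds) == NON_CYCLING_PENALTY

    def test_empty_dataset_rejected(self, params):
        ds = ReferenceDataset(times=np.array([]), cyclinA2=np.array([]),
                              cyclinB1=np.array([]), PHH3=np.array([]),
                              DNA=np.array([]))
        with pytest.raises(ValueError, match="empty"):
            objective_cost(params, ds)


@pytest.fixture(scope="module")
def ranking(params, model_ds):
    return rank_sensitivity(params, model_ds)


class TestSensitivity:

    def test_zero_constant_scores_zero_and_ranks_last(self, params, ranking):
        # a multiplicative perturbation of a zero-valued constant changes
        # nothing, so its sensitivity is exactly zero
        zeros = [n for n in PARAM_NAMES if params[n] == 0.0]
        assert zeros  # the default set has dormant terms
        scores = dict(ranking.entries)
        tail = [n for n, s in ranking.entries if s == 0.0]
        for z in zeros:
            assert scores[z] == 0.0
            assert z in tail

    def test_top_10_percent_of_103_is_11_parameters(self, ranking):
        assert len(ranking.top(0.10)) == 11
        assert len(ranking.top(0.30)) == 31

    def test_scores_descending_and_complete(self, ranking):
        scores = [s for _, s in ranking.entries]
        assert all(a >= b for a, b in zip(scores, scores[1:]))
        assert {n for n, _ in ranking.entries} == set(PARAM_NAMES)

    def test_order_invariant_to_common_weight_rescaling(self, params, model_ds,
                                                        ranking):
        cfg = FitConfig(weight_cyclinA=3.0, weight_cyclinB=3.0, weight_onset=30.0)
        scaled = rank_sensitivity(params, model_ds, config=cfg)
        top = [n for n, _ in ranking.entries[:8]]
        top_scaled = [n for n, _ in scaled.entries[:8]]
        assert top == top_scaled

    def test_invalid_perturbation_rejected(self, params, model_ds):
        with pytest.raises(ValueError):
            rank_sensitivity(params, model_ds, perturbation=1.5)


def _quadratic_stub(target):
    """Quadratic objective in place of the model cost (convex sanity case)."""
    def stub(params, data, config=None):
        return float(sum((params[n] - v) ** 2 for n, v in target.items()))
    return stub


class TestOptimizers:
    @pytest.fixture()
    def quad(self, params, model_ds, monkeypatch):
        names = ("k_se2f", "k_sa_e2f", "k_db_20")
        target = {n: params[n] * 1.2 for n in names}
        monkeypatch.setattr(cal, "objective_cost", _quadratic_stub(target))
        return names, target

    @pytest.mark.parametrize("optimizer", ["SA", "GA", "SRES"])
    def test_quadratic_objective_recovered(self, params, model_ds, quad, optimizer):
        names, target = quad
        cfg = FitConfig(optimizer=optimizer, budget=5000, seed=3, subspace=names)
        res = optimize(cfg, model_ds, params)
        for n, v in target.items():
            assert res.params[n] == pytest.approx(v, rel=1e-3)

    def test_budget_zero_returns_start(self, params, model_ds):
        cfg = FitConfig(budget=0, seed=0, subspace=("k_se2f",))
        res = optimize(cfg, model_ds, params)
        assert res.params.constants == params.constants
        assert res.n_evaluations == 0

    def test_trace_is_monotone_nonincreasing(self, params, model_ds, quad):
        names, _ = quad
        for opt in ("SA", "GA", "SRES"):
            cfg = FitConfig(optimizer=opt, budget=600, seed=1, subspace=names)
            res = optimize(cfg, model_ds, params)
            assert np.all(np.diff(res.trace) <= 0)
            assert res.cost <= res.trace[0]

    def test_subspace_contract_outside_parameters_untouched(self, params,
                                                            model_ds, quad):
        names, _ = quad
        cfg = FitConfig(optimizer="SRES", budget=400, seed=2, subspace=names)
        res = optimize(cfg, model_ds, params)
        for n in PARAM_NAMES:
            if n not in names:
                assert res.params[n] == params[n]

    def test_reproducible_for_identical_seed(self, params, model_ds, quad):
        names, _ = quad
        cfg = FitConfig(optimizer="SRES", budget=400, seed=7, subspace=names)
        r1 = optimize(cfg, model_ds, params)
        r2 = optimize(cfg, model_ds, params)
        assert r1.cost == r2.cost
        assert r1.params.constants == r2.params.constants

    def test_subspace_names_validated(self, params):
        with pytest.raises(ValueError, match="k_bogus"):
            subspace_names(FitConfig(subspace=("k_bogus",)), None)


class TestSingleParameterRecovery:
    """Refitting one perturbed constant at a time on noiseless data is a
    well-posed problem: the calibration stack recovers it within 5%."""

    @pytest.mark.parametrize("name", ["k_iw_a", "k_se2f", "k_db_20"])
    def test_single_top_sensitivity_parameter_recovered_within_5_percent(
            self, params, name):
        from cdkcycle.synth import generate_from_model

        truth = params.with_overrides({name: params[name] * 1.5})
        data = generate_from_model(truth, noise_sd=0.0, seed=0)
        cfg = FitConfig(optimizer="SRES", budget=300, seed=0, subspace=(name,))
        res = optimize(cfg, data, params)
        assert res.params[name] / truth[name] == pytest.approx(1.0, abs=0.05)


class TestFitReport:
    def test_perfect_fit_reports_zeros(self, params, model_ds):
        from cdkcycle.calibration import FitResult

        res = FitResult(params=params, cost=0.0, trace=np.array([0.0]),
                        n_evaluations=0, seed=0)
        rep = fit_report(res, model_ds)
        assert rep["rmse"]["cyclinA"] == pytest.approx(0.0, abs=1e-2)
        assert rep["rmse"]["cyclinB"] == pytest.approx(0.0, abs=1e-2)
        assert abs(rep["onset_error"]) < 5e-3

    def test_report_schema(self, params, model_ds):
        from cdkcycle.calibration import FitResult

        rep = fit_report(FitResult(params=params, cost=0.0,
                                   trace=np.array([0.0]), n_evaluations=0,
                                   seed=0), model_ds)
        assert set(rep["rmse"]) == {"cyclinA", "cyclinB"}
        assert "onset_error" in rep
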