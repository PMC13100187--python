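"""Objective, optimizer and bootstrap machinery (cheap checks only;
full protocol runs live in the acceptance tests)."""

import dataclasses

import numpy as np
import pytest

from npqtau import (
    Dataset,
    FitConfig,
    ModelEvaluator,
    default_truth,
    global_then_local,
    objective_delta2,
    stepwise_fit,
)
from npqtau.fitting import (
    Stage,
    StagePlan,
    bootstrap_ci,
    default_stage_plan,
    per_dataset_rmsd,
)
from npqtau.synth import ScenarioSpec, model_lifetimes, synth_snapshot_series


@pytest.fixture(scope="module")
def wt_dataset():
    kin, q, reg = default_truth()
    spec = ScenarioSpec(seed=5, genotypes=("WT",),
                        sequences=("5HL-10D-5HL",), noise_sd=0.0)
    return synth_snapshot_series(spec)[0]


@pytest.fixture(scope="module")
def evaluator():
    kin, q, reg = default_truth()
    return ModelEvaluator(kin, q, reg, rtol=1e-6, atol=1e-9)


class TestObjective:
    def test_perfect_model_gives_zero(self, wt_dataset, evaluator):
        assert objective_delta2({}, [wt_dataset], evaluator) < 1e-10

    def test_constant_offset_gives_n_d_squared(self, wt_dataset, evaluator):
        d = 0.05
        shifted = dataclasses.replace(wt_dataset, tau=wt_dataset.tau + d)
        n = shifted.times.size
        assert objective_delta2({}, [shifted], evaluator) == pytest.approx(
            n * d * d, rel=1e-6)

    def test_invariant_to_dataset_ordering(self, evaluator):
        kin, q, reg = default_truth()
        spec = ScenarioSpec(seed=6, genotypes=("WT", "npq4"),
                            sequences=("5HL-10D-5HL",), noise_sd=0.03)
        data = synth_snapshot_series(spec)
        theta = {"k_va": 0.009}
        assert objective_delta2(theta, data, evaluator) == pytest.approx(
            objective_delta2(theta, data[::-1], evaluator), rel=1e-12)

    def test_truth_beats_200_random_perturbations(self, wt_dataset,
                                                  evaluator):
        """The generating parameters are a local optimum of the misfit."""
        kin, q, _ = default_truth()
        base = objective_delta2({}, [wt_dataset], evaluator)
        rng = np.random.default_rng(0)
        names = ("k_va", "k_az", "k_qzf", "kappa_QZ", "kappa_qZ", "k_qlf")
        worse = 0
        for _ in range(200):
            theta = {}
            for n in names:
                true = getattr(kin, n, None)
                if true is None:
                    true = getattr(q, n)
                theta[n] = true * np.exp(rng.normal(0, 0.2))
            if objective_delta2(theta, [wt_dataset], evaluator) >= base:
                worse += 1
        assert worse == 200

    def test_simulation_failure_yields_finite_penalty(self, evaluator):
        kin, q, reg = default_truth()
        # dark Zea quenching large enough to over-explain tau_dark(0)
        theta = {"kappa_qZ": 0.9}
        times = np.array([0.0, 15.0])
        ds = Dataset(genotype="zep2", sequence="5HL-10D-5HL", times=times,
                     tau=np.array([1.35, 1.2]), se=np.array([0.02, 0.02]))
        val = objective_delta2(theta, [ds], evaluator)
        assert np.isfinite(val) and val > 1e4

    def test_rmsd_reported_in_both_domains(self, wt_dataset, evaluator):
        shifted = dataclasses.replace(wt_dataset, tau=wt_dataset.tau + 0.1)
        rmsd_tau, rmsd_rate = per_dataset_rmsd({}, [shifted], evaluator)
        key = shifted.key
        assert rmsd_tau[key] == pytest.approx(0.1, rel=1e-6)
        assert rmsd_rate[key] > 0


class TestGlobalThenLocal:
    def test_quadratic_bowl(self):
        x, f, _ = global_then_local(
            lambda v: float((v[0] - 0.3) ** 2 + (v[1] + 1.2) ** 2),
            [(-2, 2), (-2, 2)], FitConfig(seed=1))
        np.testing.assert_allclose(x, [0.3, -1.2], atol=1e-4)
        assert f < 1e-6

    def test_rastrigin_beats_random_search(self):
        def rastrigin(v):
            v = np.asarray(v)
            return float(10 * v.size
                         + np.sum(v**2 - 10 * np.cos(2 * np.pi * v)))

        bounds = [(-4.12, 5.12)] * 5
        x, f, _ = global_then_local(rastrigin, bounds,
                                    FitConfig(seed=2, de_maxiter=60,
                                              de_popsize=12))
        rng = np.random.default_rng(2)
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        samples = lo + (hi - lo) * rng.random((1000, 5))
        best_random = min(rastrigin(s) for s in samples)
        assert f <= best_random

    def test_collapsed_bounds_return_the_point(self):
        x, f, _ = global_then_local(lambda v: float(v[0] ** 2),
                                    [(1.5, 1.5)], FitConfig(seed=3))
        assert x[0] == 1.5 and f == pytest.approx(2.25)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            global_then_local(lambda v: 0.0, [(2.0, 1.0)], FitConfig())


class TestStagePlan:
    def test_default_plan_covers_each_parameter_once(self):
        plan = default_stage_plan()
        freed = plan.all_free
        assert len(freed) == len(set(freed))
        assert "V_0_WT" in freed
        assert "kappa_qI" not in freed  # fixed scale convention

    def test_empty_stage_rejected(self):
        with pytest.raises(ValueError):
            StagePlan(stages=(Stage("empty", ("WT",), ()),))

    def test_double_freeing_rejected(self):
        with pytest.raises(ValueError):
            StagePlan(stages=(Stage("a", ("WT",), ("k_va",)),
                              Stage("b", ("WT",), ("k_va",))))

    def test_missing_stage_data_is_an_error(self, evaluator):
        kin, q, reg = default_truth()
        spec = ScenarioSpec(seed=7, genotypes=("WT",),
                            sequences=("5HL-10D-5HL",), noise_sd=0.0)
        data = synth_snapshot_series(spec)
        with pytest.raises(ValueError, match="no datasets"):
            stepwise_fit(data, config=FitConfig.fast(0),
                         evaluator=evaluator)


class TestBootstrapGuards:
    def test_single_replicate_rejected(self, evaluator, wt_dataset):
        from npqtau.fitting import FitResult

        fake = FitResult(theta={}, kinetic=evaluator.base_kinetic,
                         quenching=evaluator.base_quenching, v0={},
                         delta2=0.0, rmsd_tau={}, rmsd_rate={})
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_ci(fake, [wt_dataset], n_boot=1, seed=0,
                         evaluator=evaluator)


def test_qi_only_recovery_reproduces_monotone_decline():
    """Fitting only the photoinhibition stage on qI-only data reproduces
    the generating monotone lifetime decline."""
    kin, q, reg = default_truth()
    spec = ScenarioSpec(seed=9, genotypes=("npq4npq1",),
                        sequences=("5HL-10D-5HL", "3HL-1D-1HL-3D-9HL-3D"),
                        noise_sd=0.0)
    data = synth_snapshot_series(spec)
    plan = StagePlan(stages=(
        Stage("qI", ("npq4npq1",), ("k_qI_HL", "k_qI_laser")),))
    ev = ModelEvaluator(kin, q, reg, rtol=1e-6, atol=1e-9)
    fit = stepwise_fit(data, plan=plan, config=FitConfig.fast(1),
                       evaluator=ev)
    assert fit.delta2 < 1e-8
    model = model_lifetimes(reg["npq4npq1"], "5HL-10D-5HL", fit.kinetic,
                            fit.quenching, data[0].times)
    np.testing.assert_allclose(model, data[0].tau, atol=1e-4)
    assert model[-1] < model[0]  # monotone net decline under the laser
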