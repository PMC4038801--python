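import numpy as np
import pytest

from sasglobal import fit_engine as fe
from sasglobal.catalogue import ModelInstance
from sasglobal.curve_io import SASCurve
from sasglobal.errors import ParameterError
from sasglobal.form_factors import sphere_intensity
from sasglobal.parameters import ParameterSpec, PolyConfig, PolyParam

FIXED = fe.ScalePolicy(kappa=1.0, background=0.0)


def sphere_inst(r_spec=None, drho=2e-6, weight=None):
    return ModelInstance(
        "sphere",
        params={"R": r_spec or ParameterSpec("R", 50.0),
                "drho": ParameterSpec("drho", drho)},
        weight=weight)


def single_curve_problem(curve, inst=None, methods=("quasinewton",),
                         seed=None, policy=FIXED):
    return fe.FitProblem(
        [curve], [[inst or sphere_inst()]], scale_policies=[policy],
        minimizer=fe.MinimizerSettings(methods=methods, seed=seed))


class TestModelCurve:
    def test_single_model_weight_one(self, sphere_curve):
        problem = single_curve_problem(sphere_curve)
        resolved = problem.registry.resolve(np.empty(0))
        np.testing.assert_allclose(fe.model_curve(problem, 0, resolved),
                                   sphere_curve.i_exp, rtol=1e-12)

    def test_linearity_of_weights(self, sphere_curve):
        split = [sphere_inst(weight=ParameterSpec("w", 0.3)),
                 sphere_inst(weight=ParameterSpec("w", 0.7))]
        problem = fe.FitProblem([sphere_curve], [split],
                                scale_policies=[FIXED])
        resolved = problem.registry.resolve(np.empty(0))
        whole = single_curve_problem(sphere_curve)
        np.testing.assert_allclose(
            fe.model_curve(problem, 0, resolved),
            fe.model_curve(whole, 0, whole.registry.resolve(np.empty(0))),
            rtol=1e-12)

    def test_homogeneity_in_weight(self, sphere_curve):
        double = single_curve_problem(
            sphere_curve, sphere_inst(weight=ParameterSpec("w", 2.0)))
        single = single_curve_problem(sphere_curve)
        r2 = double.registry.resolve(np.empty(0))
        r1 = single.registry.resolve(np.empty(0))
        np.testing.assert_allclose(fe.model_curve(double, 0, r2),
                                   2.0 * fe.model_curve(single, 0, r1),
                                   rtol=1e-12)


class TestScaleBackground:
    def test_exact_affine_relation(self, q_grid):
        i_model = sphere_intensity(q_grid, 40.0, 2e-6)
        curve = SASCurve(q_grid, 2.0 * i_model + 3.0, np.ones_like(q_grid))
        kappa, bkg = fe.solve_scale_background(i_model, curve)
        assert kappa == pytest.approx(2.0, rel=1e-10)
        assert bkg == pytest.approx(3.0, rel=1e-10)

    def test_heteroscedastic_grid_search_oracle(self):
        q = np.array([0.01, 0.02, 0.03, 0.04, 0.05])
        i_model = np.array([4.0, 3.0, 2.5, 1.0, 0.5])
        i_exp = np.array([9.5, 7.2, 6.4, 3.1, 1.8])
        sigma = np.array([0.5, 0.2, 0.8, 0.1, 0.3])
        curve = SASCurve(q, i_exp, sigma)
        kappa, bkg = fe.solve_scale_background(i_model, curve)

        def cost(k, b):
            return np.sum(((k * i_model + b - i_exp) / sigma) ** 2)

        ks = np.linspace(kappa - 0.05, kappa + 0.05, 401)
        bs = np.linspace(bkg - 0.05, bkg + 0.05, 401)
        grid = np.array([[cost(k, b) for b in bs] for k in ks])
        assert cost(kappa, bkg) <= grid.min() + 1e-8

    def test_fixed_kappa_free_background(self, q_grid):
        i_model = sphere_intensity(q_grid, 40.0, 2e-6)
        curve = SASCurve(q_grid, i_model + 5.0, np.ones_like(q_grid))
        kappa, bkg = fe.solve_scale_background(i_model, curve,
                                               kappa_fixed=1.0)
        assert kappa == 1.0
        assert bkg == pytest.approx(5.0, rel=1e-12)

    def test_degenerate_constant_model_warns(self, q_grid):
        curve = SASCurve(q_grid, np.full_like(q_grid, 3.0),
                         np.ones_like(q_grid))
        with pytest.warns(UserWarning, match="degenerate"):
            kappa, bkg = fe.solve_scale_background(
                np.full_like(q_grid, 1.0), curve)
        assert bkg == pytest.approx(2.0)


class TestChi2:
    def test_zero_on_perfect_model(self, sphere_curve):
        problem = single_curve_problem(sphere_curve)
        assert fe.chi2(problem, np.empty(0)).chi2 == pytest.approx(0.0,
                                                                   abs=1e-20)

    def test_unit_residuals_give_unit_chi2(self, q_grid):
        i_model = sphere_intensity(q_grid, 50.0, 2e-6)
        sigma = np.full_like(q_grid, 0.01 * i_model[0])
        curve = SASCurve(q_grid, i_model + sigma, sigma)
        problem = single_curve_problem(curve)
        assert fe.chi2(problem, np.empty(0)).chi2 == pytest.approx(1.0)

    def test_global_value_is_curve_average(self, q_grid):
        i_model = sphere_intensity(q_grid, 50.0, 2e-6)
        sigma = np.full_like(q_grid, 0.01 * i_model[0])
        c1 = SASCurve(q_grid, i_model + sigma, sigma)           # chi2 = 1
        c3 = SASCurve(q_grid, i_model + sigma * np.sqrt(3.0), sigma)
        problem = fe.FitProblem([c1, c3], [[sphere_inst()], [sphere_inst()]],
                                scale_policies=[FIXED, FIXED])
        assert fe.chi2(problem, np.empty(0)).chi2 == pytest.approx(2.0)

    def test_scale_invariance_with_free_kappa(self, q_grid):
        i_model = sphere_intensity(q_grid, 50.0, 2e-6)
        rng = np.random.default_rng(3)
        sigma = 0.02 * i_model
        noisy = i_model + rng.normal(0.0, sigma)
        base = SASCurve(q_grid, noisy, sigma)
        scaled = base.rescaled(37.0)
        free = fe.ScalePolicy(kappa=None, background=0.0)
        p1 = single_curve_problem(base, policy=free)
        p2 = single_curve_problem(scaled, policy=free)
        b1, b2 = fe.chi2(p1, np.empty(0)), fe.chi2(p2, np.empty(0))
        assert b2.chi2 == pytest.approx(b1.chi2, rel=1e-10)
        assert b2.per_curve[0][1] == pytest.approx(37.0 * b1.per_curve[0][1],
                                                   rel=1e-10)

    def test_penalty_reported_separately(self, sphere_curve):
        inst = ModelInstance(
            "sphere",
            params={"R": ParameterSpec("R", 0.0, flag=4,
                                       link="fout = 2.5; 50.0 + 0*a"),
                    "drho": ParameterSpec("drho", 2e-6)})
        problem = fe.FitProblem([sphere_curve], [[inst]],
                                scale_policies=[FIXED])
        bd = fe.chi2(problem, problem.registry.x0())
        assert bd.psi == pytest.approx(2.5)
        assert bd.chi2 == pytest.approx(0.0, abs=1e-18)


class TestMinimize:
    def test_quadratic_surrogate_minimum(self, q_grid):
        # chi2 is exactly quadratic in drho, minimum at the true contrast
        i_true = sphere_intensity(q_grid, 50.0, 2e-6)
        curve = SASCurve(q_grid, i_true, np.full_like(q_grid, 1e-4))
        for methods in (("simplex",), ("quasinewton",)):
            inst = ModelInstance(
                "sphere",
                params={"R": ParameterSpec("R", 50.0),
                        "drho": ParameterSpec("drho", 1e-6, 0.0, 5e-6,
                                              flag=1)})
            problem = single_curve_problem(curve, inst, methods=methods)
            problem.minimizer.xtol = 1e-14   # parameter scale is 1e-6
            res = fe.minimize(problem, compute_errors=False)
            assert res.x_best[0] == pytest.approx(2e-6, rel=1e-4)

    def test_sphere_radius_recovery(self, sphere_curve):
        for methods in (("simplex",), ("quasinewton",)):
            inst = sphere_inst(ParameterSpec("R", 30.0, 10.0, 100.0, flag=1))
            problem = single_curve_problem(sphere_curve, inst,
                                           methods=methods)
            res = fe.minimize(problem, compute_errors=False)
            assert res.x_best[0] == pytest.approx(50.0, rel=1e-4)

    def test_no_free_parameters_evaluation_only(self, sphere_curve):
        res = fe.minimize(single_curve_problem(sphere_curve))
        assert res.x_best.size == 0
        assert res.chi2 == pytest.approx(0.0, abs=1e-20)

    def test_monkey_deterministic_under_seed(self, sphere_curve):
        results = []
        for _ in range(2):
            inst = sphere_inst(ParameterSpec("R", 30.0, 10.0, 100.0,
                                             flag=1))
            problem = single_curve_problem(sphere_curve, inst,
                                           methods=("monkey",), seed=123)
            problem.minimizer.n_iter = 300
            results.append(fe.minimize(problem,
                                       compute_errors=False).x_best[0])
        assert results[0] == results[1]

    def test_annealing_deterministic_and_chain_monotone(self, sphere_curve):
        values = []
        for _ in range(2):
            inst = sphere_inst(ParameterSpec("R", 30.0, 10.0, 100.0,
                                             flag=1))
            problem = single_curve_problem(
                sphere_curve, inst, methods=("annealing", "quasinewton"),
                seed=7)
            res = fe.minimize(problem, compute_errors=False)
            values.append(res.x_best[0])
            stages = [v for _, v in res.log]
            assert stages[-1] <= stages[0] + 1e-12
        assert values[0] == values[1]

    def test_stochastic_methods_require_seed(self):
        with pytest.raises(ParameterError, match="seed"):
            fe.MinimizerSettings(methods=("monkey",), seed=None)


class TestErrors:
    def _linear_fit_problem(self, sigma_scale=1.0):
        # I(q) = w * P(q) with P fixed: chi2 linear-in-w least squares;
        # closed-form variance of w is sigma_w^2 = 1/sum (P_i/sigma_i)^2
        q = np.linspace(0.01, 0.3, 40)
        P = sphere_intensity(q, 50.0, 2e-6)
        w_true = 1.7
        sigma = sigma_scale * 0.05 * P
        curve = SASCurve(q, w_true * P, sigma)
        inst = sphere_inst(weight=ParameterSpec("w", 1.0, 0.0, 5.0, flag=1))
        problem = single_curve_problem(curve, inst)
        return problem, P, sigma

    def test_linear_weight_error_matches_closed_form(self):
        problem, P, sigma = self._linear_fit_problem()
        res = fe.minimize(problem)
        expected = 1.0 / np.sqrt(np.sum((P / sigma) ** 2))
        assert res.x_best[0] == pytest.approx(1.7, rel=1e-6)
        assert res.stddevs[0] == pytest.approx(expected, rel=0.01)

    def test_halving_sigma_halves_parameter_error(self):
        p1, _, _ = self._linear_fit_problem(1.0)
        p2, _, _ = self._linear_fit_problem(0.5)
        e1 = fe.minimize(p1).stddevs[0]
        e2 = fe.minimize(p2).stddevs[0]
        assert e2 == pytest.approx(0.5 * e1, rel=0.02)

    def test_duplicated_parameter_perfect_correlation(self, q_grid):
        # two identical models with both weights free: w1 + w2 only is
        # determined, so the pair is perfectly anticorrelated
        P = sphere_intensity(q_grid, 50.0, 2e-6)
        curve = SASCurve(q_grid, P, 0.02 * P)
        insts = [sphere_inst(weight=ParameterSpec("w", 0.5, 0.0, 2.0,
                                                  flag=1))
                 for _ in range(2)]
        problem = fe.FitProblem([curve], [insts], scale_policies=[FIXED])
        with pytest.warns(UserWarning):
            stddevs, cov, corr = fe.errors_hessian(problem,
                                                   np.array([0.5, 0.5]))
        assert abs(corr[0, 1]) > 0.999

    def test_resampling_with_tiny_sigma_returns_best(self):
        problem, _, _ = self._linear_fit_problem(1e-9)
        res = fe.minimize(problem, compute_errors=False)
        mean, std = fe.errors_resampling(problem, res.x_best,
                                         n_iterations=5, seed=1)
        assert std[0] < 1e-6
        assert mean[0] == pytest.approx(res.x_best[0], abs=1e-6)

    def test_resampling_agrees_with_hessian(self):
        problem, P, sigma = self._linear_fit_problem()
        res = fe.minimize(problem)
        mean, std = fe.errors_resampling(problem, res.x_best,
                                         n_iterations=200, seed=11)
        assert std[0] == pytest.approx(res.stddevs[0], rel=0.15)

    def test_resampling_deterministic(self):
        problem, _, _ = self._linear_fit_problem()
        res = fe.minimize(problem, compute_errors=False)
        out1 = fe.errors_resampling(problem, res.x_best, 10, seed=5)
        out2 = fe.errors_resampling(problem, res.x_best, 10, seed=5)
        np.testing.assert_array_equal(out1[0], out2[0])
        np.testing.assert_array_equal(out1[1], out2[1])


class TestComputePr:
    def sphere_pr(self, r, R):
        # closed-form distance distribution of a homogeneous sphere
        x = r / (2.0 * R)
        v = 4.0 / 3.0 * np.pi * R ** 3
        p = np.where(x <= 1.0,
                     3.0 * x ** 2 * (1.0 - x) ** 2 * (2.0 + x) * 4.0, 0.0)
        # normalized so integral = 1; scale to match I(0) = (drho V)^2
        return p

    def test_sphere_distance_distribution(self):
        R, drho = 30.0, 2e-6
        q = np.linspace(1e-4, 1.2, 4000)
        intensity = sphere_intensity(q, R, drho)
        r = np.linspace(1.0, 2.5 * R, 120)
        pr = fe.compute_pr(intensity, q, r)
        V = 4.0 / 3.0 * np.pi * R ** 3
        shape = self.sphere_pr(r, R)
        expected = (drho * V) ** 2 * shape / (4.0 * np.pi * 2.0 * R)
        inside = r < 2.0 * R - 2.0
        scale = np.max(expected)
        assert np.max(np.abs(pr[inside] - expected[inside])) < 0.02 * scale

    def test_support_vanishes_past_diameter(self):
        R = 30.0
        q = np.linspace(1e-4, 1.2, 4000)
        intensity = sphere_intensity(q, R, 2e-6)
        r = np.linspace(1.0, 3.0 * R, 150)
        pr = fe.compute_pr(intensity, q, r)
        outside = r > 2.0 * R + 2.0
        assert np.max(np.abs(pr[outside])) < 0.01 * pr.max()

    def test_integral_matches_forward_intensity(self):
        R, drho = 30.0, 2e-6
        q = np.linspace(1e-4, 1.5, 5000)
        intensity = sphere_intensity(q, R, drho)
        r = np.linspace(0.05, 2.2 * R, 400)
        pr = fe.compute_pr(intensity, q, r)
        total = np.trapezoid(pr, r)
        expected = intensity[0] / (4.0 * np.pi)
        assert total == pytest.approx(expected, rel=0.02)

    def test_coarse_grid_rejected(self):
        q = np.linspace(0.01, 0.5, 20)
        with pytest.raises(ParameterError, match="too coarse"):
            fe.compute_pr(np.ones_like(q), q, np.linspace(1, 500, 10))


class TestOutputs:
    def test_written_files(self, tmp_path, sphere_curve):
        inst = sphere_inst(ParameterSpec("R", 50.0, 10.0, 100.0, flag=1))
        problem = single_curve_problem(sphere_curve, inst)
        res = fe.minimize(problem)
        paths = fe.write_outputs(problem, res, "ab12", tmp_path)
        names = {p.name for p in paths}
        assert "genab12.par" in names
        assert any(n.startswith("fitab12_") for n in names)
        assert "sumab12.txt" in names

    def test_distribution_file_for_poly_parameter(self, tmp_path, q_grid):
        poly = PolyConfig(kind="gaussian",
                          params={"width": PolyParam(5.0, fixed=True)},
                          n_points=11)
        inst = ModelInstance(
            "sphere",
            params={"R": ParameterSpec("R", 50.0, flag=6, poly=poly),
                    "drho": ParameterSpec("drho", 2e-6)})
        intensity = sphere_intensity(q_grid, 50.0, 2e-6)
        curve = SASCurve(q_grid, intensity, 0.02 * intensity)
        problem = fe.FitProblem([curve], [[inst]], scale_policies=[FIXED])
        res = fe.minimize(problem)
        paths = fe.write_outputs(problem, res, "pd01", tmp_path)
        dist = [p for p in paths if p.name.startswith("distpd01")]
        assert len(dist) == 1
        data = np.loadtxt(dist[0])
        assert data.shape[1] == 2
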