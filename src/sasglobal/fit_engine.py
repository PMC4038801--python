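"""The global objective, its minimizers and uncertainty estimates.

The goodness of fit over N_c curves is the reduced

    chi^2 = (1/N_c) sum_c (1/N_qc) sum_i [(Ihat_c(q_i) - Iexp_c(q_i)) /
            sigma_c(q_i)]^2,

with Ihat_c = kappa_c I_c + B_c; the per-curve scale kappa_c and flat
background B_c are either user-fixed or solved in closed form by
sigma-weighted linear least squares at every objective evaluation.
The optional penalty Psi (accumulated by ``fout`` assignments inside
link functions) is added to the objective but never to the reported
chi^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize as scipy_minimize

from .catalogue import ModelInstance  # noqa: F401  (re-export convenience)
from .curve_io import ParFileRecord, SASCurve, write_par_file
from .errors import ParameterError, SasGlobalError
from .parameters import ParameterRegistry
from .polydispersity import grid as poly_grid
from .polydispersity import polydisperse_average
from .resolution import smear_curve


@dataclass
class ScalePolicy:
    """Per-curve handling of kappa_c and B_c; None means closed-form fit."""

    kappa: float | None = None
    background: float | None = 0.0


@dataclass
class MinimizerSettings:
    methods: tuple = ("quasinewton",)
    seed: int | None = None
    n_iter: int = 2000               # monkey draws
    t_start: float = 1.0             # annealing start temperature
    t_end: float = 1e-3
    n_temps: int = 40
    steps_per_temp: int = 25
    step_scale: float = 0.1          # annealing move size, fraction of range
    xtol: float = 1e-8
    maxiter: int = 500

    def __post_init__(self):
        valid = {"monkey", "annealing", "simplex", "quasinewton"}
        for m in self.methods:
            if m not in valid:
                raise ParameterError(f"unknown minimizer {m!r}")
        if any(m in ("monkey", "annealing") for m in self.methods) \
                and self.seed is None:
            raise ParameterError("stochastic minimizers require a seed")


@dataclass
class FitProblem:
    curves: list                     # SASCurve
    model_stacks: list               # per curve: list[ModelInstance]
    scale_policies: list | None = None
    minimizer: MinimizerSettings = field(default_factory=MinimizerSettings)
    f_bounds: dict = field(default_factory=dict)
    f_start: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.curves) < 1:
            raise ParameterError("need at least one curve")
        if len(self.model_stacks) != len(self.curves):
            raise ParameterError("one model stack per curve required")
        for stack in self.model_stacks:
            if not stack:
                raise ParameterError("every curve needs at least one model")
        if self.scale_policies is None:
            self.scale_policies = [ScalePolicy() for _ in self.curves]
        self._registry = None

    @property
    def registry(self) -> ParameterRegistry:
        if self._registry is None:
            self._registry = ParameterRegistry(
                self.curves, self.model_stacks,
                f_bounds=self.f_bounds, f_start=self.f_start)
        return self._registry

    def policy(self, ci: int) -> ScalePolicy:
        pol = self.scale_policies[ci]
        if self.curves[ci].units == "arbitrary" and pol.kappa is not None:
            # arbitrary-unit curves always fit the scale factor
            return ScalePolicy(kappa=None, background=pol.background)
        return pol

    def replace_curves(self, curves) -> "FitProblem":
        clone = FitProblem(list(curves), self.model_stacks,
                           scale_policies=self.scale_policies,
                           minimizer=self.minimizer,
                           f_bounds=self.f_bounds, f_start=self.f_start)
        return clone


@dataclass
class Chi2Breakdown:
    chi2: float
    psi: float
    per_curve: list                  # (chi2_c, kappa_c, B_c)
    fitted: list                     # Ihat_c arrays


@dataclass
class FitResult:
    x_best: np.ndarray
    chi2: float
    psi: float
    kappa: np.ndarray
    background: np.ndarray
    fitted: list
    slot_names: list
    stddevs: np.ndarray | None = None
    covariance: np.ndarray | None = None
    correlation: np.ndarray | None = None
    n_evaluations: int = 0
    log: list = field(default_factory=list)

    def summary(self) -> str:
        lines = [f"chi2 = {self.chi2:.6g}  psi = {self.psi:.6g}"]
        for i, (k, b) in enumerate(zip(self.kappa, self.background)):
            lines.append(f"curve {i + 1}: kappa = {k:.6g}  B = {b:.6g}")
        for j, name in enumerate(self.slot_names):
            err = (f" +/- {self.stddevs[j]:.3g}"
                   if self.stddevs is not None else "")
            lines.append(f"  {name} = {self.x_best[j]:.6g}{err}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def model_curve(problem: FitProblem, ci: int, resolved) -> np.ndarray:
    """I_c(q) = sum_m w_cm I_cm(q), polydispersity averaged, then
    smeared with the curve's resolution description."""
    curve = problem.curves[ci]
    stack = problem.model_stacks[ci]

    def unsmeared(q):
        total = np.zeros_like(np.asarray(q, dtype=float))
        for inst, rm in zip(stack, resolved.models[ci]):
            evaluate = inst.evaluator()
            values = dict(rm.params)
            try:
                if rm.poly:
                    intensity = polydisperse_average(
                        lambda qq, vals: evaluate(qq, vals),
                        rm.poly, values, q)
                else:
                    intensity = evaluate(q, values)
            except SasGlobalError:
                raise
            except Exception as exc:
                raise SasGlobalError(
                    f"curve {curve.label!r}, model {inst.model!r} "
                    f"(params {values}): {exc}") from exc
            total = total + rm.weight * np.asarray(intensity)
        return total

    return smear_curve(unsmeared, curve.q, curve.resolution)


def solve_scale_background(i_model, curve: SASCurve, kappa_fixed=None,
                           background_fixed=None):
    """sigma-weighted least-squares (kappa, B) for Ihat = kappa I + B."""
    i_model = np.asarray(i_model, dtype=float)
    w = 1.0 / curve.sigma ** 2
    if kappa_fixed is not None and background_fixed is not None:
        return float(kappa_fixed), float(background_fixed)
    if kappa_fixed is not None:
        resid = curve.i_exp - kappa_fixed * i_model
        return float(kappa_fixed), float(np.sum(w * resid) / np.sum(w))
    if background_fixed is not None:
        num = np.sum(w * i_model * (curve.i_exp - background_fixed))
        den = np.sum(w * i_model ** 2)
        if den == 0:
            warnings.warn("zero model intensity: kappa undetermined",
                          stacklevel=2)
            return 1.0, float(background_fixed)
        return float(num / den), float(background_fixed)
    # both free: 2x2 normal equations
    s_ii = np.sum(w * i_model ** 2)
    s_i = np.sum(w * i_model)
    s_1 = np.sum(w)
    s_yi = np.sum(w * curve.i_exp * i_model)
    s_y = np.sum(w * curve.i_exp)
    det = s_ii * s_1 - s_i ** 2
    span = np.ptp(i_model)
    if det <= 0 or (span == 0 or det < 1e-12 * s_ii * s_1):
        warnings.warn("degenerate scale/background system (constant "
                      "model); background absorbs the signal", stacklevel=2)
        return 1.0, float(np.sum(w * (curve.i_exp - i_model)) / s_1)
    kappa = (s_yi * s_1 - s_y * s_i) / det
    bkg = (s_ii * s_y - s_i * s_yi) / det
    return float(kappa), float(bkg)


def chi2(problem: FitProblem, x) -> Chi2Breakdown:
    """Global reduced chi^2 and penalty Psi at optimizer vector x."""
    resolved = problem.registry.resolve(x)
    per_curve, fitted = [], []
    total = 0.0
    for ci, curve in enumerate(problem.curves):
        i_model = model_curve(problem, ci, resolved)
        pol = problem.policy(ci)
        kappa, bkg = solve_scale_background(i_model, curve,
                                            kappa_fixed=pol.kappa,
                                            background_fixed=pol.background)
        ihat = kappa * i_model + bkg
        chi2_c = float(np.mean(((ihat - curve.i_exp) / curve.sigma) ** 2))
        per_curve.append((chi2_c, kappa, bkg))
        fitted.append(ihat)
        total += chi2_c
    return Chi2Breakdown(total / len(problem.curves), resolved.psi,
                         per_curve, fitted)


def _objective(problem, x, counter=None):
    if counter is not None:
        counter[0] += 1
    try:
        bd = chi2(problem, x)
    except SasGlobalError:
        raise
    value = bd.chi2 + bd.psi
    if not np.isfinite(value):
        return 1e30
    return value


# ---------------------------------------------------------------------------
# minimizers
# ---------------------------------------------------------------------------

def _reflect_into(x, lo, hi):
    """Fold an unconstrained vector into the box by reflection."""
    span = hi - lo
    out = x.copy()
    finite = np.isfinite(span) & (span > 0)
    y = (out[finite] - lo[finite]) % (2.0 * span[finite])
    y = np.where(y > span[finite], 2.0 * span[finite] - y, y)
    out[finite] = lo[finite] + y
    out[~finite] = np.clip(out[~finite], lo[~finite], hi[~finite])
    return out


def _run_monkey(fun, x0, lo, hi, settings, rng, log):
    best_x, best_f = x0.copy(), fun(x0)
    width = np.where(np.isfinite(hi - lo), hi - lo, 1.0)
    base = np.where(np.isfinite(lo), lo, x0 - 0.5 * width)
    for _ in range(settings.n_iter):
        x = base + width * rng.random(x0.size)
        f = fun(x)
        if f < best_f:
            best_x, best_f = x, f
    log.append(("monkey", best_f))
    return best_x, best_f


def _run_annealing(fun, x0, lo, hi, settings, rng, log):
    width = np.where(np.isfinite(hi - lo), hi - lo, 1.0)
    x, f = x0.copy(), fun(x0)
    best_x, best_f = x.copy(), f
    temps = np.geomspace(settings.t_start, settings.t_end, settings.n_temps)
    for T in temps:
        for _ in range(settings.steps_per_temp):
            step = settings.step_scale * width * rng.uniform(-1, 1, x.size)
            xn = np.clip(x + step, lo, hi)
            fn = fun(xn)
            if not np.isfinite(fn):
                log.append(("annealing-reject-nonfinite", float(T)))
                continue
            if fn < f or rng.random() < np.exp(-(fn - f) / T):
                x, f = xn, fn
                if f < best_f:
                    best_x, best_f = x.copy(), f
    log.append(("annealing", best_f))
    return best_x, best_f


def _run_simplex(fun, x0, lo, hi, settings, log):
    def wrapped(z):
        return fun(_reflect_into(z, lo, hi))

    res = scipy_minimize(wrapped, x0, method="Nelder-Mead",
                         options={"xatol": settings.xtol,
                                  "fatol": settings.xtol,
                                  "maxiter": settings.maxiter * x0.size})
    x = _reflect_into(res.x, lo, hi)
    log.append(("simplex", float(res.fun)))
    return x, float(res.fun)


def _run_quasinewton(fun, x0, lo, hi, settings, log):
    bounds = [(None if not np.isfinite(l) else l,
               None if not np.isfinite(h) else h)
              for l, h in zip(lo, hi)]
    # finite-difference step scaled to each parameter's magnitude
    span = np.where(np.isfinite(hi - lo), hi - lo, 0.0)
    scale = np.maximum(np.abs(x0), span / 10.0)
    eps = np.maximum(1e-7 * np.maximum(scale, 1e-30), 1e-13)
    res = scipy_minimize(fun, x0, method="L-BFGS-B", bounds=bounds,
                         options={"maxiter": settings.maxiter,
                                  "ftol": settings.xtol,
                                  "gtol": 1e-12, "eps": eps})
    log.append(("quasinewton", float(res.fun)))
    return np.clip(res.x, lo, hi), float(res.fun)


def minimize(problem: FitProblem, x0=None, compute_errors=True) -> FitResult:
    """Run the configured minimizer chain on chi^2 + Psi.

    Methods chain (e.g. annealing then quasinewton), each starting from
    the best vector so far; with no free parameters an evaluation-only
    result is returned.
    """
    reg = problem.registry
    settings = problem.minimizer
    counter = [0]
    log: list = []

    if reg.n_free == 0:
        bd = chi2(problem, np.empty(0))
        return _make_result(problem, np.empty(0), bd, counter[0], log, None)

    lo, hi = reg.bounds()
    x = reg.x0() if x0 is None else np.asarray(x0, dtype=float).copy()
    fun = lambda z: _objective(problem, z, counter)   # noqa: E731
    rng = np.random.default_rng(settings.seed)

    best_x, best_f = x, fun(x)
    for method in settings.methods:
        if method == "monkey":
            best_x, best_f = _run_monkey(fun, best_x, lo, hi, settings, rng,
                                         log)
        elif method == "annealing":
            best_x, best_f = _run_annealing(fun, best_x, lo, hi, settings,
                                            rng, log)
        elif method == "simplex":
            best_x, best_f = _run_simplex(fun, best_x, lo, hi, settings, log)
        else:
            best_x, best_f = _run_quasinewton(fun, best_x, lo, hi, settings,
                                              log)

    bd = chi2(problem, best_x)
    errors = None
    if compute_errors and reg.n_free:
        try:
            errors = errors_hessian(problem, best_x)
        except SasGlobalError:
            errors = None
    return _make_result(problem, best_x, bd, counter[0], log, errors)


def _make_result(problem, x, bd, n_eval, log, errors):
    kappa = np.array([k for _, k, _ in bd.per_curve])
    bkg = np.array([b for _, _, b in bd.per_curve])
    result = FitResult(
        x_best=np.asarray(x, dtype=float), chi2=bd.chi2, psi=bd.psi,
        kappa=kappa, background=bkg, fitted=bd.fitted,
        slot_names=[s.name for s in problem.registry.slots],
        n_evaluations=n_eval, log=log)
    if errors is not None:
        result.stddevs, result.covariance, result.correlation = errors
    return result


# ---------------------------------------------------------------------------
# uncertainties
# ---------------------------------------------------------------------------

def _unreduced_chi2(problem, x):
    bd = chi2(problem, x)
    total = 0.0
    for ci, (chi2_c, _, _) in enumerate(bd.per_curve):
        total += chi2_c * problem.curves[ci].n_points
    return total


def errors_hessian(problem: FitProblem, x_best, rel_step=1e-4):
    """Parameter uncertainties from the curvature at the optimum.

    The covariance is 2 H^-1 with H the numerical Hessian of the
    UNREDUCED residual sum Q = sum_c sum_i r_ci^2 (the reduced chi^2 of
    the objective differs from Q only by the fixed per-curve
    normalization, which would misscale statistical errors).  A
    non-positive-definite H falls back to the pseudo-inverse with a
    warning; one-sided curvature at active bounds is flagged.
    """
    x_best = np.asarray(x_best, dtype=float)
    n = x_best.size
    lo, hi = problem.registry.bounds()
    at_bound = (x_best <= lo + 1e-12) | (x_best >= hi - 1e-12)
    if np.any(at_bound):
        warnings.warn("parameters at bounds: one-sided uncertainty "
                      f"({[problem.registry.slots[i].name for i in np.flatnonzero(at_bound)]})",
                      stacklevel=2)
    h = rel_step * np.maximum(np.abs(x_best), 1e-3)
    f0 = _unreduced_chi2(problem, x_best)
    H = np.empty((n, n))
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h[i]
        fpp = _unreduced_chi2(problem, x_best + ei)
        fmm = _unreduced_chi2(problem, x_best - ei)
        H[i, i] = (fpp - 2.0 * f0 + fmm) / h[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = h[j]
            fpq = _unreduced_chi2(problem, x_best + ei + ej)
            fpm = _unreduced_chi2(problem, x_best + ei - ej)
            fmp = _unreduced_chi2(problem, x_best - ei + ej)
            fmq = _unreduced_chi2(problem, x_best - ei - ej)
            H[i, j] = H[j, i] = (fpq - fpm - fmp + fmq) / (4.0 * h[i] * h[j])

    eigvals = np.linalg.eigvalsh(H)
    if np.any(eigvals <= 1e-12 * np.max(np.abs(eigvals))):
        warnings.warn("Hessian singular or not positive definite; "
                      "using pseudo-inverse", stacklevel=2)
        cov = 2.0 * np.linalg.pinv(H)
    else:
        cov = 2.0 * np.linalg.inv(H)
    diag = np.diag(cov).copy()
    bad = diag <= 0
    if np.any(bad):
        warnings.warn("non-positive variances flagged as unbounded",
                      stacklevel=2)
        diag[bad] = np.inf
    stddevs = np.sqrt(diag)
    denom = np.outer(stddevs, stddevs)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(np.isfinite(denom) & (denom > 0), cov / denom, 0.0)
    np.fill_diagonal(corr, 1.0)
    return stddevs, cov, corr


def errors_resampling(problem: FitProblem, x_best, n_iterations=50,
                      seed=0):
    """Monte Carlo uncertainties by resampling the data within sigma.

    Each iteration draws I_exp' ~ Normal(I_exp, sigma) pointwise,
    re-minimizes (quasi-Newton from x_best) and records the optimum;
    reports the per-parameter mean and standard deviation.  Iterations
    that fail to converge are excluded; more than 20% exclusions is an
    error.
    """
    if n_iterations < 2:
        raise ParameterError("n_iterations must be >= 2")
    rng = np.random.default_rng(seed)
    x_best = np.asarray(x_best, dtype=float)
    solutions, failures = [], 0
    quiet = MinimizerSettings(methods=("quasinewton",),
                              seed=problem.minimizer.seed,
                              maxiter=problem.minimizer.maxiter)
    for _ in range(n_iterations):
        curves = [SASCurve(c.q.copy(),
                           c.i_exp + rng.normal(0.0, c.sigma),
                           c.sigma.copy(), units=c.units,
                           p_coeffs=dict(c.p_coeffs), resolution=c.resolution,
                           label=c.label)
                  for c in problem.curves]
        perturbed = problem.replace_curves(curves)
        perturbed.minimizer = quiet
        try:
            res = minimize(perturbed, x0=x_best, compute_errors=False)
            if not np.isfinite(res.chi2):
                raise SasGlobalError("non-finite chi2")
            solutions.append(res.x_best)
        except SasGlobalError:
            failures += 1
    if failures > 0.2 * n_iterations:
        raise SasGlobalError(
            f"{failures}/{n_iterations} resampling iterations failed")
    sols = np.array(solutions)
    return sols.mean(axis=0), sols.std(axis=0, ddof=1)


# ---------------------------------------------------------------------------
# real-space transform
# ---------------------------------------------------------------------------

def compute_pr(i_model, q_grid, r_grid):
    """Pair distance distribution p(r) from I(q) by direct quadrature.

    p(r) = (r^2 / 2 pi^2) int I(q) q^2 sinc(q r) dq over the supplied
    grid (Simpson); requires dq * r_max <= pi/2 so the oscillations
    are resolved.
    """
    q = np.asarray(q_grid, dtype=float)
    intensity = np.asarray(i_model, dtype=float)
    r = np.asarray(r_grid, dtype=float)
    dq = np.max(np.diff(q))
    if dq * r.max() > np.pi / 2.0:
        raise ParameterError(
            f"q grid too coarse for r_max = {r.max():g} "
            f"(dq * r_max = {dq * r.max():.3g} > pi/2)")
    from scipy.integrate import simpson
    out = np.empty(r.size)
    for k, rk in enumerate(r):
        integrand = intensity * q ** 2 * np.sinc(q * rk / np.pi)
        out[k] = rk ** 2 / (2.0 * np.pi ** 2) * simpson(integrand, x=q)
    return out


# ---------------------------------------------------------------------------
# output files
# ---------------------------------------------------------------------------

def result_records(problem: FitProblem, result: FitResult):
    records = []
    for j, slot in enumerate(problem.registry.slots):
        sd = float(result.stddevs[j]) if result.stddevs is not None else 0.0
        if not np.isfinite(sd):
            sd = 0.0
        records.append(ParFileRecord(j + 1, slot.name,
                                     float(result.x_best[j]), sd,
                                     slot.lower, slot.upper))
    return records


def write_outputs(problem: FitProblem, result: FitResult, code: str,
                  directory="."):
    """Write gen<code>.par, per-curve fitted curves, the chi^2 summary
    and the distribution files of polydisperse parameters."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = [write_par_file(result_records(problem, result), code, directory)]

    for ci, curve in enumerate(problem.curves):
        path = directory / f"fit{code}_{curve.label or f'c{ci + 1}'}.dat"
        with open(path, "w") as fh:
            fh.write("# q I_exp sigma I_fit\n")
            for row in zip(curve.q, curve.i_exp, curve.sigma,
                           result.fitted[ci]):
                fh.write(" ".join(f"{v:.6E}" for v in row) + "\n")
        paths.append(path)

    summary = directory / f"sum{code}.txt"
    with open(summary, "w") as fh:
        fh.write(result.summary() + "\n")
    paths.append(summary)

    resolved = problem.registry.resolve(result.x_best)
    for ci, stack in enumerate(problem.model_stacks):
        for mi, rm in enumerate(resolved.models[ci]):
            for pname, rp in rm.poly.items():
                x, wf = poly_grid(rp)
                path = directory / (f"dist{code}_c{ci + 1}m{mi + 1}_"
                                    f"{pname}.dat")
                with open(path, "w") as fh:
                    fh.write(f"# {rp.kind} distribution of {pname}\n")
                    for xi, wi in zip(x, wf):
                        fh.write(f"{xi:.6E} {wi:.6E}\n")
                paths.append(path)
    return paths
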