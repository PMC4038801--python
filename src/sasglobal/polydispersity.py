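"""Distribution models and the decoupled polydispersity average.

A polydisperse model parameter X is integrated over its normalized
distribution f(X); with several simultaneously polydisperse parameters
the joint distribution factorizes (decoupling approximation) and the
one-dimensional quadrature is applied repeatedly.  All distributions
are parametrized by their mean and a width parameter and are truncated
at zero (physical parameters are positive) and renormalized on the
integration grid.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats
from scipy.optimize import brentq

from .errors import ParameterError
from .parameters import ResolvedPoly

#: registered distribution kinds (local registry ids)
KINDS = ("delta", "uniform", "triangular", "gaussian", "lognormal",
         "schulz", "weibull")


def _mean_width(rp: ResolvedPoly):
    params = rp.params
    if "mean" not in params:
        raise ParameterError(f"{rp.kind} distribution needs a 'mean'")
    mean = float(params["mean"])
    width = float(params.get("width", 0.0))
    if width < 0:
        raise ParameterError("width must be >= 0")
    return mean, width


def _frozen(rp: ResolvedPoly):
    """scipy frozen distribution for a (mean, width) parametrization.

    width is the standard deviation for gaussian/lognormal/schulz/
    weibull and the half-range (uniform) / half-base (triangular) of
    the bounded kinds.
    """
    mean, width = _mean_width(rp)
    kind = rp.kind
    if kind == "uniform":
        return stats.uniform(loc=mean - width, scale=2.0 * width)
    if kind == "triangular":
        return stats.triang(c=0.5, loc=mean - width, scale=2.0 * width)
    if kind == "gaussian":
        return stats.norm(loc=mean, scale=width)
    if kind == "lognormal":
        if mean <= 0:
            raise ParameterError("lognormal requires mean > 0")
        s2 = np.log1p((width / mean) ** 2)
        s = np.sqrt(s2)
        mu = np.log(mean) - 0.5 * s2
        return stats.lognorm(s=s, scale=np.exp(mu))
    if kind == "schulz":
        if mean <= 0:
            raise ParameterError("schulz requires mean > 0")
        z = (mean / width) ** 2 - 1.0
        if z <= -1.0:
            raise ParameterError("schulz width too large (z <= -1)")
        return stats.gamma(a=z + 1.0, scale=mean / (z + 1.0))
    if kind == "weibull":
        if mean <= 0:
            raise ParameterError("weibull requires mean > 0")
        cv = width / mean

        def cv_of_k(k):
            from scipy.special import gamma as g
            m = g(1.0 + 1.0 / k)
            return np.sqrt(g(1.0 + 2.0 / k) - m ** 2) / m

        k = brentq(lambda kk: cv_of_k(kk) - cv, 0.1, 50.0)
        from scipy.special import gamma as g
        return stats.weibull_min(c=k, scale=mean / g(1.0 + 1.0 / k))
    raise ParameterError(f"unknown polydispersity kind {rp.kind!r}")


def _simpson_weights(n: int, h: float):
    w = np.ones(n)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    return w * h / 3.0


def grid(rp: ResolvedPoly):
    """Integration nodes and normalized weights (sum w_i f_i = 1).

    The grid spans mean +/- n_width * width, truncated at 0; Simpson
    weights; zero width degenerates to a delta with a warning for
    continuous kinds.
    """
    mean, width = _mean_width(rp)
    if rp.kind == "delta" or width == 0.0:
        if rp.kind != "delta" and width == 0.0:
            warnings.warn(f"{rp.kind} with zero width treated as delta",
                          stacklevel=2)
        return np.array([mean]), np.array([1.0])
    lo = mean - rp.n_width * width
    hi = mean + rp.n_width * width
    if rp.kind in ("uniform", "triangular"):
        lo, hi = mean - width, mean + width
    lo = max(lo, 1e-12 * max(abs(mean), 1.0)) if lo <= 0 else lo
    x = np.linspace(lo, hi, rp.n_points)
    f = _frozen(rp).pdf(x)
    w = _simpson_weights(rp.n_points, x[1] - x[0])
    norm = np.sum(w * f)
    if norm <= 0:
        raise ParameterError(f"{rp.kind} density vanishes on the grid")
    return x, w * f / norm


def density(rp: ResolvedPoly, x):
    """Normalized density values on an arbitrary grid (>= 0)."""
    x = np.asarray(x, dtype=float)
    mean, width = _mean_width(rp)
    if rp.kind == "delta" or width == 0.0:
        out = np.zeros_like(x)
        out[np.argmin(np.abs(x - mean))] = 1.0
        return out
    return _frozen(rp).pdf(x)


def polydisperse_average(evaluator, poly_map: dict, base_params: dict, q):
    """<I>(q) = sum over the product quadrature of w f(X) I(q; X).

    evaluator(q, params_dict) -> I(q); poly_map maps parameter names to
    ResolvedPoly configs (at most 3 simultaneously); delta kinds
    reproduce the monodisperse call bitwise.
    """
    active = dict(poly_map)
    # delta distributions contribute a single node at the mean
    grids = {n: grid(rp) for n, rp in active.items()}
    non_trivial = [n for n, (x, w) in grids.items() if len(x) > 1]
    if len(non_trivial) > 3:
        raise ParameterError(
            f"{len(non_trivial)} simultaneously polydisperse parameters; "
            f"at most 3 supported")
    if not non_trivial:
        params = dict(base_params)
        for n, (x, _) in grids.items():
            params[n] = float(x[0])
        return evaluator(q, params)

    q = np.asarray(q, dtype=float)
    out = np.zeros_like(q, dtype=float)

    def recurse(idx, params, weight):
        nonlocal out
        if idx == len(active):
            out = out + weight * np.asarray(evaluator(q, params))
            return
        name = list(active)[idx]
        x, w = grids[name]
        for xi, wi in zip(x, w):
            params[name] = float(xi)
            recurse(idx + 1, params, weight * wi)
        del params[name]

    recurse(0, dict(base_params), 1.0)
    return out
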