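"""Instrumental smearing of model curves.

Each instrumental effect (wavelength spread, collimation, detector
resolution) contributes to the width of a Gaussian resolution function
which is convolved with the model intensity; finite slit-height
geometry adds the classical integral over the transverse component.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.legendre import leggauss

from .curve_io import ResolutionSpec


def gaussian_smear(evaluator, q, sigma_res, n_points=21, n_width=4.0):
    """Convolve evaluator(q) with a Gaussian of width sigma_res(q).

    sigma_res: scalar or per-point array [1/A]; quadrature over
    +/- n_width sigma with Simpson weights; sigma_res = 0 rows reduce
    to the unsmeared model.  The model is evaluated at |q'| (SAS
    intensities are even in q).
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    sig = np.broadcast_to(np.asarray(sigma_res, dtype=float), q.shape).copy()
    if n_points < 15:
        n_points = 15
    if n_points % 2 == 0:
        n_points += 1
    out = np.empty_like(q)
    active = sig > 0
    if np.any(~active):
        out[~active] = np.asarray(evaluator(q[~active]))
    if not np.any(active):
        return out

    t = np.linspace(-n_width, n_width, n_points)
    h = t[1] - t[0]
    w = np.ones(n_points)
    w[1:-1:2], w[2:-1:2] = 4.0, 2.0
    w *= h / 3.0
    kernel = w * np.exp(-0.5 * t ** 2) / np.sqrt(2.0 * np.pi)
    kernel /= kernel.sum()

    qa, sa = q[active], sig[active]
    nodes = np.abs(qa[:, None] + sa[:, None] * t[None, :])
    vals = np.asarray(evaluator(nodes.ravel())).reshape(nodes.shape)
    out[active] = vals @ kernel
    return out


def slit_smear(evaluator, q, slit_length, n_points=48):
    """Finite slit-height smearing.

    I_s(q) = (1/L) int_0^L I(sqrt(q^2 + t^2)) dt with a uniform
    weighting of half-length L = slit_length [1/A]; L = 0 is the
    identity.  For I ~ q^-4 and L >> q this reproduces the classical
    slit-smeared Porod q^-3 behaviour.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if slit_length <= 0:
        return np.asarray(evaluator(q))
    x, w = leggauss(n_points)
    t = 0.5 * slit_length * (x + 1.0)
    wt = 0.5 * slit_length * w / slit_length   # normalized W(t)
    nodes = np.sqrt(q[:, None] ** 2 + t[None, :] ** 2)
    vals = np.asarray(evaluator(nodes.ravel())).reshape(nodes.shape)
    return vals @ wt


def smear_curve(evaluator, q, spec: ResolutionSpec | None):
    """Apply the full resolution description of one curve."""
    if spec is None or spec.is_trivial:
        return np.asarray(evaluator(np.asarray(q, dtype=float)))
    inner = evaluator
    if spec.slit_length > 0:
        def inner(qq, _ev=evaluator, _L=spec.slit_length):
            return slit_smear(_ev, qq, _L)
    sig = spec.sigma_at(q)
    if np.any(sig > 0):
        return gaussian_smear(inner, q, sig)
    return np.asarray(inner(np.asarray(q, dtype=float)))


def power_law_tail(q_data, i_data, fraction=0.2):
    """Fit I = A q^-p over the last decade (or ``fraction``) of the
    data; returns (A, p) for tail extrapolation beyond the data range."""
    q_data = np.asarray(q_data, dtype=float)
    i_data = np.asarray(i_data, dtype=float)
    n = max(int(len(q_data) * fraction), 5)
    qs, is_ = q_data[-n:], i_data[-n:]
    good = is_ > 0
    if good.sum() < 3:
        return 0.0, 4.0
    slope, intercept = np.polyfit(np.log(qs[good]), np.log(is_[good]), 1)
    return float(np.exp(intercept)), float(-slope)
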