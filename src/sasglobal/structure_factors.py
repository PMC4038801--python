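"""Interparticle structure factors S(q).

Each S(q) multiplies a form factor within one model instance,
I(q) = n P(q) S(q) — the monodisperse (decoupling) approximation.
Catalogue: Percus-Yevick hard spheres, the rescaled screened-Coulomb
mean spherical approximation (MSA), the random phase approximation
(RPA), the Teixeira fractal cluster factor, and finite 1-D bilayer
stacks with either paracrystalline (Gaussian cumulative) disorder or
thermal-fluctuation (modified Caille) disorder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dst
from scipy.interpolate import interp1d
from scipy.optimize import brentq
from scipy.special import gamma as gamma_fn

from .errors import ConvergenceError, ParameterError, StabilityError

EULER_GAMMA = float(np.euler_gamma)

# e^2/(4 pi eps0 k_B) in Angstrom*Kelvin: Bjerrum length = BJERRUM_AK/(eps*T)
BJERRUM_AK = 1.67101e5
# Debye length of water at 298 K, eps = 78.3: kappa^-1 [A] = 3.041/sqrt(I[M])
DEBYE_A_298 = 3.041
_EPS_T_REF = 78.3 * 298.0


@dataclass
class HardSphereParams:
    R_hs: float            # effective hard-sphere radius [A]
    phi: float             # volume fraction

    def __post_init__(self):
        if self.R_hs <= 0:
            raise ParameterError("R_hs must be > 0")
        if not (0.0 <= self.phi < 0.74):
            raise ParameterError(f"phi must be in [0, 0.74), got {self.phi}")


@dataclass
class YukawaParams(HardSphereParams):
    Z: float = 0.0         # effective charge [e]
    T: float = 298.0       # [K]
    eps: float = 78.3      # solvent dielectric constant
    I_s: float = 0.1       # ionic strength [M]

    def __post_init__(self):
        super().__post_init__()
        if self.T <= 0 or self.eps <= 0 or self.I_s < 0:
            raise ParameterError("need T > 0, eps > 0, I_s >= 0")

    @property
    def kappa(self) -> float:
        """Inverse Debye screening length [1/A]."""
        if self.I_s == 0:
            return 0.0
        scale = np.sqrt(_EPS_T_REF / (self.eps * self.T))
        return np.sqrt(self.I_s) / DEBYE_A_298 * scale

    @property
    def bjerrum(self) -> float:
        return BJERRUM_AK / (self.eps * self.T)

    @property
    def contact_potential(self) -> float:
        """beta U at contact (r = 2 R_hs), DLVO screened-Coulomb form."""
        sigma = 2.0 * self.R_hs
        ka = self.kappa * self.R_hs
        return self.Z ** 2 * self.bjerrum / (sigma * (1.0 + ka) ** 2)


@dataclass
class FractalParams:
    D: float               # fractal dimension
    r0: float              # primary particle radius [A]
    xi: float              # fractal cutoff length [A]

    def __post_init__(self):
        if not (1.0 < self.D <= 3.0):
            raise ParameterError(f"D must be in (1, 3], got {self.D}")
        if self.r0 <= 0 or self.xi < 0:
            raise ParameterError("need r0 > 0, xi >= 0")


@dataclass
class StackParams:
    N: int                 # correlated bilayers
    d: float               # repeat distance [A]
    eta: float = 0.0       # Caille parameter (MCT)
    Delta: float = 0.0     # Gaussian displacement width [A] (paracrystal)

    def __post_init__(self):
        if self.N < 1:
            raise ParameterError("N must be >= 1")
        if self.d <= 0:
            raise ParameterError("d must be > 0")
        if self.eta < 0 or self.Delta < 0:
            raise ParameterError("eta and Delta must be >= 0")


# ---------------------------------------------------------------------------
# Percus-Yevick hard spheres
# ---------------------------------------------------------------------------

def _py_g_over_a(A, phi):
    """24 phi G(A)/A of the PY direct-correlation transform."""
    al = (1.0 + 2.0 * phi) ** 2 / (1.0 - phi) ** 4
    be = -6.0 * phi * (1.0 + phi / 2.0) ** 2 / (1.0 - phi) ** 4
    ga = phi * al / 2.0
    A = np.asarray(A, dtype=float)
    small = A < 0.2
    As = np.where(small, 1.0, A)
    sinA, cosA = np.sin(As), np.cos(As)
    G = (al * (sinA - As * cosA) / As ** 2
         + be * (2.0 * As * sinA + (2.0 - As ** 2) * cosA - 2.0) / As ** 3
         + ga * (-As ** 4 * cosA
                 + 4.0 * ((3.0 * As ** 2 - 6.0) * cosA
                          + (As ** 3 - 6.0 * As) * sinA + 6.0)) / As ** 5)
    full = G / As
    series = ((al / 3.0 + be / 4.0 + ga / 6.0)
              + A ** 2 * (-al / 30.0 - be / 36.0 - ga / 48.0)
              + A ** 4 * (al / 840.0 + be / 960.0 + ga / 1200.0))
    return 24.0 * phi * np.where(small, series, full)


def py_hardsphere(q, p: HardSphereParams):
    """Percus-Yevick hard-sphere structure factor.

    S(0) = (1 - phi)^4 / (1 + 2 phi)^2 (PY compressibility limit);
    S -> 1 at large q.
    """
    q = np.asarray(q, dtype=float)
    if p.phi == 0:
        return np.ones_like(q)
    A = 2.0 * p.R_hs * q
    return 1.0 / (1.0 + _py_g_over_a(A, p.phi))


# ---------------------------------------------------------------------------
# screened-Coulomb MSA (numerical Ornstein-Zernike solution with
# Hansen-Hayter rescaling)
# ---------------------------------------------------------------------------

def _oz_msa_grids(n_r=2048, dr=0.01):
    r = dr * np.arange(1, n_r + 1)
    dq = np.pi / ((n_r + 1) * dr)
    qg = dq * np.arange(1, n_r + 1)
    return r, qg, dq


def _oz_msa_iterate(rho, core, beta_u, ft, ift, gam, tol, max_iter):
    """Picard iteration with adaptive mixing; returns gamma(r) or None."""
    for mix in (0.5, 0.2, 0.08, 0.03, 0.01):
        g = gam.copy()
        for _ in range(max_iter):
            c = np.where(core, -1.0 - g, -beta_u)
            ch = ft(c)
            denom = 1.0 - rho * ch
            if np.any(denom <= 0):
                break
            g_new = ift(rho * ch ** 2 / denom)
            if not np.all(np.isfinite(g_new)):
                break
            err = np.max(np.abs(g_new - g))
            g = (1.0 - mix) * g + mix * g_new
            if err < tol:
                return g
        # retry with smaller mixing, restarting from the supplied guess
    return None


def _oz_msa_solve(phi, gamma_contact, K, n_r=2048, dr=0.01, tol=1e-10,
                  max_iter=4000):
    """Solve OZ + MSA closure for the hard-core Yukawa fluid.

    Reduced units of the hard-core diameter sigma; the tail potential
    is beta u(x) = gamma_contact * exp(-K (x - 1))/x for x > 1.
    Strong coupling is handled by gradually charging the tail, warm-
    starting each step from the previous solution.
    Returns (q_grid, S(q), contact value of g).
    """
    r, qg, dq = _oz_msa_grids(n_r, dr)
    rho = 6.0 * phi / np.pi
    core = r < 1.0

    def tail(strength):
        bu = strength * np.exp(-K * (r - 1.0)) / r
        bu[core] = 0.0
        return bu

    def ft(fr):
        return 2.0 * np.pi * dr / qg * dst(r * fr, type=1)

    def ift(fq):
        return dq / (4.0 * np.pi ** 2 * r) * dst(qg * fq, type=1)

    n_steps = max(1, int(np.ceil(abs(gamma_contact) / 2.0)))
    n_steps = min(n_steps, 60)
    gam = np.zeros_like(r)
    for step in range(1, n_steps + 1):
        beta_u = tail(gamma_contact * step / n_steps)
        gam = _oz_msa_iterate(rho, core, beta_u, ft, ift, gam, tol, max_iter)
        if gam is None:
            raise ConvergenceError(
                f"OZ-MSA iteration failed (phi={phi}, "
                f"gamma={gamma_contact}, K={K}, step {step}/{n_steps})")

    beta_u = tail(gamma_contact)
    c = np.where(core, -1.0 - gam, -beta_u)
    ch = ft(c)
    sq = 1.0 / (1.0 - rho * ch)
    # quadratic extrapolation of g = 1 - beta_u + gamma to contact
    idx = np.flatnonzero(r >= 1.0)[:8]
    gvals = 1.0 - beta_u[idx] + gam[idx]
    coef = np.polyfit(r[idx], gvals, 2)
    return qg, sq, float(np.polyval(coef, 1.0))


def _rescaled_system(p: YukawaParams, s: float):
    """Reduced-unit parameters after enlarging the core by factor s."""
    sigma = 2.0 * p.R_hs
    phi_s = p.phi * s ** 3
    K_s = p.kappa * sigma * s
    gamma_s = p.contact_potential * np.exp(-p.kappa * sigma * (s - 1.0)) / s
    return phi_s, gamma_s, K_s


def hayter_penfold_msa(q, p: YukawaParams, n_r=2048, dr=0.01):
    """Rescaled MSA structure factor for screened-Coulomb spheres.

    The Ornstein-Zernike equation with the MSA closure for the DLVO
    Yukawa tail is solved numerically (sine-transform Picard
    iteration); whenever the contact value of g(r) would be negative
    the system is mapped onto an equivalent larger-diameter one whose
    contact value vanishes (Hansen-Hayter rescaling).  The numerical
    transform is anchored to the analytic Percus-Yevick solution by a
    ratio correction, so the Z = 0 limit reduces to PY exactly.
    """
    q = np.asarray(q, dtype=float)
    if p.phi == 0:
        return np.ones_like(q)
    if p.Z == 0 or p.contact_potential == 0:
        return py_hardsphere(q, p)

    sigma = 2.0 * p.R_hs

    def contact(s):
        # coarser grid: only the sign/zero of g(contact) matters here
        phi_s, gamma_s, K_s = _rescaled_system(p, s)
        if phi_s >= 0.74:
            raise ConvergenceError("rescaled volume fraction out of range")
        _, _, gc = _oz_msa_solve(phi_s, gamma_s, K_s, n_r=1024, dr=0.02,
                                 tol=1e-8)
        return gc

    s = 1.0
    gc = contact(1.0)
    if gc < 0.0:
        s_hi = 1.0
        for _ in range(40):
            s_hi *= 1.05
            if (p.phi * s_hi ** 3) >= 0.72:
                s_hi /= 1.05
                break
            if contact(s_hi) >= 0.0:
                break
        else:
            raise ConvergenceError("could not bracket the rescaling factor")
        if contact(s_hi) >= 0.0:
            s = brentq(contact, 1.0, s_hi, xtol=5e-3)
        else:
            s = s_hi   # densest admissible packing; best available

    phi_s, gamma_s, K_s = _rescaled_system(p, s)
    qg, sq_num, _ = _oz_msa_solve(phi_s, gamma_s, K_s, n_r, dr)
    _, sq_ref, _ = _oz_msa_solve(phi_s, 0.0, K_s, n_r, dr)
    ratio = interp1d(qg, sq_num / sq_ref, kind="cubic",
                     fill_value="extrapolate")
    Q = q * sigma * s
    py = py_hardsphere(q, HardSphereParams(R_hs=p.R_hs * s, phi=phi_s))
    return py * ratio(Q)


# ---------------------------------------------------------------------------
# random phase approximation
# ---------------------------------------------------------------------------

def yukawa_ft_beta(A, kappa):
    """3-D Fourier transform of beta v(r) = A exp(-kappa r)/r.

    A in units of k_B T * Angstrom; returns a callable q -> 4 pi A /
    (q^2 + kappa^2) [Angstrom^3, in k_B T units].
    """
    def v_tilde(q):
        q = np.asarray(q, dtype=float)
        return 4.0 * np.pi * A / (q ** 2 + kappa ** 2)
    return v_tilde


def rpa(q, n, v_tilde, S0=None):
    """Random phase approximation S(q) = S0/(1 + n S0 v(q)/kBT).

    n: number density [1/A^3]; v_tilde: callable or array giving the
    3-D Fourier transform of the perturbing potential in k_B T *
    Angstrom^3; S0: reference structure factor (array or None for 1).
    """
    q = np.asarray(q, dtype=float)
    s0 = np.ones_like(q) if S0 is None else np.asarray(S0, dtype=float)
    v = v_tilde(q) if callable(v_tilde) else np.asarray(v_tilde, dtype=float)
    denom = 1.0 + n * s0 * v
    if np.any(denom <= 0):
        raise StabilityError("RPA denominator <= 0: potential too attractive")
    return s0 / denom


# ---------------------------------------------------------------------------
# Teixeira fractal
# ---------------------------------------------------------------------------

def teixeira_fractal(q, p: FractalParams):
    """Fractal-cluster structure factor (mass fractal, cutoff xi).

    S(q) = 1 + D Gamma(D-1) sin[(D-1) arctan(q xi)] /
           [(q r0)^D (1 + 1/(q xi)^2)^((D-1)/2)];
    S(0) = 1 + Gamma(D+1) (xi/r0)^D.
    """
    q = np.asarray(q, dtype=float)
    D, r0, xi = p.D, p.r0, p.xi
    if xi == 0:
        return np.ones_like(q)
    u = q * xi
    small = u < 1e-6
    us = np.where(small, 1.0, u)
    # sin((D-1) arctan u) * u^(D-1) / (1+u^2)^((D-1)/2) rewritten so the
    # (q r0)^-D singularity cancels against (xi/r0)^D:
    shape = np.where(
        small, D - 1.0,
        np.sin((D - 1.0) * np.arctan(us)) / us
        / (1.0 + us ** 2) ** ((D - 1.0) / 2.0))
    return 1.0 + D * gamma_fn(D - 1.0) * (xi / r0) ** D * shape


# ---------------------------------------------------------------------------
# 1-D stacks: paracrystal and modified Caille theory
# ---------------------------------------------------------------------------

def _stack_sum(q, N, d, damping):
    """(1/N) [N + 2 sum_k (N-k) cos(k q d) damping(k, q)]."""
    q = np.asarray(q, dtype=float)
    s = np.ones_like(q)
    for k in range(1, N):
        s = s + 2.0 * (N - k) / N * np.cos(k * q * d) * damping(k, q)
    return s


def paracrystal_1d(q, p: StackParams):
    """Finite 1-D paracrystal with Gaussian cumulative disorder,
    normalized by N so S -> 1 at large q."""
    return _stack_sum(q, int(p.N), p.d,
                      lambda k, q_: np.exp(-k * q_ ** 2 * p.Delta ** 2 / 2.0))


def mct(q, p: StackParams):
    """Modified Caille theory for a finite bilayer stack (normalized
    by N).  Thermal fluctuations damp the k-th neighbour correlation by
    exp[-(d/2 pi)^2 q^2 eta (gamma_E + ln(pi k))]."""
    pref = (p.d / (2.0 * np.pi)) ** 2 * p.eta
    return _stack_sum(
        q, int(p.N), p.d,
        lambda k, q_: np.exp(-pref * q_ ** 2 * (EULER_GAMMA + np.log(np.pi * k))))
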