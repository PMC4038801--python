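"""Equilibrium-thermodynamics link models for model weights.

Two built-in chemical models bind form-factor weights to sample
conditions: a monomer-dimer dissociation equilibrium (weights follow
from the dissociation free energy and the weight concentration) and a
two-state folding equilibrium with a quadratic dependence of the
unfolding free energy on denaturant molarity.  Free energies are
carried in units of k_B T; the standard state for the dissociation
constant is 1 M.

The models are exposed both as plain functions and as named link
functions (``alpha_mono``, ``frac_folded``) usable inside link
expressions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .parameters import register_link_function

AVOGADRO = 6.02214076e23


@dataclass
class DissociationParams:
    """Monomer-dimer equilibrium: 2 M <-> D."""

    dG_dis: float          # dissociation free energy [k_B T]
    C: float               # weight concentration [g/l]
    M_mon: float           # monomer molar mass [g/mol]
    T: float = 298.0       # [K]; bookkeeping only (dG is in k_B T)

    def __post_init__(self):
        if self.C < 0 or self.M_mon <= 0:
            raise ParameterError("need C >= 0 and M_mon > 0")

    @property
    def total_molarity(self) -> float:
        """Total monomer molarity C_t [M]."""
        return self.C / self.M_mon


def monomer_fraction(p: DissociationParams) -> float:
    """Fraction alpha of chains present as free monomers.

    Mass action for 2 M <-> D with K_d = exp(-dG_dis) [M]:
    2 alpha^2 C_t / (1 - alpha) = K_d, solved in the numerically
    stable form alpha = 2 / (1 + sqrt(1 + 8 C_t / K_d)).
    """
    ct = p.total_molarity
    if ct == 0:
        return 1.0
    kd = np.exp(-p.dG_dis)
    alpha = 2.0 / (1.0 + np.sqrt(1.0 + 8.0 * ct / kd))
    return float(alpha)


def oligomer_weights(alpha: float, p: DissociationParams):
    """Number densities (w_mon, w_dim) in 1/cm^3.

    w_mon = alpha C N_A / M, w_dim = (1 - alpha) C N_A / (2 M) with C
    converted to g/cm^3; monomer mass is conserved exactly:
    M (w_mon + 2 w_dim) = C N_A.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ParameterError(f"alpha must be in [0, 1], got {alpha}")
    c_cm3 = p.C * 1.0e-3              # g/l -> g/cm^3
    n_chains = c_cm3 * AVOGADRO / p.M_mon
    return alpha * n_chains, (1.0 - alpha) * n_chains / 2.0


@dataclass
class UnfoldingParams:
    """Two-state folding equilibrium vs denaturant molarity U."""

    dG0: float             # [k_B T]
    dG1: float = 0.0       # [k_B T / M]
    dG2: float = 0.0       # [k_B T / M^2]
    U: float = 0.0         # urea molarity [M]
    T: float = 298.0

    def __post_init__(self):
        if self.U < 0:
            raise ParameterError("U must be >= 0")

    @property
    def dG_unf(self) -> float:
        return self.dG0 + self.dG1 * self.U + self.dG2 * self.U ** 2


def folded_fraction(p: UnfoldingParams) -> float:
    """Fraction of chains in the native state.

    K_unf = exp(-dG_unf); f_folded = 1/(1 + K_unf).  The weights of
    the native and unfolded models are f n and (1 - f) n with n the
    total chain number density.
    """
    return float(1.0 / (1.0 + np.exp(-p.dG_unf)))


# -- link-expression built-ins ----------------------------------------------

def _alpha_mono(dg, ct):
    """alpha(dG_dis [kT], C_t [M]) for use inside link expressions."""
    if ct <= 0:
        return 1.0
    return 2.0 / (1.0 + np.sqrt(1.0 + 8.0 * ct * np.exp(dg)))


def _frac_folded(dg):
    return 1.0 / (1.0 + np.exp(-dg))


register_link_function("alpha_mono", _alpha_mono)
register_link_function("frac_folded", _frac_folded)
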