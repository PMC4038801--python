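"""Simulated SAS experiments for validation and testing.

Noise model: each point of a computed curve I(q) is displaced by a
Gaussian of standard deviation sigma(q) = k I(q)^alpha, with k chosen
so the first point has a prescribed relative error (3% is the typical
synchrotron-quality default used throughout).

Two batch generators emulate condition series on beta-lactoglobulin
(BLG, an 18.4 kDa lipocalin): a SAXS concentration series probing the
monomer-dimer dissociation equilibrium and a SANS urea series probing
two-state unfolding into an excluded-volume worm-like chain.  Both can
run with volume-matched geometric surrogates (sphere monomer,
touching-sphere dimer) so no structure download is needed, or with a
PDB structure when one is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import form_factors as ff
from .catalogue import DENSITY_CM3_TO_ABS
from .curve_io import SASCurve
from .errors import ParameterError
from .thermo_links import (AVOGADRO, DissociationParams, UnfoldingParams,
                           folded_fraction, monomer_fraction,
                           oligomer_weights)

#: partial specific volume of a globular protein [cm^3/g]
PROTEIN_PSV = 0.73
#: default q grid: 100 log-spaced points in [0.01, 0.5] 1/A
DEFAULT_Q = np.geomspace(0.01, 0.5, 100)
#: protein / water electron-density contrast, X-rays [A^-2]
XRAY_PROTEIN_CONTRAST = (0.42 - ff.WATER_ELECTRON_DENSITY) * ff.R_ELECTRON
#: protein SLD [A^-2] and D2O SLD for the SANS series
NEUTRON_PROTEIN_SLD = 1.8e-6
NEUTRON_D2O_SLD = 6.38e-6

BLG_MONOMER_MASS = 18400.0


def protein_radius(molar_mass, psv=PROTEIN_PSV):
    """Radius [A] of the volume-equivalent sphere of a globular protein."""
    volume = molar_mass * psv / AVOGADRO * 1.0e24    # A^3
    return (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)


@dataclass
class NoiseModel:
    rel_err_first: float = 0.03
    alpha: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.rel_err_first <= 0:
            raise ParameterError("rel_err_first must be > 0")


def simulate_curve(evaluator, q_grid, noise: NoiseModel, p_coeffs=None,
                   label="sim", units="absolute",
                   noiseless=False) -> SASCurve:
    """Evaluate a model on the grid and add the power-law noise.

    k = rel_err_first * I(q_1)^(1 - alpha), sigma(q) = k I(q)^alpha, so
    sigma(q_1)/I(q_1) equals rel_err_first exactly; I_exp ~
    Normal(I, sigma) with the model's seed.  With ``noiseless`` the
    sigma column is kept but the intensities are not displaced.
    """
    q = np.asarray(q_grid, dtype=float)
    intensity = np.asarray(evaluator(q), dtype=float)
    if intensity[0] <= 0:
        raise ParameterError("noise model requires I(q_1) > 0")
    k = noise.rel_err_first * intensity[0] ** (1.0 - noise.alpha)
    sigma = k * np.abs(intensity) ** noise.alpha
    if noiseless:
        i_exp = intensity
    else:
        rng = np.random.default_rng(noise.seed)
        i_exp = intensity + rng.normal(0.0, sigma)
    return SASCurve(q, i_exp, sigma, units=units,
                    p_coeffs=dict(p_coeffs or {}), label=label)


# ---------------------------------------------------------------------------
# surrogate particle models
# ---------------------------------------------------------------------------

def surrogate_monomer(molar_mass=BLG_MONOMER_MASS,
                      contrast=XRAY_PROTEIN_CONTRAST):
    """Volume-matched sphere standing in for the folded monomer."""
    R = protein_radius(molar_mass)

    def evaluate(q):
        return ff.sphere_intensity(q, R, contrast)

    return evaluate, R


def surrogate_dimer(molar_mass=BLG_MONOMER_MASS,
                    contrast=XRAY_PROTEIN_CONTRAST):
    """Two touching monomer spheres standing in for the dimer."""
    R = protein_radius(molar_mass)

    def evaluate(q):
        return ff.sphere_dimer_intensity(q, R, contrast)

    return evaluate, R


# ---------------------------------------------------------------------------
# batch simulations
# ---------------------------------------------------------------------------

def batch_dissociation(dG_dis=8.0, concentrations=(2.0, 4.0, 6.0, 8.0, 10.0),
                       monomer=None, dimer=None, molar_mass=BLG_MONOMER_MASS,
                       T=298.0, q_grid=None, noise=None, seed=0,
                       noiseless=False):
    """SAXS concentration series of a monomer-dimer equilibrium.

    For each weight concentration C [g/l] the monomer fraction alpha
    follows from dG_dis [k_B T]; curve = (w_mon P_mon + w_dim P_dim)
    with number-density weights, converted to 1/cm, plus noise.
    Returns (curves, manifest) with the truth values recorded.
    """
    if monomer is None:
        monomer, _ = surrogate_monomer(molar_mass)
    if dimer is None:
        dimer, _ = surrogate_dimer(molar_mass)
    q = DEFAULT_Q if q_grid is None else np.asarray(q_grid, dtype=float)
    noise = noise or NoiseModel(seed=seed)
    curves = []
    for i, conc in enumerate(concentrations):
        dp = DissociationParams(dG_dis=dG_dis, C=conc, M_mon=molar_mass, T=T)
        alpha = monomer_fraction(dp)
        w_mon, w_dim = oligomer_weights(alpha, dp)

        def evaluate(qq, _wm=w_mon, _wd=w_dim):
            return (_wm * monomer(qq) + _wd * dimer(qq)) * DENSITY_CM3_TO_ABS

        nm = NoiseModel(rel_err_first=noise.rel_err_first, alpha=noise.alpha,
                        seed=noise.seed + i)
        curves.append(simulate_curve(
            evaluate, q, nm, p_coeffs={"conc": conc, "temp": T},
            label=f"diss_c{conc:g}", noiseless=noiseless))
    manifest = {"model": "monomer-dimer dissociation",
                "dG_dis_kT": dG_dis, "M_mon": molar_mass, "T": T,
                "concentrations_g_l": list(concentrations),
                "rel_err_first": noise.rel_err_first, "alpha": noise.alpha,
                "seed": seed}
    return curves, manifest


def batch_unfolding(dG0=10.5, dG1=-2.06, dG2=-0.0026,
                    urea_list=(0.0, 2.0, 4.0, 5.0, 6.0), conc=5.0,
                    molar_mass=BLG_MONOMER_MASS, native=None,
                    wormlike_params=None, q_grid=None, noise=None, seed=0,
                    noiseless=False):
    """SANS urea series of a two-state folding equilibrium.

    Native state: volume-matched sphere (or caller-supplied evaluator,
    e.g. a PDB form factor); unfolded state: excluded-volume worm-like
    chain with a hydrated cross section (defaults: Kuhn length 4.2 A,
    core radius 4.0 A, 100 segments, shell 3 A at relative density
    0.95).  Weights follow from the quadratic unfolding free energy
    dG0 + dG1 [U] + dG2 [U]^2 (k_B T units).
    """
    if native is None:
        native_fn, _ = surrogate_monomer(
            molar_mass, contrast=NEUTRON_PROTEIN_SLD - NEUTRON_D2O_SLD)
    else:
        native_fn = native
    wp = wormlike_params or ff.WormlikeParams(
        b=4.2, R=4.0, N_b=100.0, delta=3.0, d_w=0.95,
        rho_core=NEUTRON_PROTEIN_SLD, rho_solv=NEUTRON_D2O_SLD)
    q = DEFAULT_Q if q_grid is None else np.asarray(q_grid, dtype=float)
    noise = noise or NoiseModel(seed=seed)
    n_chain = conc * 1.0e-3 * AVOGADRO / molar_mass   # 1/cm^3
    curves = []
    for i, urea in enumerate(urea_list):
        up = UnfoldingParams(dG0=dG0, dG1=dG1, dG2=dG2, U=urea)
        f_fold = folded_fraction(up)

        def evaluate(qq, _f=f_fold):
            return n_chain * (_f * native_fn(qq)
                              + (1.0 - _f) * ff.wormlike_intensity(qq, wp)) \
                * DENSITY_CM3_TO_ABS

        nm = NoiseModel(rel_err_first=noise.rel_err_first, alpha=noise.alpha,
                        seed=noise.seed + i)
        curves.append(simulate_curve(
            evaluate, q, nm,
            p_coeffs={"urea": urea, "conc": conc},
            label=f"unf_u{urea:g}", noiseless=noiseless))
    manifest = {"model": "two-state unfolding",
                "dG0_kT": dG0, "dG1_kT_per_M": dG1, "dG2_kT_per_M2": dG2,
                "urea_M": list(urea_list), "conc_g_l": conc,
                "wormlike": {"b": wp.b, "R": wp.R, "N_b": wp.N_b,
                             "delta": wp.delta, "d_w": wp.d_w},
                "rel_err_first": noise.rel_err_first, "seed": seed}
    return curves, manifest


# ---------------------------------------------------------------------------
# structural fixtures
# ---------------------------------------------------------------------------

def toy_pdb(n_atoms, geometry="line", path="toy.pdb", seed=0, spacing=5.0,
            radius=10.0, element="C"):
    """Write a minimal synthetic PDB fixture.

    geometry: "line" (atoms spaced ``spacing`` A along x), "helix"
    (ideal helix, rise ``spacing``/turn of 5) or "random-in-sphere"
    (seeded uniform points in a ball of ``radius`` A).
    """
    import gemmi

    if n_atoms < 1:
        raise ParameterError("n_atoms must be >= 1")
    rng = np.random.default_rng(seed)
    if geometry == "line":
        pos = np.zeros((n_atoms, 3))
        pos[:, 0] = spacing * np.arange(n_atoms)
    elif geometry == "helix":
        t = np.arange(n_atoms)
        pos = np.column_stack([radius * np.cos(2 * np.pi * t / 5.0),
                               radius * np.sin(2 * np.pi * t / 5.0),
                               spacing * t / 5.0])
    elif geometry == "random-in-sphere":
        pos = np.empty((0, 3))
        while len(pos) < n_atoms:
            draw = rng.uniform(-radius, radius, size=(2 * n_atoms, 3))
            draw = draw[np.linalg.norm(draw, axis=1) <= radius]
            pos = np.vstack([pos, draw])
        pos = pos[:n_atoms]
    else:
        raise ParameterError(f"unknown geometry {geometry!r}")

    st = gemmi.Structure()
    st.name = "toy"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for i, (x, y, z) in enumerate(pos, start=1):
        res = gemmi.Residue()
        res.name = "UNK"
        res.seqid = gemmi.SeqId(i, " ")
        atom = gemmi.Atom()
        atom.name = element
        atom.element = gemmi.Element(element)
        atom.pos = gemmi.Position(float(x), float(y), float(z))
        atom.occ = 1.0
        res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
    return path
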