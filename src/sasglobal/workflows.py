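"""Ready-made global-fit problems for the built-in condition series.

These builders wire the simulated batches of :mod:`.synthetic_data` to
fit problems whose weights are computed by link functions of the
per-curve condition coefficients — the canonical use of the engine:

* dissociation series: weights of the monomer and dimer form factors
  follow from a single shared dissociation free energy ``dg`` through
  the mass-action monomer fraction;
* unfolding series: weights of the native and worm-like models follow
  from the quadratic unfolding free energy ``dg0 + dg1*[U] +
  dg2*[U]^2``, with the Kuhn length of the unfolded chain shared
  across curves.
"""

from __future__ import annotations

from .catalogue import DENSITY_CM3_TO_ABS, ModelInstance
from .fit_engine import FitProblem, MinimizerSettings, ScalePolicy
from .parameters import ParameterSpec
from .synthetic_data import (BLG_MONOMER_MASS, NEUTRON_D2O_SLD,
                             NEUTRON_PROTEIN_SLD, XRAY_PROTEIN_CONTRAST,
                             protein_radius)
from .thermo_links import AVOGADRO


def _number_density_factor(molar_mass):
    """conc [g/l] -> weight units: n [1/cm^3] times the A^2 -> 1/cm factor."""
    return AVOGADRO / (1000.0 * molar_mass) * DENSITY_CM3_TO_ABS


def build_dissociation_fit(curves, molar_mass=BLG_MONOMER_MASS,
                           contrast=XRAY_PROTEIN_CONTRAST,
                           dg_bounds=(2.0, 14.0), dg_start=5.0,
                           minimizer=None) -> FitProblem:
    """Global monomer-dimer fit with the dissociation free energy
    ``dg`` [k_B T] as the only free (shared) parameter.

    Every curve must carry p-coefficients ``conc`` [g/l] and (by
    convention) ``temp``; the surrogate form factors are the
    volume-matched sphere and touching-sphere dimer.
    """
    conv = _number_density_factor(molar_mass)
    radius = protein_radius(molar_mass)
    alpha = f"alpha_mono(dg, conc/{molar_mass!r})"
    mono_link = f"{alpha}*conc*{conv!r}"
    dim_link = f"(1-{alpha})*conc*{conv!r}/2"
    stacks = []
    for _ in curves:
        monomer = ModelInstance(
            "sphere",
            params={"R": ParameterSpec("R", radius),
                    "drho": ParameterSpec("drho", contrast)},
            weight=ParameterSpec("w", flag=5, link=mono_link))
        dimer = ModelInstance(
            "sphere_dimer",
            params={"R": ParameterSpec("R", radius),
                    "drho": ParameterSpec("drho", contrast),
                    "gap": ParameterSpec("gap", 0.0)},
            weight=ParameterSpec("w", flag=5, link=dim_link))
        stacks.append([monomer, dimer])
    return FitProblem(
        list(curves), stacks,
        scale_policies=[ScalePolicy(kappa=1.0, background=0.0)
                        for _ in curves],
        minimizer=minimizer or MinimizerSettings(methods=("quasinewton",)),
        f_bounds={"dg": dg_bounds}, f_start={"dg": dg_start})


def build_unfolding_fit(curves, molar_mass=BLG_MONOMER_MASS,
                        rho_core=NEUTRON_PROTEIN_SLD,
                        rho_solv=NEUTRON_D2O_SLD,
                        wormlike_fixed=None, b_start=3.0,
                        b_bounds=(1.0, 20.0), minimizer=None) -> FitProblem:
    """Global two-state unfolding fit.

    Free parameters: the unfolding free-energy coefficients ``dg0``
    [k_B T], ``dg1`` [k_B T/M], ``dg2`` [k_B T/M^2] (shared
    f-coefficients of the weight links) and the worm-like Kuhn length
    ``b`` [A] (flag-2 common parameter).  Curves carry p-coefficients
    ``urea`` [M] and ``conc`` [g/l].
    """
    conv = _number_density_factor(molar_mass)
    fixed = {"R": 4.0, "N_b": 100.0, "delta": 3.0, "d_w": 0.95}
    fixed.update(wormlike_fixed or {})
    f_expr = "frac_folded(dg0+dg1*urea+dg2*urea^2)"
    nat_link = f"{f_expr}*conc*{conv!r}"
    unf_link = f"(1-{f_expr})*conc*{conv!r}"
    radius = protein_radius(molar_mass)
    contrast = rho_core - rho_solv
    stacks = []
    for _ in curves:
        native = ModelInstance(
            "sphere",
            params={"R": ParameterSpec("R", radius),
                    "drho": ParameterSpec("drho", contrast)},
            weight=ParameterSpec("w", flag=5, link=nat_link))
        worm = ModelInstance(
            "wormlike",
            params={"b": ParameterSpec("b", b_start, *b_bounds, flag=2),
                    "R": ParameterSpec("R", fixed["R"]),
                    "N_b": ParameterSpec("N_b", fixed["N_b"]),
                    "delta": ParameterSpec("delta", fixed["delta"]),
                    "d_w": ParameterSpec("d_w", fixed["d_w"]),
                    "rho_core": ParameterSpec("rho_core", rho_core),
                    "rho_solv": ParameterSpec("rho_solv", rho_solv),
                    "nu": ParameterSpec("nu", 0.585)},
            weight=ParameterSpec("w", flag=5, link=unf_link))
        stacks.append([native, worm])
    return FitProblem(
        list(curves), stacks,
        scale_policies=[ScalePolicy(kappa=1.0, background=0.0)
                        for _ in curves],
        minimizer=minimizer or MinimizerSettings(
            methods=("annealing", "simplex", "quasinewton"), seed=5,
            n_temps=60, steps_per_temp=40, t_start=10.0, t_end=1e-4),
        # deliberately loose bounds: the three coefficients trade off
        # along a shallow ridge, and pinning any of them at a bound
        # would fake a small curvature-based uncertainty
        f_bounds={"dg0": (0.0, 40.0), "dg1": (-12.0, 2.0),
                  "dg2": (-2.0, 2.0)},
        f_start={"dg0": 5.0, "dg1": -1.0, "dg2": 0.0})
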