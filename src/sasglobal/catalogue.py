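"""The model catalogue: stable ids, parameter lists, evaluators.

A fitted curve is a linear combination of model instances; each
instance owns a weight, its form-factor parameters, an optional
structure factor (parameters prefixed ``sf_``) and an optional context
(e.g. an atomic structure for PDB-based form factors).  Form factors
are per particle [A^2]; weights are number densities, and the unit
factor DENSITY_CM3_TO_ABS converts (1/cm^3) * (A^2) products to the
absolute scale 1/cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import form_factors as ff
from . import structure_factors as sf
from .errors import ParameterError
from .parameters import ParameterSpec

#: (number density in 1/cm^3) x (per-particle intensity in A^2) -> 1/cm
DENSITY_CM3_TO_ABS = 1.0e-16


def _sphere(q, p, ctx):
    return ff.sphere_intensity(q, p["R"], p["drho"])


def _sphere_dimer(q, p, ctx):
    return ff.sphere_dimer_intensity(q, p["R"], p["drho"],
                                     gap=p.get("gap", 0.0))


def _core_shell_cylinder(q, p, ctx):
    return ff.core_shell_cylinder_intensity(
        q, p["R_core"], p["t_shell"], p["L"],
        p["rho_core"], p["rho_shell"], p["rho_solv"],
        n_angles=int(p.get("n_angles", 64)))


def _lamella(q, p, ctx):
    lp = ff.LamellaParams(p["z_hc"], p["t_polar"], p["rho_hc"],
                          p["rho_polar"], p["rho_solv"],
                          p.get("s_hc", 0.0), p.get("s_polar", 0.0))
    return ff.lamella_intensity(q, lp)


def _wormlike(q, p, ctx):
    wp = ff.WormlikeParams(b=p["b"], R=p["R"], N_b=p["N_b"],
                           delta=p.get("delta", 0.0),
                           d_w=p.get("d_w", 1.0),
                           rho_core=p["rho_core"], rho_solv=p["rho_solv"],
                           nu=p.get("nu", 0.585))
    return ff.wormlike_intensity(q, wp)


def _pdb(q, p, ctx):
    structure = ctx.get("structure")
    if structure is None:
        raise ParameterError("pdb model requires a 'structure' context")
    return ff.pdb_intensity(q, structure, d_w=p.get("d_w", 1.0),
                            vol_scale=p.get("vol_scale", 1.0))


@dataclass(frozen=True)
class ModelDef:
    mu: int                      # stable catalogue id
    fn: object
    param_names: tuple


MODEL_CATALOGUE = {
    "sphere": ModelDef(1, _sphere, ("R", "drho")),
    "sphere_dimer": ModelDef(2, _sphere_dimer, ("R", "drho", "gap")),
    "core_shell_cylinder": ModelDef(
        3, _core_shell_cylinder,
        ("R_core", "t_shell", "L", "rho_core", "rho_shell", "rho_solv")),
    "lamella": ModelDef(
        4, _lamella,
        ("z_hc", "t_polar", "rho_hc", "rho_polar", "rho_solv",
         "s_hc", "s_polar")),
    "wormlike": ModelDef(
        5, _wormlike,
        ("b", "R", "N_b", "delta", "d_w", "rho_core", "rho_solv", "nu")),
    "pdb": ModelDef(6, _pdb, ("d_w", "vol_scale")),
}


def _sf_py(q, p):
    return sf.py_hardsphere(q, sf.HardSphereParams(p["sf_R_hs"], p["sf_phi"]))


def _sf_msa(q, p):
    yp = sf.YukawaParams(p["sf_R_hs"], p["sf_phi"], Z=p["sf_Z"],
                         T=p.get("sf_T", 298.0), eps=p.get("sf_eps", 78.3),
                         I_s=p.get("sf_I_s", 0.1))
    return sf.hayter_penfold_msa(q, yp)


def _sf_rpa(q, p):
    v = sf.yukawa_ft_beta(p["sf_A"], p["sf_kappa"])
    return sf.rpa(q, p["sf_n"], v)


def _sf_fractal(q, p):
    return sf.teixeira_fractal(q, sf.FractalParams(p["sf_D"], p["sf_r0"],
                                                   p["sf_xi"]))


def _sf_paracrystal(q, p):
    return sf.paracrystal_1d(q, sf.StackParams(int(round(p["sf_N"])),
                                               p["sf_d"],
                                               Delta=p.get("sf_Delta", 0.0)))


def _sf_mct(q, p):
    return sf.mct(q, sf.StackParams(int(round(p["sf_N"])), p["sf_d"],
                                    eta=p.get("sf_eta", 0.0)))


SF_CATALOGUE = {
    "py": _sf_py,
    "msa": _sf_msa,
    "rpa_yukawa": _sf_rpa,
    "fractal": _sf_fractal,
    "paracrystal": _sf_paracrystal,
    "mct": _sf_mct,
}


@dataclass
class StructureFactorInstance:
    kind: str
    params: dict = field(default_factory=dict)   # name (sf_*) -> ParameterSpec

    def __post_init__(self):
        if self.kind not in SF_CATALOGUE:
            raise ParameterError(f"unknown structure factor {self.kind!r}")
        for name in self.params:
            if not name.startswith("sf_"):
                raise ParameterError(
                    f"structure-factor parameter {name!r} must carry the "
                    f"'sf_' prefix")


@dataclass
class ModelInstance:
    """One model in a curve's stack: weight + parameters (+ S(q))."""

    model: str
    params: dict = field(default_factory=dict)   # name -> ParameterSpec
    weight: ParameterSpec = None
    structure_factor: StructureFactorInstance | None = None
    context: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.model not in MODEL_CATALOGUE:
            raise ParameterError(f"unknown model {self.model!r}")
        if self.weight is None:
            self.weight = ParameterSpec("w", 1.0, flag=0)
        names = set(self.params)
        if self.structure_factor is not None:
            clash = names & set(self.structure_factor.params)
            if clash:
                raise ParameterError(f"duplicate parameter names {clash}")

    def all_specs(self):
        """Weight first, then model parameters, then S(q) parameters."""
        yield self.weight
        yield from self.params.values()
        if self.structure_factor is not None:
            yield from self.structure_factor.params.values()

    def evaluator(self):
        """callable(q, values: dict) -> I_m(q) = P(q) S(q) [A^2]."""
        mdef = MODEL_CATALOGUE[self.model]
        sf_fn = SF_CATALOGUE[self.structure_factor.kind] \
            if self.structure_factor is not None else None
        ctx = self.context

        def evaluate(q, values):
            intensity = np.asarray(mdef.fn(q, values, ctx), dtype=float)
            if sf_fn is not None:
                intensity = intensity * sf_fn(q, values)
            return intensity

        return evaluate
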