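"""Single-particle model intensities I(q) in absolute units.

Conventions
-----------
Lengths are Angstrom, scattering-length-density contrasts Angstrom^-2,
so every intensity returned here is the orientation-averaged squared
excess scattering length of ONE particle, in Angstrom^2.  Multiplying
by a number density [1/cm^3] and the unit factor 1e-16 gives a
macroscopic cross section in 1/cm (see catalogue.DENSITY_CM3_TO_ABS).

The catalogue spans geometric bodies (sphere, touching-sphere dimer,
core-shell cylinder, lamella, excluded-volume worm-like chain) and
atomic structures read from PDB files, evaluated with the exact Debye
double sum including a lattice-built hydration shell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.spatial import cKDTree
from scipy.special import j1

from .errors import ParameterError

R_ELECTRON = 2.8179403262e-5    # classical electron radius [Angstrom]
FM_TO_ANGSTROM = 1.0e-5
WATER_VOLUME = 29.9             # volume of one water molecule [Angstrom^3]
WATER_RADIUS = 1.4              # effective water radius [Angstrom]
WATER_ELECTRON_DENSITY = 0.334  # bulk water [e/Angstrom^3]

# Displaced solvent volumes of the Gaussian dummy atoms [Angstrom^3]
# (Fraser-style values as used throughout the PDB-SAXS literature).
DUMMY_ATOM_VOLUME = {
    "H": 5.15, "D": 5.15, "C": 16.44, "N": 2.49, "O": 9.13,
    "S": 19.86, "P": 5.73, "FE": 7.99, "ZN": 9.85, "CA": 31.89,
    "MG": 21.69, "NA": 4.45, "CL": 24.84, "K": 11.01, "MN": 9.20,
    "CU": 8.78,
}

# van der Waals radii [Angstrom] for the hydration-contact criterion.
VDW_RADIUS = {
    "H": 1.20, "D": 1.20, "C": 1.70, "N": 1.55, "O": 1.52,
    "S": 1.80, "P": 1.80, "FE": 2.00, "ZN": 1.39, "CA": 1.97,
    "MG": 1.73, "NA": 2.27, "CL": 1.75, "K": 2.75, "MN": 2.00,
    "CU": 1.40,
}
_DEFAULT_RADIUS = 1.8


def _vdw_radius(element: str) -> float:
    return VDW_RADIUS.get(element.upper(), _DEFAULT_RADIUS)


def _dummy_volume(element: str) -> float:
    el = element.upper()
    if el in DUMMY_ATOM_VOLUME:
        return DUMMY_ATOM_VOLUME[el]
    r = _vdw_radius(el)
    return 4.0 / 3.0 * np.pi * r ** 3


# ---------------------------------------------------------------------------
# geometric bodies
# ---------------------------------------------------------------------------

def _sphere_amp(x):
    """3(sin x - x cos x)/x^3 with the x -> 0 limit 1."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    small = np.abs(x) < 1e-4
    xs = np.where(small, 1.0, x)
    out = np.where(small, 1.0 - x ** 2 / 10.0,
                   3.0 * (np.sin(xs) - xs * np.cos(xs)) / xs ** 3)
    return out


def sphere_intensity(q, R, drho):
    """Homogeneous sphere: I(q) = [drho V phi(qR)]^2, V = 4 pi R^3 / 3."""
    if R <= 0:
        raise ParameterError(f"sphere radius must be > 0, got {R}")
    q = np.asarray(q, dtype=float)
    V = 4.0 / 3.0 * np.pi * R ** 3
    return (drho * V * _sphere_amp(q * R)) ** 2


def sphere_dimer_intensity(q, R, drho, gap=0.0):
    """Two touching identical spheres (surrogate dimer).

    Exact orientational average from the two-site Debye formula:
    I(q) = 2 F(q)^2 [1 + sinc(q d)], with d = 2R + gap.
    """
    if R <= 0:
        raise ParameterError(f"sphere radius must be > 0, got {R}")
    q = np.asarray(q, dtype=float)
    V = 4.0 / 3.0 * np.pi * R ** 3
    F = drho * V * _sphere_amp(q * R)
    d = 2.0 * R + gap
    return 2.0 * F ** 2 * (1.0 + np.sinc(q * d / np.pi))


def _lambda1(x):
    """2 J1(x)/x with limit 1."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-6
    xs = np.where(small, 1.0, x)
    return np.where(small, 1.0 - x ** 2 / 8.0, 2.0 * j1(xs) / xs)


def cylinder_intensity(q, R, L, drho, n_angles=64):
    """Uniform right circular cylinder, numerically orientation averaged."""
    return core_shell_cylinder_intensity(q, R, 0.0, L, drho, 0.0, 0.0,
                                         n_angles=n_angles)


def core_shell_cylinder_intensity(q, R_core, t_shell, L, rho_core, rho_shell,
                                  rho_solv, n_angles=64):
    """Core-shell (radial shell) right circular cylinder.

    Gauss-Legendre average over the tilt angle in [0, pi/2] of the
    standard amplitude; the shell has the same length L as the core.
    """
    if R_core <= 0 or L <= 0 or t_shell < 0:
        raise ParameterError("need R_core > 0, L > 0, t_shell >= 0")
    if n_angles < 16:
        raise ParameterError("n_angles must be >= 16")
    if rho_core == rho_shell == rho_solv:
        warnings.warn("all densities equal: zero intensity", stacklevel=2)
    q = np.asarray(q, dtype=float)
    x, w = leggauss(n_angles)
    alpha = 0.25 * np.pi * (x + 1.0)           # [0, pi/2]
    wa = 0.25 * np.pi * w * np.sin(alpha)       # solid-angle weight
    sa, ca = np.sin(alpha), np.cos(alpha)

    R_out = R_core + t_shell
    V_core = np.pi * R_core ** 2 * L
    V_out = np.pi * R_out ** 2 * L

    qz = np.outer(q, ca) * (L / 2.0)
    longitudinal = np.sinc(qz / np.pi)
    qr_core = np.outer(q, sa) * R_core
    amp = (rho_core - rho_shell) * V_core * longitudinal * _lambda1(qr_core)
    if t_shell > 0 or rho_shell != rho_solv:
        qr_out = np.outer(q, sa) * R_out
        amp = amp + (rho_shell - rho_solv) * V_out * longitudinal \
            * _lambda1(qr_out)
    return (amp ** 2) @ wa


@dataclass
class LamellaParams:
    """Symmetric bilayer profile: hydrocarbon core + polar headgroups.

    z_hc: half-thickness of the hydrocarbon region [A]; t_polar:
    thickness of each polar region [A]; rho_* are scattering-length (or
    electron) densities; s_hc / s_polar are Gaussian smoothing widths of
    the core/head and head/water interfaces [A].
    """

    z_hc: float
    t_polar: float
    rho_hc: float
    rho_polar: float
    rho_solv: float
    s_hc: float = 0.0
    s_polar: float = 0.0

    def __post_init__(self):
        if self.z_hc < 0 or self.t_polar < 0 or self.s_hc < 0 \
                or self.s_polar < 0:
            raise ParameterError("lamella widths must be >= 0")


def lamella_amplitude(q, p: LamellaParams):
    """1-D Fourier transform F(q) of the centrosymmetric contrast profile."""
    q = np.asarray(q, dtype=float)
    if p.rho_hc == p.rho_polar == p.rho_solv:
        warnings.warn("zero total contrast", stacklevel=2)
    qs = np.where(q == 0, 1.0, q)
    z1 = p.z_hc
    z2 = p.z_hc + p.t_polar
    F = 2.0 / qs * (
        (p.rho_hc - p.rho_polar) * np.sin(qs * z1)
        * np.exp(-0.5 * (qs * p.s_hc) ** 2)
        + (p.rho_polar - p.rho_solv) * np.sin(qs * z2)
        * np.exp(-0.5 * (qs * p.s_polar) ** 2))
    F0 = 2.0 * ((p.rho_hc - p.rho_polar) * z1 + (p.rho_polar - p.rho_solv) * z2)
    return np.where(q == 0, F0, F)


def lamella_intensity(q, p: LamellaParams):
    """Per-unit-area lamellar intensity I(q) = |F(q)|^2 / q^2 (q > 0)."""
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ParameterError("lamella intensity requires q > 0 "
                             "(the 1/q^2 Lorentz factor diverges at 0)")
    return lamella_amplitude(q, p) ** 2 / q ** 2


# ---------------------------------------------------------------------------
# worm-like chain with excluded volume
# ---------------------------------------------------------------------------

@dataclass
class WormlikeParams:
    """Excluded-volume worm-like chain with a hydrated circular cross
    section.

    b: Kuhn length [A]; R: inner cross-section radius [A]; N_b: number
    of statistical segments (contour length L = N_b * b); delta:
    hydration-shell thickness [A]; d_w: relative mass density of the
    shell water; rho_core / rho_solv: scattering length densities
    [A^-2]; nu: excluded-volume (Flory) exponent, 0.5 recovers the
    ideal chain.
    """

    b: float = 4.2
    R: float = 4.0
    N_b: float = 100.0
    delta: float = 3.0
    d_w: float = 0.95
    rho_core: float = 1.8e-6
    rho_solv: float = 6.36e-6
    nu: float = 0.585

    def __post_init__(self):
        if self.b <= 0 or self.R <= 0:
            raise ParameterError("b and R must be > 0")
        if self.N_b < 1:
            raise ParameterError("N_b must be >= 1")
        if self.delta < 0:
            raise ParameterError("delta must be >= 0")

    @property
    def contour_length(self) -> float:
        return self.N_b * self.b


def _debye_function(u):
    """D(u) = 2 (exp(-u) + u - 1)/u^2 with the u -> 0 limit 1."""
    u = np.asarray(u, dtype=float)
    small = u < 1e-6
    us = np.where(small, 1.0, u)
    return np.where(small, 1.0 - u / 3.0,
                    2.0 * (np.exp(-us) + us - 1.0) / us ** 2)


def wormlike_rg2(L, b, nu=0.585):
    """Radius of gyration squared of the (swollen) worm-like chain.

    Ideal part from the Benoit-Doty expression for a Kratky-Porod
    chain; excluded volume enters through the swelling factor
    alpha^2(n) = [1 + (n/3.12)^2 + (n/8.67)^3]^(eps/3) with n = L/b and
    eps = 0.170 for nu = 0.585 (eps = 0 for the ideal chain).
    """
    n = L / b
    rg2_ideal = (L * b / 6.0) * (1.0 - 1.5 / n + 1.5 / n ** 2
                                 - 0.75 / n ** 3 * (1.0 - np.exp(-2.0 * n)))
    eps = 2.0 * nu - 1.0   # 0.170 at nu = 0.585, 0 for the ideal chain
    alpha2 = (1.0 + (n / 3.12) ** 2 + (n / 8.67) ** 3) ** (eps / 3.0)
    return alpha2 * rg2_ideal


def wormlike_chain_factor(q, L, b, nu=0.585):
    """Normalized chain structure factor S(q) of the worm-like chain.

    Low q: crossover interpolation between the Debye function of
    q^2 Rg^2 and the power-law regime x^(-1/nu) of the swollen coil
    with coefficients (1.22, 0.4288, -1.651) for the excluded-volume
    exponent nu = 0.585; at nu = 1/2 the ideal-chain Debye function is
    used throughout the coil regime.  High q (qb > ~3.1):
    rigid-rod behaviour pi/(qL) + 2/(3 q^2 L l_p), l_p = b/2; branches
    are blended smoothly in qb.
    """
    q = np.asarray(q, dtype=float)
    rg2 = wormlike_rg2(L, b, nu)
    x = q * np.sqrt(rg2)
    u = x ** 2

    if abs(nu - 0.5) < 1e-12:
        # ideal chain: the Debye function is exact, no crossover needed
        s_coil = _debye_function(u)
    else:
        w = 0.5 * (1.0 + np.tanh((x - 1.523) / 0.1477))
        # the power-law branch diverges at small x faster than the tanh
        # switch decays; keep the coil branch pure below x = 1
        w = np.where(x < 1.0, 0.0, w)
        c1, c2, c3 = 1.22, 0.4288, -1.651
        xs = np.where(x < 1e-8, 1.0, x)
        power = (c1 * xs ** (-1.0 / nu) + c2 * xs ** (-2.0 / nu)
                 + c3 * xs ** (-3.0 / nu))
        s_coil = (1.0 - w) * _debye_function(u) + w * power

    qb = q * b
    qs = np.where(q == 0, 1.0, q)
    s_rod = np.pi / (qs * L) + 2.0 / (3.0 * qs ** 2 * L * (b / 2.0))
    blend = 0.5 * (1.0 + np.tanh((qb - 3.1) / 0.25))
    s = (1.0 - blend) * s_coil + blend * s_rod
    return np.where(q == 0, 1.0, s)


def wormlike_cross_section(q, R, delta, d_w, rho_core, rho_solv):
    """Normalized squared cross-section amplitude of core + shell."""
    q = np.asarray(q, dtype=float)
    rho_shell = d_w * rho_solv
    a_core = (rho_core - rho_shell) * np.pi * R ** 2
    a_out = (rho_shell - rho_solv) * np.pi * (R + delta) ** 2
    a0 = a_core + a_out
    if a0 == 0:
        warnings.warn("zero cross-section contrast", stacklevel=2)
        return np.ones_like(q)
    amp = a_core * _lambda1(q * R) + a_out * _lambda1(q * (R + delta))
    return (amp / a0) ** 2


def wormlike_intensity(q, p: WormlikeParams):
    """I(q) of the excluded-volume worm-like chain, in A^2 per chain.

    I(0) equals the squared total excess scattering length of the
    chain (core + hydration shell).
    """
    q = np.asarray(q, dtype=float)
    L = p.contour_length
    rho_shell = p.d_w * p.rho_solv
    lin = ((p.rho_core - rho_shell) * np.pi * p.R ** 2
           + (rho_shell - p.rho_solv) * np.pi * (p.R + p.delta) ** 2)
    total = lin * L
    return (total ** 2 * wormlike_chain_factor(q, L, p.b, p.nu)
            * wormlike_cross_section(q, p.R, p.delta, p.d_w,
                                     p.rho_core, p.rho_solv))


# ---------------------------------------------------------------------------
# atomic structures (PDB)
# ---------------------------------------------------------------------------

NEUTRON_B_H = -3.739 * FM_TO_ANGSTROM
NEUTRON_B_D = 6.671 * FM_TO_ANGSTROM


def water_sld(d2o_fraction=0.0):
    """Neutron scattering length density of H2O/D2O mixtures [A^-2]."""
    import gemmi
    b_o = gemmi.Element("O").neutron92.get_coefs()[0] * FM_TO_ANGSTROM
    b_h = (1.0 - d2o_fraction) * NEUTRON_B_H + d2o_fraction * NEUTRON_B_D
    return (2.0 * b_h + b_o) / WATER_VOLUME


@dataclass
class AtomicStructure:
    """Atoms plus (optionally) lattice-built hydration sites."""

    elements: list
    positions: np.ndarray              # (N, 3) [Angstrom]
    occupancies: np.ndarray
    probe: str = "xray"                # "xray" or "neutron"
    solvent_density: float = WATER_ELECTRON_DENSITY
    d2o_fraction: float = 0.0
    extra_hydrogens: np.ndarray | None = None   # collapsed H per atom
    exchangeable: np.ndarray | None = None      # exchangeable collapsed H
    hydration_sites: np.ndarray = field(
        default_factory=lambda: np.empty((0, 3)))

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.elements) < 1:
            raise ParameterError("structure must contain at least one atom")
        if self.extra_hydrogens is None:
            self.extra_hydrogens = np.zeros(len(self.elements))
        if self.exchangeable is None:
            self.exchangeable = np.zeros(len(self.elements))

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def radii(self) -> np.ndarray:
        return np.array([_vdw_radius(e) for e in self.elements])

    @property
    def volumes(self) -> np.ndarray:
        v = np.array([_dummy_volume(e) for e in self.elements])
        return v + self.extra_hydrogens * DUMMY_ATOM_VOLUME["H"]


def load_structure(pdb_path, probe="xray", solvent_density=None,
                   d2o_fraction=0.0, hydrogens="collapse") -> AtomicStructure:
    """Read ATOM/HETATM records from a PDB file.

    Elements come from columns 77-78 with name-based fallback; among
    alternate locations the highest-occupancy one is kept; file waters
    are dropped (the hydration shell is rebuilt on a lattice).
    ``hydrogens`` is "keep", "drop" or "collapse" (fold each H onto its
    nearest heavy atom, the default).
    """
    import gemmi

    st = gemmi.read_structure(str(Path(pdb_path)))
    st.setup_entities()
    elements, positions, occupancies = [], [], []
    skipped = set()
    for model in st:
        for chain in model:
            for residue in chain:
                if residue.is_water():
                    continue
                by_name: dict = {}
                for atom in residue:
                    prev = by_name.get(atom.name)
                    if prev is None or atom.occ > prev.occ:
                        by_name[atom.name] = atom
                for atom in by_name.values():
                    el = atom.element.name.upper()
                    if atom.element.atomic_number == 0:
                        skipped.add(atom.name)
                        continue
                    elements.append(el)
                    positions.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    occupancies.append(atom.occ)
        break  # first model only
    if skipped:
        warnings.warn(f"{pdb_path}: skipped atoms with unknown element: "
                      f"{sorted(skipped)}", stacklevel=2)
    if not elements:
        raise ParameterError(f"{pdb_path}: no ATOM/HETATM records")

    positions = np.asarray(positions, dtype=float)
    occupancies = np.asarray(occupancies, dtype=float)
    is_h = np.array([e in ("H", "D") for e in elements])
    extra_h = np.zeros(len(elements))
    exch = np.zeros(len(elements))
    if np.any(is_h) and hydrogens != "keep":
        heavy_idx = np.flatnonzero(~is_h)
        if hydrogens == "collapse" and heavy_idx.size:
            tree = cKDTree(positions[heavy_idx])
            _, nearest = tree.query(positions[is_h])
            owners = heavy_idx[nearest]
            for owner in owners:
                extra_h[owner] += 1.0
                if elements[owner] in ("N", "O", "S"):
                    exch[owner] += 1.0
        keep = ~is_h
        elements = [e for e, k in zip(elements, keep) if k]
        positions = positions[keep]
        occupancies = occupancies[keep]
        extra_h = extra_h[keep]
        exch = exch[keep]

    if solvent_density is None:
        solvent_density = (WATER_ELECTRON_DENSITY if probe == "xray"
                           else water_sld(d2o_fraction))
    return AtomicStructure(elements, positions, occupancies, probe=probe,
                           solvent_density=solvent_density,
                           d2o_fraction=d2o_fraction,
                           extra_hydrogens=extra_h, exchangeable=exch)


def fcc_lattice_points(lo, hi, spacing):
    """FCC lattice points with nearest-neighbour distance ``spacing``
    covering the box [lo, hi] (inclusive)."""
    a = spacing * np.sqrt(2.0)   # conventional cubic cell edge
    basis = np.array([[0.0, 0.0, 0.0], [0.0, 0.5, 0.5],
                      [0.5, 0.0, 0.5], [0.5, 0.5, 0.0]])
    imin = np.floor(np.asarray(lo) / a).astype(int) - 1
    imax = np.ceil(np.asarray(hi) / a).astype(int) + 1
    ranges = [np.arange(imin[d], imax[d] + 1) for d in range(3)]
    grid = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1)
    cells = grid.reshape(-1, 3)[:, None, :] + basis[None, :, :]
    pts = (cells.reshape(-1, 3)) * a
    inside = np.all((pts >= np.asarray(lo) - 1e-9)
                    & (pts <= np.asarray(hi) + 1e-9), axis=1)
    return pts[inside]


def build_hydration_shell(s: AtomicStructure, spacing=2.8, contact_tol=0.5,
                          r_w=WATER_RADIUS, offset=None) -> AtomicStructure:
    """Assign hydration waters on an FCC lattice around the structure.

    A lattice site becomes a hydration water iff its distance d to some
    atom satisfies |d - (r_atom + r_w)| <= contact_tol while no atom
    has d < r_atom + r_w - contact_tol (sites inside cavities and
    grooves qualify by the same rule).
    """
    if spacing <= 0:
        raise ParameterError("spacing must be > 0")
    radii = s.radii
    pad = radii.max() + r_w + contact_tol + spacing
    lo = s.positions.min(axis=0) - pad
    hi = s.positions.max(axis=0) + pad
    sites = fcc_lattice_points(lo, hi, spacing)
    if offset is not None:
        sites = sites + np.asarray(offset, dtype=float)

    in_shell = np.zeros(len(sites), dtype=bool)
    inside = np.zeros(len(sites), dtype=bool)
    tree = cKDTree(sites)
    for pos, r in zip(s.positions, radii):
        contact = r + r_w
        idx = tree.query_ball_point(pos, contact + contact_tol)
        if not idx:
            continue
        idx = np.asarray(idx)
        d = np.linalg.norm(sites[idx] - pos, axis=1)
        inside[idx[d < contact - contact_tol]] = True
        in_shell[idx[np.abs(d - contact) <= contact_tol]] = True
    chosen = sites[in_shell & ~inside]
    return AtomicStructure(list(s.elements), s.positions.copy(),
                           s.occupancies.copy(), probe=s.probe,
                           solvent_density=s.solvent_density,
                           d2o_fraction=s.d2o_fraction,
                           extra_hydrogens=s.extra_hydrogens.copy(),
                           exchangeable=s.exchangeable.copy(),
                           hydration_sites=chosen)


def effective_amplitudes(q, s: AtomicStructure, d_w=1.0, vol_scale=1.0):
    """Per-scatterer effective amplitudes f_eff(q) [Angstrom].

    Atoms: f_j(q) minus the Gaussian dummy-atom excluded-solvent term
    rho_s v_j exp(-q^2 v_j^(2/3) / 4 pi).  Hydration sites carry the
    excess amplitude (d_w - 1) rho_s v_w with the same damping.
    X-rays use IT92 multi-Gaussian atomic factors (converted to length
    by r_e); neutrons use coherent lengths with H/D exchange weighted
    by the D2O volume fraction.
    """
    import gemmi

    q = np.atleast_1d(np.asarray(q, dtype=float))
    volumes = s.volumes * vol_scale
    n_atoms = s.n_atoms
    f = np.empty((n_atoms + len(s.hydration_sites), q.size))

    if s.probe == "xray":
        stol2 = (q / (4.0 * np.pi)) ** 2
        cache = {}
        for j, el in enumerate(s.elements):
            if el not in cache:
                it92 = gemmi.Element(el).it92
                cache[el] = np.array([it92.calculate_sf(s2) for s2 in stol2])
            f_at = cache[el].copy()
            if s.extra_hydrogens[j]:
                if "H" not in cache:
                    it92h = gemmi.Element("H").it92
                    cache["H"] = np.array([it92h.calculate_sf(s2)
                                           for s2 in stol2])
                f_at = f_at + s.extra_hydrogens[j] * cache["H"]
            f[j] = f_at * s.occupancies[j] * R_ELECTRON
        rho_s = s.solvent_density * R_ELECTRON     # e/A^3 -> A^-2
        w_excess = (d_w - 1.0) * s.solvent_density * R_ELECTRON * WATER_VOLUME
    else:
        b_h_eff = ((1.0 - s.d2o_fraction) * NEUTRON_B_H
                   + s.d2o_fraction * NEUTRON_B_D)
        for j, el in enumerate(s.elements):
            b = gemmi.Element(el).neutron92.get_coefs()[0] * FM_TO_ANGSTROM
            n_h = s.extra_hydrogens[j]
            n_x = s.exchangeable[j]
            b = b + (n_h - n_x) * NEUTRON_B_H + n_x * b_h_eff
            if el in ("H", "D"):
                pass   # explicit hydrogens keep their own length
            f[j] = b * s.occupancies[j]
        rho_s = s.solvent_density                  # already A^-2
        w_excess = (d_w - 1.0) * s.solvent_density * WATER_VOLUME

    damp = np.exp(-q[None, :] ** 2 * volumes[:, None] ** (2.0 / 3.0)
                  / (4.0 * np.pi))
    f[:n_atoms] = f[:n_atoms] - rho_s * volumes[:, None] * damp
    if len(s.hydration_sites):
        w_damp = np.exp(-q ** 2 * (WATER_VOLUME * vol_scale) ** (2.0 / 3.0)
                        / (4.0 * np.pi))
        f[n_atoms:] = w_excess * vol_scale * w_damp[None, :]
    return f


def pdb_intensity(q, s: AtomicStructure, d_w=1.0, vol_scale=1.0,
                  max_scatterers=8000):
    """Exact Debye double sum over atoms + hydration sites [A^2].

    I(q) = sum_jk f_eff,j(q) f_eff,k(q) sinc(q r_jk); the orientational
    average is exact by construction.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    pts = np.vstack([s.positions, s.hydration_sites]) \
        if len(s.hydration_sites) else s.positions
    n = len(pts)
    if n > max_scatterers:
        raise ParameterError(
            f"{n} scatterers exceed the Debye-sum budget of "
            f"{max_scatterers}; coarse-grain the structure or raise "
            f"max_scatterers")
    f = effective_amplitudes(q, s, d_w=d_w, vol_scale=vol_scale)
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt(np.sum(diff ** 2, axis=-1))
    out = np.empty(q.size)
    for iq, qi in enumerate(q):
        fq = f[:, iq]
        kernel = np.sinc(qi * dist / np.pi)
        out[iq] = fq @ kernel @ fq
    return out
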