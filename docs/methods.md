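# Methods

This note records the models implemented in `sasglobal`, the numerical
choices behind them, and the limits of what the validation suite
demonstrates.

## Objective and scaling conventions

The global objective is the reduced

    chi^2 = (1/N_c) sum_c (1/N_q,c) sum_i r_ci^2,
    r_ci = (kappa_c I_c(q_i) + B_c - I_exp,c(q_i)) / sigma_c(q_i).

No degrees-of-freedom count is subtracted: chi^2 is normalized by the
number of points only, so a perfect fit of noise-free data gives 0 and
data scattered by exactly one error bar give 1 regardless of how many
parameters are free. The per-curve scale kappa_c and background B_c
are solved at every objective evaluation by sigma-weighted linear least
squares (2x2 normal equations; one-dimensional closed forms when either
is user-fixed). A constant model with both free is rank-deficient; the
code warns and lets the background absorb the signal. Curves in
arbitrary units always fit kappa_c. The penalty Psi accumulated by
`fout` assignments inside link functions is added to the *objective*
(chi^2 + Psi) but never to the reported chi^2; fout is reset at the
start of each objective evaluation and accumulates over all link
evaluations of that call (a single global accumulator, not per curve).

Units: lengths in Angstrom, scattering-length-density contrasts in
A^-2, so per-particle intensities are in A^2. A macroscopic cross
section in 1/cm is obtained as w * P(q) * 1e-16 when the weight w is a
number density in 1/cm^3 (`catalogue.DENSITY_CM3_TO_ABS`); the built-in
workflows fold this factor into their weight links.

## Parameter flags and link functions

Flags follow the scheme: 0 fixed, 1 fitted per curve, 2 common across
all curves using the model, 4/5 computed by a link function
(f-coefficients per curve / global), 6/7 polydisperse with fitted
(per-curve / common) distribution parameters, 8/9 polydisperse with
linked distribution parameters. Flag 3 is not defined and is rejected.
An f-name appearing under flag 4 in several curves denotes distinct
per-curve coefficients; under flag 5 one shared coefficient.
f-coefficient bounds default to [0, 1]; they may be given directly in
the problem (`f_bounds`) or through the two-pass parameter-file
workflow, in which a first run emits `gen<code>.par` for editing.

The expression grammar is deliberately small: reals, identifiers,
`+ - * / ^`, parentheses, the functions exp/log/sqrt/sin/cos/tan/
abs/min/max, and `fout = <expr>` statements separated by `;` (only
`fout` may be assigned). Domain built-ins register extra named
functions: `alpha_mono(dg, ct)` (mass-action monomer fraction) and
`frac_folded(dg)` (two-state folded fraction). Expressions are parsed
into a vetted AST (node allowlist) and evaluated with an empty builtin
namespace; evaluation is pure in (p, f) apart from fout.

Optimizer-slot ordering is deterministic: curve order, then model
order, then parameter order with the weight first; flag-2/7 slots are
allocated at first encounter; global f-coefficients come last.
Resolved flag-1 values are clipped to their bounds.

## Form factors

* **Sphere / touching-sphere dimer.** Closed forms; the dimer is the
  exact two-site Debye average 2F^2(1 + sinc(2qR)), used as the
  volume-matched surrogate for a protein dimer.
* **Core–shell cylinder.** Radial shell of the same length as the core
  (no end caps); orientational average by Gauss–Legendre quadrature on
  the tilt angle (default 64 nodes; doubling changes the result by
  < 1e-4 for q R_core < 5).
* **Lamella.** Centrosymmetric contrast profile built from
  erf-smoothed strips (hydrocarbon half-thickness z_hc, polar thickness
  t_polar, Gaussian interface widths); F(q) is analytic and the
  per-unit-area intensity is |F|^2/q^2, which diverges at q = 0 — the
  model is defined for q > 0 only.
* **Worm-like chain with excluded volume.** Chain factor: below the
  rod regime, a crossover interpolation between the Debye function of
  q^2 Rg^2 and the swollen-coil power law with coefficients
  (1.22, 0.4288, −1.651) and exponent nu = 0.585; Rg^2 combines the
  Benoit–Doty ideal wormlike expression with the swelling factor
  alpha^2(n) = [1 + (n/3.12)^2 + (n/8.67)^3]^(eps/3), n = L/b,
  eps = 2 nu − 1. The power-law branch is suppressed below q Rg = 1
  (it diverges faster than the switch function decays). Setting
  nu = 1/2 selects the ideal-chain variant, which uses the Debye
  function throughout the coil regime. Above q b ≈ 3.1 the factor
  blends smoothly (tanh in q b) into the rigid-rod form
  pi/(qL) + 2/(3 q^2 L l_p), l_p = b/2. The cross section is a
  hydrated core–shell circle (radius R, shell delta at relative water
  density d_w), normalized to 1 at q = 0 so that I(0) equals the
  squared total excess scattering length.
* **Atomic structures (PDB).** Read with gemmi (elements from columns
  77–78 with name fallback, highest-occupancy altloc, file waters
  dropped, first model only). Hydrogens are kept, dropped, or
  collapsed onto their nearest heavy atom (default), which also marks
  N/O/S-bound hydrogens as exchangeable. X-ray amplitudes use the IT92
  four-Gaussian atomic factors; neutrons use coherent lengths with
  exchangeable hydrogens mixed H/D by the D2O volume fraction.
  Excluded solvent follows the Gaussian dummy-atom model with a small
  table of published displaced volumes (water 29.9 A^3, electron
  density 0.334 e/A^3); the `vol_scale` knob scales all volumes.
  Hydration shell: a face-centred-cubic lattice with 2.8 A
  nearest-neighbour spacing; a site becomes a water iff its distance to
  some atom is within ±0.5 A (contact_tol) of r_atom + 1.4 A and it is
  inside no atom — cavities and grooves qualify by the same rule.
  Shell waters carry the excess amplitude (d_w − 1) rho_s v_w with the
  same Gaussian damping. The intensity is the exact Debye double sum
  (orientational average exact by construction); structures beyond a
  configurable scatterer budget (default 8000) are refused with advice
  to coarse-grain rather than failing silently.

## Structure factors

The fitted curve uses I = n P(q) S(q) per model — the monodisperse
decoupling approximation; polydispersity averaging is applied to the
product.

* **Percus–Yevick hard spheres.** Standard closed form; for
  q sigma < 0.2 a Taylor series (coefficients generated symbolically)
  makes the q → 0 compressibility limit (1−phi)^4/(1+2 phi)^2 exact.
* **Screened-Coulomb MSA with rescaling.** The DLVO Yukawa tail
  (contact potential from Z, the Bjerrum length 1.671e5/(eps T) A, and
  the Debye length 3.041/sqrt(I[M]) A at 298 K scaled by
  sqrt(eps T / (78.3 · 298))) is solved with the MSA closure of the
  Ornstein–Zernike equation by sine-transform Picard iteration
  (N = 2048, dr = 0.01 sigma, adaptive mixing, gradual charging of the
  tail in ≤ 2 k_BT steps with warm starts). Because a discrete
  transform carries O(dr^2) bias, the solver is anchored to the
  analytic PY solution: S(q) = S_PY(q) · [S_num(q)/S_num,PY(q)], which
  makes the Z = 0 limit exact to machine precision and cancels most of
  the grid bias elsewhere. When the contact value of g(r)
  (quadratic extrapolation of the first grid points outside the core)
  is negative, the system is mapped onto an equivalent larger-diameter
  one whose contact value vanishes (bisection on the diameter scale
  with a coarser 1024-point grid; the tail potential is kept fixed in
  physical units). Failure to converge raises an explicit error.
* **RPA.** S = S0/(1 + n S0 v(q)) with v the potential transform in
  k_BT A^3 (Yukawa closed form provided); a non-positive denominator
  raises a stability error.
* **Teixeira fractal.** Standard form with Gamma(D−1); rewritten so
  the q^−D singularity cancels analytically, giving the finite q → 0
  limit 1 + Gamma(D+1)(xi/r0)^D.
* **1-D stacks.** Finite N-bilayer sums normalized by N (so S → 1 at
  large q; with a freely fitted scale factor the convention is
  immaterial). Paracrystal: cumulative Gaussian disorder
  exp(−k q^2 Delta^2/2). Modified Caillé: logarithmic damping
  exp[−(d/2 pi)^2 q^2 eta (gamma_E + ln(pi k))], the finite sum
  avoiding resolution-limited divergences.

## Polydispersity

Seven kinds (local registry ids): delta, uniform, triangular,
gaussian, lognormal, schulz, weibull; all parametrized by mean and a
width (the standard deviation, except half-range/half-base for the
bounded kinds). Grids span mean ± 4 widths (21 points, odd, Simpson
weights), truncated at zero and renormalized so the discrete weights
sum to one; zero width degenerates to a delta with a warning. The
decoupled product quadrature supports at most three simultaneously
polydisperse parameters; a delta distribution reproduces the
monodisperse call bitwise. The 21-point default is converged to
better than 1e-3 against a 41-point grid for widths up to 20% of the
mean over q·mean ≲ 10; push n_points up for wider distributions or
higher q, where the integrand oscillates faster than the grid
resolves. Correlated multi-parameter distributions are out of scope —
the factorized form is an approximation the user must judge.

## Resolution

Gaussian q-resolution (per-point widths, or components — relative
wavelength spread, collimation, detector — combined in quadrature) is
applied as a Simpson convolution over ± 4 sigma (≥ 15 nodes),
evaluating the model at |q'|. Finite slit-height smearing integrates
I(sqrt(q^2 + t^2)) over a normalized uniform weighting by
Gauss–Legendre quadrature; slit length 0 is the identity, and the
classical Porod q^−4 → q^−3 slit result is reproduced numerically. A
power-law tail fitted to the last decade of a data-backed model
supports extrapolation beyond the measured range (also used by the
p(r) transform if requested).

## Thermodynamic links

Dissociation 2M ⇌ D: K_d = exp(−ΔG_dis) with a 1 M standard state and
ΔG in k_BT (temperature enters only as a p-coefficient). The monomer
fraction solves 2 alpha^2 C_t/(1−alpha) = K_d in the stable form
alpha = 2/(1 + sqrt(1 + 8 C_t/K_d)); weights
w_mon = alpha C N_A / M and w_dim = (1−alpha) C N_A / (2M) conserve
monomer mass identically. Two-state unfolding: ΔG_unf(U) =
ΔG0 + ΔG1 U + ΔG2 U^2, f_folded = 1/(1 + exp(−ΔG_unf)). Both are
plain functions and registered link built-ins, so the same physics can
be written as an explicit link expression.

## Minimization and uncertainties

Four chainable methods share one box-constrained objective
(chi^2 + Psi): best-of-n uniform random search ("monkey"), Metropolis
annealing with a geometric temperature ladder and clipped box moves,
Nelder–Mead with reflection of iterates into the box, and L-BFGS-B
with finite-difference steps scaled to each parameter's magnitude.
Stochastic methods refuse to run without a seed; all randomness flows
through `numpy.random.default_rng(seed)`, so every fit and simulation
is reproducible bit for bit.

Curvature ("Hessian") uncertainties: covariance = 2 H^-1 with H the
central-difference Hessian of the *unreduced* residual sum
Q = sum_c sum_i r_ci^2 — using the reduced chi^2 would misscale
statistical errors by the point count. Eigenvalues below 1e-12 of the
largest trigger a pseudo-inverse with a warning (perfectly correlated
parameters report |correlation| → 1); parameters at bounds are flagged
as one-sided. Resampling uncertainties redraw I_exp ~ Normal(I_exp,
sigma) pointwise, re-minimize from the optimum, and report the spread;
iterations that fail are excluded, more than 20% failures is an error.

The pair distance distribution p(r) = (r^2/2 pi^2) ∫ I(q) q^2
sinc(qr) dq is computed by Simpson quadrature on the supplied grid,
which must satisfy dq · r_max ≤ pi/2.

## Synthetic experiments and what the tests show

The simulator reproduces the structure of the validation experiments:
Gaussian noise with sigma(q) = k I(q)^alpha (alpha = 1/2), k fixed by
a 3% relative error at the first point; q in [0.01, 0.5] 1/A with 100
log-spaced points; five-curve series (concentrations 2, 4, 6, 8,
10 g/l for dissociation at truth ΔG_dis = 8 k_BT; urea 0, 2, 4, 5,
6 M for unfolding at truth 10.5, −2.06, −0.0026 with worm-like
parameters b = 4.2 A, R = 4.0 A, N_b = 100, delta = 3 A, d_w = 0.95).
By default the particles are geometric surrogates — a volume-matched
sphere (radius from M v̄/N_A with v̄ = 0.73 cm^3/g) and a
touching-sphere dimer — so the whole pipeline runs without any
structure download; PDB-based evaluators can be passed in instead.
Interparticle interference is neglected (S = 1), appropriate for
≤ 1% w/w protein solutions.

What passing recovery tests demonstrate: the engine's plumbing — links,
shared parameters, weights, noise propagation, uncertainty estimates —
is self-consistent, and the thermodynamic parameters are identifiable
from curve series of this design at this noise level. What they do not
demonstrate: robustness to real-data pathologies (background
mis-subtraction, inter-particle interactions, radiation damage,
non-Gaussian errors) or to form-factor mismatch, since the surrogate
that generated the data is also fitted to it.

Identifiability caveat: in the unfolding series the three free-energy
coefficients trade off along a shallow chi^2 ridge because curves below
~4 M urea contain almost no unfolded signal. The built-in workflow
therefore uses deliberately loose f-coefficient bounds (dg0 ∈ [0, 40],
dg1 ∈ [−12, 2], dg2 ∈ [−2, 2]) so the optimum stays interior and the
curvature errors honestly reflect the ridge width (a few k_BT on dg0);
pinning a coefficient at a tight bound would fake precision. The Kuhn
length, by contrast, is sharply identified (±0.01 A at this design).

Validation problem sizes: five curves × 100 points per series,
24 resampling iterations, 1e5-stack Monte Carlo for the paracrystal
oracle, 1e6-sample Monte Carlo for the polydispersity oracle, a
~10^4-point discretized sphere for the Debye oracle.

## Known limitations

* The lamellar form factor is per unit area and diverges at q = 0.
* The MSA solver costs ~0.1–1 s per evaluation (more when rescaling
  engages); cache or pre-tabulate when fitting with it in the loop.
* Structure-factor polydispersity is not modelled (monodisperse
  decoupling only), and oligomer-mixture structure factors are out of
  scope.
* Implicit hydrogens are approximated by collapsing explicit H onto
  heavy atoms when present; files without hydrogens are used as-is
  (no topology-based H addition).
* Two-dimensional resolution kernels and TOF wavelength-band smearing
  are not implemented.
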