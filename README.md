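# sasglobal

Global model fitting of small-angle X-ray and neutron scattering
(SAXS/SANS) curve batches.

Solution scattering experiments increasingly produce *series* of
curves — the same sample measured across concentration, temperature,
denaturant, pressure. Fitted one by one, such curves yield structural
parameters; fitted *together*, with parameters shared across curves and
tied to the sample conditions through physical relations, they also
yield the thermodynamics driving the series: association constants,
unfolding free energies, interaction potentials. `sasglobal` is a
library (plus a small CLI) for exactly this kind of analysis, aimed at
structural biologists and soft-matter scientists analysing batches of
1-D SAS curves.

## The model

A batch of N_c experimental curves I_exp,c(q) is fitted by minimizing
the global reduced chi-square

    chi^2 = (1/N_c) * sum_c (1/N_q,c) * sum_i
            [ (Ihat_c(q_i) - I_exp,c(q_i)) / sigma_c(q_i) ]^2 ,

where Ihat_c = kappa_c I_c(q) + B_c; the per-curve scale kappa_c and
flat background B_c are user-fixed or solved in closed form by weighted
linear least squares. Each model curve is a weighted combination of
catalogue models,

    I_c(q) = sum_m  w_c,m * I_c,m(q),        I_c,m = P(q) * S(q),

with per-particle form factors P(q) (sphere, touching-sphere dimer,
core-shell cylinder, smoothed-profile lamella, excluded-volume
worm-like chain, and atomic structures from PDB files evaluated by the
exact Debye sum with a lattice-built hydration shell) and structure
factors S(q) (Percus-Yevick hard spheres, rescaled screened-Coulomb
MSA, RPA, Teixeira fractal, finite 1-D paracrystal, modified Caillé
theory).

Every parameter and weight carries a flag: fixed (0), fitted per curve
(1), common to all curves using the model (2), computed by a **link
function** of per-curve condition coefficients (*p*-coefficients such
as `temp`, `conc`, `urea`) and adjustable *f*-coefficients (flags 4/5),
or polydisperse with fitted/linked distribution parameters (flags
6/7/8/9). Link expressions are ordinary arithmetic (`a+b*temp`,
`frac_folded(dg0+dg1*urea+dg2*urea^2)`), may assign a penalty via the
reserved variable `fout`, and are how e.g. oligomer weights get tied to
a dissociation free energy. Polydispersity integrates any model
parameter over one of seven distribution kinds; instrumental smearing
convolves the model with Gaussian and slit resolution kernels.
Minimizers: uniform random search ("monkey"), simulated annealing,
Nelder-Mead simplex and L-BFGS quasi-Newton, freely chainable;
uncertainties from the Hessian at the optimum or by resampling the
data within their error bars.

## Worked example: dissociation free energy from a concentration series

β-lactoglobulin (18.4 kDa) sits in a monomer–dimer equilibrium with
dissociation free energy ΔG_dis ≈ 8 k_BT. Simulate a five-curve SAXS
series at 2–10 g/l with 3% first-point noise, then fit all five
curves globally with ΔG_dis as the only free parameter, entering the
monomer/dimer weights through the mass-action link:

```python
from sasglobal import fit_engine as fe
from sasglobal import synthetic_data as sd
from sasglobal.workflows import build_dissociation_fit

curves, truth = sd.batch_dissociation(dG_dis=8.0, seed=11)
problem = build_dissociation_fit(curves)
result = fe.minimize(problem)
print(result.summary())

_, resamp = fe.errors_resampling(problem, result.x_best,
                                 n_iterations=24, seed=11)
print(f"resampling std: {resamp[0]:.4f}")
```

Output:

```
chi2 = 0.942899  psi = 0
curve 1: kappa = 1  B = 0
curve 2: kappa = 1  B = 0
curve 3: kappa = 1  B = 0
curve 4: kappa = 1  B = 0
curve 5: kappa = 1  B = 0
  dg = 8.01647 +/- 0.0207
resampling std: 0.0174
```

The shared f-coefficient `dg` recovers the simulation truth of
8 k_BT within its uncertainty (curvature estimate ±0.021 k_BT,
data-resampling estimate ±0.017 k_BT), and chi^2 ≈ 0.94 confirms the
fit sits at the noise level. `sasglobal.workflows.build_unfolding_fit`
does the same for a urea unfolding series, recovering the quadratic
unfolding free energy and the Kuhn length of the unfolded chain.

## Command line

```sh
sasglobal simulate sim.yaml    # write a synthetic batch + manifest
sasglobal fit run.yaml         # (two-pass) global fit from a YAML config
sasglobal show gencode.par     # pretty-print a parameter file
```

A fit config declares curves (file, units, sigma power law,
p-coefficients, resolution), per-curve model stacks with parameter
flags/links, scale policies and the minimizer chain. When links
introduce new f-coefficients, the first `fit` run only emits
`gen<code>.par` with default bounds [0, 1] for editing; the second run
reads it back and minimizes.

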