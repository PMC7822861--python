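# actinex

Competitive nucleotide-exchange kinetics on monomeric (G-) actin, measured by
fluorescence anisotropy: simulation, calibration, global fitting, and seeded
synthetic data.

## The problem

G-actin binds one adenine nucleotide in its central cleft. Fluorescent ATP
analogs (ATP carrying a dye on the N⁶ base position via a flexible linker)
compete with unlabeled ATP for that site, and their binding can be followed
in real time by steady-state fluorescence anisotropy: the free analog tumbles
fast and shows low anisotropy *r*, while the actin-bound analog is
immobilized and shows high *r*. This package implements the quantitative
machinery needed to turn such anisotropy time courses and titrations into
rate and equilibrium constants:

* a mass-action model of the competitive exchange

  ```
  A + T  ⇌  AT      k₊,T (µM⁻¹ s⁻¹), k₋,T (s⁻¹)
  A + S  ⇌  AS      k₊,S (µM⁻¹ s⁻¹), k₋,S (s⁻¹)
  ```

  with five species — free nucleotide-free actin A, the ATP complex AT, the
  labeled-analog complex AS, and the free nucleotides T and S — integrated
  as a stiff ODE system with the three conservation laws enforced to machine
  precision, plus an independent analytic solver for the competitive
  equilibrium;

* the anisotropy observation layer: *r* = (I_VV − G·I_VH)/(I_VV + 2·G·I_VH)
  with the grating factor G = I_HV/I_HH, and the linear calibration mapping
  *r* ∈ [r_MIN, r_MAX] onto the bound fraction of the labeled species;

* global kinetic fitting: all association and chase time courses fit
  simultaneously with one shared rate-constant set (trust-region least
  squares in log-parameter space), with an identifiability scan showing that
  the individual association rates are not determined by the data — only
  their ratio is;

* equilibrium titration fitting with the quadratic (tight-binding) isotherm

  ```
  r = r_min + (r_max − r_min) · (K_d + G + P − √((K_d + G + P)² − 4·G·P)) / (2·P)
  ```

  for a labeled actin-binding protein (total P) titrated with G-actin
  (total G), valid with no free-ligand approximation;

* a seeded synthetic-data generator reproducing the statistical structure of
  each assay (association ladders, ATP chases, cation/salt/ABP scenarios,
  titrations), so the full pipeline is testable without measured data.

Units throughout: concentrations in µM, time in s, association rates in
µM⁻¹ s⁻¹, dissociation rates in s⁻¹.

## Worked example

Fit the reference rate set back from a noiseless synthetic bundle — four
association traces (2 µM actin, labeled analog at 25–200 nM, sampled every
10 s) plus one 100-µM-ATP chase — with the ATP association rate fixed:

```python
from actinex import (REFERENCE_RATES, ATTO488_CAL, KineticFitProblem,
                     generate_association_bundle, generate_chase,
                     global_kinetic_fit)

bundle = generate_association_bundle(REFERENCE_RATES) + [generate_chase(REFERENCE_RATES)]
problem = KineticFitProblem(datasets=bundle,
                            calibrations=[ATTO488_CAL] * 5, k_on_T=10.0)
fit = global_kinetic_fit(problem)
for name in ("k_on_T", "k_on_S", "k_off_T", "k_off_S"):
    flag = "fixed" if fit.fixed[name] else "fitted"
    print(f"{name:8s} = {fit.params[name]:.4g}  ({flag})")
print(f"ratio k_on_S/k_on_T = {fit.params['k_on_S'] / fit.params['k_on_T']:.3f}")
```

prints

```
k_on_T   = 10  (fixed)
k_on_S   = 12  (fitted)
k_off_T  = 0.0028  (fitted)
k_off_S  = 0.001  (fitted)
ratio k_on_S/k_on_T = 1.200
```

i.e. ATP leaves G-actin at 2.8×10⁻³ s⁻¹ and the labeled analog at 1×10⁻³ s⁻¹,
and the analog associates 1.2× faster than ATP — the ratio is the identifiable
quantity, not the individual on-rates.

The same stages are scriptable from a shell; for example, converting a
measured anisotropy into label occupancy with a calibrated r_MIN/r_MAX pair:

```sh
$ actinex occupancy --r 0.268 --rmin 0.242 --rmax 0.295
occupancy: 0.4906 (49%)
```

Other subcommands: `synth` (seeded datasets + manifest), `simulate` (state
trajectories), `fit-kinetics`, `fit-titration` (optionally with a residual
bootstrap), and `profile` (identifiability scan). All read/write plain CSV
with `# key=value` metadata headers and emit JSON reports.

## Layout

```
src/actinex/kinetics.py    reaction scheme, ODE simulation, analytic equilibrium
src/actinex/anisotropy.py  polarized intensities, G factor, r ↔ bound fraction
src/actinex/fitting.py     global kinetic fit, identifiability, titrations, bootstrap
src/actinex/synth.py       seeded generators and scenario presets
src/actinex/io.py          CSV dialects and metadata plumbing
src/actinex/cli.py         command-line surface
docs/methods.md            model, assumptions, numerical choices, limitations
```
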