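# Methods

## Reaction scheme and state space

The model describes competition between unlabeled ATP (T) and a fluorescent
ATP analog (S) for the single nucleotide-binding cleft of monomeric actin
(A), as two reversible bimolecular reactions:

    A + T ⇌ AT,   forward k_on_T·[A][T], reverse k_off_T·[AT]
    A + S ⇌ AS,   forward k_on_S·[A][S], reverse k_off_S·[AS]

Assumptions: well-mixed deterministic mass action; G-actin only (conditions
are chosen so filament assembly is negligible on the exchange time scale);
no ATP hydrolysis on the monomer; nucleotide-free actin is a transient
intermediate, not a stable pool. The five concentrations obey three
conservation laws (total actin, total T, total S), so the system has two
dynamical degrees of freedom.

Units are fixed package-wide: µM, seconds, µM⁻¹ s⁻¹, s⁻¹. The shipped
reference rate set for Mg²⁺-G-actin with a green-dye analog is
(k_on_T, k_on_S, k_off_T, k_off_S) = (10, 12, 2.8×10⁻³, 1×10⁻³); the derived
dissociation constants are Kd_T = 0.28 nM and Kd_S ≈ 0.083 nM, i.e. both
nucleotides are effectively stoichiometrically bound at micromolar actin.

## Simulation

`simulate_exchange` integrates the reduced system (AT, AS) with LSODA
(stiff-capable), rtol 1e-10 and atol 1e-13 µM, and reconstructs A, T and S
from the conservation laws, so conservation holds to machine precision by
construction rather than to integrator tolerance. The tolerance choice is
validated by a tolerance-halving test (halving changes no concentration by
more than 1e-6 µM) and by the equilibrium oracle below.

Initial loading convention: actin is purified ATP-bound, so the default
initial state is AT(0) = A_total, A(0) = AS(0) = 0. "Two-fold excess of free
ATP over actin" therefore means T_total = 3×A_total (1:1 bound plus the free
excess). A chase is an instantaneous step increase of free T at the chase
time — added volumes are negligible and no dilution of other species is
applied; the sample at the exact chase time reports the pre-addition state.

`competitive_equilibrium` solves the long-time limit independently of the
ODE path: substituting the binding-polynomial relations
AT = a·T_tot/(a+Kd_T), AS = a·S_tot/(a+Kd_S) into actin conservation gives a
single monotone equation for free actin a, bracketed on [0, A_total] and
solved by Brent's method with a Newton polish. It serves as the oracle for
the ODE: on random draws the simulated state at t = 50/min(k_off) matches it
to relative 1e-4 per species.

## Scenario modifiers

Buffer, cation and actin-binding-protein (ABP) effects are reported in the
literature as net fold-changes of exchange speed, not as changes of
individual microscopic constants. Because exchange from fully loaded actin
is dissociation-limited, the package applies the multiplier to both
dissociation rates and leaves the association rates untouched — an
interpretive choice, recorded here. Shipped presets: Mg baseline (1.0),
Ca²⁺ (0.2; five-fold slower), Mg + 50 mM KCl (2.0), saturating profilin
(3.5, within the reported 3–4× acceleration), ADF/cofilin-inhibited (0.3).
A direct consequence tested in the suite: the early label-binding flux
scales linearly with the multiplier.

## Anisotropy observation layer

Anisotropy is computed from the four polarized intensities as
r = (I_VV − G·I_VH)/(I_VV + 2·G·I_VH), G = I_HV/I_HH. With the two
calibration plateaus — r_MIN (label free) and r_MAX (label fully bound) —
the bound fraction is the linear map (r − r_MIN)/(r_MAX − r_MIN), and bound
concentration is fraction × S_total. The linear scale is exact only if the
label's total fluorescence is occupancy-independent; the package records
this assumption in output metadata rather than testing it. Readings pushed
outside [r_MIN, r_MAX] by noise are clipped to [0, 1] with a counted
warning: clipping preserves downstream mass constraints while surfacing
calibration drift. r_MAX may be measured by F-actin pelleting or by
free-nucleotide removal on ion-exchange resin; the two differ by a few
percent, so the calibration type carries a provenance tag but is treated as
a single user-supplied number.

Default synthetic calibration for the green-dye analog: r_MIN = 0.05,
r_MAX = 0.22 (plausible for a ~4 ns lifetime dye). A red-dye (long
wavelength) calibration of 0.242/0.295 is shipped as a second preset.

## Global kinetic fitting

All association and chase datasets are fit simultaneously with one shared
rate-constant set. Anisotropy traces are first converted to
bound-concentration space through their calibrations (mirroring the
conversion-then-fit workflow of the assay), residuals are equal-weight per
point, and optimization runs over log-parameters (positivity by
construction) with scipy's trust-region-reflective least squares,
convergence thresholds 1e-12, and 3-point finite-difference Jacobians.
Two numerical choices matter and were chosen after observing failure modes:

* **3-point Jacobians.** k_on_S and k_off_T span a shallow, curved valley
  (the observable AS(t) pins their product far more strongly than either
  factor), and 2-point Jacobians are inaccurate enough there to stall the
  trust region orders of magnitude short of the optimum.
* **Data-driven initial guesses.** k_off_T starts at ln2 divided by the
  association half-rise time (release-limited exchange), k_off_S at ln2 over
  the post-chase half-decay time, k_on_S at the fixed k_on_T; estimates are
  clamped to [1e-5, 1] s⁻¹. Fixed cold starts left coarse-grid fits in a
  local minimum.

Datasets are canonically ordered internally (by totals, chase, then value
bytes) so results are bit-identical under permutation of the input list.

k_on_T is fixed (default 10 µM⁻¹ s⁻¹) because the individual association
rates are structurally unidentifiable in the dissociation-limited regime:
`identifiability_profile` refits all free parameters along a grid of fixed
k_on_T values and shows a flat optimum residual with a stable recovered
ratio k_on_S/k_on_T ≈ 1.2. Each grid refit is warm-started from a reference
fit with k_on_S rescaled to preserve the ratio (profile-likelihood
continuation). On noiseless model-generated data every optimum residual is
at numerical zero, so "flat" is asserted as a spread below 1% of the mean
residual or all residuals below 1e-8 of the data's total sum of squares.

A full fit needs at least one association and one chase dataset: the chase
makes analog dissociation effectively irreversible and is what pins k_off_S
(dropping it measurably degrades k_off_S recovery, which the suite checks by
ablation).

## Titration fitting

Equilibrium titrations of a labeled ABP (profilin or ADF/cofilin) against
G-actin are fit with the quadratic isotherm (exact two-body closed form, no
free-ligand approximation); for trace ABP (≤ Kd/100) it collapses onto the
hyperbola G/(G + Kd) within 1% of the dynamic range. Free parameters are
(Kd, r_min, r_max), Kd in log space; initial guesses come from the data
(r_min at smallest G, r_max at largest, Kd at the half-rise G). Flat data
raise an unidentifiable-Kd error. Canonical examples: 0.5 µM labeled
profilin, Kd 2.1 µM; 2 µM labeled ADF/cofilin, Kd 1.7 µM, both on a 0–20 µM
G-actin grid of 12 points.

## Uncertainty

Parameter uncertainty is a seeded residual-resampling bootstrap: residuals
of the converged fit are resampled with replacement, added back to the
fitted curve, and the model refit per replicate; percentile intervals at the
requested level (default 95%, 200 replicates). The package makes no claim
that these intervals coincide with any other ± convention. More than 20%
replicate failures abort with diagnostics. The same machinery applies to
titration datasets and to kinetic problems (the latter resamples pooled
bound-concentration residuals; use modest replicate counts, since each
replicate is a full ODE fit).

## Synthetic data

Generators emulate: association ladders (defaults 2 µM actin; 25, 50, 100,
200 nM analog; 1800 s at 10-s sampling), an excess-ATP chase (100 µM added
at t = 1800 s, 5400 s total), scenario variants via the presets above, and
titrations from the quadratic isotherm. Noise is additive Gaussian on the
anisotropy reading, default sd 0.002 — twice the ±0.001 precision typical of
plateau means on a bench spectrofluorimeter — and a seed is mandatory
whenever sd > 0, making every dataset bit-reproducible. What the generator
does *not* emulate: photon-counting statistics, detector gain,
photobleaching, baseline drift, pipetting error in the totals, or any
occupancy dependence of the label's brightness. Tests passing on these data
therefore validate the estimation machinery under the stated noise model,
not robustness to instrument systematics.

Problem sizes used by the test suite and the acceptance script — the full
four-trace ladder plus chase (1265 points) for headline fits, a two-trace
20-s-sampled variant for tests that need many refits, 20 seeded replicates
for noisy-recovery statistics — are chosen so the entire suite runs in a
couple of minutes on one core while keeping every estimate deep in its
asymptotic regime.

## Known limitations

* The scenario multiplier is a net description; if a condition actually
  changes association rates (or the two off-rates unequally), the preset
  cannot represent that.
* The linear anisotropy scale ignores state-dependent quantum yield; with a
  brightness-changing label the bound fractions would be biased.
* k_off_T is the softest direction of the kinetic fit even with full
  convergence: at noise sd 0.002 its replicate-to-replicate spread is an
  order of magnitude larger than that of k_off_S (which the chase pins
  directly).
* The equilibrium solver assumes both ligands bind a single shared site;
  ternary complexes or allosteric coupling are out of scope.
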