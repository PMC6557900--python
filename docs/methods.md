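# Methods

This note records the models implemented in `sh2bind`, the defaults they
ship with, the numerical choices made where the design was open, and what
the synthetic-data generators do and do not emulate.

## Competition equilibria

Two 1:1 equilibria share a single protein pool:

    P + L ⇌ PL   K_D = [P][L]/[PL]     (spy reporter ligand)
    P + I ⇌ PI   K_i = [P][I]/[PI]     (competitor peptide)

All concentrations are in μM throughout the core; any unit conversion
belongs to the I/O layer.

* **Two-component solver.** [PL₀] is the smaller root of the binding
  quadratic, evaluated in the subtraction-safe form `P₀L₀ / larger_root` to
  avoid cancellation when binding is tight or weak.
* **Three-component forward solver.** The free-protein concentration `Pf`
  solves `Pf·(1 + L₀/(K_D+Pf) + I₀/(K_i+Pf)) = P₀`, a strictly increasing
  function on `[0, P₀]`, so bracketed root-finding (Brent) is globally
  convergent; the root is then polished with Newton steps carried out in
  extended precision so [PL] and [PI] are correctly rounded even in
  ill-conditioned corners (tight spy binding, near-zero displacement). The
  closed-form cubic exists but is numerically fragile for extreme
  parameters; it is kept only as a test oracle. Degenerate totals
  (P₀ = 0, or L₀ = I₀ = 0) return the analytic zero state directly.
* **Inversion.** Given an observed [PL], the bound competitor is
  `[PI] = (P₀ − PL) − K_D·PL/(L₀ − PL)`, the cancellation-safe
  factorisation of the textbook quadratic expansion, again evaluated in
  extended precision because [PI] can sit many orders of magnitude below
  the individual terms.
* **Clamping policy.** Inferred concentrations within 1e−6 μM outside the
  feasible interval are clamped and flagged — measurement noise produces
  slight infeasibility — while larger violations raise an error, since
  gross infeasibility signals bad input rather than noise.
* A competitor saturated at [PI] = [I₀] implies K_i = 0 regardless of the
  other species and is returned as such rather than tripping the protein
  mass-balance check.

## ¹⁹F CPMG displacement NMR

The spy molecule is a fluorinated pY analog (K_D 50 μM) whose ¹⁹F signal
relaxes slowly free in solution (R₂ ≈ 3 s⁻¹) and much faster when a
protein-bound population is present (R₂ ≈ 11 s⁻¹ observed at the default
condition). The T₂ measurement fits `I(t) = I(0)·e^(−t/T₂)` to integrals at
delays {0.05, 0.1, 0.2, 0.4, 0.8} s by nonlinear least squares in intensity
space (noise on integrals is closer to additive than log-additive),
initialised from the log-linear regression; noiseless data are recovered to
machine precision and `R₂ = 1/T₂` exactly by construction.

The displacement assay reads three integrals at a single 0.133 s delay:
spy alone (I_F), spy + protein (I_P), spy + protein + competitor (I_I).
The pipeline is

1. `PL₀` from the binding quadratic (defaults P₀ = 5 μM, L₀ = 100 μM,
   K_D = 50 μM);
2. bound fraction `f = (I_F − I_I)/(I_F − I_P)`, clamped into [0, 1] when
   it overshoots by ≤ 0.05 (noise), rejected beyond that; a measurement
   with `(I_F − I_P)/I_F` below 10 % is rejected outright as having no
   assay window;
3. `PL = f·PL₀`, then [PI] by inversion, then K_i.

**Censoring.** At `f ≥ 0.98` the competitor displaced nothing resolvable:
the result is flagged `no_displacement` and K_i is reported as the bound
implied by `f = 0.98` rather than an unstable point estimate. Symmetrically
`f ≤ 0.02` flags `complete_displacement` with the `f = 0.02` upper
quantitation bound. Explicit censoring was chosen over propagating
infinities or zeros.

**Replicates.** K_i is computed per replicate and then aggregated as
mean ± s.e.m. (sample s.d./√n); the alternative — averaging integrals first
— commutes only in the noiseless limit, and per-replicate fitting keeps the
replicate scatter visible. Censored replicates are excluded from the mean
and counted separately. The s.e.m. of a single replicate is reported as
NaN, not zero.

Default competitor totals are 10 μM for GHR-derived peptides and 50 μM for
EpoR-derived ones, matching the assay concentrations the panel fixture was
measured at.

## SPR steady state

Equilibrium responses on the 7-point dilution series
(0.08, 0.25, 0.7, 2.2, 6.7, 20, 60 μM) are fit to
`R_eq = R_max·C/(K_D + C)` by trust-region least squares. Triage follows
the conventions used for reporting weak binders: `n.d.` when the maximum
response is below 3× the response noise, `weak` when signal is present but
saturation was not achieved (fitted K_D beyond the highest tested
concentration, or non-convergence — reported as a status rather than an
exception), `quantified` otherwise. Kinetic (k_on/k_off) analysis and
sensorgram double-referencing are out of scope; inputs are steady-state
responses.

## ITC one-set-of-sites

Cumulative heat after injection i:

    Q_i = (N·Mt_i·ΔH·V₀/2)·[A_i − √(A_i² − 4·Xt_i/(N·Mt_i))],
    A_i = 1 + Xt_i/(N·Mt_i) + K_D/(N·Mt_i)

with the standard fixed-cell displacement correction
`Mt = [cell]·(1 − dV/2V₀)`, `Xt = [syringe]·(dV/V₀)·(1 − dV/2V₀)` for
cumulative injected volume dV. Per-injection heat:

    ΔQ_i = Q_i − Q_{i−1} + (dv_i/V₀)·(Q_i + Q_{i−1})/2 + offset

where the middle term compensates for bound material expelled from the
cell and `offset` absorbs the residual heat of dilution (the raw
buffer-control titration is modelled as this constant). Note the expelled-
volume convention leaves a small residual per-injection heat past
saturation that only vanishes as dV → V₀; this is a property of the
convention, not a bug, and is why an offset is fit.

Defaults mirror a small-cell calorimeter protocol: 200 μl cell at 50 μM,
750 μM syringe, one 0.4 μl priming injection (discarded from analysis, but
kept in the volume bookkeeping) followed by 19 × 2 μl injections at 298 K.
The cell volume is not a measured quantity here and is configurable.

The fit optimises (N, log₁₀K_D, ΔH, offset) by trust-region least squares
from three spread-out initialisations, keeping the best. The Wiseman
parameter `c = N·[cell]/K_D` is reported and N is flagged low-confidence
when c < 1, where stoichiometry and enthalpy become degenerate.

## Panel analytics

Fold change = mutant/wild-type affinity per assay within a panel (> 1 means
weakened binding). Hotspot calling scans only plain alanine substitutions
(labels `pY(±n)`); targeted chemistry probes such as V(−3)R are reported
but not scanned. The default rule scores each position by the geometric
mean of the two assays' fold changes and calls a hotspot at ≥ 2.0. The
verbal criterion "at least two-fold weakened" is ambiguous when the assays
disagree — GHR pY(−2) is > 2-fold in NMR alone — and the geometric-mean
consensus is the single-threshold rule that reproduces both published
hotspot lists on the packaged panel; `either` and `both` single-assay rules
are available as options.

Cross-assay concordance is the Pearson correlation of log₁₀K_D vs log₁₀K_i
pooled across panels (n = 23 for the fixture). Affinities are treated as
log-normal, which is also the convention under which the fixture reproduces
the published R² of 0.74. s.e.m. values are carried through reports but not
used as weights.

## Interface metrics

SASA is computed with a Shrake–Rupley kernel: each atom's accessible
sphere (van der Waals radius + 1.4 Å probe) is sampled on a deterministic
golden-section spiral lattice (960 points by default; deterministic for a
given count), and points occluded by any neighbour's accessible sphere are
removed. Radii: C 1.70, N 1.55, O 1.52, S 1.80, P 1.80 Å; unknown elements
fall back to 1.70 Å with a warning. Hydrogens, waters and (by default)
heteroatoms are excluded; PTR/SEP/TPO count as peptide residues. Buried
surface area between selections A and B is
`ΔSASA_A = SASA(A) − SASA(A in A∪B)` per side; the peptide-side number is
the headline value and the two-side mean is also reported because
deposition-service conventions differ. Tests pin the kernel to the analytic
single-sphere value and to an independent Monte-Carlo surface-point oracle.

Hydrogen bonds are assessed without hydrogens: an interfacial N/O pair
within 3.5 Å qualifies when the angle through each partner's covalent
antecedent (where one exists) is ≥ 120°; pairs with no computable
antecedent geometry fall back to distance-only and are flagged.
Hydrophobic contacts are pairs of apolar carbons (no covalently bonded
N/O) within 4.5 Å. Contact lists are deterministically ordered and
symmetric under selection swap. Altloc handling keeps the highest-occupancy
location; only the first model of multi-model files is read; residue
numbering follows the source file.

## Synthetic-data generators

Every generator is a pure function of (parameters, seed); a fixed seed
gives bit-identical output, and there is no hidden global RNG state.

* **CPMG.** Two-state fast exchange: the observed rate is the population
  mix `R₂_obs = (1 − f_b)·R₂_free + f_b·R₂_bound` with the bound fraction
  from the equilibrium solver. The defaults reproduce the observed pair
  (3 s⁻¹ free, 11 s⁻¹ with protein at ~3.3 % bound spy), which fixes the
  intrinsic bound-state rate at ≈ 246 s⁻¹ — an exchange-broadened bound
  state, as expected for a small reporter on a 60 kDa complex. Linear
  mixing is the simplest model consistent with a single observed
  mono-exponential decay; full Bloch–McConnell exchange simulation is out
  of scope.
* **Displacement triplets.** I_F and I_P follow the exponential
  attenuation at the 0.133 s readout; I_I is placed between them linearly
  in the remaining bound fraction PL/PL₀ — exactly the linearity the
  displacement relation assumes — so the noiseless table round-trips
  through the Ki pipeline to machine precision. A strictly exponential
  I_I would make the displacement relation only first-order accurate;
  the choice keeps generator and analysis model consistent and is a
  stated idealisation of the real readout.
* **SPR / ITC.** Exact isotherm plus additive Gaussian noise (SPR: fixed
  RU sd; ITC: sd proportional to the largest heat).
* **Toy structures.** Deterministic presets (`single_sphere`, `far_dimer`,
  `touching_dimer`, `hbond_pair`, `hydrophobic_pair`) exercising each
  interface metric, writable as PDB/mmCIF.

Noise defaults — CPMG 1 % multiplicative, SPR 1 RU additive, ITC 2 % of the
largest heat, panel inter-replicate log-sd 0.05, 4 replicates — are
assumptions chosen as typical instrument performance; real integral and
heat noise levels are not published for the assays the generators emulate.
Consequently the recovery tests demonstrate correctness of the estimation
chain under the assumed noise model, not instrument-accurate error bars.
The generators also do not emulate baseline drift, temperature gradients,
mass-transport limitation (SPR) or incomplete equilibration between
injections (ITC).

## Problem sizes used in the automated checks

The equilibrium solver is validated against a 200-iteration bisection
oracle on a 50×50 log-spaced (K_D, K_i) grid; parameter-recovery checks use
4-peptide panels × 4 replicates and 10 seeded repetitions per modality; the
end-to-end hotspot-recovery test uses a 5-position panel over 60 seeds; the
Monte-Carlo SASA oracle uses 2×10⁵ surface points per atom. These sizes
give stable statistics while keeping the full suite fast.

## Known limitations

* Absolute affinities of specific peptides are fixture constants from the
  published panel, not quantities this package can recompute — the raw
  instrument data behind them are not public.
* The displacement model assumes pure competition at a single site;
  allosteric or ternary effects would bias K_i.
* The buried-area convention (probe radius, radii set, point density,
  which side is quoted) varies between services; published interface areas
  are reproducible only up to that convention.
* Hotspot calling with the default rule depends on both assays being
  present; single-assay panels should use the `either` rule explicitly.
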