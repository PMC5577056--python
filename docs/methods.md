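# Methods

## Two-state exchange model

All dispersion analysis assumes two-state chemical exchange A ⇌ B between a
major conformer (population p_A) and a minor one (p_B = 1 − p_A ≤ 0.5), with
exchange rate k_ex = k_AB + k_BA and a chemical-shift difference Δω between
the states. Both states share one intrinsic transverse relaxation rate R₂⁰
(the "population-average intrinsic rate" fitted per residue per field); the
package deliberately does not support unequal intrinsic rates or three-state
schemes.

CPMG convention: ν_CPMG = 1/(2τ_cp) with τ_cp the delay between consecutive
180° pulses. ppm → rad/s conversion uses Δω = Δδ · 2π · f_H · γ_X/γ_H, with
the ¹⁵N/¹H ratio fixed at 0.10136767. Because Δδ and Φ are specified in ppm
(ppm²), a single parameter set produces correctly B₀-scaled curves at any
set of fields; amplitudes in rad²/s² scale with B₀².

### Closed forms and the numerical oracle

Three forward models are provided:

- `luz_meiboom_r2eff` — fast-exchange limit; only Φ = p_A·p_B·Δω² is
  identifiable there.
- `carver_richards_r2eff` — the full two-state closed form with equal
  intrinsic rates (the Ψ/ζ/D±/η± expression in the README).
- `bloch_mcconnell_r2eff` — explicit propagation of the two-site transverse
  magnetization through the echo train: the 2×2 complex evolution operator
  (relaxation + exchange + precession at 0 and Δω) is exponentiated per
  half-echo; ideal instantaneous 180° pulses act as complex conjugation; a
  pulse pair collapses to the operator P·P̄·P̄·P. The echo count is the
  relaxation period rounded down to whole pairs (logged when it does not
  divide evenly). R₂ᵉᶠᶠ = −ln(|M_A(T)|/p_A)/T, i.e. the observable is the
  major-state resonance with equilibrium initial magnetization — the same
  convention as peak-intensity analysis of constant-time CPMG spectra.

The propagator is the single source of truth for prefactor conventions.
Two facts the test suite exploits:

1. The Carver–Richards expression reproduces the **asymptotic decay rate**
   (slowest eigenmode of the echo-pair operator) to machine precision.
2. A finite constant-time measurement additionally carries the projection of
   the initial magnetization onto that eigenmode, contributing |ln c|/T to
   the apparent rate. This *projection transient* grows with p_B and is
   largest in intermediate exchange; it is a property of the experiment, not
   an error in either implementation.

`equivalence_grid()` therefore defines the documented validity grid by an
explicit criterion: candidate parameter sets spanning slow
(k_ex/Δω < 0.5), intermediate and fast (> 5) regimes are retained when the
projection transient at T = 40 ms — computed by eigendecomposition,
independent of the closed-form algebra — is below half the 0.05 s⁻¹
equivalence tolerance. On that grid (146 sets, all three regimes) the
closed forms agree with the propagator to better than 0.03 s⁻¹.

Numerical safeguards: arccosh arguments pushed below 1 by rounding are
clamped to 1 (counted in `CLAMP_COUNTER`, logged); for η₊ > 350 the
cosh overflow region switches to the asymptotic identity
arccosh(D₊cosh η₊ − …) → η₊ + ln D₊. `rex_amplitude` evaluates the
dispersion limits at 10⁻³ and 10⁶ Hz; beyond ~10⁶ Hz cancellation in the
arccosh argument exceeds 10⁻⁶ s⁻¹, and the approach to the ν → 0 plateau is
linear in ν, so nominal "plateau" frequencies like 10 Hz still sit 1–3 %
below the true limit in intermediate exchange.

## Global cluster fitting

Residues in a cluster share k_ex (and, for Carver–Richards, p_minor by
default — releasable per residue via `share_p_minor=False`); Δδ or Φ is per
residue in ppm units and converted per field; R₂⁰ is free per residue per
field. The weighted least-squares objective Σ((obs − model)/σ)² is minimized
with `scipy.optimize.least_squares` (trf, bounds: k_ex ∈ [1, 10⁶] s⁻¹,
p_minor ∈ [10⁻⁶, 0.5], Δδ ∈ [0, 50] ppm, R₂⁰ ∈ [0, 500] s⁻¹) from 8
log-spaced k_ex starts between 50 and 5000 s⁻¹; the lowest final χ² wins,
so the fit is deterministic given the data and configuration. Parameter
standard errors come from the Gauss–Newton covariance (JᵀJ)⁻¹ at the
optimum; an optional leave-one-point-out jackknife for the shared rate is
available (`jackknife_errors`) but off by default.

Measurement σ is taken from the input table; when absent it is estimated
from duplicate ν_CPMG points (pooled SD), else a 0.2 s⁻¹ floor. Curves whose
R₂ᵉᶠᶠ changed by less than 1 s⁻¹ over the whole CPMG range on every field
are excluded before fitting (strictly-below rule: a range of exactly
1 s⁻¹ is kept); every exclusion is logged with its range.

Model/regime choice: the fast-exchange fit (fewer parameters) is the simple
model, the full two-state fit the complex one;
F = [(χ²_s − χ²_c)/(dof_s − dof_c)] / (χ²_c/dof_c) with the complex model
selected at p < α = 0.05 (the significance level is a package choice). Ties
and negative numerators keep the simple model; fits of different data are
rejected by a fingerprint check. `cluster_search` fits alternative residue
partitions, ranks them by reduced χ², and reports F tests between nested
pairs.

## Candidate selection

A residue is a mutation candidate iff it (1) survived the exclusion filter
and fitting (has dispersion), (2) lies outside the CDR, (3) is not
Ala/Gly/Ser/Thr/Val, and (4) has relative ASA strictly above 20 %. Rejections
record the first failed criterion in that order. CDR boundaries are a
configurable `CdrDefinition`; Kabat ranges (H: 31–35, 50–65, 95–102;
L: 24–34, 50–56, 89–97) ship as the default scheme, and tests pass explicit
ranges so nothing depends on the scheme choice.

Relative ASA is whole-residue Shrake–Rupley area (probe 1.4 Å, 960 sphere
points per atom, hydrogens ignored) over the residue's theoretical maximum
(Tien et al. 2013 values), ×100. Missing backbone/CB atoms flag the record
and the area of the present atoms is used. Composite chemical-shift
perturbation is √(Δδ_H² + (0.14·Δδ_N)²) — the community-standard ¹⁵N weight —
and the mean / mean+SD flags use the population SD with strict comparisons,
so an all-identical set yields no flags.

## Binding thermodynamics

R = 8.314 J/(mol·K); energies in kJ/mol (4.184 J/cal for calorie inputs);
temperatures in K. ΔG = −RT ln K_A and TΔS = ΔH − ΔG hold exactly for every
assembled record (enforced to 10⁻⁶ kJ/mol). ΔC_p is the 1/σ²-weighted linear
slope of ΔH(T) with the SE from the weighted normal equations — the weighted
form is the documented choice; with equal σ it reduces to ordinary least
squares.

The one-site ITC forward model uses plug displacement: each injection of
volume dV expels an equal volume of pre-injection cell solution before
mixing, so M_i = M_{i−1}(V₀−dV)/V₀ and
X_i = [X_{i−1}(V₀−dV) + X_syr·dV]/V₀. The complex concentration solves the
1:1 mass-balance quadratic exactly (verified against a numeric root solve to
10⁻¹⁰), and q_i = ΔH·V₀·(B_i − B_{i−1}(V₀−dV)/V₀). Heat of dilution is a
constant-offset option, off by default. The default geometry is 25 × 10 µl
of 30 µM titrant into 2 µM macromolecule; the cell volume, which the
titration protocol itself does not fix, defaults to 1.4 ml (the nominal
working volume of a standard perfusion calorimeter). The fit optimizes
(log₁₀K_A, ΔH, n) from five log-spaced K_A starts; in the very-high-c regime
(c = K_A·[M] ≈ 4000 at K_A = 2×10⁹) the isotherm is nearly rectangular and
K_A is only weakly identified — round-trip tests therefore bound it within a
factor 1.5 there, while ΔH and n recover within 1 % and a low-c isotherm
(K_A = 10⁶) recovers K_A within 2 %.

DSC enthalpy is the trapezoidal integral of Cp minus baseline; absent an
explicit baseline a straight line is fitted through the flanking 10 % windows
and a warning is raised when the transition peak reaches into them.
Multi-transition deconvolution is out of scope.

## Ensemble distance analysis

Snapshot ensembles are multi-model PDB files (one frame per MODEL; altloc ''
or 'A'; all frames must share one atom roster). Distances are Euclidean
Cα–Cα per frame, order-preserving. Distribution comparison reports
median(a) − median(b) (standard median, mean of the central pair for even n)
and a two-sided Mann–Whitney U test: exact enumeration when both sides have
≤ 8 tie-free values, otherwise the tie-corrected normal approximation; an
all-tied degenerate input returns p = 1. The choice of a rank test is a
package decision — it is invariant under monotone transforms and makes no
normality assumption about snapshot distances.

## Synthetic data: what it does and does not emulate

Generators draw from `numpy.random.default_rng([seed, stream])` with a fixed
per-kind stream tag, so one integer seed reproduces every file bit for bit.

- Dispersion: curves sampled exactly from the closed forms plus i.i.d.
  Gaussian noise (default σ = 0.3 s⁻¹, which makes two-field k_ex standard
  errors land in the tens of s⁻¹). The default scenario has two 10-residue
  clusters at 840 s⁻¹ (Carver–Richards, p_minor 0.03, Δδ 0.5–2 ppm) and
  2033 s⁻¹ (fast exchange), two fields (600/750 MHz), a 12-point 25–1000 Hz
  grid with T = 40 ms (the grid is a package default, instruments vary), and
  flat decoys with R_ex < 0.5 s⁻¹. Not emulated: spectrometer artifacts,
  peak overlap, non-uniform sampling, temperature drift, correlated noise —
  so passing recovery tests demonstrate estimator correctness, not
  robustness to spectral pathology.
- ITC: heats from the one-site model plus optional Gaussian noise; no
  injection-kinetics distortion or dilution heats.
- Annotations: 32 dispersive residues of which exactly 8 pass all criteria
  (the counts mirror the motivating study; the residue identities are
  synthetic), failures rotating through CDR/size/ASA modes; the expected set
  is enumerated directly from the predicates and shipped with the fixture.
- Ensembles: isotropic Gaussian perturbations (default 0.5 Å) around a
  deterministic CA-only two-chain fold, 130 frames by default, with optional
  mean translations to emulate a repacked mutant. No force-field physics.
- DSC: two-state van't Hoff excess heat capacity on a linear baseline.

## Problem sizes and test design

The recovery studies fit 20 seeded replicates per exchange rate (10-residue
clusters for the wild-type rates, 6-residue for the mutant rates) and assert
median relative error < 5 % with ≥ 80 % coverage of 2-SE intervals; regime
selection uses 50 replicates per regime with 2-residue clusters. These sizes
were chosen as the smallest at which the statistical claims are stable.
Acceptance-style checks and the full suite run in a few minutes on one core.

## Known limitations

- Off-resonance effects, finite pulse widths, R1ρ, three-state exchange and
  temperature-dependent kinetics are out of scope.
- Covariance-based errors assume a locally quadratic objective; strongly
  non-identifiable corners (very fast exchange with tiny Φ) can report
  optimistic SEs — the jackknife option is the cross-check.
- The Carver–Richards form describes asymptotic decay; for p_minor ≳ 0.05 in
  intermediate exchange at short constant-time periods the projection
  transient exceeds 0.05 s⁻¹ and the numerical propagator should be the
  reference.
- The exact p-values of rank tests on real trajectory data depend on frame
  autocorrelation, which the i.i.d. synthetic ensembles do not model.
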