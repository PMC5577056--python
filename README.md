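# fluctedit

**Fluctuation editing** is a strategy for raising the affinity of an antibody
without touching its antigen-contacting loops: find residues of the free
antibody that undergo millisecond-timescale conformational exchange, mutate
the large, solvent-exposed, non-CDR ones to alanine, and keep the mutants
whose binding thermodynamics improve. `fluctedit` implements the full
computational side of that workflow for structural biologists and antibody
engineers:

1. **Selection** — quantify conformational exchange from ¹⁵N CPMG
   relaxation-dispersion data. Effective transverse relaxation rates
   R₂ᵉᶠᶠ(ν_CPMG) are fitted globally over residue clusters that share one
   exchange rate k_ex, using the Luz–Meiboom equation in fast exchange,

       R₂ᵉᶠᶠ = R₂⁰ + (Φ/k_ex)·[1 − (4ν/k_ex)·tanh(k_ex/4ν)],   Φ = p_A·p_B·Δω²,

   or the Carver–Richards equation (equal intrinsic rates) in slow to
   intermediate exchange,

       R₂ᵉᶠᶠ = R₂⁰ + k_ex/2 − ν·arccosh[D₊cosh η₊ − D₋cos η₋],

   with Ψ = k_ex² − Δω², ζ² = 4Δω²k_ex²(p_A − p_B)²,
   D± = ½[±1 + (Ψ + 2Δω²)/√(Ψ² + ζ²)] and
   η± = √(±Ψ + √(Ψ² + ζ²)) / (2√2·ν). A numerical Bloch–McConnell
   propagator pins the sign/prefactor conventions and serves as the oracle
   in the tests. Regime and cluster choice use reduced χ² and an F test;
   curves whose R₂ range is below 1 s⁻¹ are excluded up front.
2. **Fluctuation editing** — the four-criterion filter: a candidate must
   (i) display dispersion, (ii) lie outside the CDR (Kabat ranges by
   default, fully configurable), (iii) have a large side chain (not
   A/G/S/T/V), and (iv) expose > 20 % of its theoretical maximum
   solvent-accessible surface area (Shrake–Rupley, probe 1.4 Å).
3. **Evaluation** — one-site ITC isotherm simulation and fitting
   (K_A, ΔH, n), the exact decomposition ΔG = −RT ln K_A = ΔH − TΔS,
   error-weighted ΔC_p regression of ΔH(T), and baseline-corrected DSC
   enthalpy integration.
4. **Validation** — composite ¹H/¹⁵N chemical-shift perturbations with
   mean / mean+SD flags, and Cα–Cα distance-distribution comparison between
   snapshot ensembles (median shift + two-sided Mann–Whitney U).

A seeded synthetic-data module generates every input with known ground
truth, so the whole pipeline is testable offline.

## Worked example

The bundled scenario simulates a free antibody with two fluctuation
clusters (840 s⁻¹ and 2033 s⁻¹) observed at 600 and 750 MHz with
σ = 0.3 s⁻¹ noise, a 32-residue annotation table of which exactly 8 residues
satisfy all four criteria, and a high-affinity one-site titration:

```
$ fluctedit simulate --out demo --seed 7
simulate: wrote 12 files to demo
$ fluctedit fit-dispersion --out demo
cluster H:E4..: carver_richards k_ex=820+-28 s^-1 redchi2=0.96
cluster L:E4..: luz_meiboom k_ex=2004+-57 s^-1 redchi2=1.10
$ fluctedit select --out demo
select: 8 candidate(s): H:R1, H:K2, H:Q3, H:E4, H:F5, H:W6, H:Y7, H:L8
$ fluctedit itc-fit --out demo
itc-fit: K_A=2e+09 M^-1, dH=-99.50 kJ/mol, n=1.000
```

Both generating exchange rates are recovered within error, the F test
assigns the slow-to-intermediate cluster to Carver–Richards and the fast one
to Luz–Meiboom, and the selection stage returns exactly the fixture's
expected candidates. Thermodynamic decomposition from a config of measured
K_A and ΔH values:

```
$ fluctedit thermo --out demo --config thermo.yaml
H:R71A: dG=-52.17 dH=-99.50 TdS=-47.33 kJ/mol
L:R45A: dG=-52.17 dH=-68.88 TdS=-16.71 kJ/mol
H:R71A: dCp=-2.852+-0.078 kJ/mol/K
L:R45A: dCp=-1.044+-0.031 kJ/mol/K
```

i.e. at K_A = 2.0×10⁹ M⁻¹ and 293 K the binding free energy is
−52.17 kJ/mol; an enthalpy of −99.50 kJ/mol then implies an entropic
penalty TΔS of −47.33 kJ/mol, and the 1/σ²-weighted slope of ΔH over
293–303 K gives the heat-capacity change of binding.

The same operations are available as a library:

```python
from fluctedit import fit_cluster, select_candidates
from fluctedit.synth import gen_dispersion_dataset

curves, truth = gen_dispersion_dataset(seed=7)
fit = fit_cluster([c for c in curves if c.residue_id.startswith("H")],
                  model="carver_richards")
print(fit.k_ex, "+-", fit.k_ex_se)
```

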