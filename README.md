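# bindkin

Model fitting for the pH-dependent, cooperative binding of bile salts to
human ileal bile acid-binding protein (hI-BABP) — and, more generally,
for any two-site protein–ligand system studied by the same four
experiments:

* **Isothermal titration calorimetry (ITC)** of a two-step sequential
  binding equilibrium, fitted by least squares and by Bayesian ensemble
  MCMC;
* **Stopped-flow fluorescence kinetics** of a four-step sequential
  binding mechanism, with observed rates as rate-matrix eigenvalues;
* **NMR pH titrations** of backbone ¹⁵N shifts, fitted to the
  Henderson–Hasselbalch equation for apparent histidine pKₐ values;
* **¹⁵N CPMG relaxation dispersion**, fitted to a two-state
  (ground ↔ excited) conformational-exchange model.

The package is aimed at biophysicists who have integrated heats,
fluorescence transients, titration shift tables or R₂,eff dispersion
tables and want tested, reproducible fits with honest diagnostics — plus
synthetic-data generators with known ground truth for validating every
fitting stage by parameter recovery.

## Models

**ITC.** Sequential macroscopic equilibria P+L ⇌ PL (K_d1, ΔH₁) and
PL+L ⇌ PL₂ (K_d2, ΔH₂). Free ligand solves
L_tot = L + P_tot·(K₁L + 2K₁K₂L²)/(1 + K₁L + K₁K₂L²) with Kᵢ = 1/K_dᵢ;
per-injection heats follow the perfusion-cell volume bookkeeping with a
constant dilution-heat nuisance. Cooperativity is summarized by the Hill
coefficient n_H = 2/[1 + √(K_d2/K_d1)] and entropies by
TΔS = ΔH − RT·ln K_d. The Bayesian fit samples
(K_d1, K_d2, ΔH₁, ΔH₂, q_dil, σ) with log-uniform priors on the K_d.

**Kinetics.** P′ ⇌ P ⇌(+L) PL ⇌(+L) PL₂ ⇌ PL₂\* under pseudo-first-order
conditions. Observed rates are magnitudes of eigenvalues of the 5×5 rate
matrix; k_app,1 is the amplitude-dominant fast mode, k_app,2 the slowest
nonzero mode (≈ the PL₂ ⇌ PL₂\* interconversion). Traces
F(t) = F∞ + ΣAᵢexp(−ζᵢt) are fitted by variable projection.

**pH titrations.** δ_obs = δ_d + (δ_p − δ_d)/(1 + 10^(pH−pKₐ)).
Combined amide perturbations Δδ = √[Δδ_HN² + (0.154·Δδ_N)²] are tiered
at mean + 0.5 SD and mean + SD.

**CPMG.** Two-state exchange with k_ex = k_GE + k_EG, excited population
p_E and shift difference |Δδ|. The fitted form is the all-timescales
Carver–Richards expression (single-quantum); an independent
Bloch–McConnell matrix-exponential propagation of the explicit
τ–180°–τ echo train serves as numerical oracle. Fits are per-residue or
cluster-global with shared (k_ex, p_E).

## Worked example

Fit a synthetic dihydroxy-bile-salt isotherm (truth: K_d1 = 47 µM,
K_d2 = 13.2 µM, ΔH₁ = 0.86, ΔH₂ = −9.9 kcal/mol; 1% heat noise) by MCMC:

```python
from bindkin.itc import ITCModel, default_protocol
from bindkin.reference import BINDING_PARAMS
from bindkin.synthetic import generate_itc, NoiseSpec

truth = BINDING_PARAMS[("GCDA", 5.8)]
iso, _ = generate_itc(truth, noise=NoiseSpec("relative-gaussian", 0.01), seed=11)
post = ITCModel(iso, default_protocol()).fit_bayes(seed=0)
print(post.summary().to_string(index=False))
```

```
        parameter  post_mean      post_sd  wide
              kd1   0.000048 1.623816e-06 False
              kd2   0.000013 4.873110e-07 False
              dh1   0.905917 8.950351e-02 False
              dh2 -10.004029 8.175109e-02 False
    dilution_heat   0.006173 1.442824e-02 False
      noise_scale   0.033616 3.590958e-03 False
               nH   1.308176          NaN False
tds1_kcal_per_mol   6.795776          NaN False
tds2_kcal_per_mol  -3.359277          NaN False
```

The posterior means recover the generating constants (48 ± 1.6 µM and
13 ± 0.5 µM) within uncertainty, the Hill coefficient 1.31 reflects the
moderate positive cooperativity of the dihydroxy ligand, and the
stepwise entropies show the familiar signature of an entropy-driven
first step (TΔS₁ ≈ +6.8 kcal/mol) and an enthalpy-driven second step.
No parameter is flagged `wide`; in strongly cooperative regimes
(K_d2 ≪ K_d1) the first-step enthalpy posterior broadens by an order of
magnitude and is flagged.

A command-line interface mirrors the library:
`bindkin itc fit --mode bayes --data isotherm.csv --seed 1 --out run/`,
with analogous `sf`, `pka`, `shifts`, `cpmg` and `synth` subcommands.

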