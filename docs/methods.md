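# Methods

This note documents the models, the numerical choices behind them, what
the synthetic-data generators do and do not emulate, and the known
limitations. Everything quantitative here is computed by the test suite
or by `scripts/acceptance.py`; nothing is asserted that the code does
not measure.

## Two-site ITC model (`bindkin.itc`)

**Model.** Sequential macroscopic binding, P+L ⇌ PL and PL+L ⇌ PL₂,
parameterized by dissociation constants (kd1, kd2, in M) and stepwise
enthalpies (dh1, dh2, kcal/mol). Free ligand is the unique non-negative
root of the mass-balance equation; we solve it by 30 bracketed
bisections on [0, L_tot] (the function is strictly increasing) followed
by bracket-clamped Newton polish, vectorized across injections and MCMC
walkers. Agreement with a pure-bisection reference is ~1e-15 relative;
both mass balances hold to better than 1e-9.

**Heats.** Cell heat content after injection i is
Q_i = V₀(ΔH₁[PL]ᵢ + (ΔH₁+ΔH₂)[PL₂]ᵢ); the observed normalized heat is
q_i = [Q_i − Q_{i−1} + (dVᵢ/V₀)(Q_i+Q_{i−1})/2] / (dVᵢ·c_syr) + q_dil.
Totals follow the perfusion-cell convention
P_tot,i = P₀(1−vᵢ/2V₀)/(1+vᵢ/2V₀), L_tot,i = c_syr(vᵢ/V₀)/(1+vᵢ/2V₀).
The heat of dilution is a constant nuisance parameter rather than a
pre-subtracted correction, so the model is self-contained. The default
protocol is 8×0.4 µL + 37×0.8 µL of 5.1 mM ligand into 0.2019 mL of
0.2 mM protein at 25 °C. First-injection exclusion is available but off
by default.

**Fitting.** Least squares works in (ln kd1, ln kd2, dh1, dh2, q_dil)
with tight (1e-15) convergence tolerances; on noiseless synthetic data
it returns the generating parameters to ~1e-15 relative. The Bayesian
fit uses an affine-invariant ensemble sampler (20 walkers), initialized
in a small ball around the least-squares optimum, with log-uniform
priors on kd over [1e-9, 1e-1] M, uniform enthalpies over ±50 kcal/mol,
uniform dilution heat over ±10 kcal/mol, and a Jeffreys prior on the
Gaussian noise scale with a floor of e⁻¹² kcal/mol (far below instrument
precision; it keeps the posterior proper on degenerate noise-free
input). Defaults draw 10 000 total samples and discard the first 1 000.
Diagnostics: mean acceptance fraction (warning outside [0.05, 0.95]) and
a split-chain variance ratio per marginal (target < 1.05).

**Wide-parameter flag.** A parameter is reported `wide` when its
posterior SD exceeds 5× the inferred noise scale (enthalpies) or 50% of
its posterior mean (dissociation constants). The factor 5 separates the
two regimes this package targets by an order of magnitude on either
side: in moderately cooperative fits the enthalpy SD sits at ~2.5× the
noise scale, while in strongly cooperative fits (kd2 ≪ kd1, PL barely
populated) it reaches 10–20×. ΔH₁ in such regimes is intrinsically hard
to determine and the flag says so rather than printing a false-precision
number.

**Calibration caveat.** The mean ± 2 SD posterior interval for kd1 has
~87–90% frequentist coverage under the default recovery conditions
(45-injection design, 1% heat noise): the per-dataset posterior SD
(≈4.1% relative) slightly understates the across-dataset scatter of the
estimator (≈4.5%), with no systematic bias. Treat 2-SD kd intervals as
approximate.

## Four-step kinetics (`bindkin.stoppedflow`)

**Model.** P′ ⇌ P ⇌ PL ⇌ PL₂ ⇌ PL₂* with constants k1/k_1 (s⁻¹,
conformational pre-equilibrium), k2/k_2 and k3/k_3 (binding, second
order in s⁻¹µM⁻¹), k4/k_4 (post-binding conformational step). Under
pseudo-first-order mixing (warning when protein > ligand/10) the system
is linear; propagation uses the eigendecomposition of the 5×5 rate
matrix (exact, equivalent to the matrix exponential), starting from the
k1/k_1-equilibrated P′/P mixture with no complexes. The matrix has
exactly one zero eigenvalue (equilibrium) and otherwise negative real
parts; total protein is conserved to 1e-10.

**Observed-rate assignment.** A measured transient is fitted with two
exponentials, so of the four relaxing modes the package reports the
slowest nonzero mode (k_app,2) and, among the rest, the mode carrying
the largest absolute fluorescence amplitude (k_app,1) — the pair a
biexponential fit detects. All four eigenvalues and amplitudes are
available via `observed_rates_eigen(..., full=True)` for diagnostics.

**Trace sampling and fluorescence coefficients.** The default time grid
is 8 000 linearly spaced points over (0, 10 s], mirroring how a
stopped-flow instrument acquires; linear sampling matters because an
unweighted fit of a log-spaced grid overweights the early transient and
biases multi-mode rate estimates. Per-state brightness defaults to
(P′, P, PL, PL₂, PL₂*) = (1.0, 1.0, 0.8, 0.6, 0.5) (arbitrary units,
quenching-like); mechanism fitting uses rates only, never amplitudes.

**Biexponential fits** use variable projection (offset and amplitudes
solved linearly at each iterate; only the two log-rates are nonlinear),
multi-started over decade-spaced rate pairs. The default extraction
window starts at 5 ms, past the fast conformational mode.

**Mechanism fits** minimize residuals between both observed-rate
branches and the eigenvalue predictions over all ligand concentrations,
inverse-variance weighted when uncertainties are supplied and relative
otherwise (the branches differ by ~100×). k1/k_1 are held fixed by
default: they are faster than the observable modes and barely influence
the remaining constants. Parameters with a 95% relative CI wider than
10 are flagged unidentifiable. Temperature is metadata only.

**Limitations.** With the default brightness coefficients the slow
conformational mode carries almost no amplitude below ~100 µM ligand,
so the biexponential route is validated against the eigenvalue route at
≥300 µM, where both agree within 2% on noiseless traces. The often-used
shortcut "k2 from the high-ligand slope of k_app,1" is only approximate:
across the shipped reference schemes the 300–500 µM secant slope is
0.76–0.87 × k2, because the binding branch already feels the
conformational-step ceiling (~k1+k_1) and repulsion from the second
binding branch. The package reports the fitted k2; the slope is a
sanity check, not an estimator.

## Henderson–Hasselbalch titrations (`bindkin.titration`)

Single-site model δ(pH) = δ_d + (δ_p−δ_d)/(1+10^(pH−pKₐ)); multi-site
extensions are deliberately excluded. Weighted least squares with
uncertainties from the local quadratic approximation; an initial guess
from the curve endpoints and midpoint crossing. Flags: `unreliable` when
the fitted pKₐ leaves the sampled pH span ±1 unit, `unidentifiable` when
|δ_p−δ_d| < 3× the noise, `poor_fit` when the reduced χ² exceeds 9 with
supplied errors. Recovery at the seven-point unbound-protein pH grid
(4.7–8.0, 0.02 ppm noise) is essentially unbiased (<0.02 pKₐ units over
200 simulations). The combined amide perturbation uses w₁ = 0.154 for
¹⁵N; tier thresholds use the population SD (configurable via `ddof`).

## Two-state CPMG dispersion (`bindkin.cpmg`)

**Closed form.** Single-quantum Carver–Richards R2eff(ν_CPMG) with equal
intrinsic R₂ in both states (a free excited-state R₂ is unidentifiable
from one field and one relaxation delay) and
Δω = Δδ·2π·f_N, f_N = 60.81 MHz at 14.1 T (configurable). ν_CPMG is
1/(2τ) with τ the spacing of successive 180° pulses. Hyperbolic terms
are evaluated via ln cosh asymptotics for large arguments, so slow
exchange with large Δω never overflows. Although the measurement cited
for this experiment family is the multiple-quantum formulation, with a
zero proton shift difference it reduces to the single-quantum form used
here; the numerical oracle, not a transcribed formula, is the arbiter
of correctness.

**Numerical oracle.** `bloch_mcconnell_r2eff` builds the one-echo
(τ/2–180°–τ/2) propagator of the two-site complex transverse
magnetization by matrix exponentials, with the 180° pulse as complex
conjugation, and by default returns the decay rate of the dominant
eigenmode of that cycle — the quantity the closed form describes, and
the rate a constant-time experiment estimates once the minor mode
(which decays at ~k_ex) has died. On a 5×5×5×3 grid spanning k_ex
12–1852 s⁻¹, p_E 0.3–23%, |Δδ| 0.5–3.5 ppm and R₂⁰ 5–12 s⁻¹ at all 19
acquisition frequencies, closed form and oracle agree to ~1e-11 s⁻¹.
Finite-time two-point measures from the (1−p_E, p_E) initial condition
(`measure="total"` or `"ground"`, propagated through
n = max(1, round(2·T_CP·ν)) echoes) are also available; at large p_E
they differ from the eigenmode rate by up to ~10 s⁻¹ through the
projection amplitude of the slow mode — a real property of short
constant-time experiments worth remembering when p_E is not small. Note
the printed acquisition frequencies (74, 99 Hz, …) are not commensurate
with T_CP = 40 ms; the eigen measure uses the exact spacing 1/(2ν), the
finite-time measures the quantized train.

**Fitting.** R2eff uncertainties come from duplicate scatter, pooled
across the profile (the pooled estimate recovers an injected noise SD
within 25% at 50 residues). Residues are screened by
Rex = R2eff(ν_min) − R2eff(ν_max) > 2 s⁻¹. Individual fits optimize
(k_ex, p_E, |Δδ|, R₂⁰) by bounded least squares, multi-started on
k_ex ∈ {50, 200, 800, 3200} s⁻¹ × p_E ∈ {0.01, 0.05, 0.2} with χ² ties
broken toward smaller p_E (the slow-exchange Δδ/p_E degeneracy);
uncertainties by residual bootstrap (200 resamples, seeded). Cluster
fits share (k_ex, p_E) with per-residue (|Δδ|, R₂⁰); a single-residue
cluster reproduces the individual fit exactly. Flat profiles yield a
no-exchange flag instead of a number. At cluster-like parameters
(k_ex = 836 s⁻¹, p_E = 3.1%, R₂⁰ = 8 s⁻¹) the 2 s⁻¹ screen is cleared
from |Δδ| ≈ 0.7 ppm upward; 0.5 ppm gives Rex ≈ 1.1 s⁻¹.

## Synthetic data (`bindkin.synthetic`)

Generators reproduce the four acquisition designs: the 45-injection ITC
protocol; stopped-flow series at 20–500 µM ligand with 1 µM protein;
seven-point pH grids (4.7…8.0 unbound, 4.6…9.1 bound); and 19-point
duplicate dispersion profiles at 14.1 T, T_CP = 40 ms. Default noise —
calibrated once to the visual quality of published data of this kind —
is Gaussian: 1% of the largest |heat| (ITC), 0.5% of the trace dynamic
range (stopped flow), 0.02 ppm (titrations), 0.3 s⁻¹ per duplicate
(dispersion). One RNG per dataset; the seed rides along in the
`SyntheticTruth` sidecar, and equal seeds give bit-identical data.

What the generators do **not** emulate: baseline drift and injection
artifacts in thermograms, instrument dead time and photobleaching in
transients, peak overlap and assignment errors in spectra, or any
non-Gaussian noise. Passing recovery tests therefore demonstrates that
the fitters invert their own forward models at realistic noise — a
necessary condition — not that every instrumental pathology is handled.

## I/O and reproducibility (`bindkin.io`, `bindkin.cli`)

All formats are plain CSV/JSON; readers validate schemas and report the
offending row on errors; reports are byte-deterministic for fixed input
and seed. The `bindkin` CLI is a thin layer over the library, logging to
stderr (JSON-lines optional); every numeric column name carries units.

## Problem sizes

Recovery studies use 20 seeds (ITC), 10 seeds (kinetics, global
dispersion) and 50 seeds (titrations) per condition, with 10 residues
per dispersion cluster in the headline study and 5 per cluster in the
two-cluster study — enough for stable medians while keeping each study
in the seconds-to-minutes range.
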