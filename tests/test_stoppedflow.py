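"""Four-step binding kinetics: rate matrix, eigen rates, traces, fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bindkin.stoppedflow import (
    BiexpModel, KineticScheme, MechanismModel, Trace, default_times,
    observed_rates_eigen, rate_matrix, simulate_trace, species_trajectory,
)
from bindkin.reference import KINETIC_SCHEMES
from bindkin.synthetic import NoiseSpec, generate_observed_rates, generate_stopped_flow

# strictly positive rate constants: a vanishing constant disconnects a
# state and legitimately adds a second equilibrium (zero) eigenvalue
rates_strategy = st.builds(
    KineticScheme,
    k1=st.floats(10, 3000), k_1=st.floats(10, 500),
    k2=st.floats(0.01, 3), k_2=st.floats(1, 300),
    k3=st.floats(0.01, 10), k_3=st.floats(1, 100),
    k4=st.floats(0.01, 3), k_4=st.floats(1, 30),
)


class TestRateMatrix:
    def test_zero_scheme_gives_zero_matrix(self):
        z = KineticScheme(0, 0, 0, 0, 0, 0, 0, 0)
        assert np.all(rate_matrix(z, 100.0) == 0.0)

    def test_hand_assembled_entries(self):
        s = KINETIC_SCHEMES[("GCDA", 7.2)]
        m = rate_matrix(s, 300.0)
        assert m[2, 1] == pytest.approx(366.0)  # k2 * L
        assert m[1, 0] == s.k1
        assert m[0, 1] == s.k_1
        assert m[3, 2] == pytest.approx(s.k3 * 300.0)
        assert m[4, 3] == s.k4
        assert m[3, 4] == s.k_4
        assert m[1, 1] == pytest.approx(-(s.k_1 + s.k2 * 300.0))

    @given(rates_strategy, st.floats(1.0, 500.0))
    @settings(max_examples=100, derandomize=True)
    def test_columns_sum_to_zero_and_spectrum(self, scheme, ligand):
        m = rate_matrix(scheme, ligand)
        assert np.allclose(m.sum(axis=0), 0.0, atol=1e-10 * max(np.abs(m).max(), 1))
        off = m - np.diag(np.diag(m))
        assert np.all(off >= 0)
        lam = np.linalg.eigvals(m)
        mags = np.abs(lam)
        tol = 1e-8 * max(mags.max(), 1.0)
        assert np.sum(mags < tol) == 1  # exactly one equilibrium mode
        assert np.all(lam.real[mags >= tol] < tol)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            KineticScheme(-1, 0, 0, 0, 0, 0, 0, 0)


class TestObservedRatesEigen:
    def test_two_state_closed_form(self):
        s = KineticScheme(0, 0, 1.48, 73.0, 0, 0, 0, 0)
        ka1, ka2 = observed_rates_eigen(s, 100.0)
        assert ka1 == pytest.approx(1.48 * 100 + 73, rel=1e-12)
        assert ka2 == pytest.approx(221.0, rel=1e-12)

    def test_fast_rate_rises_with_ligand(self):
        s = KINETIC_SCHEMES[("GCA", 7.2)]
        lo, _ = observed_rates_eigen(s, 20.0)
        hi, _ = observed_rates_eigen(s, 300.0)
        assert hi > lo

    def test_slow_rate_near_conformational_step(self):
        s = KINETIC_SCHEMES[("GCDA", 5.8)]
        _, ka2 = observed_rates_eigen(s, 500.0)
        assert ka2 == pytest.approx(s.k4 + s.k_4, rel=0.20)

    def test_slow_rate_ligand_independent(self):
        """k_app2 varies by <5% across 100-500 uM for the published schemes."""
        for s in KINETIC_SCHEMES.values():
            k2s = [observed_rates_eigen(s, L)[1] for L in (100, 200, 300, 400, 500)]
            assert (max(k2s) - min(k2s)) / min(k2s) < 0.05


class TestSimulateTrace:
    def test_equal_coefficients_constant_fluorescence(self, scheme_gcda_ph58):
        tr = simulate_trace(scheme_gcda_ph58, fluor_coeffs=np.ones(5),
                            ligand=300.0, p0=1.0)
        assert np.allclose(tr.fluorescence, tr.fluorescence[0], rtol=1e-9)

    def test_stationarity_at_long_times(self, scheme_gcda_ph58):
        t = np.linspace(0.0, 50.0, 2000)[1:]
        tr = simulate_trace(scheme_gcda_ph58, ligand=300.0, p0=1.0, times=t)
        df = np.abs(np.diff(tr.fluorescence[-10:]))
        assert np.all(df < 1e-10)

    def test_total_protein_conserved(self, scheme_gcda_ph58):
        t = default_times(500)
        x = species_trajectory(scheme_gcda_ph58, p0=1.0, ligand=300.0, times=t)
        assert np.allclose(x.sum(axis=1), 1.0, rtol=1e-10)

    def test_pseudo_first_order_warning(self, scheme_gcda_ph58):
        with pytest.warns(UserWarning, match="pseudo-first-order"):
            simulate_trace(scheme_gcda_ph58, ligand=5.0, p0=1.0)

    def test_trace_matches_eigen_rates(self, scheme_gcda_ph58):
        """Biexponential rates from the noiseless 300 uM trace agree with
        the selected eigenvalues within 2%."""
        tr = simulate_trace(scheme_gcda_ph58, ligand=300.0, p0=1.0)
        fit = BiexpModel(tr).fit(n_exp=2, t_min=5e-3)
        ka1, ka2 = observed_rates_eigen(scheme_gcda_ph58, 300.0)
        assert fit.rates[0] == pytest.approx(ka1, rel=0.02)
        assert fit.rates[1] == pytest.approx(ka2, rel=0.02)


class TestBiexpFit:
    def test_exact_model_recovery(self):
        t = np.linspace(0, 1.0, 20000)[1:]
        y = 1.0 + 0.5 * np.exp(-200 * t) + 0.2 * np.exp(-10 * t)
        fit = BiexpModel(Trace(times=t, fluorescence=y, ligand=100.0, protein=1.0)).fit()
        assert fit.rates[0] == pytest.approx(200.0, rel=1e-6)
        assert fit.rates[1] == pytest.approx(10.0, rel=1e-6)
        assert fit.amplitudes[0] == pytest.approx(0.5, rel=1e-6)
        assert fit.amplitudes[1] == pytest.approx(0.2, rel=1e-6)
        assert fit.f_inf == pytest.approx(1.0, rel=1e-6)
        assert not fit.single_exponential

    def test_single_exponential_flag(self):
        t = np.linspace(0, 1.0, 5000)[1:]
        y = 2.0 + 0.7 * np.exp(-50 * t)
        fit = BiexpModel(Trace(times=t, fluorescence=y, ligand=100.0, protein=1.0)).fit(n_exp=2)
        assert fit.single_exponential

    def test_noisy_recovery_vs_eigen(self, scheme_gcda_ph58):
        """Median fitted rates across seeds stay within 5% of eigen rates."""
        ka1, ka2 = observed_rates_eigen(scheme_gcda_ph58, 300.0)
        clean = simulate_trace(scheme_gcda_ph58, ligand=300.0, p0=1.0)
        dyn = np.ptp(clean.fluorescence)
        r1, r2 = [], []
        for seed in range(20):
            noisy = clean.fluorescence + np.random.default_rng(seed).normal(
                0, 0.005 * dyn, clean.fluorescence.shape)
            tr = Trace(times=clean.times, fluorescence=noisy, ligand=300.0, protein=1.0)
            fit = BiexpModel(tr).fit(n_exp=2, t_min=5e-3)
            r1.append(fit.rates[0])
            r2.append(fit.rates[1])
        assert np.median(r1) == pytest.approx(ka1, rel=0.05)
        assert np.median(r2) == pytest.approx(ka2, rel=0.05)


class TestMechanismFit:
    def test_noiseless_exact_recovery(self, scheme_gcda_ph58):
        obs, _ = generate_observed_rates(scheme_gcda_ph58, noise=NoiseSpec(scale=0.0))
        init = scheme_gcda_ph58.replace(k2=scheme_gcda_ph58.k2 * 1.6,
                                        k_2=scheme_gcda_ph58.k_2 * 0.6,
                                        k4=scheme_gcda_ph58.k4 * 2.0)
        res = MechanismModel(obs).fit(init=init)
        assert res.rss < 1e-8
        for n in ("k2", "k_2", "k3", "k_3", "k4", "k_4"):
            assert getattr(res.scheme, n) == pytest.approx(
                getattr(scheme_gcda_ph58, n), rel=1e-6)

    def test_k2_recovery_under_noise(self, scheme_gcda_ph58):
        k2s = []
        for seed in range(8):
            obs, _ = generate_observed_rates(
                scheme_gcda_ph58, noise=NoiseSpec("relative-gaussian", 0.03), seed=seed)
            res = MechanismModel(obs).fit(
                init=scheme_gcda_ph58.replace(k2=scheme_gcda_ph58.k2 * 2))
            k2s.append(res.scheme.k2)
        assert np.median(k2s) == pytest.approx(1.48, rel=0.10)

    def test_fixed_parameters_stay_fixed(self, scheme_gcda_ph58):
        obs, _ = generate_observed_rates(scheme_gcda_ph58, noise=NoiseSpec(scale=0.0))
        res = MechanismModel(obs).fit(init=scheme_gcda_ph58)
        assert res.scheme.k1 == scheme_gcda_ph58.k1
        assert res.scheme.k_1 == scheme_gcda_ph58.k_1
        assert res.fixed == frozenset({"k1", "k_1"})


class TestGenerators:
    def test_zero_protein_gives_flat_traces(self, scheme_gcda_ph58):
        traces, _, _ = generate_stopped_flow(
            scheme_gcda_ph58, ligand_concs=(300.0,), protein=0.0,
            noise=NoiseSpec(scale=0.0), seed=0, rates_from="eigen")
        assert np.allclose(traces[0].fluorescence, 0.0)

    def test_rate_ordering(self, scheme_gcda_ph58):
        _, obs, _ = generate_stopped_flow(
            scheme_gcda_ph58, ligand_concs=(100.0, 300.0), protein=1.0,
            noise=NoiseSpec(scale=0.0), seed=0, rates_from="eigen")
        assert np.all(obs.kapp1 > obs.kapp2)

    def test_biexp_pipeline_matches_eigen_at_high_ligand(self, scheme_gcda_ph58):
        """At >=300 uM the slow mode carries amplitude and the trace-fit
        route reproduces the eigen route within 2%."""
        _, obs_fit, _ = generate_stopped_flow(
            scheme_gcda_ph58, ligand_concs=(300.0, 500.0), protein=1.0,
            noise=NoiseSpec(scale=0.0), seed=0, rates_from="biexp")
        _, obs_eig, _ = generate_stopped_flow(
            scheme_gcda_ph58, ligand_concs=(300.0, 500.0), protein=1.0,
            noise=NoiseSpec(scale=0.0), seed=0, rates_from="eigen")
        assert obs_fit.kapp1 == pytest.approx(obs_eig.kapp1, rel=0.02)
        assert obs_fit.kapp2 == pytest.approx(obs_eig.kapp2, rel=0.02)

    def test_same_seed_determinism(self, scheme_gcda_ph58):
        a, ra, _ = generate_stopped_flow(scheme_gcda_ph58, ligand_concs=(300.0,),
                                         seed=5, rates_from="eigen")
        b, rb, _ = generate_stopped_flow(scheme_gcda_ph58, ligand_concs=(300.0,),
                                         seed=5, rates_from="eigen")
        assert np.array_equal(a[0].fluorescence, b[0].fluorescence)
        assert np.array_equal(ra.kapp1, rb.kapp1)
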