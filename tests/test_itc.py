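"""Two-site binding thermodynamics: species solver, heats, Hill, entropy, fits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bindkin import itc
from bindkin.itc import (
    BindingParams, ITCModel, hill_coefficient, simulate_isotherm,
    solve_species, stepwise_entropy,
)
from bindkin.reference import BINDING_PARAMS, ENTROPIES_TDS, HILL_COEFFICIENTS
from bindkin.synthetic import NoiseSpec, generate_itc


def grid_bisect_free_ligand(p_tot, l_tot, kd1, kd2, n_grid=10**6):
    """Independent dense-grid bracketing of the free-ligand mass balance."""
    k1, k2 = 1.0 / kd1, 1.0 / kd2

    def g(l):
        den = 1.0 + k1 * l + k1 * k2 * l * l
        return l + p_tot * (k1 * l + 2 * k1 * k2 * l * l) / den - l_tot

    grid = np.linspace(0.0, l_tot, n_grid)
    vals = grid + p_tot * (k1 * grid + 2 * k1 * k2 * grid**2) / (
        1.0 + k1 * grid + k1 * k2 * grid**2) - l_tot
    i = int(np.searchsorted(vals > 0, True)) - 1
    lo, hi = grid[max(i, 0)], grid[min(i + 1, n_grid - 1)]
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if g(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


class TestSpeciesSolver:
    def test_no_ligand_limit(self, gcda_ph58):
        st_ = solve_species(2e-4, 0.0, gcda_ph58)
        assert st_.free_ligand == 0.0 and st_.pl == 0.0 and st_.pl2 == 0.0
        assert st_.free_protein == 2e-4

    def test_non_binding_limit(self):
        weak = BindingParams(kd1=1e6, kd2=1e6, dh1=1.0, dh2=1.0)
        st_ = solve_species(2e-4, 4e-4, weak)
        assert st_.pl < 1e-12 and st_.pl2 < 1e-12

    def test_against_grid_bisection_oracle(self, gca_ph58):
        expected = grid_bisect_free_ligand(2e-4, 4e-4, gca_ph58.kd1, gca_ph58.kd2)
        got = solve_species(2e-4, 4e-4, gca_ph58).free_ligand
        assert got == pytest.approx(expected, rel=1e-9)

    def test_mass_balances_random(self, rng):
        """Both conservation laws hold to 1e-9 relative over random inputs."""
        n = 10**4
        p = 10 ** rng.uniform(-7, -2, n)
        lt = 10 ** rng.uniform(-7, -2, n)
        kd1 = 10 ** rng.uniform(-7, -2, n)
        kd2 = 10 ** rng.uniform(-7, -2, n)
        for i in range(0, n, 500):
            params = BindingParams(kd1=kd1[i], kd2=kd2[i], dh1=0.0, dh2=0.0)
            for j in (i, i + 137):
                s = solve_species(p[j], lt[j], params)
                assert s.free_protein + s.pl + s.pl2 == pytest.approx(p[j], rel=1e-9)
                assert s.free_ligand + s.pl + 2 * s.pl2 == pytest.approx(lt[j], rel=1e-9)

    def test_matches_oracle_random(self, rng):
        for _ in range(25):
            p, lt, kd1, kd2 = 10 ** rng.uniform(-6, -3, 4)
            params = BindingParams(kd1=kd1, kd2=kd2, dh1=0.0, dh2=0.0)
            expected = grid_bisect_free_ligand(p, lt, kd1, kd2, n_grid=10**5)
            assert solve_species(p, lt, params).free_ligand == pytest.approx(
                expected, rel=1e-8, abs=1e-18)


class TestSimulateIsotherm:
    def test_athermal_binding_returns_dilution_heat(self, protocol):
        params = BindingParams(kd1=1e-5, kd2=1e-5, dh1=0.0, dh2=0.0)
        iso = simulate_isotherm(params, protocol, dilution_heat=-0.25)
        assert np.allclose(iso.heats, -0.25)

    def test_saturation_tail_approaches_dilution(self, protocol, gcda_ph58):
        iso = simulate_isotherm(gcda_ph58, protocol, dilution_heat=0.1)
        p_tot, l_tot = protocol.totals()
        tail = np.abs(iso.heats[l_tot / p_tot > 2.5] - 0.1)
        assert np.all(np.diff(tail) < 0)
        assert tail[-1] < tail[0] / 10

    def test_finite_difference_oracle(self, protocol, gca_ph58):
        """Per-injection heats match an independent reconstruction of the
        cumulative heat content at every injection."""
        iso = simulate_isotherm(gca_ph58, protocol)
        p_tot, l_tot = protocol.totals()
        v0 = protocol.cell_volume
        q_cum = []
        for p, l in zip(p_tot, l_tot):
            s = solve_species(p, l, gca_ph58)
            q_cum.append(v0 * (gca_ph58.dh1 * s.pl + (gca_ph58.dh1 + gca_ph58.dh2) * s.pl2))
        q_cum = np.array(q_cum)
        dv = np.asarray(protocol.injection_volumes)
        q_prev = np.concatenate([[0.0], q_cum[:-1]])
        expected = (q_cum - q_prev + dv / v0 * 0.5 * (q_cum + q_prev)) / (
            dv * protocol.syringe_ligand_conc)
        assert iso.heats == pytest.approx(expected, rel=1e-8)

    def test_energy_bookkeeping_conservation(self, protocol, gcda_ph58):
        """Total injected heat equals the final cell heat content plus the
        displaced-volume correction terms."""
        iso = simulate_isotherm(gcda_ph58, protocol)
        p_tot, l_tot = protocol.totals()
        v0 = protocol.cell_volume
        q_cum = []
        for p, l in zip(p_tot, l_tot):
            s = solve_species(p, l, gcda_ph58)
            q_cum.append(v0 * (gcda_ph58.dh1 * s.pl + (gcda_ph58.dh1 + gcda_ph58.dh2) * s.pl2))
        q_cum = np.array(q_cum)
        dv = np.asarray(protocol.injection_volumes)
        moles = dv * protocol.syringe_ligand_conc
        q_prev = np.concatenate([[0.0], q_cum[:-1]])
        corrections = np.sum(dv / v0 * 0.5 * (q_cum + q_prev))
        assert np.sum(iso.heats * moles) == pytest.approx(
            q_cum[-1] + corrections, rel=1e-8)


class TestHillAndEntropy:
    @pytest.mark.parametrize("key", sorted(HILL_COEFFICIENTS))
    def test_printed_hill_coefficients(self, key):
        p = BINDING_PARAMS[key]
        assert hill_coefficient(p.kd1, p.kd2) == pytest.approx(
            HILL_COEFFICIENTS[key], abs=0.005)

    def test_equal_kds_give_unity(self):
        assert hill_coefficient(3e-5, 3e-5) == 1.0

    def test_limits_and_monotonicity(self):
        assert hill_coefficient(1e-4, 1e-12) == pytest.approx(2.0, abs=1e-3)
        ratios = np.logspace(-4, 2, 30)
        vals = [hill_coefficient(1.0, r) for r in ratios]
        assert np.all(np.diff(vals) < 0)

    @given(st.floats(1e-8, 1e-2), st.floats(1e-8, 1e-2))
    @settings(max_examples=50, derandomize=True)
    def test_hill_in_open_interval(self, kd1, kd2):
        assert 0.0 < hill_coefficient(kd1, kd2) < 2.0

    @pytest.mark.parametrize("key", sorted(ENTROPIES_TDS))
    def test_printed_stepwise_entropies(self, key):
        p = BINDING_PARAMS[key]
        tds1 = stepwise_entropy(p.dh1, p.kd1, 298.15)
        tds2 = stepwise_entropy(p.dh2, p.kd2, 298.15)
        assert tds1 == pytest.approx(ENTROPIES_TDS[key][0], abs=0.05)
        assert tds2 == pytest.approx(ENTROPIES_TDS[key][1], abs=0.05)

    def test_isoentropic_construction(self):
        kd = 5e-6
        dh = itc.R_KCAL * 298.15 * math.log(kd)
        assert stepwise_entropy(dh, kd, 298.15) == 0.0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            hill_coefficient(-1.0, 1.0)
        with pytest.raises(ValueError):
            stepwise_entropy(1.0, 0.0)


class TestLeastSquaresFit:
    def test_noiseless_recovery_from_perturbed_init(self, protocol, gcda_ph58):
        iso = simulate_isotherm(gcda_ph58, protocol)
        init = BindingParams(kd1=gcda_ph58.kd1 * 2, kd2=gcda_ph58.kd2 * 2,
                             dh1=gcda_ph58.dh1 * 2, dh2=gcda_ph58.dh2 * 2)
        res = ITCModel(iso, protocol).fit(init=init)
        for name in ("kd1", "kd2", "dh1", "dh2"):
            assert getattr(res.params, name) == pytest.approx(
                getattr(gcda_ph58, name), rel=1e-3)

    def test_flat_isotherm_flags_kd_unidentifiable(self, protocol):
        iso = itc.Isotherm(heats=np.zeros(protocol.n_injections),
                           cumulative_volumes=protocol.cumulative_volumes)
        res = ITCModel(iso, protocol).fit(
            init=BindingParams(kd1=1e-5, kd2=1e-5, dh1=0.0, dh2=0.0))
        assert abs(res.params.dh1) < 1e-6 and abs(res.params.dh2) < 1e-6
        assert res.kd_unidentifiable

    def test_hill_recovery_under_noise(self, protocol, gcda_ph58):
        """Median recovered cooperativity stays within 0.05 of the truth."""
        hills = []
        for seed in range(20):
            iso, _ = generate_itc(gcda_ph58, protocol,
                                  NoiseSpec("relative-gaussian", 0.01), seed=seed)
            res = ITCModel(iso, protocol).fit()
            hills.append(res.hill)
        assert np.median(hills) == pytest.approx(1.31, abs=0.05)


class TestBayesFit:
    def test_posterior_recovers_truth_within_two_sd(self, protocol, gcda_ph58):
        iso, _ = generate_itc(gcda_ph58, protocol,
                              NoiseSpec("relative-gaussian", 0.01), seed=42)
        post = ITCModel(iso, protocol).fit_bayes(n_samples=6000, burn_in=1200, seed=7)
        m, s = post.posterior_mean(), post.posterior_sd()
        for name in ("kd1", "kd2", "dh2"):
            assert abs(m[name] - getattr(gcda_ph58, name)) < 2.5 * s[name]
        assert post.retained_draws == 4800
        assert np.all(post.samples[:, :2] > 0)

    def test_chain_reproducibility_across_seeds(self, protocol, gcda_ph58):
        iso, _ = generate_itc(gcda_ph58, protocol,
                              NoiseSpec("relative-gaussian", 0.01), seed=42)
        model = ITCModel(iso, protocol)
        a = model.fit_bayes(n_samples=6000, burn_in=1200, seed=1)
        b = model.fit_bayes(n_samples=6000, burn_in=1200, seed=2)
        ma, sa = a.posterior_mean(), a.posterior_sd()
        mb = b.posterior_mean()
        for name in ("kd1", "kd2", "dh1", "dh2"):
            assert abs(ma[name] - mb[name]) < 0.5 * sa[name]

    def test_same_seed_is_deterministic(self, protocol, gcda_ph58):
        iso, _ = generate_itc(gcda_ph58, protocol,
                              NoiseSpec("relative-gaussian", 0.01), seed=42)
        model = ITCModel(iso, protocol)
        a = model.fit_bayes(n_samples=3000, burn_in=600, seed=5)
        b = model.fit_bayes(n_samples=3000, burn_in=600, seed=5)
        assert np.array_equal(a.samples, b.samples)

    def test_flat_isotherm_enthalpies_concentrate_near_zero(self, protocol):
        iso = itc.Isotherm(heats=np.zeros(protocol.n_injections),
                           cumulative_volumes=protocol.cumulative_volumes)
        post = ITCModel(iso, protocol).fit_bayes(n_samples=3000, burn_in=600, seed=3)
        m, s = post.posterior_mean(), post.posterior_sd()
        assert abs(m["dh1"]) < 0.05 and abs(m["dh2"]) < 0.05
        # with no signal the kd marginal is prior-dominated: an order of
        # magnitude more spread than an informative fit (~0.04 ln units)
        ln_kd1 = np.log(post.samples[:, 0])
        assert ln_kd1.std() > 0.3

    def test_ls_and_bayes_agree_on_low_noise_data(self, protocol, gcda_ph58):
        iso, _ = generate_itc(gcda_ph58, protocol,
                              NoiseSpec("relative-gaussian", 0.002), seed=9)
        model = ITCModel(iso, protocol)
        ls = model.fit()
        post = model.fit_bayes(n_samples=6000, burn_in=1200, seed=10)
        m, s = post.posterior_mean(), post.posterior_sd()
        for name in ("kd1", "kd2", "dh1", "dh2"):
            assert abs(m[name] - getattr(ls.params, name)) < max(
                1.0 * s[name], 1e-12)
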