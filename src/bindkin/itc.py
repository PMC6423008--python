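"""Two-site cooperative binding thermodynamics from isothermal titration calorimetry.

The model is the stepwise (macroscopic) binding scheme

    P + L  <->  PL    (K_d1, dH1)
    PL + L <->  PL2   (K_d2, dH2)

with observed dissociation constants ``kd1 = [P][L]/[PL]`` and
``kd2 = [PL][L]/[PL2]``.  Positive cooperativity corresponds to
``kd2 < kd1/4`` (statistical factor) and is summarized by the Hill
coefficient ``nH = 2/(1 + sqrt(kd2/kd1))``.

:class:`ITCModel` fits an injection-heat isotherm either by nonlinear
least squares (:meth:`ITCModel.fit`) or by ensemble MCMC sampling of the
posterior (:meth:`ITCModel.fit_bayes`), the latter initialized from the
former.  The heat of dilution is modelled as a constant nuisance offset
rather than being subtracted beforehand.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "R_KCAL",
    "BindingParams",
    "ITCProtocol",
    "Isotherm",
    "SpeciesState",
    "solve_species",
    "simulate_isotherm",
    "hill_coefficient",
    "stepwise_entropy",
    "ITCModel",
    "ITCResults",
    "ITCPosteriorResults",
    "default_protocol",
]

#: Gas constant in kcal mol^-1 K^-1 (1 M standard state).
R_KCAL = 1.9872e-3


@dataclass(frozen=True)
class BindingParams:
    """Stepwise binding parameters.

    Parameters
    ----------
    kd1, kd2 : float
        Macroscopic dissociation constants of the first and second
        binding step, in molar.
    dh1, dh2 : float
        Stepwise binding enthalpies, kcal/mol.
    """

    kd1: float
    kd2: float
    dh1: float
    dh2: float

    def __post_init__(self):
        if not (self.kd1 > 0 and self.kd2 > 0):
            raise ValueError("dissociation constants must be positive")
        if not (math.isfinite(self.dh1) and math.isfinite(self.dh2)):
            raise ValueError("enthalpies must be finite")

    @property
    def k1(self) -> float:
        """Association constant of step 1 (M^-1)."""
        return 1.0 / self.kd1

    @property
    def k2(self) -> float:
        """Association constant of step 2 (M^-1)."""
        return 1.0 / self.kd2

    @property
    def hill(self) -> float:
        return hill_coefficient(self.kd1, self.kd2)


@dataclass(frozen=True)
class ITCProtocol:
    """Injection protocol of a titration experiment.

    Volumes in liters, concentrations in molar, temperature in kelvin.
    ``injection_volumes`` is the ordered list of syringe injections.
    """

    cell_volume: float
    cell_protein_conc: float
    syringe_ligand_conc: float
    injection_volumes: tuple
    temperature: float = 298.15

    def __post_init__(self):
        if self.cell_volume <= 0:
            raise ValueError("cell volume must be positive")
        if self.cell_protein_conc <= 0 or self.syringe_ligand_conc <= 0:
            raise ValueError("concentrations must be positive")
        vols = tuple(float(v) for v in self.injection_volumes)
        if len(vols) == 0:
            raise ValueError("injection list must be non-empty")
        if any(v <= 0 for v in vols):
            raise ValueError("all injection volumes must be positive")
        object.__setattr__(self, "injection_volumes", vols)

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes)

    @property
    def cumulative_volumes(self) -> np.ndarray:
        return np.cumsum(self.injection_volumes)

    def totals(self):
        """Cell protein and ligand totals after each injection.

        Uses the perfusion-cell (overflow) convention: after cumulative
        injected volume ``v``,

            P_tot = P0 (1 - v/2V0) / (1 + v/2V0)
            L_tot = L_syr (v/V0) / (1 + v/2V0)
        """
        v = self.cumulative_volumes
        v0 = self.cell_volume
        d = 1.0 + v / (2.0 * v0)
        p_tot = self.cell_protein_conc * (1.0 - v / (2.0 * v0)) / d
        l_tot = self.syringe_ligand_conc * (v / v0) / d
        return p_tot, l_tot


def default_protocol() -> ITCProtocol:
    """The bile-salt titration protocol: 8 x 0.4 uL then 37 x 0.8 uL of
    5.1 mM ligand into 0.2019 mL of 0.2 mM protein at 25 C."""
    vols = (0.4e-6,) * 8 + (0.8e-6,) * 37
    return ITCProtocol(
        cell_volume=0.2019e-3,
        cell_protein_conc=0.2e-3,
        syringe_ligand_conc=5.1e-3,
        injection_volumes=vols,
        temperature=298.15,
    )


@dataclass
class Isotherm:
    """Normalized per-injection heats (kcal per mole of injectant)."""

    heats: np.ndarray
    cumulative_volumes: np.ndarray
    errors: np.ndarray | None = None

    def __post_init__(self):
        self.heats = np.asarray(self.heats, dtype=float)
        self.cumulative_volumes = np.asarray(self.cumulative_volumes, dtype=float)
        if self.heats.shape != self.cumulative_volumes.shape:
            raise ValueError("heats and volumes must have equal length")
        if self.errors is not None:
            self.errors = np.asarray(self.errors, dtype=float)

    def __len__(self):
        return len(self.heats)


@dataclass(frozen=True)
class SpeciesState:
    """Equilibrium concentrations (M) of the binding species."""

    free_ligand: float
    free_protein: float
    pl: float
    pl2: float


def _free_ligand_bisect(p_tot, l_tot, k1, k2, n_bisect=30, n_newton=12):
    """Vectorized bracketed solve for free ligand L on [0, l_tot].

    The mass-balance function
    ``g(L) = L + P (K1 L + 2 K1 K2 L^2)/(1 + K1 L + K1 K2 L^2) - L_tot``
    is strictly increasing in L, so the bracket [0, l_tot] always
    contains the unique non-negative root.  Bisection localizes the
    root, then bracket-clamped Newton steps polish it to better than
    1e-14 relative.
    """
    p_tot = np.asarray(p_tot, dtype=float)
    l_tot = np.asarray(l_tot, dtype=float)
    lo = np.zeros_like(l_tot)
    hi = l_tot.copy()
    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        den = 1.0 + k1 * mid + k1 * k2 * mid * mid
        bound = p_tot * (k1 * mid + 2.0 * k1 * k2 * mid * mid) / den
        too_high = mid + bound > l_tot
        hi = np.where(too_high, mid, hi)
        lo = np.where(too_high, lo, mid)
    x = 0.5 * (lo + hi)
    for _ in range(n_newton):
        num = k1 * x + 2.0 * k1 * k2 * x * x
        den = 1.0 + k1 * x + k1 * k2 * x * x
        g = x + p_tot * num / den - l_tot
        dnum = k1 + 4.0 * k1 * k2 * x
        dden = k1 + 2.0 * k1 * k2 * x
        gp = 1.0 + p_tot * (dnum * den - num * dden) / (den * den)
        step = g / gp
        x = np.clip(x - step, lo, hi)
    return x


def solve_species(p_tot: float, l_tot: float, params: BindingParams) -> SpeciesState:
    """Solve the mass-action equilibrium of the two-step scheme.

    Returns the unique non-negative root of the free-ligand equation and
    the implied species concentrations.  Both mass balances hold to
    better than 1e-10 relative.
    """
    if p_tot < 0 or l_tot < 0:
        raise ValueError("totals must be non-negative")
    if l_tot == 0.0:
        return SpeciesState(0.0, p_tot, 0.0, 0.0)
    k1, k2 = params.k1, params.k2
    l_free = float(_free_ligand_bisect(np.array([p_tot]), np.array([l_tot]), k1, k2)[0])
    den = 1.0 + k1 * l_free + k1 * k2 * l_free**2
    free_protein = p_tot / den
    pl = free_protein * k1 * l_free
    pl2 = free_protein * k1 * k2 * l_free**2
    return SpeciesState(l_free, free_protein, pl, pl2)


def _complex_concs(p_tot, l_tot, kd1, kd2):
    """Vectorized [PL] and [PL2] for arrays of totals."""
    k1, k2 = 1.0 / kd1, 1.0 / kd2
    l_free = _free_ligand_bisect(p_tot, l_tot, k1, k2)
    den = 1.0 + k1 * l_free + k1 * k2 * l_free * l_free
    p_free = p_tot / den
    pl = p_free * k1 * l_free
    pl2 = p_free * k1 * k2 * l_free * l_free
    return pl, pl2


def simulate_isotherm(
    params: BindingParams, protocol: ITCProtocol, dilution_heat: float = 0.0
) -> Isotherm:
    """Simulate normalized injection heats for the two-step model.

    The total cell heat content after injection i is
    ``Q_i = V0 (dH1 [PL]_i + (dH1+dH2) [PL2]_i)``; the observed heat of
    injection i corrects for the displaced volume,

        q_i = Q_i - Q_{i-1} + (dV_i/V0) (Q_i + Q_{i-1})/2,

    and is normalized by the moles of ligand injected, plus a constant
    dilution heat (kcal per mole of injectant).
    """
    p_tot, l_tot = protocol.totals()
    pl, pl2 = _complex_concs(p_tot, l_tot, params.kd1, params.kd2)
    v0 = protocol.cell_volume
    q_cum = v0 * (params.dh1 * pl + (params.dh1 + params.dh2) * pl2)
    dv = np.asarray(protocol.injection_volumes)
    q_prev = np.concatenate([[0.0], q_cum[:-1]])
    q_inj = q_cum - q_prev + (dv / v0) * 0.5 * (q_cum + q_prev)
    moles = dv * protocol.syringe_ligand_conc
    heats = q_inj / moles + dilution_heat
    return Isotherm(heats=heats, cumulative_volumes=protocol.cumulative_volumes)


def hill_coefficient(kd1: float, kd2: float) -> float:
    """Hill coefficient of a two-site system, nH = 2/(1 + sqrt(kd2/kd1)).

    Lies in (0, 2); equals 1 for kd2 = kd1 and approaches 2 at maximal
    positive cooperativity (kd2 << kd1).
    """
    if kd1 <= 0 or kd2 <= 0:
        raise ValueError("dissociation constants must be positive")
    return 2.0 / (1.0 + math.sqrt(kd2 / kd1))


def stepwise_entropy(dh: float, kd: float, temperature: float = 298.15) -> float:
    """T*dS (kcal/mol) of a binding step from dH and Kd.

    Uses dG = RT ln Kd (1 M standard state) and TdS = dH - dG.
    """
    if kd <= 0:
        raise ValueError("kd must be positive")
    return dh - R_KCAL * temperature * math.log(kd)


# ---------------------------------------------------------------------------
# fitting


def _heats_model(theta, p_tot, l_tot, dv, v0, moles):
    ln_kd1, ln_kd2, dh1, dh2, q_dil = theta
    pl, pl2 = _complex_concs(p_tot, l_tot, math.exp(ln_kd1), math.exp(ln_kd2))
    q_cum = v0 * (dh1 * pl + (dh1 + dh2) * pl2)
    q_prev = np.concatenate([[0.0], q_cum[:-1]])
    q_inj = q_cum - q_prev + (dv / v0) * 0.5 * (q_cum + q_prev)
    return q_inj / moles + q_dil


class ITCModel:
    """Two-site sequential binding model for an injection-heat isotherm.

    Parameters
    ----------
    isotherm : Isotherm
        Normalized per-injection heats; length must match the protocol.
    protocol : ITCProtocol
    exclude_first : bool, optional
        Drop the first injection from the fit (a common instrument
        artifact); off by default.
    """

    # prior bounds shared by the least-squares parameterization and the
    # Bayesian sampler: log-uniform Kd over [1e-9, 1e-1] M, uniform
    # enthalpies over [-50, 50] kcal/mol, Jeffreys prior on the noise scale.
    LN_KD_LO, LN_KD_HI = math.log(1e-9), math.log(1e-1)
    DH_LO, DH_HI = -50.0, 50.0
    QDIL_LO, QDIL_HI = -10.0, 10.0
    # noise floor: heats are O(1) kcal/mol, so 6e-6 kcal/mol is far below
    # any instrument precision; keeps the sigma posterior proper on
    # degenerate (noise-free) inputs
    LN_SIGMA_LO, LN_SIGMA_HI = -12.0, 5.0

    def __init__(self, isotherm: Isotherm, protocol: ITCProtocol, exclude_first: bool = False):
        if len(isotherm) != protocol.n_injections:
            raise ValueError(
                f"isotherm has {len(isotherm)} heats but protocol defines "
                f"{protocol.n_injections} injections"
            )
        self.isotherm = isotherm
        self.protocol = protocol
        self.exclude_first = exclude_first
        p_tot, l_tot = protocol.totals()
        self._p_tot, self._l_tot = p_tot, l_tot
        self._dv = np.asarray(protocol.injection_volumes)
        self._moles = self._dv * protocol.syringe_ligand_conc
        self._mask = np.ones(protocol.n_injections, dtype=bool)
        if exclude_first:
            self._mask[0] = False

    def predict(self, params: BindingParams, dilution_heat: float = 0.0) -> np.ndarray:
        theta = (
            math.log(params.kd1),
            math.log(params.kd2),
            params.dh1,
            params.dh2,
            dilution_heat,
        )
        return _heats_model(theta, self._p_tot, self._l_tot, self._dv,
                            self.protocol.cell_volume, self._moles)

    def _residuals(self, theta):
        model = _heats_model(theta, self._p_tot, self._l_tot, self._dv,
                             self.protocol.cell_volume, self._moles)
        return (model - self.isotherm.heats)[self._mask]

    def _default_init(self) -> BindingParams:
        heats = self.isotherm.heats
        scale = float(np.max(np.abs(heats))) if np.any(heats != 0) else 1.0
        dh = -scale if np.mean(heats[: max(3, len(heats) // 4)]) < 0 else scale
        kd = self.protocol.cell_protein_conc / 4.0
        return BindingParams(kd1=kd, kd2=kd, dh1=dh, dh2=dh)

    def fit(self, init: BindingParams | None = None, dilution_heat: float = 0.0) -> "ITCResults":
        """Nonlinear least squares in (ln kd1, ln kd2, dh1, dh2, q_dil)."""
        from scipy.optimize import least_squares

        if init is None:
            init = self._default_init()
        x0 = np.array([
            math.log(init.kd1), math.log(init.kd2), init.dh1, init.dh2, dilution_heat,
        ])
        lb = [self.LN_KD_LO, self.LN_KD_LO, self.DH_LO, self.DH_LO, self.QDIL_LO]
        ub = [self.LN_KD_HI, self.LN_KD_HI, self.DH_HI, self.DH_HI, self.QDIL_HI]
        x0 = np.clip(x0, lb, ub)
        sol = least_squares(
            self._residuals, x0, bounds=(lb, ub),
            xtol=1e-15, ftol=1e-15, gtol=1e-15, method="trf",
        )
        if not sol.success:
            raise RuntimeError(
                f"least-squares fit did not converge (status {sol.status}); "
                f"last iterate {sol.x}"
            )
        theta = sol.x
        params = BindingParams(
            kd1=math.exp(theta[0]), kd2=math.exp(theta[1]), dh1=theta[2], dh2=theta[3]
        )
        n, k = sol.fun.size, theta.size
        rss = float(sol.fun @ sol.fun)
        sigma2 = rss / max(n - k, 1)
        jtj = sol.jac.T @ sol.jac
        try:
            cov = sigma2 * np.linalg.pinv(jtj)
            stderr = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:  # pragma: no cover
            cov = np.full((k, k), np.nan)
            stderr = np.full(k, np.nan)
        # the heats carry no information on Kd when the signal is flat
        scale = float(np.max(np.abs(self.isotherm.heats[self._mask]), initial=0.0))
        kd_unidentifiable = (
            scale < 1e-12
            or max(abs(theta[2]), abs(theta[2] + theta[3])) < 10 * math.sqrt(sigma2)
            or stderr[0] > 5.0
            or stderr[1] > 5.0
        )
        return ITCResults(
            model=self, params=params, dilution_heat=float(theta[4]),
            stderr_log=stderr, cov_log=cov, rss=rss,
            kd_unidentifiable=bool(kd_unidentifiable),
        )

    # -- Bayesian sampling ---------------------------------------------------

    def _log_posterior(self, theta):
        """Vectorized log posterior; ``theta`` has shape (n_walkers, 6)."""
        theta = np.atleast_2d(theta)
        lb = np.array([self.LN_KD_LO, self.LN_KD_LO, self.DH_LO, self.DH_LO,
                       self.QDIL_LO, self.LN_SIGMA_LO])
        ub = np.array([self.LN_KD_HI, self.LN_KD_HI, self.DH_HI, self.DH_HI,
                       self.QDIL_HI, self.LN_SIGMA_HI])
        ok = np.all((theta >= lb) & (theta <= ub), axis=1)
        out = np.full(theta.shape[0], -np.inf)
        if not np.any(ok):
            return out
        th = theta[ok]
        kd1 = np.exp(th[:, 0])[:, None]
        kd2 = np.exp(th[:, 1])[:, None]
        pl, pl2 = _complex_concs(self._p_tot[None, :], self._l_tot[None, :], kd1, kd2)
        v0 = self.protocol.cell_volume
        q_cum = v0 * (th[:, 2, None] * pl + (th[:, 2, None] + th[:, 3, None]) * pl2)
        q_prev = np.concatenate([np.zeros((q_cum.shape[0], 1)), q_cum[:, :-1]], axis=1)
        model = (q_cum - q_prev + (self._dv / v0) * 0.5 * (q_cum + q_prev)) / self._moles
        res = (model + th[:, 4, None] - self.isotherm.heats)[:, self._mask]
        n = res.shape[1]
        ln_sigma = th[:, 5]
        sigma2 = np.exp(2.0 * ln_sigma)
        # Gaussian likelihood + Jeffreys p(sigma) ~ 1/sigma (flat in ln sigma)
        out[ok] = -0.5 * np.einsum("ij,ij->i", res, res) / sigma2 - n * ln_sigma
        return out

    def fit_bayes(
        self,
        n_samples: int = 10000,
        burn_in: int = 1000,
        seed: int | None = None,
        n_walkers: int = 20,
        init: BindingParams | None = None,
    ) -> "ITCPosteriorResults":
        """Ensemble MCMC posterior sampling of the binding parameters.

        ``n_samples`` is the total number of posterior draws across the
        ensemble; the first ``burn_in`` draws are discarded, so the
        defaults retain 9000 points.  Walkers start in a tight ball
        around the least-squares optimum.
        """
        import emcee

        if n_samples <= burn_in:
            raise ValueError("n_samples must exceed burn_in")
        ls = self.fit(init=init)
        center = np.array([
            math.log(ls.params.kd1), math.log(ls.params.kd2),
            ls.params.dh1, ls.params.dh2, ls.dilution_heat,
            math.log(max(math.sqrt(ls.rss / max(len(self.isotherm) - 5, 1)), 1e-5)),
        ])
        lb = np.array([self.LN_KD_LO, self.LN_KD_LO, self.DH_LO, self.DH_LO, self.QDIL_LO, self.LN_SIGMA_LO])
        ub = np.array([self.LN_KD_HI, self.LN_KD_HI, self.DH_HI, self.DH_HI, self.QDIL_HI, self.LN_SIGMA_HI])
        rng = np.random.default_rng(seed)
        ndim = 6
        p0 = center + 1e-3 * rng.standard_normal((n_walkers, ndim)) * np.maximum(np.abs(center), 0.1)
        p0 = np.clip(p0, lb + 1e-9, ub - 1e-9)
        n_steps = -(-(n_samples) // n_walkers)  # ceil
        sampler = emcee.EnsembleSampler(n_walkers, ndim, self._log_posterior, vectorize=True)
        sampler.random_state = np.random.RandomState(
            rng.integers(0, 2**31 - 1)
        ).get_state()
        sampler.run_mcmc(p0, n_steps, progress=False)
        chain = sampler.get_chain()  # (steps, walkers, dim)
        flat = chain.reshape(-1, ndim)[:n_samples]
        retained = flat[burn_in:]
        acc = float(np.mean(sampler.acceptance_fraction))
        warnings_list = []
        if not (0.05 <= acc <= 0.95):
            warnings_list.append(f"acceptance rate {acc:.3f} outside [0.05, 0.95]")
            warnings.warn(warnings_list[-1])
        # split-chain convergence check on each retained marginal
        half = retained.shape[0] // 2
        split_ratio = np.ones(ndim)
        if half > 10:
            a, b = retained[:half], retained[half:2 * half]
            w = 0.5 * (a.var(axis=0, ddof=1) + b.var(axis=0, ddof=1))
            bvar = half * (a.mean(axis=0) - b.mean(axis=0)) ** 2 / 2.0
            var_hat = (half - 1) / half * w + bvar / half
            with np.errstate(divide="ignore", invalid="ignore"):
                split_ratio = np.sqrt(np.where(w > 0, var_hat / w, 1.0))
        samples = retained.copy()
        samples[:, 0] = np.exp(samples[:, 0])  # kd1
        samples[:, 1] = np.exp(samples[:, 1])  # kd2
        samples[:, 5] = np.exp(samples[:, 5])  # noise scale
        return ITCPosteriorResults(
            model=self,
            samples=samples,
            total_draws=n_samples,
            retained_draws=retained.shape[0],
            seed=seed,
            acceptance_fraction=acc,
            split_chain_ratio=split_ratio,
            ls_results=ls,
            warnings=tuple(warnings_list),
        )


_PARAM_NAMES = ("kd1", "kd2", "dh1", "dh2", "dilution_heat", "noise_scale")


@dataclass
class ITCResults:
    """Least-squares fit of the two-site model."""

    model: ITCModel
    params: BindingParams
    dilution_heat: float
    stderr_log: np.ndarray  # on (ln kd1, ln kd2, dh1, dh2, q_dil)
    cov_log: np.ndarray
    rss: float
    kd_unidentifiable: bool

    @property
    def hill(self) -> float:
        return hill_coefficient(self.params.kd1, self.params.kd2)

    def entropies(self) -> tuple:
        t = self.model.protocol.temperature
        return (
            stepwise_entropy(self.params.dh1, self.params.kd1, t),
            stepwise_entropy(self.params.dh2, self.params.kd2, t),
        )

    def summary(self) -> pd.DataFrame:
        tds1, tds2 = self.entropies()
        p = self.params
        rows = [
            ("kd1_M", p.kd1, p.kd1 * self.stderr_log[0]),
            ("kd2_M", p.kd2, p.kd2 * self.stderr_log[1]),
            ("dh1_kcal_per_mol", p.dh1, self.stderr_log[2]),
            ("dh2_kcal_per_mol", p.dh2, self.stderr_log[3]),
            ("dilution_heat_kcal_per_mol", self.dilution_heat, self.stderr_log[4]),
            ("nH", self.hill, np.nan),
            ("tds1_kcal_per_mol", tds1, np.nan),
            ("tds2_kcal_per_mol", tds2, np.nan),
        ]
        return pd.DataFrame(rows, columns=["parameter", "estimate", "stderr"])


@dataclass
class ITCPosteriorResults:
    """Posterior samples over (kd1, kd2, dh1, dh2, dilution heat, noise scale)."""

    model: ITCModel
    samples: np.ndarray
    total_draws: int
    retained_draws: int
    seed: int | None
    acceptance_fraction: float
    split_chain_ratio: np.ndarray
    ls_results: ITCResults
    warnings: tuple = field(default_factory=tuple)
    #: an enthalpy is flagged 'wide' when its posterior SD exceeds this
    #: multiple of the inferred per-injection noise scale: the data then
    #: constrain it only weakly (the hallmark of dH1 in a highly
    #: cooperative system, where PL is barely populated)
    WIDE_DH_NOISE_MULT: float = 5.0
    #: a Kd is flagged 'wide' above this relative posterior SD
    WIDE_KD_RSD: float = 0.5

    def posterior_mean(self) -> dict:
        return dict(zip(_PARAM_NAMES, self.samples.mean(axis=0)))

    def posterior_sd(self) -> dict:
        return dict(zip(_PARAM_NAMES, self.samples.std(axis=0, ddof=1)))

    @property
    def params(self) -> BindingParams:
        m = self.posterior_mean()
        return BindingParams(kd1=m["kd1"], kd2=m["kd2"], dh1=m["dh1"], dh2=m["dh2"])

    @property
    def wide_parameters(self) -> list:
        """Parameters whose posterior is too broad for a point estimate."""
        m, s = self.posterior_mean(), self.posterior_sd()
        out = []
        for name in ("kd1", "kd2"):
            if s[name] > self.WIDE_KD_RSD * abs(m[name]):
                out.append(name)
        noise = m["noise_scale"]
        for name in ("dh1", "dh2"):
            if s[name] > self.WIDE_DH_NOISE_MULT * noise:
                out.append(name)
        return out

    def kd_scatter(self) -> pd.DataFrame:
        """Retained (kd1, kd2) draws, the posterior scatter-plot table."""
        return pd.DataFrame({"kd1_M": self.samples[:, 0], "kd2_M": self.samples[:, 1]})

    @property
    def hill(self) -> float:
        m = self.posterior_mean()
        return hill_coefficient(m["kd1"], m["kd2"])

    def summary(self) -> pd.DataFrame:
        m, s = self.posterior_mean(), self.posterior_sd()
        rows = [(k, m[k], s[k], k in self.wide_parameters) for k in _PARAM_NAMES]
        df = pd.DataFrame(rows, columns=["parameter", "post_mean", "post_sd", "wide"])
        t = self.model.protocol.temperature
        extra = pd.DataFrame(
            [
                ("nH", self.hill, np.nan, False),
                ("tds1_kcal_per_mol", stepwise_entropy(m["dh1"], m["kd1"], t), np.nan, False),
                ("tds2_kcal_per_mol", stepwise_entropy(m["dh2"], m["kd2"], t), np.nan, False),
            ],
            columns=df.columns,
        )
        return pd.concat([df, extra], ignore_index=True)
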