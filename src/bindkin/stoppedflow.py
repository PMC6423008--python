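"""Four-step sequential binding kinetics under pseudo-first-order mixing.

The mechanism couples a pre-binding conformational equilibrium, two
sequential ligand-binding steps and a post-binding conformational change:

    P'  <->  P        (k1 / k_1)
    P + L  <->  PL    (k2 / k_2)
    PL + L <->  PL2   (k3 / k_3)
    PL2 <->  PL2*     (k4 / k_4)

With the ligand in large excess its concentration is constant, the
mass-action equations become linear, and every fluorescence transient is
a sum of exponentials whose rates are the nonzero eigenvalue magnitudes
of the 5x5 rate matrix over the states (P', P, PL, PL2, PL2*).

Units: first-order rate constants in s^-1, second-order constants in
s^-1 uM^-1, concentrations in uM, time in seconds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "KineticScheme",
    "Trace",
    "ObservedRates",
    "DEFAULT_FLUOR_COEFFS",
    "rate_matrix",
    "observed_rates_eigen",
    "simulate_trace",
    "BiexpModel",
    "BiexpResults",
    "MechanismModel",
    "MechanismResults",
]

STATES = ("P'", "P", "PL", "PL2", "PL2*")

#: Per-species fluorescence weights giving quenching-like transients
#: (arbitrary units); the true per-state brightnesses are unknown, and
#: mechanism fitting never uses amplitudes.
DEFAULT_FLUOR_COEFFS = np.array([1.0, 1.0, 0.8, 0.6, 0.5])

_RATE_NAMES = ("k1", "k_1", "k2", "k_2", "k3", "k_3", "k4", "k_4")


@dataclass(frozen=True)
class KineticScheme:
    """Rate constants of the four-step mechanism.

    k1, k_1, k_2, k_3, k4, k_4 are first order (s^-1); k2 and k3 are
    second order (s^-1 uM^-1).
    """

    k1: float
    k_1: float
    k2: float
    k_2: float
    k3: float
    k_3: float
    k4: float
    k_4: float

    def __post_init__(self):
        for name in _RATE_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"rate constant {name} must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in _RATE_NAMES])

    def replace(self, **kw) -> "KineticScheme":
        d = {n: getattr(self, n) for n in _RATE_NAMES}
        d.update(kw)
        return KineticScheme(**d)

    def initial_state(self, p0: float = 1.0) -> np.ndarray:
        """Pre-mixing state: P'/P equilibrated by k1/k_1, no complexes."""
        x0 = np.zeros(5)
        tot = self.k1 + self.k_1
        if tot > 0:
            x0[0] = p0 * self.k_1 / tot
            x0[1] = p0 * self.k1 / tot
        else:
            x0[1] = p0
        return x0


def rate_matrix(scheme: KineticScheme, ligand: float) -> np.ndarray:
    """5x5 rate matrix M with d[x]/dt = M x over (P', P, PL, PL2, PL2*).

    Columns sum to zero (conservation of total protein); off-diagonal
    entries are non-negative.  ``ligand`` (uM) is the constant
    pseudo-first-order ligand concentration.
    """
    if ligand < 0:
        raise ValueError("ligand concentration must be non-negative")
    s = scheme
    m = np.zeros((5, 5))
    m[1, 0] = s.k1
    m[0, 1] = s.k_1
    m[2, 1] = s.k2 * ligand
    m[1, 2] = s.k_2
    m[3, 2] = s.k3 * ligand
    m[2, 3] = s.k_3
    m[4, 3] = s.k4
    m[3, 4] = s.k_4
    np.fill_diagonal(m, -m.sum(axis=0))
    return m


def _eigen_modes(scheme, ligand, fluor_coeffs, p0):
    m = rate_matrix(scheme, ligand)
    lam, vec = np.linalg.eig(m)
    x0 = scheme.initial_state(p0)
    beta = np.linalg.solve(vec, x0.astype(complex))
    c = np.asarray(fluor_coeffs, dtype=float)
    amps = (c @ vec) * beta  # F(t) = sum_j amps_j exp(lam_j t)
    return lam, amps


def observed_rates_eigen(
    scheme: KineticScheme,
    ligand: float,
    fluor_coeffs: np.ndarray = DEFAULT_FLUOR_COEFFS,
    p0: float = 1.0,
    full: bool = False,
):
    """Observed rates (k_app1, k_app2) from the rate-matrix eigenvalues.

    The rate matrix has exactly one zero eigenvalue (the equilibrium
    mode).  Among the nonzero modes, ``k_app2`` is the slowest and
    ``k_app1`` the mode with the largest absolute fluorescence amplitude
    among the remaining ones — the pair a biexponential fit of the
    measured transient detects.  With ``full=True`` also returns all
    nonzero eigenvalue magnitudes and their amplitudes, for diagnostics.
    """
    if ligand <= 0:
        raise ValueError("ligand concentration must be positive")
    lam, amps = _eigen_modes(scheme, ligand, fluor_coeffs, p0)
    mags = np.abs(lam)
    tol = 1e-9 * max(mags.max(), 1.0)
    nz = mags > tol
    mags_nz = mags[nz]
    amps_nz = np.abs(amps[nz])
    if mags_nz.size == 0:
        raise ValueError("scheme has no relaxing mode (all rate constants zero?)")
    order = np.argsort(mags_nz)
    k_app2 = float(mags_nz[order[0]])
    if mags_nz.size == 1:
        k_app1 = k_app2
    else:
        rest = order[1:]
        best = rest[np.argmax(amps_nz[rest])]
        k_app1 = float(mags_nz[best])
        # warn on a near-degenerate amplitude tie between candidate modes
        a_sorted = np.sort(amps_nz[rest])[::-1]
        if a_sorted.size > 1 and a_sorted[1] > 0 and abs(a_sorted[0] - a_sorted[1]) < 1e-9 * a_sorted[0]:
            warnings.warn("degenerate amplitude spectrum; observed-rate assignment is a tie-break")
    if full:
        return k_app1, k_app2, mags_nz[order], amps_nz[order]
    return k_app1, k_app2


@dataclass
class Trace:
    """A stopped-flow fluorescence transient."""

    times: np.ndarray
    fluorescence: np.ndarray
    ligand: float
    protein: float

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.times.size < 50:
            raise ValueError("a trace needs at least 50 points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time points must be strictly increasing")
        if self.times.shape != self.fluorescence.shape:
            raise ValueError("times and fluorescence must match in length")


def default_times(n: int = 8000, t_max: float = 10.0) -> np.ndarray:
    """Linearly spaced acquisition grid over (0, t_max], instrument-style.

    Linear sampling matters for unweighted trace fitting: a log grid
    concentrates points in the early transient and biases multi-mode
    traces toward the fast modes.
    """
    return np.linspace(0.0, t_max, n + 1)[1:]


def simulate_trace(
    scheme: KineticScheme,
    fluor_coeffs: np.ndarray = DEFAULT_FLUOR_COEFFS,
    p0: float = 1.0,
    ligand: float = 100.0,
    times: np.ndarray | None = None,
) -> Trace:
    """Integrate the linear kinetics exactly and project onto fluorescence.

    Propagation uses the eigendecomposition of the constant-ligand rate
    matrix (equivalent to the matrix exponential), starting from the
    equilibrated P'/P mixture with no complexes.
    """
    if times is None:
        times = default_times()
    times = np.asarray(times, dtype=float)
    if p0 > ligand / 10.0:
        warnings.warn(
            f"protein ({p0} uM) exceeds a tenth of the ligand ({ligand} uM); "
            "the pseudo-first-order approximation may be poor"
        )
    lam, amps = _eigen_modes(scheme, ligand, fluor_coeffs, p0)
    f = np.real(np.exp(np.outer(times, lam)) @ amps)
    return Trace(times=times, fluorescence=f, ligand=ligand, protein=p0)


def species_trajectory(scheme: KineticScheme, p0: float, ligand: float, times: np.ndarray) -> np.ndarray:
    """Species concentrations over time, shape (len(times), 5)."""
    m = rate_matrix(scheme, ligand)
    lam, vec = np.linalg.eig(m)
    beta = np.linalg.solve(vec, scheme.initial_state(p0).astype(complex))
    return np.real((np.exp(np.outer(times, lam)) * beta) @ vec.T)


# ---------------------------------------------------------------------------
# biexponential trace fitting


@dataclass
class BiexpResults:
    """Exponential fit F(t) = f_inf + sum_i A_i exp(-zeta_i t)."""

    f_inf: float
    amplitudes: np.ndarray
    rates: np.ndarray  # ordered zeta_1 >= zeta_2 > 0
    residual_norm: float
    single_exponential: bool


class BiexpModel:
    """Least-squares exponential fit of a fluorescence transient.

    The amplitudes and offset enter linearly, so the fit is performed by
    variable projection: only the (log) rates are optimized nonlinearly,
    with the linear coefficients solved exactly at each iterate.
    Multi-start over decade-spaced rate pairs guards against local
    minima.
    """

    def __init__(self, trace: Trace):
        self.trace = trace

    def _varpro_residual(self, log_rates, t, y):
        rates = np.exp(np.clip(log_rates, -20.0, 25.0))
        phi = np.column_stack(
            [np.ones_like(t)] + [np.exp(-np.minimum(r * t, 700.0)) for r in rates]
        )
        coef, *_ = np.linalg.lstsq(phi, y, rcond=None)
        return phi @ coef - y, coef

    def fit(self, n_exp: int = 2, t_min: float = 0.0) -> BiexpResults:
        """Fit with ``n_exp`` (1 or 2) exponentials to times >= ``t_min``."""
        if n_exp not in (1, 2):
            raise ValueError("n_exp must be 1 or 2")
        t = self.trace.times
        y = self.trace.fluorescence
        keep = t >= t_min
        t, y = t[keep], y[keep]
        lo, hi = max(0.1 / t[-1], 1e-6), 2.0 / max(t[0], 1e-12)
        decades = np.arange(math.floor(math.log10(lo)), math.ceil(math.log10(hi)) + 1)
        cands = 10.0 ** decades
        if n_exp == 1:
            starts = [(r,) for r in cands]
        else:
            starts = [(r1, r2) for i, r1 in enumerate(cands) for r2 in cands[:i]]
        best = None
        for start in starts:
            x0 = np.log(np.asarray(start, dtype=float))
            sol = least_squares(
                lambda x: self._varpro_residual(x, t, y)[0], x0,
                xtol=1e-15, ftol=1e-15, gtol=1e-15, method="lm",
            )
            if best is None or sol.cost < best.cost:
                best = sol
        res, coef = self._varpro_residual(best.x, t, y)
        rates = np.exp(np.clip(best.x, -20.0, 25.0))
        amps = coef[1:]
        order = np.argsort(rates)[::-1]
        rates, amps = rates[order], amps[order]
        single = False
        if n_exp == 2:
            a_scale = max(np.max(np.abs(amps)), 1e-300)
            if np.min(np.abs(amps)) < 1e-6 * a_scale or abs(rates[0] - rates[1]) < 1e-6 * rates[0]:
                single = True
        return BiexpResults(
            f_inf=float(coef[0]),
            amplitudes=amps,
            rates=rates,
            residual_norm=float(np.linalg.norm(res)),
            single_exponential=single,
        )


# ---------------------------------------------------------------------------
# mechanism fitting


@dataclass
class ObservedRates:
    """Observed rates versus ligand concentration (uM, s^-1)."""

    ligand: np.ndarray
    kapp1: np.ndarray
    kapp2: np.ndarray
    kapp1_err: np.ndarray | None = None
    kapp2_err: np.ndarray | None = None

    def __post_init__(self):
        self.ligand = np.asarray(self.ligand, dtype=float)
        self.kapp1 = np.asarray(self.kapp1, dtype=float)
        self.kapp2 = np.asarray(self.kapp2, dtype=float)
        if np.any(self.ligand <= 0):
            raise ValueError("ligand concentrations must be positive")
        if np.any(self.kapp1 <= 0) or np.any(self.kapp2 <= 0):
            raise ValueError("observed rates must be positive")
        for name in ("kapp1_err", "kapp2_err"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))

    def to_frame(self) -> pd.DataFrame:
        d = {"ligand_uM": self.ligand, "kapp1_s": self.kapp1, "kapp2_s": self.kapp2}
        if self.kapp1_err is not None:
            d["kapp1_err"] = self.kapp1_err
        if self.kapp2_err is not None:
            d["kapp2_err"] = self.kapp2_err
        return pd.DataFrame(d)


@dataclass
class MechanismResults:
    scheme: KineticScheme
    fixed: frozenset
    stderr: dict
    unidentifiable: list
    rss: float
    predicted: ObservedRates

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in _RATE_NAMES:
            rows.append(
                (
                    name,
                    getattr(self.scheme, name),
                    self.stderr.get(name, np.nan),
                    "fixed" if name in self.fixed else "free",
                    name in self.unidentifiable,
                )
            )
        return pd.DataFrame(rows, columns=["rate_constant", "estimate", "stderr", "status", "unidentifiable"])


class MechanismModel:
    """Fit the four-step scheme to observed rates versus ligand concentration.

    Residuals compare both observed-rate branches with the eigenvalue
    predictions across all concentrations.  With per-point uncertainties
    the weighting is inverse-variance; otherwise residuals are relative
    (the two branches differ by ~100x in magnitude).  The conformational
    pre-equilibrium constants (k1, k_1) are typically held fixed, since
    they are much faster than the observable modes and barely influence
    the binding-step constants.
    """

    def __init__(self, observed: ObservedRates):
        if observed.ligand.size < 2:
            raise ValueError("need observed rates at >= 2 ligand concentrations")
        self.observed = observed

    def _predict(self, scheme):
        k1 = np.empty_like(self.observed.ligand)
        k2 = np.empty_like(self.observed.ligand)
        for i, lig in enumerate(self.observed.ligand):
            k1[i], k2[i] = observed_rates_eigen(scheme, lig)
        return k1, k2

    def fit(
        self,
        init: KineticScheme,
        fixed: frozenset | set = frozenset({"k1", "k_1"}),
    ) -> MechanismResults:
        fixed = frozenset(fixed)
        free = [n for n in _RATE_NAMES if n not in fixed]
        if not free:
            raise ValueError("no free parameters")
        obs = self.observed
        if obs.kapp1_err is not None and obs.kapp2_err is not None:
            w1, w2 = 1.0 / obs.kapp1_err, 1.0 / obs.kapp2_err
        else:
            w1, w2 = 1.0 / obs.kapp1, 1.0 / obs.kapp2

        def residuals(x):
            kw = {n: math.exp(v) for n, v in zip(free, x)}
            scheme = init.replace(**kw)
            p1, p2 = self._predict(scheme)
            return np.concatenate([(p1 - obs.kapp1) * w1, (p2 - obs.kapp2) * w2])

        x0 = np.array([math.log(max(getattr(init, n), 1e-6)) for n in free])
        sol = least_squares(residuals, x0, xtol=1e-14, ftol=1e-14, gtol=1e-14, method="lm")
        if not sol.success:
            raise RuntimeError(f"mechanism fit did not converge: {sol.message}; last iterate {sol.x}")
        est = {n: math.exp(v) for n, v in zip(free, sol.x)}
        scheme = init.replace(**est)
        # stderr on log-parameters -> relative stderr on the constants
        n_pts, k = sol.fun.size, len(free)
        sigma2 = float(sol.fun @ sol.fun) / max(n_pts - k, 1)
        cov = sigma2 * np.linalg.pinv(sol.jac.T @ sol.jac)
        rel_err = np.sqrt(np.maximum(np.diag(cov), 0.0))
        stderr = {n: est[n] * re for n, re in zip(free, rel_err)}
        # relative CI width (95%) > 10 means the data do not constrain it
        unident = [n for n, re in zip(free, rel_err) if 2 * 1.96 * re > 10]
        p1, p2 = self._predict(scheme)
        predicted = ObservedRates(ligand=obs.ligand, kapp1=p1, kapp2=p2)
        return MechanismResults(
            scheme=scheme, fixed=fixed, stderr=stderr,
            unidentifiable=unident, rss=float(sol.fun @ sol.fun), predicted=predicted,
        )

    def high_l_slope(self, scheme: KineticScheme, l_lo: float = 300.0, l_hi: float = 500.0) -> float:
        """Slope of the fast observed rate at high ligand (estimates k2)."""
        a1, _ = observed_rates_eigen(scheme, l_lo)
        b1, _ = observed_rates_eigen(scheme, l_hi)
        return (b1 - a1) / (l_hi - l_lo)
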