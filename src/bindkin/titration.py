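"""Henderson-Hasselbalch pKa fitting of NMR pH titrations.

Backbone 15N chemical shifts of residues near a titrating histidine
follow a single-site sigmoid in pH,

    delta_obs(pH) = delta_d + (delta_p - delta_d) / (1 + 10**(pH - pKa)),

where ``delta_p`` and ``delta_d`` are the limiting shifts of the
protonated and deprotonated forms.  :class:`TitrationModel` fits the
three parameters by weighted nonlinear least squares.  The module also
provides the combined amide 1H/15N chemical-shift perturbation
``sqrt(dHN**2 + (w1*dN)**2)`` (w1 = 0.154) and its threshold
classification at mean + 0.5 SD and mean + SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "W1_DEFAULT",
    "TitrationCurve",
    "TitrationResults",
    "ShiftPerturbation",
    "hh_model",
    "TitrationModel",
    "combined_shift",
    "classify_perturbations",
    "APO_PH_GRID",
    "HOLO_PH_GRID",
]

#: 15N weight in the combined amide chemical-shift perturbation.
W1_DEFAULT = 0.154

#: pH sampling points of the ligand-free and ligand-bound titration series.
APO_PH_GRID = (4.7, 5.1, 5.9, 6.4, 7.0, 7.5, 8.0)
HOLO_PH_GRID = (4.6, 5.3, 5.9, 6.5, 7.0, 7.9, 9.1)


def hh_model(ph, pka, delta_p, delta_d):
    """Single-site titration shift at ``ph``; bounded by the two limits."""
    ph = np.asarray(ph, dtype=float)
    out = delta_d + (delta_p - delta_d) / (1.0 + 10.0 ** (ph - pka))
    return out if out.ndim else float(out)


@dataclass
class TitrationCurve:
    """Observed 15N shifts of one residue versus pH."""

    residue: str
    ph: np.ndarray
    shifts: np.ndarray
    errors: np.ndarray | None = None

    def __post_init__(self):
        self.ph = np.asarray(self.ph, dtype=float)
        self.shifts = np.asarray(self.shifts, dtype=float)
        if np.unique(self.ph).size < 4:
            raise ValueError("need at least 4 distinct pH points")
        if np.any((self.ph < 0) | (self.ph > 14)):
            raise ValueError("pH out of [0, 14]")
        if self.errors is not None:
            self.errors = np.asarray(self.errors, dtype=float)


@dataclass
class TitrationResults:
    """Fitted pKa and limiting shifts with local-quadratic uncertainties."""

    residue: str
    pka: float
    delta_p: float
    delta_d: float
    stderr: np.ndarray  # (pka, delta_p, delta_d)
    rss: float
    unreliable: bool  # pKa outside the sampled span +- 1 unit
    unidentifiable: bool  # limiting shifts indistinguishable from noise
    poor_fit: bool  # residuals beyond what the noise supports

    @property
    def pka_err(self) -> float:
        return float(self.stderr[0])

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (self.residue, self.pka, self.pka_err, self.delta_p, self.delta_d,
                 self.unreliable, self.unidentifiable, self.poor_fit)
            ],
            columns=["residue", "pKa", "pKa_err", "delta_p_ppm", "delta_d_ppm",
                     "unreliable", "unidentifiable", "poor_fit"],
        )


class TitrationModel:
    """Weighted least-squares fit of the single-site titration model."""

    def __init__(self, curve: TitrationCurve):
        self.curve = curve

    def _init_guess(self):
        ph, y = self.curve.ph, self.curve.shifts
        order = np.argsort(ph)
        ph_s, y_s = ph[order], y[order]
        delta_p, delta_d = y_s[0], y_s[-1]
        mid = 0.5 * (delta_p + delta_d)
        pka = float(np.interp(mid, y_s, ph_s) if y_s[0] < y_s[-1] else np.interp(mid, y_s[::-1], ph_s[::-1]))
        if not np.isfinite(pka):
            pka = float(np.median(ph_s))
        return np.array([pka, delta_p, delta_d])

    def fit(self) -> TitrationResults:
        c = self.curve
        w = 1.0 / c.errors if c.errors is not None else np.ones_like(c.shifts)

        def residuals(x):
            return (hh_model(c.ph, *x) - c.shifts) * w

        sol = least_squares(residuals, self._init_guess(),
                            xtol=1e-15, ftol=1e-15, gtol=1e-15, method="lm")
        pka, delta_p, delta_d = sol.x
        n, k = sol.fun.size, 3
        rss = float(sol.fun @ sol.fun)
        sigma2 = rss / max(n - k, 1)
        cov = sigma2 * np.linalg.pinv(sol.jac.T @ sol.jac)
        stderr = np.sqrt(np.maximum(np.diag(cov), 0.0))
        span_lo, span_hi = c.ph.min() - 1.0, c.ph.max() + 1.0
        unreliable = not (span_lo <= pka <= span_hi)
        noise = float(np.median(c.errors)) if c.errors is not None else np.sqrt(sigma2)
        unidentifiable = abs(delta_p - delta_d) < 3.0 * max(noise, 1e-12)
        # non-sigmoidal data leave structure in the residuals
        poor_fit = False
        if c.errors is not None:
            poor_fit = rss / max(n - k, 1) > 9.0  # reduced chi^2 > 9
        return TitrationResults(
            residue=c.residue, pka=float(pka), delta_p=float(delta_p),
            delta_d=float(delta_d), stderr=stderr, rss=rss,
            unreliable=unreliable, unidentifiable=unidentifiable, poor_fit=poor_fit,
        )


def combined_shift(d_hn: float, d_n: float, w1: float = W1_DEFAULT) -> float:
    """Combined amide perturbation sqrt(dHN^2 + (w1*dN)^2), in ppm."""
    return float(np.hypot(d_hn, w1 * np.asarray(d_n, dtype=float)))


@dataclass
class ShiftPerturbation:
    residue: str
    d_hn: float
    d_n: float
    combined: float = None
    tier: str = "none"

    def __post_init__(self):
        if self.combined is None:
            self.combined = combined_shift(self.d_hn, self.d_n)


def classify_perturbations(perturbations: list, w1: float = W1_DEFAULT, ddof: int = 0) -> list:
    """Tier residues by combined shift against mean + 0.5 SD and mean + SD.

    The SD is the population SD by default (``ddof=0``).  Returns new
    :class:`ShiftPerturbation` objects with tiers filled in; input order
    is irrelevant to the assigned tiers.
    """
    if len(perturbations) < 3:
        raise ValueError("need at least 3 residues to classify")
    combined = np.array([combined_shift(p.d_hn, p.d_n, w1) for p in perturbations])
    mean, sd = float(np.mean(combined)), float(np.std(combined, ddof=ddof))
    out = []
    for p, c in zip(perturbations, combined):
        if sd > 0 and c > mean + sd:
            tier = "above_mean_plus_sd"
        elif sd > 0 and c > mean + 0.5 * sd:
            tier = "above_mean_plus_half_sd"
        else:
            tier = "none"
        out.append(ShiftPerturbation(residue=p.residue, d_hn=p.d_hn, d_n=p.d_n,
                                     combined=float(c), tier=tier))
    return out
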