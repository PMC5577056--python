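"""Binding thermodynamics: K_A/ΔG/ΔH/TΔS decomposition, ΔC_p regression,
one-site ITC isotherm simulation and fitting, and DSC enthalpy integration.

Canonical units: temperatures in K, energies in kJ/mol, association constants
in M^-1, volumes in L.  Calorie inputs convert at 4.184 J/cal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .models import InvalidInputError

logger = logging.getLogger(__name__)

R_GAS = 8.314          # J/(mol K)
J_PER_CAL = 4.184


def gibbs_from_ka(ka: float, temperature: float) -> float:
    """Binding free energy ΔG = -R T ln(K_A), in kJ/mol."""
    if ka <= 0 or temperature <= 0:
        raise InvalidInputError("ka and temperature must be > 0")
    return -R_GAS * temperature * np.log(ka) / 1000.0


def entropy_term(delta_h: float, delta_g: float) -> float:
    """TΔS = ΔH - ΔG (kJ/mol)."""
    return delta_h - delta_g


@dataclass(frozen=True)
class BindingThermodynamics:
    """K_A, ΔG, ΔH, TΔS, ΔC_p (kJ/mol, kJ/(mol K)) at one temperature."""

    temperature: float
    ka: float
    delta_g: float
    delta_h: float
    t_delta_s: float
    ka_error: float = float("nan")
    delta_h_error: float = float("nan")
    delta_cp: float = float("nan")
    delta_cp_error: float = float("nan")

    def __post_init__(self) -> None:
        if self.ka <= 0:
            raise InvalidInputError("ka must be > 0")
        if abs(self.delta_g - (self.delta_h - self.t_delta_s)) > 1e-6:
            raise InvalidInputError("delta_g != delta_h - t_delta_s")

    @classmethod
    def from_ka_dh(cls, ka: float, delta_h: float, temperature: float, **kw):
        """Assemble a record from K_A and ΔH, deriving ΔG and TΔS."""
        dg = gibbs_from_ka(ka, temperature)
        return cls(temperature=temperature, ka=ka, delta_g=dg, delta_h=delta_h,
                   t_delta_s=entropy_term(delta_h, dg), **kw)


def delta_cp_weighted(temperatures, delta_h, sigma):
    """Heat-capacity change from ΔH(T): 1/σ²-weighted linear regression.

    Returns (slope, slope_SE) in kJ/(mol K).  The SE comes from the weighted
    normal equations, i.e. it assumes the supplied σ are correct on scale.
    """
    t = np.asarray(temperatures, dtype=float)
    h = np.asarray(delta_h, dtype=float)
    s = np.asarray(sigma, dtype=float)
    if t.size < 3:
        raise InvalidInputError("need >= 3 (T, delta_h) points")
    if np.any(s <= 0):
        raise InvalidInputError("sigma must be > 0")
    if np.unique(t).size < 2:
        raise InvalidInputError("degenerate temperatures")
    w = 1.0 / s**2
    sw = w.sum()
    sx, sy = (w * t).sum(), (w * h).sum()
    sxx, sxy = (w * t * t).sum(), (w * t * h).sum()
    delta = sw * sxx - sx**2
    slope = (sw * sxy - sx * sy) / delta
    return float(slope), float(np.sqrt(sw / delta))


@dataclass(frozen=True)
class ItcExperiment:
    """Geometry and (optionally) observed heats of a titration.

    The macromolecule sits in the cell, the titrant in the syringe; heats are
    in joules per injection when present.
    """

    cell_concentration: float          # M
    syringe_concentration: float       # M
    cell_volume: float                 # L
    injection_volumes: tuple           # L each
    temperature: float                 # K
    heats: tuple | None = None         # J per injection

    def __post_init__(self) -> None:
        if self.cell_concentration <= 0 or self.syringe_concentration <= 0:
            raise InvalidInputError("concentrations must be > 0")
        if len(self.injection_volumes) < 5:
            raise InvalidInputError("need >= 5 injections")
        if self.heats is not None and len(self.heats) != len(self.injection_volumes):
            raise InvalidInputError("heats/injections length mismatch")


def bound_concentration(ka: float, sites: float, titrant: float) -> float:
    """Equilibrium complex concentration for 1:1 binding (quadratic root).

    ``sites`` is n*[M]_total, ``titrant`` [X]_total, both in M.
    """
    if ka <= 0:
        raise InvalidInputError("ka must be > 0")
    b = sites + titrant + 1.0 / ka
    disc = b * b - 4.0 * sites * titrant
    return 0.5 * (b - np.sqrt(max(disc, 0.0)))


def one_site_itc_heats(ka: float, delta_h: float, n: float,
                       experiment: ItcExperiment) -> np.ndarray:
    """Expected heat per injection (J) under the one-site binding model.

    Each injection of volume dV displaces an equal volume of pre-injection
    cell solution (plug displacement before mixing):
        M_i = M_{i-1} (V0 - dV)/V0
        X_i = (X_{i-1} (V0 - dV) + X_syr dV)/V0
    The complex concentration after each injection solves the 1:1 mass-balance
    quadratic, and the observed heat is
        q_i = ΔH V0 (B_i - B_{i-1} (V0 - dV)/V0),
    the bound material formed beyond what the displaced plug carried out.
    """
    v0 = experiment.cell_volume
    m_tot = experiment.cell_concentration
    x_tot = 0.0
    b_prev = 0.0
    dh_j = delta_h * 1000.0  # kJ/mol -> J/mol
    heats = []
    for dv in experiment.injection_volumes:
        keep = (v0 - dv) / v0
        m_tot *= keep
        x_tot = x_tot * keep + experiment.syringe_concentration * dv / v0
        b = bound_concentration(ka, n * m_tot, x_tot)
        heats.append(dh_j * v0 * (b - b_prev * keep))
        b_prev = b
    return np.asarray(heats)


@dataclass(frozen=True)
class ItcFit:
    ka: float
    ka_se: float
    delta_h: float           # kJ/mol
    delta_h_se: float
    n: float
    n_se: float
    chi2: float
    converged: bool


def fit_itc(experiment: ItcExperiment, sigma: float | None = None,
            log10_ka_starts=(5.0, 6.5, 8.0, 9.5, 11.0)) -> ItcFit:
    """Fit (K_A, ΔH, n) to observed injection heats by least squares.

    Multi-start over log10 K_A; standard errors from the covariance at the
    optimum (in log10 K_A space for K_A, propagated via K_A ln10).
    """
    if experiment.heats is None:
        raise InvalidInputError("experiment carries no observed heats")
    q_obs = np.asarray(experiment.heats, dtype=float)
    if q_obs.size < 5:
        raise InvalidInputError("need >= 5 informative injections")
    scale = max(np.abs(q_obs).max(), 1e-30) if sigma is None else sigma

    dh0 = q_obs[:3].sum() * 3.0 / (experiment.cell_concentration
                                   * experiment.cell_volume) / 1000.0
    dh0 = dh0 if np.isfinite(dh0) and dh0 != 0 else -50.0

    def residuals(theta):
        log_ka, dh, n = theta
        model = one_site_itc_heats(10.0**log_ka, dh, n, experiment)
        return (q_obs - model) / scale

    best = None
    for lk0 in log10_ka_starts:
        try:
            res = least_squares(residuals, np.array([lk0, dh0, 1.0]),
                                bounds=([1.0, -1e4, 0.05], [15.0, 1e4, 20.0]),
                                method="trf", x_scale="jac")
        except Exception as exc:  # pragma: no cover
            logger.warning("itc start log10Ka=%.1f failed: %s", lk0, exc)
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("ITC fit failed to converge from any start")

    jac = best.jac
    cov = np.linalg.pinv(jac.T @ jac)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    log_ka, dh, n = best.x
    ka = 10.0**log_ka
    return ItcFit(
        ka=float(ka), ka_se=float(ka * np.log(10.0) * se[0]),
        delta_h=float(dh), delta_h_se=float(se[1]),
        n=float(n), n_se=float(se[2]),
        chi2=float(2.0 * best.cost), converged=True,
    )


@dataclass(frozen=True)
class DscTrace:
    """Molar heat capacity vs temperature, with an optional baseline."""

    temperatures: np.ndarray     # K, strictly increasing
    cp: np.ndarray               # kJ/(mol K)
    baseline: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("temperatures must be strictly increasing")
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "cp", np.asarray(self.cp, dtype=float))
        if self.baseline is not None:
            object.__setattr__(self, "baseline", np.asarray(self.baseline, dtype=float))


def dsc_enthalpy(trace: DscTrace, baseline_fraction: float = 0.1) -> float:
    """Calorimetric ΔH (kJ/mol): trapezoidal integral of Cp minus baseline.

    Without an explicit baseline, a straight line is fitted through the
    flanking windows (first/last ``baseline_fraction`` of points); a warning
    is raised when the transition peak reaches into those windows.
    """
    t, cp = trace.temperatures, trace.cp
    if trace.baseline is not None:
        base = trace.baseline
    else:
        k = max(2, int(round(baseline_fraction * t.size)))
        idx = np.r_[np.arange(k), np.arange(t.size - k, t.size)]
        coef = np.polyfit(t[idx], cp[idx], 1)
        base = np.polyval(coef, t)
        peak = int(np.argmax(cp - base))
        if peak < k or peak >= t.size - k:
            warnings.warn("DSC baseline windows overlap the transition peak")
    return float(np.trapezoid(cp - base, t))
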