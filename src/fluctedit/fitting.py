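"""Global (cluster) fitting of CPMG relaxation-dispersion curves.

Residues in a cluster are assumed to fluctuate at the same exchange rate, so
k_ex (and optionally the minor-state population) is shared across all curves
of all cluster members at all static fields, while the dispersion amplitude
(Phi in ppm^2 for the fast-exchange model, or delta-omega in ppm for
Carver–Richards) is per residue and the intrinsic rate R2_0 is free per
residue per field.  Fits are weighted least squares with multi-start over a
log-spaced k_ex grid; model/regime choice uses reduced chi^2 and an F test.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .models import (ExchangeParams, FieldContext, carver_richards_r2eff,
                     luz_meiboom_r2eff, InvalidInputError)

logger = logging.getLogger(__name__)

#: default sigma floor (s^-1) when a table carries no measurement errors
SIGMA_FLOOR = 0.2

#: default multi-start grid for the shared exchange rate
KEX_STARTS = tuple(np.geomspace(50.0, 5000.0, 8))


class FitError(RuntimeError):
    """All starts failed to converge."""


class InvalidComparisonError(ValueError):
    """F test requested between fits of different data."""


@dataclass
class DispersionCurve:
    """One residue's R2eff profile vs CPMG frequency at one static field."""

    residue_id: str
    field: FieldContext
    nu_cpmg: np.ndarray
    r2eff: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.nu_cpmg = np.asarray(self.nu_cpmg, dtype=float)
        self.r2eff = np.asarray(self.r2eff, dtype=float)
        if self.nu_cpmg.size < 4:
            raise InvalidInputError(f"{self.residue_id}: need >= 4 points per field")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if np.any(self.sigma <= 0):
                raise InvalidInputError(f"{self.residue_id}: sigma must be > 0")

    @property
    def field_label(self) -> str:
        return f"{self.field.spectrometer_frequency:g}"

    @property
    def r2_range(self) -> float:
        """Peak-to-peak change of R2eff over the full CPMG range."""
        return float(self.r2eff.max() - self.r2eff.min())


def ensure_sigma(curves, floor: float = SIGMA_FLOOR):
    """Fill missing measurement errors.

    Duplicate nu_cpmg points within a curve provide an empirical estimate
    (pooled SD of duplicates); otherwise a configured floor is used.
    """
    for c in curves:
        if c.sigma is not None:
            continue
        est = floor
        vals, counts = np.unique(c.nu_cpmg, return_counts=True)
        dup = vals[counts > 1]
        if dup.size:
            sds = [np.std(c.r2eff[c.nu_cpmg == v], ddof=1) for v in dup]
            pooled = float(np.sqrt(np.mean(np.square(sds))))
            if pooled > 0:
                est = pooled
        c.sigma = np.full_like(c.r2eff, est)
    return curves


def exclude_flat_curves(curves, min_range: float = 1.0):
    """Partition curves by residue into (kept, excluded).

    A residue is kept iff its R2eff changed by at least ``min_range`` (s^-1)
    over the CPMG range on at least one field; data below the threshold carry
    no exchange information and are excluded from fitting.
    """
    if not curves:
        raise InvalidInputError("no curves supplied")
    by_res: dict = {}
    for c in curves:
        by_res.setdefault(c.residue_id, []).append(c)
    kept, excluded = [], []
    for rid in by_res:
        ranges = [c.r2_range for c in by_res[rid]]
        if max(ranges) >= min_range:
            kept.extend(by_res[rid])
        else:
            excluded.extend(by_res[rid])
            logger.info("excluded %s: max R2eff range %.3f s^-1 < %.3f",
                        rid, max(ranges), min_range)
    return kept, excluded


@dataclass
class ClusterFit:
    """Result of a global cluster fit."""

    member_residues: tuple
    model: str
    share_p_minor: bool
    k_ex: float
    k_ex_se: float
    p_minor: float | None
    p_minor_se: float | None
    per_residue: dict
    chi2: float
    dof: int
    n_points: int
    data_fingerprint: str
    n_starts: int
    converged: bool

    @property
    def n_parameters(self) -> int:
        return self.n_points - self.dof

    @property
    def reduced_chi2(self) -> float:
        return reduced_chi2(self)


def reduced_chi2(fit: ClusterFit) -> float:
    """chi^2 divided by the degrees of freedom (points minus free parameters)."""
    if fit.dof <= 0:
        raise InvalidInputError("dof must be > 0")
    return fit.chi2 / fit.dof


def _fingerprint(curves) -> str:
    h = hashlib.sha256()
    for c in sorted(curves, key=lambda c: (c.residue_id, c.field_label)):
        h.update(c.residue_id.encode())
        h.update(np.ascontiguousarray(c.nu_cpmg).tobytes())
        h.update(np.ascontiguousarray(c.r2eff).tobytes())
        h.update(np.ascontiguousarray(c.sigma).tobytes())
    return h.hexdigest()


class _Design:
    """Parameter packing for a global fit (one flat theta vector)."""

    def __init__(self, curves, model: str, share_p_minor: bool):
        if model not in ("luz_meiboom", "carver_richards"):
            raise InvalidInputError(f"unknown fit model {model!r}")
        self.model = model
        self.share_p_minor = share_p_minor
        self.curves = list(curves)
        self.residues = sorted({c.residue_id for c in self.curves})
        names = ["k_ex"]
        if model == "carver_richards" and share_p_minor:
            names.append("p_minor")
        for rid in self.residues:
            if model == "luz_meiboom":
                names.append(f"phi:{rid}")
            else:
                if not share_p_minor:
                    names.append(f"p_minor:{rid}")
                names.append(f"dw:{rid}")
        for c in self.curves:
            names.append(f"r2_0:{c.residue_id}:{c.field_label}")
        self.names = names
        self.index = {n: i for i, n in enumerate(names)}
        self.n_points = int(sum(c.nu_cpmg.size for c in self.curves))

    @property
    def n_params(self) -> int:
        return len(self.names)

    def bounds(self):
        lo, hi = [], []
        for n in self.names:
            if n == "k_ex":
                lo.append(1.0), hi.append(1e6)
            elif n.startswith("p_minor"):
                lo.append(1e-6), hi.append(0.5)
            elif n.startswith("phi:"):
                lo.append(0.0), hi.append(np.inf)
            elif n.startswith("dw:"):
                lo.append(0.0), hi.append(50.0)
            else:  # r2_0
                lo.append(0.0), hi.append(500.0)
        return np.array(lo), np.array(hi)

    def initial(self, kex0: float) -> np.ndarray:
        theta = np.zeros(self.n_params)
        theta[self.index["k_ex"]] = kex0
        pb0 = 0.05
        if "p_minor" in self.index:
            theta[self.index["p_minor"]] = pb0
        # amplitude guesses from the observed dispersion range
        rex_by_res = {}
        for c in self.curves:
            rex_by_res.setdefault(c.residue_id, []).append((c.r2_range, c.field))
        for rid in self.residues:
            rex, fld = max(rex_by_res[rid])
            rex = max(rex, 0.05)
            if self.model == "luz_meiboom":
                theta[self.index[f"phi:{rid}"]] = rex * kex0 / fld.ppm_to_rad**2
            else:
                if f"p_minor:{rid}" in self.index:
                    theta[self.index[f"p_minor:{rid}"]] = pb0
                dw0 = np.sqrt(rex * kex0 / ((1 - pb0) * pb0)) / fld.ppm_to_rad
                theta[self.index[f"dw:{rid}"]] = float(np.clip(dw0, 0.05, 6.0))
        for c in self.curves:
            theta[self.index[f"r2_0:{c.residue_id}:{c.field_label}"]] = float(c.r2eff.min())
        return theta

    def residuals(self, theta: np.ndarray) -> np.ndarray:
        kex = theta[self.index["k_ex"]]
        out = []
        for c in self.curves:
            r2_0 = theta[self.index[f"r2_0:{c.residue_id}:{c.field_label}"]]
            if self.model == "luz_meiboom":
                params = ExchangeParams(
                    r2_0=r2_0, k_ex=kex,
                    phi_ppm2=theta[self.index[f"phi:{c.residue_id}"]])
                model_r2 = luz_meiboom_r2eff(c.nu_cpmg, params, c.field)
            else:
                pb_key = "p_minor" if self.share_p_minor else f"p_minor:{c.residue_id}"
                params = ExchangeParams(
                    r2_0=r2_0, k_ex=kex,
                    p_minor=theta[self.index[pb_key]],
                    delta_omega_ppm=theta[self.index[f"dw:{c.residue_id}"]])
                model_r2 = carver_richards_r2eff(c.nu_cpmg, params, c.field)
            out.append((c.r2eff - model_r2) / c.sigma)
        return np.concatenate(out)

    def unpack(self, theta: np.ndarray, se: np.ndarray) -> dict:
        per = {}
        for rid in self.residues:
            rec = {"r2_0": {}, "r2_0_se": {}}
            if self.model == "luz_meiboom":
                i = self.index[f"phi:{rid}"]
                rec["phi_ppm2"], rec["phi_ppm2_se"] = float(theta[i]), float(se[i])
            else:
                i = self.index[f"dw:{rid}"]
                rec["delta_omega_ppm"], rec["delta_omega_ppm_se"] = float(theta[i]), float(se[i])
                if not self.share_p_minor:
                    j = self.index[f"p_minor:{rid}"]
                    rec["p_minor"], rec["p_minor_se"] = float(theta[j]), float(se[j])
            per[rid] = rec
        for c in self.curves:
            i = self.index[f"r2_0:{c.residue_id}:{c.field_label}"]
            per[c.residue_id]["r2_0"][c.field_label] = float(theta[i])
            per[c.residue_id]["r2_0_se"][c.field_label] = float(se[i])
        return per


def fit_cluster(curves, model: str = "luz_meiboom", share_p_minor: bool = True,
                kex_starts=KEX_STARTS, sigma_floor: float = SIGMA_FLOOR) -> ClusterFit:
    """Globally fit a residue cluster sharing one exchange rate.

    Weighted least squares minimising sum(((obs - model)/sigma)^2) with
    multi-start over ``kex_starts``; the best final chi^2 wins.  Parameter
    standard errors come from the covariance (J^T J)^-1 at the optimum.
    """
    curves = ensure_sigma(list(curves), sigma_floor)
    if not curves:
        raise InvalidInputError("no curves to fit")
    design = _Design(curves, model, share_p_minor)
    if design.n_points <= design.n_params:
        raise InvalidInputError(
            f"dof <= 0: {design.n_points} points, {design.n_params} parameters")
    lo, hi = design.bounds()

    best = None
    n_ok = 0
    for kex0 in kex_starts:
        theta0 = np.clip(design.initial(float(kex0)), lo, hi)
        try:
            res = least_squares(design.residuals, theta0, bounds=(lo, hi),
                                method="trf", x_scale="jac", max_nfev=400 * design.n_params)
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("start k_ex=%.1f failed: %s", kex0, exc)
            continue
        if not np.all(np.isfinite(res.x)):
            continue
        n_ok += 1
        if best is None or res.cost < best.cost:
            best = res
        logger.debug("start k_ex=%.1f -> chi2=%.4g (status %d)", kex0, 2 * res.cost, res.status)
    if best is None or n_ok == 0:
        raise FitError("no multi-start converged; check data and sigma")

    chi2 = float(2.0 * best.cost)
    dof = design.n_points - design.n_params
    # covariance from the Gauss-Newton approximation at the optimum
    jac = best.jac
    try:
        cov = np.linalg.pinv(jac.T @ jac)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:  # pragma: no cover
        se = np.full(design.n_params, np.nan)

    theta = best.x
    i_kex = design.index["k_ex"]
    p_minor = p_minor_se = None
    if "p_minor" in design.index:
        j = design.index["p_minor"]
        p_minor, p_minor_se = float(theta[j]), float(se[j])
    return ClusterFit(
        member_residues=tuple(design.residues),
        model=model,
        share_p_minor=share_p_minor,
        k_ex=float(theta[i_kex]),
        k_ex_se=float(se[i_kex]),
        p_minor=p_minor,
        p_minor_se=p_minor_se,
        per_residue=design.unpack(theta, se),
        chi2=chi2,
        dof=dof,
        n_points=design.n_points,
        data_fingerprint=_fingerprint(curves),
        n_starts=len(tuple(kex_starts)),
        converged=True,
    )


@dataclass(frozen=True)
class FTestResult:
    selected: str            # 'simple' | 'complex'
    selected_model: str
    f_statistic: float
    p_value: float
    alpha: float


def f_test_select(fit_simple: ClusterFit, fit_complex: ClusterFit,
                  alpha: float = 0.05) -> FTestResult:
    """Choose between two nested fits of the same data by an F test.

    F = ((chi2_s - chi2_c) / (dof_s - dof_c)) / (chi2_c / dof_c); the complex
    model is selected iff p < alpha.  Ties or a negative numerator keep the
    simple model.
    """
    if fit_simple.data_fingerprint != fit_complex.data_fingerprint:
        raise InvalidComparisonError("fits are not over identical data")
    d_dof = fit_simple.dof - fit_complex.dof
    if d_dof <= 0:
        raise InvalidComparisonError("fit_complex must have more free parameters")
    num = (fit_simple.chi2 - fit_complex.chi2) / d_dof
    den = fit_complex.chi2 / fit_complex.dof
    if num <= 0 or den <= 0:
        return FTestResult("simple", fit_simple.model, 0.0, 1.0, alpha)
    f_stat = num / den
    p = float(stats.f.sf(f_stat, d_dof, fit_complex.dof))
    if p < alpha:
        return FTestResult("complex", fit_complex.model, f_stat, p, alpha)
    return FTestResult("simple", fit_simple.model, f_stat, p, alpha)


@dataclass
class PartitionResult:
    partition: tuple          # tuple of tuples of residue ids
    fits: tuple               # one ClusterFit per group
    chi2: float
    dof: int

    @property
    def reduced_chi2(self) -> float:
        return self.chi2 / self.dof


@dataclass
class ClusterSearchResult:
    ranked: tuple             # PartitionResult, best (lowest reduced chi2) first
    f_tests: tuple            # (i_simple, j_complex, F, p) over nested pairs

    @property
    def best(self) -> PartitionResult:
        return self.ranked[0]


def _is_refinement(fine, coarse) -> bool:
    """True if every group of ``fine`` is contained in one group of ``coarse``."""
    coarse_sets = [frozenset(g) for g in coarse]
    return all(any(set(g) <= cs for cs in coarse_sets) for g in fine)


def cluster_search(curves, candidate_partitions, model: str = "luz_meiboom",
                   share_p_minor: bool = True, kex_starts=KEX_STARTS) -> ClusterSearchResult:
    """Fit every candidate residue partition and rank by reduced chi^2.

    Each partition is a list of residue-id groups covering the same residue
    set; each group is fitted globally with its own shared exchange rate.
    Nested partition pairs are additionally compared by F test.
    """
    if not candidate_partitions:
        raise InvalidInputError("empty partition list")
    curves = ensure_sigma(list(curves))
    all_res = {c.residue_id for c in curves}
    results = []
    for part in candidate_partitions:
        flat = [r for g in part for r in g]
        if set(flat) != all_res or len(flat) != len(set(flat)):
            raise InvalidInputError(f"partition {part!r} does not cover the residue set")
        fits = []
        for group in part:
            sub = [c for c in curves if c.residue_id in set(group)]
            fits.append(fit_cluster(sub, model=model, share_p_minor=share_p_minor,
                                    kex_starts=kex_starts))
        results.append(PartitionResult(
            partition=tuple(tuple(g) for g in part),
            fits=tuple(fits),
            chi2=sum(f.chi2 for f in fits),
            dof=sum(f.dof for f in fits),
        ))
    order = sorted(range(len(results)), key=lambda i: results[i].reduced_chi2)
    ranked = tuple(results[i] for i in order)

    f_tests = []
    for i, coarse in enumerate(results):
        for j, fine in enumerate(results):
            if i == j or not _is_refinement(fine.partition, coarse.partition):
                continue
            d_dof = coarse.dof - fine.dof
            if d_dof <= 0:
                continue
            num = (coarse.chi2 - fine.chi2) / d_dof
            den = fine.chi2 / fine.dof
            if num <= 0 or den <= 0:
                f_tests.append((i, j, 0.0, 1.0))
            else:
                f_stat = num / den
                f_tests.append((i, j, f_stat, float(stats.f.sf(f_stat, d_dof, fine.dof))))
    return ClusterSearchResult(ranked=ranked, f_tests=tuple(f_tests))


def jackknife_errors(curves, fit: ClusterFit, max_points: int | None = None):
    """Leave-one-point-out jackknife SE for the shared exchange rate.

    Optional alternative to covariance errors; refits from the global
    optimum, so it is fast but assumes a stable basin.
    """
    curves = list(curves)
    design = _Design(curves, fit.model, fit.share_p_minor)
    # flatten point index -> (curve, point)
    flat = [(ci, pi) for ci, c in enumerate(curves) for pi in range(c.nu_cpmg.size)]
    if max_points is not None:
        flat = flat[:max_points]
    kex_values = []
    for ci, pi in flat:
        pruned = []
        for k, c in enumerate(curves):
            if k == ci and c.nu_cpmg.size <= 4:
                pruned = None
                break
            if k == ci:
                keep = np.arange(c.nu_cpmg.size) != pi
                pruned.append(DispersionCurve(c.residue_id, c.field,
                                              c.nu_cpmg[keep], c.r2eff[keep], c.sigma[keep]))
            else:
                pruned.append(c)
        if pruned is None:
            continue
        sub = fit_cluster(pruned, model=fit.model, share_p_minor=fit.share_p_minor,
                          kex_starts=(fit.k_ex,))
        kex_values.append(sub.k_ex)
    k = np.asarray(kex_values)
    n = k.size
    return float(np.sqrt((n - 1) / n * np.sum((k - k.mean()) ** 2)))
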