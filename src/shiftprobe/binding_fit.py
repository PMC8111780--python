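"""Global Kd fitting of fast-exchange CSP titration curves.

In fast exchange the observed CSP of a residue is proportional to the bound
fraction of the protein.  With total (not free) concentrations the 1:1 bound
fraction is the root of a quadratic, giving the ligand-depletion isotherm

    CSP(P, L) = csp_max * [ (P + L + Kd) - sqrt((P + L + Kd)^2 - 4 P L) ] / (2 P)

All residues in a binding event share one Kd, so the fit is global: one Kd
plus one ``csp_max`` amplitude per residue.  Because the model is linear in
the amplitudes given Kd, the solver profiles them out (variable projection)
and searches Kd alone, multistarted on a log grid; standard errors come from
the Jacobian covariance at the optimum, with a residual-resampling bootstrap
as an alternative interval estimate.

Concentrations are mM and CSPs ppm throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import optimize

from .errors import FitError, UnderdeterminedError, ValidationError

#: Multistart grid for Kd (mM), and hard bounds for the refinement.
KD_START_GRID = np.logspace(np.log10(0.01), np.log10(1000.0), 8)
KD_BOUNDS = (1e-4, 1e5)
CSP_MAX_BOUND = 10.0  # ppm


def bound_fraction(p_total, l_total, kd):
    """Fraction of protein bound for a 1:1 complex at total concentrations."""
    p = np.asarray(p_total, dtype=float)
    l = np.asarray(l_total, dtype=float)
    b = p + l + kd
    disc = b * b - 4.0 * p * l
    return (b - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * p)


def binding_isotherm(p_total: float, l_total: float, kd: float, csp_max: float):
    """Ligand-depletion isotherm: expected CSP at total P and L.

    Continuous and nondecreasing in ``l_total``; bounded by ``csp_max``.
    """
    if np.any(np.asarray(p_total) <= 0):
        raise ValueError("p_total must be > 0")
    if np.any(np.asarray(l_total) < 0):
        raise ValueError("l_total must be >= 0")
    if kd <= 0:
        raise ValueError("kd must be > 0")
    if np.any(np.asarray(csp_max) < 0):
        raise ValueError("csp_max must be >= 0")
    return csp_max * bound_fraction(p_total, l_total, kd)


#: residue -> (P totals, L totals, observed CSPs), all 1-D arrays of equal length
ResidueCurves = Dict[int, Tuple[np.ndarray, np.ndarray, np.ndarray]]


@dataclass
class BindingFitResult:
    """Shared Kd with per-residue amplitudes and fit diagnostics."""

    kd: float  # mM
    kd_se: float  # mM, from Jacobian covariance
    csp_max: Dict[int, float]  # ppm
    csp_max_se: Dict[int, float]
    ssr: float
    residuals: Dict[int, np.ndarray]
    converged: bool
    n_points: int
    saturation: Dict[int, float]  # bound fraction at the final point
    metadata: dict = field(default_factory=dict)
    kd_ci: Optional[Tuple[float, float]] = None  # filled by the bootstrap
    csp_max_ci: Optional[Dict[int, Tuple[float, float]]] = None


def curves_from_profile(series, tracked, profiles_by_step) -> ResidueCurves:
    """Assemble per-residue (P, L, CSP) arrays from per-step CSP profiles."""
    curves: ResidueCurves = {}
    concs = [(pt.protein_conc, pt.ligand_conc) for pt in series.points]
    residues = set.intersection(*(set(p.values) for p in profiles_by_step.values()))
    for res in sorted(residues):
        steps = sorted(profiles_by_step)
        p = np.array([concs[s][0] for s in steps])
        l = np.array([concs[s][1] for s in steps])
        y = np.array([profiles_by_step[s].values[res] for s in steps])
        curves[res] = (p, l, y)
    return curves


def curves_from_tracked(series, tracked) -> ResidueCurves:
    """Per-residue (P, L, CSP) arrays by projection onto the trajectory.

    In fast exchange a peak moves along a straight line from free to bound
    position, so each step's displacement is projected onto the residue's
    endpoint-displacement direction in the weighted shift space.  Unlike the
    per-step CSP magnitude, the projection carries additive (sign-preserving)
    noise and is not biased upward at small displacements, which matters for
    the early steps of a titration.  Residues flagged during tracking are
    skipped.
    """
    from .csp_titration import shift_weight

    curves: ResidueCurves = {}
    concs = [(pt.protein_conc, pt.ligand_conc) for pt in series.points]
    n_steps = len(series.points)
    for res in tracked.tracked_residues():
        traj = tracked.positions[res]
        a = shift_weight(tracked.codes[res])
        h0, n0 = traj[0]
        end = np.array([traj[-1][0] - h0, a * (traj[-1][1] - n0)])
        norm = np.linalg.norm(end)
        if norm == 0:
            u = np.array([1.0, 0.0])  # degenerate: no displacement at all
        else:
            u = end / norm
        p = np.array([concs[s][0] for s in range(1, n_steps)])
        l = np.array([concs[s][1] for s in range(1, n_steps)])
        y = np.array(
            [
                np.dot(np.array([traj[s][0] - h0, a * (traj[s][1] - n0)]), u)
                for s in range(1, n_steps)
            ]
        )
        curves[res] = (p, l, y)
    return curves


def _stack(curves: ResidueCurves, weights=None):
    order = sorted(curves)
    p = np.concatenate([curves[r][0] for r in order])
    l = np.concatenate([curves[r][1] for r in order])
    y = np.concatenate([curves[r][2] for r in order])
    idx = np.concatenate(
        [np.full(len(curves[r][2]), k) for k, r in enumerate(order)]
    )
    if weights is None:
        w = np.ones_like(y)
    else:
        w = np.concatenate([np.asarray(weights[r], dtype=float) for r in order])
        w = w / w.mean()  # only relative weights matter
    return order, p, l, y, idx, w


def _profiled_amplitudes(kd, p, l, y, idx, w, n_res):
    """Weighted least-squares amplitudes given Kd (nonnegative, capped)."""
    f = bound_fraction(p, l, kd)
    ii = idx.astype(int)
    denom = np.bincount(ii, weights=w * f * f, minlength=n_res)
    numer = np.bincount(ii, weights=w * y * f, minlength=n_res)
    amps = np.divide(numer, denom, out=np.zeros(n_res), where=denom > 0)
    return np.clip(amps, 0.0, CSP_MAX_BOUND), f


def _profiled_ssr(kd, p, l, y, idx, w, n_res):
    amps, f = _profiled_amplitudes(kd, p, l, y, idx, w, n_res)
    r = y - amps[idx.astype(int)] * f
    return float(np.sum(w * r * r))


def _golden_min(fun, lo, hi, tol=1e-8):
    """Golden-section minimum of a scalar function on [lo, hi]."""
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = fun(c), fun(d)
    while abs(b - a) > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = fun(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = fun(d)
    return (a + b) / 2.0


def fit_global_kd(
    curves: ResidueCurves,
    residues=None,
    weights=None,
    n_boot: int = 0,
    seed: Optional[int] = None,
) -> BindingFitResult:
    """Fit one shared Kd and per-residue maximal CSPs by weighted least squares.

    Parameters
    ----------
    curves
        Residue -> (P, L, CSP) arrays.  ``residues`` restricts the fit to a
        subset (e.g. the significantly perturbed set).
    weights
        Optional residue -> per-point weights; default uniform.
    n_boot, seed
        If ``n_boot`` > 0, attach bootstrap confidence intervals.
    """
    if residues is not None:
        curves = {r: curves[r] for r in residues}
    if not curves:
        raise ValidationError("no residues to fit")
    order, p, l, y, idx, w = _stack(curves, weights)
    n_res = len(order)
    n_points = y.size
    n_params = n_res + 1
    if n_points < n_params + 1:
        raise UnderdeterminedError(
            f"{n_points} points cannot constrain {n_params} parameters"
        )
    if min(len(np.unique(curves[r][1])) for r in order) < 3:
        raise UnderdeterminedError("need >= 3 distinct ligand concentrations")

    log_bounds = (math.log10(KD_BOUNDS[0]), math.log10(KD_BOUNDS[1]))
    best = (np.inf, None)
    for kd0 in KD_START_GRID:
        res = optimize.minimize(
            lambda x: _profiled_ssr(10.0 ** x[0], p, l, y, idx, w, n_res),
            x0=[math.log10(kd0)],
            method="L-BFGS-B",
            bounds=[log_bounds],
        )
        if res.fun < best[0]:
            best = (res.fun, 10.0 ** res.x[0])
    if best[1] is None or not np.isfinite(best[0]):
        raise FitError("global Kd fit failed from every start")
    kd_hat = best[1]
    amps, _ = _profiled_amplitudes(kd_hat, p, l, y, idx, w, n_res)

    # Polish jointly and extract the Jacobian for covariance-based SEs.
    sw = np.sqrt(w)

    def joint_resid(theta):
        kd = 10.0 ** theta[0]
        a = theta[1:]
        f = bound_fraction(p, l, kd)
        return sw * (y - a[idx.astype(int)] * f)

    theta0 = np.concatenate([[math.log10(kd_hat)], amps])
    lower = np.concatenate([[log_bounds[0]], np.zeros(n_res)])
    upper = np.concatenate([[log_bounds[1]], np.full(n_res, CSP_MAX_BOUND)])
    ls = optimize.least_squares(joint_resid, theta0, bounds=(lower, upper))
    kd_hat = 10.0 ** ls.x[0]
    amps = ls.x[1:]
    ssr = float(2.0 * ls.cost)

    dof = max(n_points - n_params, 1)
    s2 = ssr / dof
    jtj = ls.jac.T @ ls.jac
    try:
        cov = s2 * np.linalg.inv(jtj)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        # d(kd)/d(log10 kd) = kd ln 10
        kd_se = float(se[0] * kd_hat * math.log(10.0))
        amp_se = se[1:]
    except np.linalg.LinAlgError:
        kd_se = float("nan")
        amp_se = np.full(n_res, np.nan)

    residuals = {}
    saturation = {}
    for k, r in enumerate(order):
        pc, lc, yc = curves[r]
        pred = binding_isotherm(pc, lc, kd_hat, amps[k])
        residuals[r] = yc - pred
        saturation[r] = float(bound_fraction(pc[-1], lc[-1], kd_hat))

    result = BindingFitResult(
        kd=float(kd_hat),
        kd_se=kd_se,
        csp_max={r: float(amps[k]) for k, r in enumerate(order)},
        csp_max_se={r: float(amp_se[k]) for k, r in enumerate(order)},
        ssr=ssr,
        residuals=residuals,
        converged=bool(ls.success),
        n_points=n_points,
        saturation=saturation,
        metadata={
            "seed": seed,
            "kd_bounds_mM": list(KD_BOUNDS),
            "start_grid_mM": [float(x) for x in KD_START_GRID],
        },
    )
    if n_boot:
        lo_kd, hi_kd, amp_ci = bootstrap_uncertainty(
            curves, result, n_boot=n_boot, seed=seed, weights=weights
        )
        result.kd_ci = (lo_kd, hi_kd)
        result.csp_max_ci = amp_ci
    return result


def _fast_refit(p, l, y, idx, w, n_res, kd_init):
    """Profiled refit for bootstrap replicates (no polish, no SEs).

    Resampled datasets stay close to the original fit, so a golden-section
    search bracketing the original optimum (two decades either side) is
    sufficient and much cheaper than the full multistart.
    """
    lo = max(math.log10(kd_init) - 2.0, math.log10(KD_BOUNDS[0]))
    hi = min(math.log10(kd_init) + 2.0, math.log10(KD_BOUNDS[1]))
    x = _golden_min(
        lambda t: _profiled_ssr(10.0 ** t, p, l, y, idx, w, n_res), lo, hi, tol=1e-6
    )
    kd = 10.0 ** x
    amps, _ = _profiled_amplitudes(kd, p, l, y, idx, w, n_res)
    return kd, amps


def bootstrap_uncertainty(
    curves: ResidueCurves,
    fit: BindingFitResult,
    n_boot: int = 500,
    seed: Optional[int] = None,
    weights=None,
    level: float = 0.95,
):
    """Residual-resampling bootstrap confidence intervals for Kd and csp_max.

    Residuals are pooled across all residues and steps, centred and inflated
    by sqrt(n / (n - p)) to undo the variance shrinkage of least-squares
    residuals, resampled with replacement onto the fitted curves, and the
    global fit repeated.  The same seed always yields the same intervals.
    """
    if n_boot < 10:
        raise ValueError(f"n_boot must be >= 10, got {n_boot}")
    order, p, l, y, idx, w = _stack(curves, weights)
    n_res = len(order)
    amps0 = np.array([fit.csp_max[r] for r in order])
    fitted = amps0[idx.astype(int)] * bound_fraction(p, l, fit.kd)
    resid = y - fitted
    n_pts, n_par = y.size, n_res + 1
    if n_pts > n_par:
        resid = (resid - resid.mean()) * math.sqrt(n_pts / (n_pts - n_par))

    rng = np.random.default_rng(seed)
    kds = np.empty(n_boot)
    amps_b = np.empty((n_boot, n_res))
    for b in range(n_boot):
        y_b = fitted + rng.choice(resid, size=resid.size, replace=True)
        kds[b], amps_b[b] = _fast_refit(p, l, y_b, idx, w, n_res, fit.kd)

    alpha = (1.0 - level) / 2.0
    lo_kd, hi_kd = np.quantile(kds, [alpha, 1.0 - alpha])
    # Percentile intervals widened to contain the point estimate.
    lo_kd, hi_kd = min(lo_kd, fit.kd), max(hi_kd, fit.kd)
    amp_ci = {}
    for k, r in enumerate(order):
        lo, hi = np.quantile(amps_b[:, k], [alpha, 1.0 - alpha])
        amp_ci[r] = (float(min(lo, fit.csp_max[r])), float(max(hi, fit.csp_max[r])))
    return float(lo_kd), float(hi_kd), amp_ci
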