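"""Cytochrome c oxidase turnover kinetics.

Turnover rates are extracted from Clark-electrode oxygen traces as the
background-corrected O2 consumption slope, converted to electrons per enzyme
per second (4 electrons per O2 reduced), optionally normalized to a reference
rate in percent, and fitted to one- or two-component hyperbolic
(Michaelis-Menten) models of the rate vs electron-donor (cytochrome c)
concentration:

    v(c) = sum_k  V_k * c / (Km_k + c)

Model choice between one and two components uses the extra-sum-of-squares
F-test (with AICc reported alongside).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .errors import FitError, UnderdeterminedError, ValidationError

#: Electrons transferred per O2 reduced to water (oxidase stoichiometry).
ELECTRONS_PER_O2 = 4

#: Km multistart grid (uM) and bounds for the fits.
KM_START_GRID = np.logspace(-2, 3, 6)
KM_BOUNDS = (1e-6, 1e6)


@dataclass
class OxygenTrace:
    """A dissolved-O2 time course with optional event markers."""

    time: np.ndarray  # s
    o2: np.ndarray  # uM
    events: dict = field(default_factory=dict)  # name -> time (s)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.o2 = np.asarray(self.o2, dtype=float)
        if self.time.shape != self.o2.shape:
            raise ValidationError("time and O2 arrays differ in length")
        if np.any(np.diff(self.time) <= 0):
            raise ValidationError("time must be strictly increasing")


@dataclass
class RateCurve:
    """Substrate-rate pairs for one condition (averaged or single replicate)."""

    conc: np.ndarray  # cyt c, uM
    rates: np.ndarray  # e-/s or % relative
    unit: str = "e-/s"
    condition: str = ""
    replicate: Optional[int] = None

    def __post_init__(self):
        self.conc = np.asarray(self.conc, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.conc.shape != self.rates.shape:
            raise ValidationError("concentration and rate arrays differ in length")
        if np.any(self.conc < 0):
            raise ValidationError("concentrations must be >= 0")
        if not np.all(np.isfinite(self.rates)):
            raise ValidationError("rates must be finite")


@dataclass
class MMFitResult:
    """Fitted one- or two-component hyperbolic model."""

    model: str  # 'one_site' | 'two_site'
    v: Tuple[float, ...]  # V per component, same unit as the input rates
    km: Tuple[float, ...]  # uM, ascending
    v_se: Tuple[float, ...]
    km_se: Tuple[float, ...]
    ssr: float
    n_points: int
    converged: bool
    degenerate: bool = False  # two_site collapsed onto one component
    metadata: dict = field(default_factory=dict)

    @property
    def n_params(self) -> int:
        return 2 * len(self.km)

    def predict(self, conc):
        return mm_model(conc, self.v, self.km)


def mm_model(conc, v: Sequence[float], km: Sequence[float]):
    """Sum of hyperbolic components, v(0) = 0."""
    c = np.asarray(conc, dtype=float)
    out = np.zeros_like(c)
    for vk, kk in zip(v, km):
        out = out + vk * c / (kk + c)
    return out


def _window_slope(trace: OxygenTrace, window: Tuple[float, float]) -> float:
    t0, t1 = window
    m = (trace.time >= t0) & (trace.time <= t1)
    if m.sum() < 3:
        raise ValueError(f"window {window} contains {int(m.sum())} samples (< 3)")
    slope = np.polyfit(trace.time[m], trace.o2[m], 1)[0]
    return float(slope)


def rate_from_trace(
    trace: OxygenTrace,
    window: Tuple[float, float],
    background_window: Tuple[float, float],
    enzyme_conc: float,
) -> float:
    """Turnover in e-/s from an oxygen-electrode trace.

    Both windows are fitted by least squares on [O2] vs time; the background
    slope (reductant autoxidation, before enzyme addition) is subtracted and
    the O2 consumption rate converted to electrons per enzyme per second.
    Invariant to a uniform time shift of the trace.
    """
    if enzyme_conc <= 0:
        raise ValidationError(f"enzyme concentration must be > 0, got {enzyme_conc}")
    slope_bg = _window_slope(trace, background_window)
    slope_win = _window_slope(trace, window)
    return ELECTRONS_PER_O2 * (slope_bg - slope_win) / enzyme_conc


def normalize_rates(curve: RateCurve, reference: float) -> RateCurve:
    """Express a rate curve relative to a reference rate, in percent."""
    if reference <= 0:
        raise ValueError(f"reference rate must be > 0, got {reference}")
    return RateCurve(
        conc=curve.conc.copy(),
        rates=100.0 * curve.rates / reference,
        unit="%",
        condition=curve.condition,
        replicate=curve.replicate,
    )


def _nnls_amplitudes(c, y, km, weights):
    """Best nonnegative V's given Km's (model is linear in V)."""
    X = np.column_stack([c / (k + c) for k in km]) * weights[:, None]
    v, _ = optimize.nnls(X, y * weights)
    return v


def fit_mm(
    curve: RateCurve,
    n_sites: int = 1,
    weights: Optional[np.ndarray] = None,
) -> MMFitResult:
    """Fit a one- or two-component hyperbolic model by least squares.

    Multistart over a log-spaced Km grid with the amplitudes profiled out
    (nonnegative linear solve), followed by a joint refinement for the
    Jacobian-covariance standard errors.  Two-site results are ordered
    Km1 <= Km2; a collapse of the two Km's onto each other (within 1%) is
    reported via ``degenerate`` because V1 and V2 are then not identifiable.
    """
    if n_sites not in (1, 2):
        raise ValidationError(f"n_sites must be 1 or 2, got {n_sites}")
    m = curve.conc > 0
    c, y = curve.conc[m], curve.rates[m]
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)[m]
    n_distinct = np.unique(c).size
    if n_distinct < 2 * n_sites + 1:
        raise UnderdeterminedError(
            f"{n_distinct} distinct concentrations cannot constrain "
            f"{2 * n_sites} parameters"
        )

    sw = np.sqrt(w)
    if n_sites == 1:
        km_starts = [(k,) for k in KM_START_GRID]
    else:
        km_starts = list(itertools.combinations(KM_START_GRID, 2))

    # Screen the multistart grid by the profiled (amplitudes solved by NNLS)
    # SSR, then run the full refinement only from the most promising starts.
    screened = []
    for kms in km_starts:
        v0 = _nnls_amplitudes(c, y, kms, sw)
        ssr0 = float(np.sum((sw * (y - mm_model(c, v0, kms))) ** 2))
        screened.append((ssr0, kms, v0))
    screened.sort(key=lambda t: t[0])

    def resid(theta, _n=n_sites):
        v = theta[:_n]
        km = 10.0 ** theta[_n:]
        return sw * (y - mm_model(c, v, km))

    lb = np.concatenate([np.zeros(n_sites), np.full(n_sites, math.log10(KM_BOUNDS[0]))])
    ub = np.concatenate(
        [np.full(n_sites, np.inf), np.full(n_sites, math.log10(KM_BOUNDS[1]))]
    )
    best = (np.inf, None)
    for _, kms, v0 in screened[: max(3, n_sites)]:
        theta0 = np.concatenate([v0, np.log10(kms)])
        try:
            ls = optimize.least_squares(resid, theta0, bounds=(lb, ub))
        except Exception:
            continue
        if ls.cost < best[0]:
            best = (ls.cost, ls)
    if best[1] is None:
        raise FitError(f"{n_sites}-site fit failed from every start")
    ls = best[1]
    v = np.maximum(ls.x[:n_sites], 0.0)
    km = 10.0 ** ls.x[n_sites:]
    ssr = float(2.0 * ls.cost)

    n_params = 2 * n_sites
    dof = max(c.size - n_params, 1)
    s2 = ssr / dof
    try:
        cov = s2 * np.linalg.inv(ls.jac.T @ ls.jac)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        v_se = se[:n_sites]
        km_se = se[n_sites:] * km * math.log(10.0)
    except np.linalg.LinAlgError:
        v_se = np.full(n_sites, np.nan)
        km_se = np.full(n_sites, np.nan)

    order = np.argsort(km)
    v, km = v[order], km[order]
    v_se, km_se = v_se[order], km_se[order]
    # A two-component fit is non-identifiable when the Km's coincide (only
    # V1+V2 is determined) or when one amplitude vanishes.
    degenerate = bool(
        n_sites == 2
        and (
            (km[1] > 0 and (km[1] - km[0]) / km[1] < 0.01)
            or (v.sum() > 0 and v.min() < 1e-6 * v.sum())
        )
    )
    return MMFitResult(
        model="one_site" if n_sites == 1 else "two_site",
        v=tuple(float(x) for x in v),
        km=tuple(float(x) for x in km),
        v_se=tuple(float(x) for x in v_se),
        km_se=tuple(float(x) for x in km_se),
        ssr=ssr,
        n_points=int(c.size),
        converged=bool(ls.success),
        degenerate=degenerate,
        metadata={"unit": curve.unit, "condition": curve.condition},
    )


@dataclass
class ModelComparison:
    preferred: str
    f_statistic: float
    p_value: float
    aicc: Dict[str, float]
    alpha: float = 0.05


def _aicc(ssr: float, n: int, k: int) -> float:
    # least-squares AICc; k counts model params + 1 for the noise variance
    kk = k + 1
    aic = n * math.log(max(ssr, 1e-300) / n) + 2 * kk
    if n - kk - 1 > 0:
        aic += 2 * kk * (kk + 1) / (n - kk - 1)
    return aic


def compare_models(
    fit1: MMFitResult, fit2: MMFitResult, n_points: int, alpha: float = 0.05
) -> ModelComparison:
    """Extra-sum-of-squares F-test between nested hyperbolic fits.

    ``fit1`` is the simpler model.  The preferred model follows the F-test at
    the given alpha; AICc for both models is reported alongside.  If the
    richer model somehow has the larger SSR (a failed nested fit), a warning
    is raised and the simpler model preferred.
    """
    if fit2.n_params <= fit1.n_params:
        raise ValidationError("fit2 must be the richer model")
    aicc = {
        fit1.model: _aicc(fit1.ssr, n_points, fit1.n_params),
        fit2.model: _aicc(fit2.ssr, n_points, fit2.n_params),
    }
    if fit2.ssr > fit1.ssr:
        warnings.warn(
            "richer model has larger SSR than the nested simpler model; "
            "preferring the simpler model",
            stacklevel=2,
        )
        return ModelComparison(fit1.model, float("nan"), 1.0, aicc, alpha)
    dp = fit2.n_params - fit1.n_params
    dof2 = n_points - fit2.n_params
    if dof2 <= 0:
        raise UnderdeterminedError("no residual degrees of freedom for the F-test")
    if fit2.ssr == 0.0:
        # Perfect fit of the richer model: prefer it only if it improved.
        preferred = fit2.model if fit1.ssr > 0 else fit1.model
        return ModelComparison(preferred, float("inf") if fit1.ssr > 0 else 0.0,
                               0.0 if fit1.ssr > 0 else 1.0, aicc, alpha)
    f = ((fit1.ssr - fit2.ssr) / dp) / (fit2.ssr / dof2)
    p = float(stats.f.sf(f, dp, dof2))
    preferred = fit2.model if p < alpha else fit1.model
    return ModelComparison(preferred, float(f), p, aicc, alpha)
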