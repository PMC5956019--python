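"""Nonlinear least-squares estimation of K_d, IC50 and decay parameters.

Three fitters, all trust-region least squares with multi-start on a log
grid of the scale parameter (affinities in a single panel span more than
four decades, so a single start is not safe):

* :func:`fit_saturation` — conventional MST: F_norm vs antibody-site
  concentration, depletion-exact binding isotherm, estimates K_d.
* :func:`fit_competition` — competition MST: F_norm vs competitor
  concentration, log-logistic displacement curve, estimates IC50.
* :func:`fit_one_phase_decay` — first-order kinetics Y = (Y0-P) e^(-kt) + P,
  estimates the rate and half-life.

Confidence intervals are asymptotic (linearized), as standard nonlinear
regression packages report; fits are unweighted (constant variance).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .errors import (
    DataError,
    DomainError,
    FitError,
    FlatCurveError,
    NotDecayingError,
)
from .traces import FnormPoint

__all__ = [
    "Mode",
    "TitrationSeries",
    "BindingFit",
    "DecayFit",
    "fit_saturation",
    "fit_competition",
    "fit_one_phase_decay",
    "goodness_of_fit",
]

_KD_STARTS = (0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)  # nM, multi-start grid


class Mode(str, Enum):
    SATURATION = "SATURATION"
    COMPETITION = "COMPETITION"


@dataclass(frozen=True)
class TitrationSeries:
    """An ordered titration: (concentration, F_norm) points plus design constants.

    ``tracer_total`` is required in both modes.  In COMPETITION mode
    ``antibody_sites`` (and optionally ``tracer_kd``) carry the fixed design
    constants needed downstream for the IC50 -> K_i conversion.
    """

    mode: Mode
    points: tuple[FnormPoint, ...]
    tracer_total: float
    antibody_sites: float | None = None
    tracer_kd: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(self.points))
        concs = [p.titrant_conc for p in self.points]
        if any(c <= 0 for c in concs):
            raise DataError("titrant concentrations must be strictly positive")
        if len(set(concs)) != len(concs):
            raise DataError("titrant concentrations must be distinct")
        if len(self.unflagged) < 8:
            raise DataError("need >= 8 unflagged points to fit")
        if self.tracer_total <= 0:
            raise DataError("tracer_total must be positive")

    @property
    def unflagged(self) -> tuple[FnormPoint, ...]:
        return tuple(p for p in self.points if not p.qc_flags)


@dataclass(frozen=True)
class BindingFit:
    """Result of a saturation (K_d) or competition (IC50) fit.

    ``estimate`` is the K_d or IC50 in nM; ``ci95`` its asymptotic 95%
    confidence interval.  Plateaus are on the F_norm scale: ``fnorm_unbound``
    is the free-tracer plateau, ``fnorm_bound`` the saturated one.
    """

    mode: Mode
    estimate: float
    fnorm_unbound: float
    fnorm_bound: float
    ci95: tuple[float, float]
    r2: float
    n_used: int
    converged: bool
    warnings: frozenset[str] = field(default_factory=frozenset)

    @property
    def response_amplitude(self) -> float:
        return self.fnorm_bound - self.fnorm_unbound

    def to_dict(self) -> dict:
        return {
            "mode": self.mode.value,
            "estimate_nM": self.estimate,
            "ci95_nM": list(self.ci95),
            "fnorm_unbound": self.fnorm_unbound,
            "fnorm_bound": self.fnorm_bound,
            "r2": self.r2,
            "n_used": self.n_used,
            "converged": self.converged,
            "flags": sorted(self.warnings),
        }


@dataclass(frozen=True)
class DecayFit:
    """First-order decay fit: rate k (1/h), half-life and 99% CI range (h)."""

    k: float
    t_half: float
    t_half_ci99: tuple[float, float]
    plateau: float
    y0: float
    r2: float

    def to_dict(self) -> dict:
        return {
            "k_per_h": self.k,
            "t_half_h": self.t_half,
            "t_half_ci99_h": list(self.t_half_ci99),
            "plateau": self.plateau,
            "y0": self.y0,
            "r2": self.r2,
        }


def _binary_f(a: np.ndarray, t: float, kd: float) -> np.ndarray:
    """Vectorized depletion-exact bound fraction (stable quadratic form)."""
    s = a + t + kd
    disc = np.maximum(s * s - 4.0 * a * t, 0.0)
    return 2.0 * a / (s + np.sqrt(disc))


def goodness_of_fit(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Coefficient of determination r^2 = 1 - SS_res / SS_tot."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 3:
        raise DataError("observed and predicted must be equal-length series of >= 3")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise DomainError("r^2 undefined: observed series has zero variance")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def _multistart_lsq(
    residual: Callable[[np.ndarray], np.ndarray],
    starts: Sequence[np.ndarray],
    bounds: tuple[np.ndarray, np.ndarray],
):
    best = None
    for x0 in starts:
        x0 = np.clip(x0, bounds[0], bounds[1])
        try:
            res = least_squares(
                residual, x0, bounds=bounds, method="trf", x_scale="jac",
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=5000,
            )
        except Exception:
            continue
        # keep the lowest-cost completed solve; the trf success flag only
        # reports which stopping criterion fired, not solution quality
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitError("nonlinear fit failed to converge from every start")
    return best


def _param_ci(res, index: int, n: int, level: float) -> tuple[float, float]:
    """Asymptotic CI of one parameter from the jacobian at the solution."""
    j = res.jac
    dof = max(n - j.shape[1], 1)
    s2 = 2.0 * res.cost / dof
    try:
        cov = np.linalg.inv(j.T @ j) * s2
        se = float(np.sqrt(max(cov[index, index], 0.0)))
    except np.linalg.LinAlgError:
        return (0.0, np.inf)
    tval = float(stats.t.ppf(0.5 + level / 2.0, dof))
    x = res.x[index]
    return (x - tval * se, x + tval * se)


def _amplitude_guard(amp: float, resid_sd: float, scale: float) -> None:
    if abs(amp) <= max(3.0 * resid_sd, 1e-9 * scale):
        raise FlatCurveError(
            "response amplitude indistinguishable from zero; no binding signal to fit"
        )


def fit_saturation(series: TitrationSeries) -> BindingFit:
    """Fit the conventional-MST saturation curve and estimate K_d.

    Model: ``F_norm(A) = U + (B - U) * f(A; T, K_d)`` where ``f`` is the
    depletion-exact bound fraction at total sites A and total tracer T.
    Parameters (U, B, K_d) are fitted by trust-region least squares with a
    multi-start over a log grid of K_d; QC-flagged points are excluded.
    """
    if series.mode is not Mode.SATURATION:
        raise DataError("series mode must be SATURATION")
    pts = series.unflagged
    a = np.array([p.titrant_conc for p in pts])
    y = np.array([p.fnorm for p in pts])
    t = series.tracer_total
    order = np.argsort(a)
    a, y = a[order], y[order]

    def residual(x: np.ndarray) -> np.ndarray:
        u, b, kd = x
        return u + (b - u) * _binary_f(a, t, kd) - y

    u0, b0 = float(y[0]), float(y[-1])
    lo = np.array([-np.inf, -np.inf, 1e-9])
    hi = np.array([np.inf, np.inf, 1e12])
    starts = [np.array([u0, b0, kd]) for kd in _KD_STARTS]
    res = _multistart_lsq(residual, starts, (lo, hi))
    u, b, kd = res.x
    resid = residual(res.x)
    n = len(y)
    resid_sd = float(np.sqrt(2.0 * res.cost / max(n - 3, 1)))
    _amplitude_guard(b - u, resid_sd, float(np.max(np.abs(y))))
    r2 = goodness_of_fit(y, y + resid)
    ci = _param_ci(res, 2, n, 0.95)
    warnings: set[str] = set()
    if not (a.min() <= kd <= a.max()):
        warnings.add("EXTRAPOLATED_ESTIMATE")
    return BindingFit(
        mode=Mode.SATURATION,
        estimate=float(kd),
        fnorm_unbound=float(u),
        fnorm_bound=float(b),
        ci95=(max(ci[0], 0.0), ci[1]),
        r2=r2,
        n_used=n,
        converged=True,
        warnings=frozenset(warnings),
    )


def fit_competition(series: TitrationSeries, free_slope: bool = True) -> BindingFit:
    """Fit the competition-MST displacement curve and estimate the IC50.

    Model: ``F_norm(L) = B + (U - B) * L^s / (L^s + IC50^s)`` — at zero
    competitor the tracer sits on the bound plateau B, at saturating
    competitor it is fully displaced to the unbound plateau U.  The Hill
    slope s is free by default: although the displacement is 1:1
    competitive, antibody depletion of the competitor steepens the curve on
    the *total*-concentration axis whenever the site concentration is not
    negligible against K_d, and pinning s = 1 then biases the midpoint by
    >10%.  Pass ``free_slope=False`` to fix s = 1.

    The result carries an ``EXTRAPOLATED_IC50`` warning when the estimate
    falls outside the titrated concentration range (only the upper or lower
    plateau was sampled); converting such an IC50 to K_i is unreliable.
    """
    if series.mode is not Mode.COMPETITION:
        raise DataError("series mode must be COMPETITION")
    pts = series.unflagged
    ell = np.array([p.titrant_conc for p in pts])
    y = np.array([p.fnorm for p in pts])
    order = np.argsort(ell)
    ell, y = ell[order], y[order]

    def residual(x: np.ndarray) -> np.ndarray:
        b, u, ic50 = x[0], x[1], x[2]
        s = x[3] if free_slope else 1.0
        h = ell**s / (ell**s + ic50**s)
        return b + (u - b) * h - y

    b0, u0 = float(y[0]), float(y[-1])
    ic50_starts = np.geomspace(ell.min(), ell.max(), 7)
    if free_slope:
        starts = [np.array([b0, u0, c, 1.0]) for c in ic50_starts]
        lo = np.array([-np.inf, -np.inf, 1e-9, 0.2])
        hi = np.array([np.inf, np.inf, 1e12, 5.0])
    else:
        starts = [np.array([b0, u0, c]) for c in ic50_starts]
        lo = np.array([-np.inf, -np.inf, 1e-9])
        hi = np.array([np.inf, np.inf, 1e12])
    res = _multistart_lsq(residual, starts, (lo, hi))
    b, u, ic50 = res.x[0], res.x[1], res.x[2]
    resid = residual(res.x)
    n = len(y)
    npar = 4 if free_slope else 3
    resid_sd = float(np.sqrt(2.0 * res.cost / max(n - npar, 1)))
    _amplitude_guard(u - b, resid_sd, float(np.max(np.abs(y))))
    r2 = goodness_of_fit(y, y + resid)
    ci = _param_ci(res, 2, n, 0.95)
    warnings: set[str] = set()
    if not (ell.min() <= ic50 <= ell.max()):
        warnings.add("EXTRAPOLATED_IC50")
    return BindingFit(
        mode=Mode.COMPETITION,
        estimate=float(ic50),
        fnorm_unbound=float(u),
        fnorm_bound=float(b),
        ci95=(max(ci[0], 0.0), ci[1]),
        r2=r2,
        n_used=n,
        converged=True,
        warnings=frozenset(warnings),
    )


def fit_one_phase_decay(
    times: Sequence[float],
    values: Sequence[float],
    fix_plateau: float | None = 0.0,
) -> DecayFit:
    """Fit one-phase decay ``Y(t) = (Y0 - P) exp(-k t) + P``.

    ``fix_plateau`` pins the asymptote P (default 0, i.e. complete
    disappearance of the analyte); pass None to fit it.  The half-life is
    ``ln 2 / k`` and its 99% CI is obtained by transforming the endpoints of
    the asymptotic 99% CI of ``k`` (a monotone map); an upper endpoint of
    +inf results when the rate is not distinguishable from zero at the 99%
    level.

    Raises :class:`NotDecayingError` when the fitted rate is non-positive.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.size < 2:
        raise DataError("need >= 2 (time, value) pairs")
    if np.any(y < 0):
        raise DataError("values must be non-negative")
    if t.min() > 0:
        raise DataError("the series must include t = 0")
    if np.ptp(y) == 0:
        raise NotDecayingError("constant series: nothing decays")

    free_p = fix_plateau is None

    def residual(x: np.ndarray) -> np.ndarray:
        y0, k = x[0], x[1]
        p = x[2] if free_p else fix_plateau
        return (y0 - p) * np.exp(-k * t) + p - y

    y0_guess = float(y[np.argmin(t)])
    # crude rate guesses spanning fast to slow decay on the sampled span
    span = max(t.max() - t.min(), 1e-9)
    k_starts = [5.0 / span, 1.0 / span, 0.2 / span]
    if free_p:
        starts = [np.array([y0_guess, k, float(y.min())]) for k in k_starts]
        lo = np.array([-np.inf, -1e6, -np.inf])
        hi = np.array([np.inf, 1e6, np.inf])
    else:
        starts = [np.array([y0_guess, k]) for k in k_starts]
        lo = np.array([-np.inf, -1e6])
        hi = np.array([np.inf, 1e6])
    res = _multistart_lsq(residual, starts, (lo, hi))
    y0, k = float(res.x[0]), float(res.x[1])
    p = float(res.x[2]) if free_p else float(fix_plateau)
    if k <= 0:
        raise NotDecayingError("fitted rate k <= 0: the course does not decay")
    # inline r^2: a two-point exact fit is legitimate here
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(residual(res.x) ** 2)) / ss_tot
    k_lo, k_hi = _param_ci(res, 1, t.size, 0.99)
    t_half_hi = np.inf if k_lo <= 0 else np.log(2.0) / k_lo
    t_half_lo = np.log(2.0) / k_hi
    return DecayFit(
        k=k,
        t_half=float(np.log(2.0) / k),
        t_half_ci99=(float(t_half_lo), float(t_half_hi)),
        plateau=p,
        y0=y0,
        r2=r2,
    )
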