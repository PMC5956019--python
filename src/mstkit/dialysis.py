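"""Two-chamber equilibrium-dialysis model and K_d estimation.

Setup: a sample chamber (default 100 uL) holds diluted serum (antibody,
confined by the membrane) plus a deuterated tracer; a buffer chamber
(default 300 uL) holds the unlabeled competitor.  Small molecules cross the
membrane until their free concentrations are uniform; antibody-bound ligand
is confined to the sample chamber.  The measured quantity is b, the bound
fraction of the tracer in the sample chamber, from which binding-site
concentration (Mueller's equation) and, via a competition series, K_d are
estimated.

The homologous assumption is built in: the tracer is the deuterated form of
the competitor itself, so both share a single dissociation constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, least_squares

from .errors import DataError, DomainError, SolverError, UnidentifiableError
from .fitting import goodness_of_fit

__all__ = [
    "DialysisDesign",
    "DialysisState",
    "dialysis_equilibrium",
    "estimate_kd_from_competition",
]

#: default competitor series (nM, in the buffer chamber at t=0) bracketing
#: the displacement transition of the default design
DEFAULT_COMPETITOR_SERIES = (0.5, 1.5, 4.0, 10.0, 25.0, 60.0, 150.0, 400.0)


@dataclass(frozen=True)
class DialysisDesign:
    """Chamber volumes and starting concentrations of an ED experiment."""

    v_sample: float = 100.0  # uL
    v_buffer: float = 300.0  # uL
    tracer_total_in_sample: float = 5.0  # nM, in the sample chamber at t=0
    ab_sites_in_sample: float = 10.0  # nM binding sites, confined to sample
    competitor_series: tuple[float, ...] = field(default=DEFAULT_COMPETITOR_SERIES)

    def __post_init__(self) -> None:
        if self.v_sample <= 0 or self.v_buffer <= 0:
            raise DomainError("chamber volumes must be positive")
        if self.tracer_total_in_sample < 0 or self.ab_sites_in_sample < 0:
            raise DomainError("concentrations must be non-negative")
        object.__setattr__(self, "competitor_series", tuple(self.competitor_series))


@dataclass(frozen=True)
class DialysisState:
    """Equilibrium state of one dialysis cell.

    ``free_tracer`` / ``free_competitor`` are the uniform free
    concentrations (nM) across both chambers; ``bound_*_sample`` the
    antibody-bound concentrations in the sample chamber; ``b`` the bound
    fraction of total tracer in the sample chamber.
    """

    free_tracer: float
    free_competitor: float
    bound_tracer_sample: float
    bound_competitor_sample: float
    free_sites: float
    b: float


def dialysis_equilibrium(
    design: DialysisDesign,
    kd_tracer: float,
    ki_competitor: float,
    competitor: float,
) -> DialysisState:
    """Solve the coupled mass-action / membrane-partition balances.

    ``competitor`` is the starting concentration (nM) in the buffer chamber.
    With free-site concentration r, the tracer balance reads

        cT * (Vs + Vb) + (r * cT / Kd) * Vs = T0 * Vs

    (and similarly for the competitor with its starting moles L0*Vb), which
    gives each free concentration in closed form; the site balance
    g(r) = r + boundT(r) + boundL(r) - S is strictly increasing, so the
    physical root is unique and bracketed on [0, S].
    """
    if kd_tracer <= 0 or ki_competitor <= 0:
        raise DomainError("dissociation constants must be positive")
    if competitor < 0:
        raise DomainError("competitor concentration must be non-negative")
    vs, vb = design.v_sample, design.v_buffer
    vt = vs + vb
    t_moles = design.tracer_total_in_sample * vs
    l_moles = competitor * vb
    s = design.ab_sites_in_sample

    def free_concs(r: float) -> tuple[float, float]:
        c_t = t_moles / (vt + r * vs / kd_tracer)
        c_l = l_moles / (vt + r * vs / ki_competitor)
        return c_t, c_l

    if s == 0.0:
        r = 0.0
    else:

        def g(r: float) -> float:
            c_t, c_l = free_concs(r)
            return r + r * c_t / kd_tracer + r * c_l / ki_competitor - s

        try:
            r = brentq(g, 0.0, s, xtol=1e-300, rtol=1e-14, maxiter=300)
        except Exception as exc:  # pragma: no cover - bracket guaranteed
            raise SolverError(f"dialysis equilibrium did not converge: {exc}") from exc
    c_t, c_l = free_concs(r)
    bound_t = r * c_t / kd_tracer
    bound_l = r * c_l / ki_competitor
    total_t_sample = bound_t + c_t
    b = bound_t / total_t_sample if total_t_sample > 0 else 0.0
    return DialysisState(
        free_tracer=c_t,
        free_competitor=c_l,
        bound_tracer_sample=bound_t,
        bound_competitor_sample=bound_l,
        free_sites=r,
        b=b,
    )


def estimate_kd_from_competition(
    measured_b: Sequence[tuple[float, float]],
    design: DialysisDesign,
    ab_sites: float,
) -> tuple[float, float]:
    """Estimate K_d from a homologous ED competition series.

    ``measured_b`` is a list of (competitor nM, bound fraction b) pairs at a
    known binding-site concentration ``ab_sites``.  Because the tracer is
    the deuterated competitor, a single dissociation constant governs both
    species; it is recovered by least squares on log K_d against the forward
    dialysis model.  Returns ``(kd, r2)``.
    """
    pairs = [(float(c), float(b)) for c, b in measured_b]
    if len(pairs) < 6:
        raise DataError("need >= 6 competitor levels")
    concs = np.array([c for c, _ in pairs])
    bs = np.array([b for _, b in pairs])
    if np.ptp(bs) < 1e-12:
        raise UnidentifiableError("b identical at all competitor levels")
    dsn = DialysisDesign(
        v_sample=design.v_sample,
        v_buffer=design.v_buffer,
        tracer_total_in_sample=design.tracer_total_in_sample,
        ab_sites_in_sample=ab_sites,
        competitor_series=tuple(concs),
    )

    def predict(kd: float) -> np.ndarray:
        return np.array([dialysis_equilibrium(dsn, kd, kd, c).b for c in concs])

    def residual(x: np.ndarray) -> np.ndarray:
        return predict(math.exp(x[0])) - bs

    best = None
    for start in (-2.0, 0.0, 2.0, 5.0):  # log kd starts: 0.14 .. 150 nM
        res = least_squares(residual, np.array([start]), method="trf", xtol=1e-14, ftol=1e-14)
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise SolverError("K_d fit did not converge")
    kd = math.exp(float(best.x[0]))
    r2 = goodness_of_fit(bs, predict(kd))
    return kd, r2
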