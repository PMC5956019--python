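"""Closed-form and root-solved binding equilibria.

The module collects the equilibrium math behind tandem conventional /
competition MST analysis of antibody–hapten binding:

* binary antibody–tracer binding with ligand depletion (quadratic isotherm),
* the exact ternary one-site / two-ligand competitive equilibrium,
* conversion between IC50 and the competitor dissociation constant K_i,
* Mueller's equation for the total antibody binding-site concentration.

All concentrations are in nM; conversions belong at I/O boundaries.
"Antibody concentration" always means binding-site concentration (an IgG
carries two sites; dividing by two is the caller's concern).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import DegenerateSystemError, DomainError, SolverError

__all__ = [
    "EquilibriumState",
    "TernarySystem",
    "binary_bound_fraction",
    "ternary_equilibrium",
    "ic50_from_ki",
    "ki_from_ic50",
    "mueller_binding_sites",
    "average_binding_sites",
]

_KI_BRACKET = (1e-6, 1e9)  # nM, search range for ki_from_ic50


@dataclass(frozen=True)
class TernarySystem:
    """Total concentrations and constants of a two-ligand / one-site system.

    Attributes
    ----------
    i0 : float
        Total antibody binding-site concentration (nM).
    t0 : float
        Total labeled-tracer concentration (nM).
    l0 : float
        Total unlabeled-competitor concentration (nM).
    kd : float
        Tracer dissociation constant (nM).
    ki : float
        Competitor dissociation constant (nM).
    """

    i0: float
    t0: float
    l0: float
    kd: float
    ki: float

    def __post_init__(self) -> None:
        if min(self.i0, self.t0, self.l0) < 0:
            raise DomainError("total concentrations must be non-negative")
        if self.kd <= 0 or self.ki <= 0:
            raise DomainError("dissociation constants must be positive")


@dataclass(frozen=True)
class EquilibriumState:
    """Species concentrations (nM) of a solved ternary equilibrium."""

    free_sites: float
    bound_tracer: float
    bound_competitor: float
    free_tracer: float
    free_competitor: float


def binary_bound_fraction(ab_total: float, tracer_total: float, kd: float) -> float:
    """Fraction of tracer bound in a 1:1 equilibrium with ligand depletion.

    Solves the law of mass action for total site concentration ``ab_total``
    (A), total tracer ``tracer_total`` (T) and dissociation constant ``kd``::

        f = ((A + T + Kd) - sqrt((A + T + Kd)^2 - 4 A T)) / (2 T)

    evaluated in the numerically stable form ``2A / (s + sqrt(s^2 - 4AT))``
    with ``s = A + T + Kd``, which avoids cancellation for A << Kd.

    Returns a fraction in [0, 1]. Valid for any T, including T comparable to
    A (the depletion regime of MST titrations at sub-nM tracer is the easy
    case; the quadratic form is exact in all regimes).
    """
    if tracer_total <= 0:
        raise DegenerateSystemError("tracer_total must be > 0")
    if ab_total < 0 or kd <= 0:
        raise DomainError("ab_total >= 0 and kd > 0 required")
    if ab_total == 0:
        return 0.0
    a, t = float(ab_total), float(tracer_total)
    s = a + t + kd
    disc = s * s - 4.0 * a * t
    # disc >= (a - t)^2 + kd^2 > 0 always, but guard rounding
    root = math.sqrt(max(disc, 0.0))
    f = 2.0 * a / (s + root)
    return min(f, 1.0)


def ternary_equilibrium(sys: TernarySystem) -> EquilibriumState:
    """Solve the exact ternary competitive equilibrium.

    Two ligands (tracer T, competitor L) compete for one class of sites I:

        I + T <-> IT   with Kd = [I][T]/[IT]
        I + L <-> IL   with Ki = [I][L]/[IL]

    Writing r for the free-site concentration, the mass balances give

        bound_T = t0 * r / (r + Kd),   bound_L = l0 * r / (r + Ki)

    and the site balance g(r) = r + bound_T + bound_L - i0 = 0.  g is
    strictly increasing on [0, i0], so the physical root is unique and is
    found by bracketed root-finding to 1e-12 relative tolerance.  This is
    algebraically equivalent to the cubic closed form but unconditionally
    stable across the >8 decades of Kd/Ki met in hapten panels.
    """
    i0, t0, l0, kd, ki = sys.i0, sys.t0, sys.l0, sys.kd, sys.ki
    if i0 == 0.0:
        return EquilibriumState(0.0, 0.0, 0.0, t0, l0)

    def g(r: float) -> float:
        return r + t0 * r / (r + kd) + l0 * r / (r + ki) - i0

    if g(i0) <= 0:  # only when t0 == l0 == 0
        r = i0
    else:
        try:
            r = brentq(g, 0.0, i0, xtol=1e-300, rtol=1e-14, maxiter=300)
        except Exception as exc:  # pragma: no cover - bracket is guaranteed
            raise SolverError(f"ternary equilibrium did not converge: {exc}") from exc
    bound_t = t0 * r / (r + kd)
    bound_l = l0 * r / (r + ki)
    return EquilibriumState(
        free_sites=r,
        bound_tracer=bound_t,
        bound_competitor=bound_l,
        free_tracer=t0 - bound_t,
        free_competitor=l0 - bound_l,
    )


def bound_tracer(i0: float, t0: float, l0: float, kd: float, ki: float) -> float:
    """Bound-tracer concentration (nM) of the ternary equilibrium (convenience)."""
    return ternary_equilibrium(TernarySystem(i0, t0, l0, kd, ki)).bound_tracer


def ic50_from_ki(sys_base: TernarySystem) -> float:
    """Total competitor concentration at half-maximal tracer displacement.

    IC50 is defined on the *total* competitor axis as the point where the
    bound-tracer concentration is midway between its zero-competitor value
    and its infinite-competitor limit (zero).  bound_tracer(L) is strictly
    decreasing in L, so the IC50 is unique; it is located by bracketed
    root-finding on log L.  ``sys_base.l0`` is ignored (it only bounds the
    identifiable range in the inverse problem).
    """
    i0, t0, kd, ki = sys_base.i0, sys_base.t0, sys_base.kd, sys_base.ki
    if min(i0, t0, kd, ki) <= 0:
        raise DomainError("i0, t0, kd, ki must all be positive")
    b0 = bound_tracer(i0, t0, 0.0, kd, ki)
    if b0 <= 0:
        raise DegenerateSystemError("no tracer bound at zero competitor")
    target = 0.5 * b0

    def h(log_l: float) -> float:
        return bound_tracer(i0, t0, math.exp(log_l), kd, ki) - target

    lo, hi = math.log(1e-9), math.log(1e-9)
    # expand the upper bracket until the displacement passes the midpoint
    hi = math.log(max(ki, kd, i0, t0, 1.0))
    while h(hi) > 0:
        hi += math.log(10.0)
        if hi > math.log(1e15):  # pragma: no cover
            raise SolverError("IC50 bracket expansion failed")
    lo = hi
    while h(lo) < 0:
        lo -= math.log(10.0)
        if lo < math.log(1e-15):  # pragma: no cover
            raise SolverError("IC50 bracket expansion failed")
    return math.exp(brentq(h, lo, hi, rtol=1e-12, maxiter=200))


def ki_from_ic50(kd: float, i0: float, t0: float, l0: float, ic50: float) -> float:
    """Invert the competition experiment: K_i from a measured IC50.

    Inputs mirror what a competition MST analysis provides: the tracer
    dissociation constant ``kd``, the antibody binding-site concentration
    ``i0``, the tracer concentration ``t0``, the highest competitor
    concentration of the titration ``l0`` and the fitted ``ic50`` (all nM).

    The unique ``ki`` with ``ic50_from_ki(ki) == ic50`` is found by
    root-finding on log ki over [1e-6, 1e9] nM: since the infinite-competitor
    plateau is zero, the defining condition reduces to
    ``bound_tracer(L=ic50; ki) = bound_tracer(L=0)/2``, which is strictly
    increasing in ki — one ternary solve per iteration.

    Raises
    ------
    DomainError
        If ``ic50 > l0`` — the half-displacement point lies outside the
        titration range, so the IC50 (hence K_i) is not identifiable from
        this design.
    SolverError
        If no root exists in the bracket.
    """
    if min(kd, i0, t0, l0, ic50) <= 0:
        raise DomainError("all inputs must be positive")
    if ic50 > l0:
        raise DomainError(
            f"ic50 ({ic50:g} nM) exceeds the highest competitor concentration "
            f"l0 ({l0:g} nM); K_i is unidentifiable from this design"
        )
    target = 0.5 * bound_tracer(i0, t0, 0.0, kd, 1.0)  # ki value irrelevant at l0=0

    def h(log_ki: float) -> float:
        return bound_tracer(i0, t0, ic50, kd, math.exp(log_ki)) - target

    lo, hi = math.log(_KI_BRACKET[0]), math.log(_KI_BRACKET[1])
    if h(lo) * h(hi) > 0:
        raise SolverError("no K_i in [1e-6, 1e9] nM reproduces this IC50")
    return math.exp(brentq(h, lo, hi, rtol=1e-10, maxiter=200))


def mueller_binding_sites(b: float, tracer_total: float, kd: float) -> float:
    """Total antibody binding-site concentration from Mueller's equation.

    ``[Ab_t] = b [T_t] + b Kd / (1 - b)`` where ``b`` is the fraction of
    tracer bound in the absence of competitor, ``[T_t]`` the total tracer
    concentration and ``Kd`` the tracer dissociation constant.  This is the
    exact algebraic inverse of the binary depletion isotherm.
    """
    if not 0.0 <= b < 1.0:
        raise DomainError("b must lie in [0, 1)")
    if tracer_total < 0 or kd <= 0:
        raise DomainError("tracer_total >= 0 and kd > 0 required")
    return b * tracer_total + b * kd / (1.0 - b)


def average_binding_sites(estimates: Sequence[float]) -> float:
    """Arithmetic mean of binding-site concentration estimates (nM).

    The site concentration of a serum is estimated once per tracer ligand
    (e.g. once with the 6-AM tracer, once with the morphine tracer) and the
    estimates are averaged.
    """
    if len(estimates) == 0:
        raise DomainError("at least one estimate required")
    return float(np.mean([float(e) for e in estimates]))
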