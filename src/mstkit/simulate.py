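"""Seeded generators for every input the pipeline consumes.

No raw instrument data is deposited for this kind of experiment, so the
package ships forward models of the assays themselves: MST titration runs
(saturation and competition), serum degradation time courses, and
equilibrium-dialysis measurements.  Every generator is a pure function of
(parameters, seed), which makes the whole pipeline verifiable by parameter
recovery: simulate with known truth, analyze, compare.

The trace model is phenomenological — cold plateau, exponential approach to
the hot plateau after the IR laser switches on, back-diffusion after it
switches off, multiplicative count noise and slow photobleaching.  The
analysis only consumes window means, so Soret-level physics would add
nothing testable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .degradation import Condition, DegradationCourse
from .dialysis import DialysisDesign, dialysis_equilibrium
from .equilibria import TernarySystem, binary_bound_fraction, ternary_equilibrium
from .errors import DomainError
from .traces import MstTrace

__all__ = [
    "TitrationDesign",
    "TraceNoiseModel",
    "make_dilution_series",
    "simulate_saturation_run",
    "simulate_competition_run",
    "simulate_degradation_course",
    "simulate_dialysis_measurements",
]


@dataclass(frozen=True)
class TitrationDesign:
    """A serial-dilution titration design.

    The laboratory protocol: a working solution of the titrated species is
    serially diluted (1:1 by default) — the first tube is already one
    dilution step below the working stock — and each dilution is then mixed
    with an equal volume of the tracer (or tracer:antibody) solution, so
    final in-capillary concentrations are ``top_working_conc * mix_ratio /
    dilution_factor**j`` for j = 1..n_points.  E.g. a 16,000 nM working
    competitor yields a series topping out at 4,000 nM final.

    ``tracer_final`` is the constant in-capillary tracer concentration;
    ``antibody_sites_final`` the constant antibody binding-site
    concentration (competition mode only).
    """

    top_working_conc: float
    tracer_final: float
    n_points: int = 16
    dilution_factor: float = 2.0
    mix_ratio: float = 0.5
    antibody_sites_final: float | None = None

    def __post_init__(self) -> None:
        if self.n_points < 8:
            raise DomainError("n_points must be >= 8")
        if self.dilution_factor <= 1:
            raise DomainError("dilution_factor must exceed 1")
        if not 0 < self.mix_ratio < 1:
            raise DomainError("mix_ratio must lie in (0, 1)")
        if self.top_working_conc <= 0 or self.tracer_final <= 0:
            raise DomainError("concentrations must be positive")

    @classmethod
    def from_top_final(cls, top_final_conc: float, tracer_final: float, **kw) -> "TitrationDesign":
        """Build a design from the desired *final* top concentration."""
        d = kw.get("dilution_factor", 2.0)
        m = kw.get("mix_ratio", 0.5)
        return cls(top_working_conc=top_final_conc * d / m, tracer_final=tracer_final, **kw)

    @property
    def top_final_conc(self) -> float:
        return self.top_working_conc * self.mix_ratio / self.dilution_factor


@dataclass(frozen=True)
class TraceNoiseModel:
    """Phenomenological trace model parameters and noise levels.

    ``fnorm_unbound`` and ``response_amplitude`` are on the permille F_norm
    scale; the default amplitude is negative (bound tracer thermophoreses
    away faster, so the saturated F_norm plateau sits below the free one,
    matching downward displacement curves).  ``depletion_tau_*`` set the
    exponential approach to the hot plateau for fully bound / fully free
    tracer (mixtures interpolate); ``bleach_rate`` is a slow multiplicative
    fluorescence loss (fraction/s); ``noise_cv`` the per-sample
    multiplicative count noise.
    """

    fnorm_unbound: float = 1000.0  # permille
    response_amplitude: float = -50.0  # permille
    depletion_tau_bound_s: float = 1.5
    depletion_tau_unbound_s: float = 1.0
    bleach_rate: float = 2e-4  # fraction/s
    noise_cv: float = 0.005
    cold_counts: float = 1000.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise DomainError("noise_cv must be >= 0")
        if self.depletion_tau_bound_s <= 0 or self.depletion_tau_unbound_s <= 0:
            raise DomainError("depletion time constants must be positive")


def make_dilution_series(design: TitrationDesign) -> np.ndarray:
    """Final in-capillary concentrations of the titrated species, descending.

    ``top_working_conc * mix_ratio / dilution_factor**j`` for j = 1..n_points
    (the serial-dilution step itself dilutes the working stock once before
    the equal-volume mix with the tracer solution).
    """
    j = np.arange(1, design.n_points + 1)
    return design.top_working_conc * design.mix_ratio / design.dilution_factor ** j


def _build_trace(
    capillary_id: str,
    titrant_conc: float,
    fraction_bound: float,
    noise: TraceNoiseModel,
    rng: np.random.Generator,
    laser_on_s: float = 5.0,
    laser_off_s: float = 35.0,
    dt_s: float = 0.25,
) -> MstTrace:
    f = fraction_bound
    fnorm_target = noise.fnorm_unbound + noise.response_amplitude * f
    g_inf = fnorm_target / 1000.0
    tau = f * noise.depletion_tau_bound_s + (1.0 - f) * noise.depletion_tau_unbound_s
    t = np.arange(0.0, laser_off_s + 5.0 + dt_s / 2, dt_s)
    g = np.ones_like(t)
    hot = (t >= laser_on_s) & (t <= laser_off_s)
    g[hot] = 1.0 + (g_inf - 1.0) * (1.0 - np.exp(-(t[hot] - laser_on_s) / tau))
    after = t > laser_off_s
    g_off = 1.0 + (g_inf - 1.0) * (1.0 - math.exp(-(laser_off_s - laser_on_s) / tau))
    g[after] = 1.0 + (g_off - 1.0) * np.exp(-(t[after] - laser_off_s) / tau)
    counts = noise.cold_counts * g * np.exp(-noise.bleach_rate * t)
    if noise.noise_cv > 0:
        counts = counts * (1.0 + noise.noise_cv * rng.standard_normal(t.shape))
        counts = np.maximum(counts, 1e-6)  # counts are physical, strictly positive
    return MstTrace(
        capillary_id=capillary_id,
        titrant_conc=titrant_conc,
        time_s=t,
        fluorescence=counts,
        laser_on_s=laser_on_s,
        laser_off_s=laser_off_s,
    )


def simulate_saturation_run(
    design: TitrationDesign,
    kd: float,
    noise: TraceNoiseModel,
) -> list[MstTrace]:
    """Simulate a conventional-MST run: fixed tracer, titrated antibody.

    For each antibody-site concentration A in the dilution series the bound
    fraction follows the depletion-exact binary isotherm, the expected
    F_norm is ``unbound + amplitude * f``, and a full time trace is built
    around it.  Deterministic given ``noise.rng_seed``.
    """
    if kd <= 0:
        raise DomainError("kd must be positive")
    rng = np.random.default_rng(noise.rng_seed)
    traces = []
    for i, a in enumerate(make_dilution_series(design)):
        f = binary_bound_fraction(a, design.tracer_final, kd)
        traces.append(_build_trace(f"cap{i:02d}", a, f, noise, rng))
    return traces


def simulate_competition_run(
    design: TitrationDesign,
    kd_tracer: float,
    ki: float,
    noise: TraceNoiseModel,
) -> list[MstTrace]:
    """Simulate a competition-MST run: fixed tracer:antibody, titrated competitor.

    The bound-tracer fraction at each competitor concentration L comes from
    the exact ternary equilibrium at (i0 = antibody_sites_final,
    t0 = tracer_final, l0 = L).  Deterministic given ``noise.rng_seed``.
    """
    if kd_tracer <= 0 or ki <= 0:
        raise DomainError("dissociation constants must be positive")
    if design.antibody_sites_final is None:
        raise DomainError("competition design requires antibody_sites_final")
    rng = np.random.default_rng(noise.rng_seed)
    i0, t0 = design.antibody_sites_final, design.tracer_final
    traces = []
    for i, ell in enumerate(make_dilution_series(design)):
        st = ternary_equilibrium(TernarySystem(i0, t0, ell, kd_tracer, ki))
        traces.append(_build_trace(f"cap{i:02d}", ell, st.bound_tracer / t0, noise, rng))
    return traces


def _free_heroin(h_total: float, ab_sites: float, kd: float) -> float:
    """Free heroin at rapid binding equilibrium (stable quadratic form)."""
    if h_total <= 0:
        return 0.0
    if ab_sites == 0:
        return h_total
    s = ab_sites + h_total + kd
    bound = 2.0 * ab_sites * h_total / (s + math.sqrt(s * s - 4.0 * ab_sites * h_total))
    return h_total - bound


def simulate_degradation_course(
    condition: Condition,
    heroin_initial: float,
    ab_sites: float,
    kd_heroin: float,
    k_free: float,
    times: Sequence[float],
    noise_cv: float = 0.05,
    seed: int = 0,
) -> DegradationCourse:
    """Simulate a heroin degradation time course in dilute serum.

    Esterases hydrolyse only the *free* heroin; antibody binding is fast
    relative to hydrolysis, so the model integrates

        d[H_total]/dt = -k_free * [H_free]([H_total])

    with the free concentration given at each instant by the binary
    rapid-equilibrium solution against ``ab_sites`` at ``kd_heroin``.  With
    no antibody this reduces exactly to first-order decay; with heroin at or
    below the site concentration it produces the protection phenomenon
    (little degradation over hours).  This protected-kinetics ODE is a model
    of this package, built to reproduce the observed phenomenology, not a
    fitted enzymological mechanism.

    BUFFER courses use ``k_free = 0``; esterase-inhibited courses a reduced
    ``k_free``.  Multiplicative measurement noise (CV ``noise_cv``) is
    applied to every sampled concentration; deterministic given ``seed``.
    """
    from scipy.integrate import solve_ivp

    if k_free < 0:
        raise DomainError("k_free must be >= 0")
    if kd_heroin <= 0:
        raise DomainError("kd_heroin must be positive")
    t = np.asarray(list(times), dtype=float)
    if t[0] != 0:
        raise DomainError("times must start at 0")
    if k_free == 0.0 or heroin_initial == 0.0:
        conc = np.full_like(t, heroin_initial)
    else:
        sol = solve_ivp(
            lambda _t, y: [-k_free * _free_heroin(max(y[0], 0.0), ab_sites, kd_heroin)],
            (0.0, float(t[-1])),
            [heroin_initial],
            t_eval=t,
            rtol=1e-10,
            atol=1e-12 * heroin_initial,
            method="LSODA",
        )
        conc = np.maximum(sol.y[0], 0.0)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        conc = np.maximum(conc * (1.0 + noise_cv * rng.standard_normal(t.shape)), 0.0)
    return DegradationCourse(
        condition=condition,
        heroin_initial=heroin_initial,
        ab_sites=ab_sites,
        times=t,
        concentrations=conc,
    )


def simulate_dialysis_measurements(
    design: DialysisDesign,
    kd: float,
    noise_cv: float = 0.05,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """Simulate homologous ED competition measurements: (competitor nM, b).

    Evaluates the forward dialysis model across ``design.competitor_series``
    with a single dissociation constant for tracer and competitor (the
    tracer is the deuterated competitor) and applies multiplicative noise to
    the bound fraction b.  Deterministic given ``seed``.
    """
    if kd <= 0:
        raise DomainError("kd must be positive")
    rng = np.random.default_rng(seed)
    out = []
    for c in design.competitor_series:
        b = dialysis_equilibrium(design, kd, kd, c).b
        if noise_cv > 0:
            b = float(np.clip(b * (1.0 + noise_cv * rng.standard_normal()), 0.0, 1.0))
        out.append((float(c), float(b)))
    return out
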