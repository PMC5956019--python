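"""Multi-seed parameter-recovery studies.

A laboratory reports an affinity as mean +/- SD over replicate titrations;
the in-silico analogue is to rerun the full pipeline over many seeded
replicates of the same design and summarize the recovered parameter.  These
helpers drive the generator -> analysis loop for each assay type and return
the per-replicate estimates; they are what the acceptance checks and the
examples call.
"""

from __future__ import annotations

import numpy as np

from .degradation import Condition, analyze_course
from .dialysis import DialysisDesign, estimate_kd_from_competition
from .equilibria import ki_from_ic50
from .errors import DomainError, SolverError
from .fitting import Mode, TitrationSeries, fit_competition, fit_saturation
from .simulate import (
    TitrationDesign,
    TraceNoiseModel,
    simulate_competition_run,
    simulate_degradation_course,
    simulate_dialysis_measurements,
    simulate_saturation_run,
)
from .workflows import traces_to_points

__all__ = [
    "child_seeds",
    "saturation_recovery",
    "competition_recovery",
    "ed_recovery",
    "degradation_recovery",
]


def child_seeds(seed: int, n: int) -> np.ndarray:
    """Derive ``n`` independent child seeds (< 2^31) from one master seed."""
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def saturation_recovery(
    kd_true: float,
    top_final_sites: float,
    tracer_final: float,
    n_replicates: int,
    seed: int,
    exclude_top_point: bool = False,
) -> np.ndarray:
    """Recovered K_d per replicate of a conventional-MST design."""
    design = TitrationDesign.from_top_final(top_final_sites, tracer_final=tracer_final)
    out = []
    for s in child_seeds(seed, n_replicates):
        traces = simulate_saturation_run(
            design, kd=kd_true, noise=TraceNoiseModel(rng_seed=int(s))
        )
        pts = traces_to_points(traces, exclude_top_point=exclude_top_point)
        series = TitrationSeries(Mode.SATURATION, pts, tracer_total=tracer_final)
        out.append(fit_saturation(series).estimate)
    return np.asarray(out)


def competition_recovery(
    ki_true: float,
    kd_tracer: float,
    top_working_competitor: float,
    n_replicates: int,
    seed: int,
    antibody_sites: float = 10.0,
    tracer_final: float = 0.25,
) -> np.ndarray:
    """Recovered K_i per replicate of the heterologous pipeline.

    Each replicate runs trace simulation -> F_norm -> IC50 fit -> exact
    ternary conversion.  Replicates whose fitted IC50 falls below the
    zero-affinity floor of the design are left-censored at the conversion
    bracket minimum (1e-6 nM); ones whose IC50 exceeds the titration range
    are right-censored at +inf.  The median over replicates is insensitive
    to either as long as censoring stays in the minority.
    """
    design = TitrationDesign(
        top_working_conc=top_working_competitor,
        tracer_final=tracer_final,
        antibody_sites_final=antibody_sites,
    )
    out = []
    for s in child_seeds(seed, n_replicates):
        traces = simulate_competition_run(
            design, kd_tracer=kd_tracer, ki=ki_true, noise=TraceNoiseModel(rng_seed=int(s))
        )
        pts = traces_to_points(traces)
        series = TitrationSeries(
            Mode.COMPETITION, pts, tracer_total=tracer_final,
            antibody_sites=antibody_sites, tracer_kd=kd_tracer,
        )
        fit = fit_competition(series)
        l0 = max(p.titrant_conc for p in pts)
        try:
            out.append(ki_from_ic50(kd_tracer, antibody_sites, tracer_final, l0, fit.estimate))
        except DomainError:
            out.append(np.inf)  # IC50 beyond the titration range
        except SolverError:
            out.append(1e-6)  # IC50 below the zero-affinity floor
    return np.asarray(out)


def ed_recovery(
    kd_true: float,
    n_replicates: int,
    seed: int,
    design: DialysisDesign | None = None,
) -> np.ndarray:
    """Recovered K_d per replicate of the homologous ED competition assay."""
    design = design or DialysisDesign(ab_sites_in_sample=10.0)
    out = []
    for s in child_seeds(seed, n_replicates):
        data = simulate_dialysis_measurements(design, kd=kd_true, seed=int(s))
        kd, _ = estimate_kd_from_competition(data, design, design.ab_sites_in_sample)
        out.append(kd)
    return np.asarray(out)


def degradation_recovery(
    t_half_true: float,
    n_replicates: int,
    seed: int,
    heroin_initial: float = 4000.0,
    times=(0.0, 0.25, 0.5, 1.0, 2.0, 3.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Fitted (t_half, r^2) per replicate of an unprotected serum course."""
    k = np.log(2.0) / t_half_true
    t_halves, r2s = [], []
    for s in child_seeds(seed, n_replicates):
        course = simulate_degradation_course(
            Condition.PRE_IMMUNE, heroin_initial, 0.0, 1.0, k, list(times), seed=int(s)
        )
        verdict = analyze_course(course)
        if verdict.fit is not None:
            t_halves.append(verdict.fit.t_half)
            r2s.append(verdict.r2)
    return np.asarray(t_halves), np.asarray(r2s)
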