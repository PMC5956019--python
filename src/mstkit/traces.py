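"""Thermophoresis trace processing: F_norm, QC and fraction bound.

An MST capillary yields a fluorescence time trace F(t): a steady "cold"
baseline, a drop (or rise) after the IR laser switches on as molecules
migrate in the temperature gradient, and back-diffusion after the laser
switches off.  The binding readout is the normalized fluorescence

    F_norm = F_h / F_c * 1000   (permille)

where F_c is the mean steady-state fluorescence in a window before laser-on
and F_h the mean in a window late in the laser-on phase.  Bound and free
tracer thermophorese differently, so F_norm shifts with the bound fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np

from .errors import ConfigError, DataError, DegenerateSystemError, WindowError

__all__ = [
    "QcFlag",
    "MstTrace",
    "AnalysisWindows",
    "FnormPoint",
    "compute_fnorm",
    "default_windows",
    "hot_window_grid",
    "select_hot_window",
    "qc_capillaries",
    "fraction_bound",
]


class QcFlag(str, Enum):
    """Capillary-level quality-control flags."""

    BASELINE_OUTLIER = "BASELINE_OUTLIER"
    BLEACHING = "BLEACHING"
    EXCLUDED_TOP_POINT = "EXCLUDED_TOP_POINT"


@dataclass(frozen=True)
class MstTrace:
    """One capillary's fluorescence time series.

    Parameters
    ----------
    capillary_id : str
        Identifier of the capillary within a run.
    titrant_conc : float
        Final in-capillary concentration of the titrated species (nM):
        antibody sites in saturation mode, competitor in competition mode.
    time_s, fluorescence : arrays
        Strictly increasing timestamps (s) and strictly positive counts.
    laser_on_s, laser_off_s : float
        Times the IR laser switched on and off.
    """

    capillary_id: str
    titrant_conc: float
    time_s: np.ndarray
    fluorescence: np.ndarray
    laser_on_s: float = 5.0
    laser_off_s: float = 35.0

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "fluorescence", f)
        if t.ndim != 1 or f.shape != t.shape:
            raise DataError("time_s and fluorescence must be equal-length 1-D arrays")
        if t.size and np.any(np.diff(t) <= 0):
            raise DataError("time_s must be strictly increasing")
        if np.any(f <= 0):
            raise DataError("fluorescence must be strictly positive")
        if not self.laser_on_s < self.laser_off_s:
            raise DataError("laser_on_s must precede laser_off_s")
        if np.sum(t < self.laser_on_s) < 3:
            raise DataError("need >= 3 samples before laser_on_s")
        if np.sum((t >= self.laser_on_s) & (t <= self.laser_off_s)) < 3:
            raise DataError("need >= 3 samples during the laser-on phase")


@dataclass(frozen=True)
class AnalysisWindows:
    """Cold/hot averaging windows (closed intervals, seconds)."""

    cold_window: tuple[float, float]
    hot_window: tuple[float, float]

    def __post_init__(self) -> None:
        for name, (a, b) in (("cold", self.cold_window), ("hot", self.hot_window)):
            if not a < b:
                raise WindowError(f"{name}_window must have start < end")


@dataclass(frozen=True)
class FnormPoint:
    """One titration point: concentration, F_norm and QC annotation."""

    titrant_conc: float
    fnorm: float
    cold_mean: float
    qc_flags: frozenset[QcFlag] = field(default_factory=frozenset)

    @property
    def excluded(self) -> bool:
        return bool(self.qc_flags)


def default_windows(trace: MstTrace) -> AnalysisWindows:
    """Default analysis windows for a trace.

    Cold: [laser_on - 4 s, laser_on - 0.5 s] (the pre-laser baseline).
    Hot: [laser_off - 1.5 s, laser_off] (late in the laser-on phase, where
    the thermophoretic depletion has effectively reached steady state).
    """
    return AnalysisWindows(
        cold_window=(trace.laser_on_s - 4.0, trace.laser_on_s - 0.5),
        hot_window=(trace.laser_off_s - 1.5, trace.laser_off_s),
    )


def _window_mean(trace: MstTrace, window: tuple[float, float], label: str) -> float:
    lo, hi = window
    if lo < trace.time_s[0] or hi > trace.time_s[-1]:
        raise WindowError(f"{label} window [{lo}, {hi}] s outside trace time span")
    mask = (trace.time_s >= lo) & (trace.time_s <= hi)
    if mask.sum() < 2:
        raise WindowError(f"{label} window contains fewer than 2 samples")
    return float(trace.fluorescence[mask].mean())


def compute_fnorm(trace: MstTrace, windows: AnalysisWindows) -> FnormPoint:
    """F_norm of one capillary: hot-window mean over cold-window mean x 1000.

    Window means (not single samples) are used on both sides, so the result
    is invariant under uniform rescaling of the counts.
    """
    c0, c1 = windows.cold_window
    if c1 > trace.laser_on_s:
        raise WindowError("cold window must end at or before laser_on_s")
    h0, h1 = windows.hot_window
    if h0 <= trace.laser_on_s or h1 > trace.laser_off_s:
        raise WindowError("hot window must lie within (laser_on_s, laser_off_s]")
    cold = _window_mean(trace, windows.cold_window, "cold")
    hot = _window_mean(trace, windows.hot_window, "hot")
    return FnormPoint(
        titrant_conc=trace.titrant_conc,
        fnorm=hot / cold * 1000.0,
        cold_mean=cold,
    )


def hot_window_grid(trace: MstTrace, width_s: float = 1.0, step_s: float = 1.0) -> list[AnalysisWindows]:
    """Candidate windows: ``width_s``-wide hot windows tiling the laser-on phase.

    Window starts run from laser_on + 1 s to laser_off - width_s; the cold
    window is the default one.  Mirrors the manual F_h point selection of
    instrument software, but as an enumerable grid.
    """
    cold = default_windows(trace).cold_window
    starts = np.arange(trace.laser_on_s + 1.0, trace.laser_off_s - width_s + 1e-9, step_s)
    return [AnalysisWindows(cold, (float(s), float(s + width_s))) for s in starts]


def select_hot_window(
    traces: Sequence[MstTrace],
    windows_grid: Sequence[AnalysisWindows],
) -> AnalysisWindows:
    """Pick the hot window maximizing response amplitude over fit residual.

    For each candidate window the titration's F_norm values are computed and
    a preliminary hyperbolic saturation curve is fitted; the score is
    |amplitude| / residual SD.  Deterministic: the grid is scanned in order
    of window start and a candidate replaces the incumbent only on a
    strictly greater score, so ties go to the earliest window.

    Raises
    ------
    ConfigError
        Fewer than 2 candidate windows.
    DegenerateSystemError
        Zero response amplitude for every candidate (nothing to select on).
    """
    if len(windows_grid) < 2:
        raise ConfigError("need at least 2 candidate windows")
    if len(traces) < 8:
        raise DataError("need >= 8 traces to select a hot window")
    concs = np.array([tr.titrant_conc for tr in traces], dtype=float)
    pos = concs[concs > 0]
    if pos.size and np.log10(pos.max() / pos.min()) < 3.0:
        raise DataError("titration must span >= 3 decades of titrant concentration")

    order = np.argsort([w.hot_window[0] for w in windows_grid], kind="stable")
    best: AnalysisWindows | None = None
    best_score = -np.inf
    any_amplitude = False
    # tiny residual floor so the score stays finite and amplitude-dominated
    # on (near-)noiseless data instead of becoming scale-invariant
    floor = 1e-9 * float(np.median([tr.fluorescence.mean() for tr in traces])) or 1e-12
    for idx in order:
        win = windows_grid[idx]
        y = np.array([compute_fnorm(tr, win).fnorm for tr in traces])
        amp, resid_sd = _preliminary_saturation_score(concs, y)
        if amp == 0.0:
            continue
        any_amplitude = True
        score = abs(amp) / (resid_sd + floor)
        if score > best_score:
            best, best_score = win, score
    if not any_amplitude or best is None:
        raise DegenerateSystemError("zero response amplitude in every candidate window")
    return best


def _preliminary_saturation_score(conc: np.ndarray, fnorm: np.ndarray) -> tuple[float, float]:
    """Amplitude and residual SD of a quick hyperbolic fit (for window scoring).

    The preliminary model F = U + (B-U) * c/(c+K) is linear in (U, B) given
    K, so a small log-grid over K with linear least squares suffices; this
    is a scoring heuristic, not the production fitter.
    """
    best = None
    for k in np.logspace(-2, 4, 25):
        h = conc / (conc + k)
        x = np.column_stack([np.ones_like(h), h])
        coef, *_ = np.linalg.lstsq(x, fnorm, rcond=None)
        resid = fnorm - x @ coef
        ss = float(resid @ resid)
        if best is None or ss < best[0]:
            best = (ss, float(coef[1]), len(fnorm))
    ss, amp, n = best
    if abs(amp) < 1e-12:
        return 0.0, 0.0
    dof = max(n - 3, 1)
    return amp, float(np.sqrt(ss / dof))


def qc_capillaries(
    points: Sequence[FnormPoint],
    traces: Sequence[MstTrace] | None = None,
    baseline_tol: float = 0.10,
    bleach_tol: float | None = None,
    exclude_top_point: bool = False,
) -> list[FnormPoint]:
    """Annotate titration points with capillary QC flags.

    Pure annotation: F_norm values are never altered and every point is
    retained; downstream fitters skip flagged points.

    * ``BASELINE_OUTLIER`` — cold-window mean deviates from the series
      median by more than ``baseline_tol`` (fraction, default 0.10).
    * ``BLEACHING`` — |least-squares slope of the pre-laser fluorescence|
      exceeds ``bleach_tol`` (counts/s).  When ``bleach_tol`` is None the
      threshold is 1%/s of that capillary's cold mean.  Requires ``traces``.
    * ``EXCLUDED_TOP_POINT`` — the highest titrant concentration, flagged on
      request (``exclude_top_point=True``): the abrupt buffer-composition
      change at the top of a serial dilution can distort the MST signal.
    """
    if len(points) < 4:
        raise DataError("need >= 4 points for QC")
    median_cold = float(np.median([p.cold_mean for p in points]))
    trace_by_conc = {}
    if traces is not None:
        for tr in traces:
            trace_by_conc[tr.titrant_conc] = tr
    top_conc = max(p.titrant_conc for p in points)

    out: list[FnormPoint] = []
    for p in points:
        flags = set(p.qc_flags)
        if median_cold > 0 and abs(p.cold_mean - median_cold) > baseline_tol * median_cold:
            flags.add(QcFlag.BASELINE_OUTLIER)
        tr = trace_by_conc.get(p.titrant_conc)
        if tr is not None:
            mask = tr.time_s < tr.laser_on_s
            slope = float(np.polyfit(tr.time_s[mask], tr.fluorescence[mask], 1)[0])
            tol = bleach_tol if bleach_tol is not None else 0.01 * p.cold_mean
            if abs(slope) > tol:
                flags.add(QcFlag.BLEACHING)
        if exclude_top_point and p.titrant_conc == top_conc:
            flags.add(QcFlag.EXCLUDED_TOP_POINT)
        out.append(replace(p, qc_flags=frozenset(flags)))
    return out


def fraction_bound(x: float, fnorm_unbound: float, fnorm_bound: float) -> float:
    """Map an F_norm value onto the fraction-bound scale.

        fraction = (x - F_norm,Unbound) / (F_norm,Bound - F_norm,Unbound)

    The response amplitude is the plateau difference.  Noisy values may fall
    slightly outside [0, 1]; they are deliberately not clipped (clipping
    before least squares would bias the fit).
    """
    amplitude = fnorm_bound - fnorm_unbound
    if amplitude == 0:
        raise DegenerateSystemError("zero response amplitude")
    return (x - fnorm_unbound) / amplitude
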