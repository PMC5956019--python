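"""CSV dialects and JSON reports.

Long-format trace CSV (one file per titration run):
    capillary_id, titrant_conc_nM, time_s, fluorescence
F_norm table CSV:
    titrant_conc_nM, fnorm_permille, cold_mean, qc_flags (semicolon-joined)
Degradation CSV:
    condition, heroin_initial_nM, ab_sites_nM, time_h, conc_nM
ED CSV:
    competitor_nM, b_measured
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .degradation import Condition, DegradationCourse
from .errors import DataError
from .traces import FnormPoint, MstTrace, QcFlag

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "write_fnorm_table",
    "read_fnorm_table",
    "write_degradation_csv",
    "read_degradation_csv",
    "write_ed_csv",
    "read_ed_csv",
    "write_json_report",
]


def write_trace_csv(traces: Sequence[MstTrace], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "capillary_id": tr.capillary_id,
                "titrant_conc_nM": tr.titrant_conc,
                "time_s": tr.time_s,
                "fluorescence": tr.fluorescence,
            }
        )
        for tr in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trace_csv(
    path: str | Path,
    laser_on_s: float = 5.0,
    laser_off_s: float = 35.0,
) -> list[MstTrace]:
    """Read a long-format trace CSV.  Laser timings are run metadata, not
    stored per row, so they are passed here."""
    df = pd.read_csv(path)
    required = {"capillary_id", "titrant_conc_nM", "time_s", "fluorescence"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"trace CSV missing columns: {sorted(missing)}")
    if df.empty:
        raise DataError(f"trace CSV {path} is empty")
    traces = []
    for cid, grp in df.groupby("capillary_id", sort=False):
        grp = grp.sort_values("time_s")
        concs = grp["titrant_conc_nM"].unique()
        if len(concs) != 1:
            raise DataError(f"capillary {cid} has multiple titrant concentrations")
        traces.append(
            MstTrace(
                capillary_id=str(cid),
                titrant_conc=float(concs[0]),
                time_s=grp["time_s"].to_numpy(),
                fluorescence=grp["fluorescence"].to_numpy(),
                laser_on_s=laser_on_s,
                laser_off_s=laser_off_s,
            )
        )
    return traces


def write_fnorm_table(points: Sequence[FnormPoint], path: str | Path) -> None:
    pd.DataFrame(
        {
            "titrant_conc_nM": [p.titrant_conc for p in points],
            "fnorm_permille": [p.fnorm for p in points],
            "cold_mean": [p.cold_mean for p in points],
            "qc_flags": [";".join(sorted(f.value for f in p.qc_flags)) for p in points],
        }
    ).to_csv(path, index=False)


def read_fnorm_table(path: str | Path) -> list[FnormPoint]:
    df = pd.read_csv(path)
    required = {"titrant_conc_nM", "fnorm_permille"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"F_norm table missing columns: {sorted(missing)}")
    points = []
    for _, row in df.iterrows():
        raw = row.get("qc_flags", "")
        flags = frozenset(
            QcFlag(tok) for tok in str(raw).split(";") if tok and tok != "nan"
        )
        points.append(
            FnormPoint(
                titrant_conc=float(row["titrant_conc_nM"]),
                fnorm=float(row["fnorm_permille"]),
                cold_mean=float(row.get("cold_mean", float("nan"))),
                qc_flags=flags,
            )
        )
    return points


def write_degradation_csv(courses: Sequence[DegradationCourse], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "condition": c.condition.value,
                "heroin_initial_nM": c.heroin_initial,
                "ab_sites_nM": c.ab_sites,
                "time_h": c.times,
                "conc_nM": c.concentrations,
            }
        )
        for c in courses
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_degradation_csv(path: str | Path) -> list[DegradationCourse]:
    df = pd.read_csv(path)
    required = {"condition", "heroin_initial_nM", "ab_sites_nM", "time_h", "conc_nM"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"degradation CSV missing columns: {sorted(missing)}")
    courses = []
    keys = ["condition", "heroin_initial_nM", "ab_sites_nM"]
    for (cond, h0, sites), grp in df.groupby(keys, sort=False):
        grp = grp.sort_values("time_h")
        courses.append(
            DegradationCourse(
                condition=Condition(cond),
                heroin_initial=float(h0),
                ab_sites=float(sites),
                times=grp["time_h"].to_numpy(),
                concentrations=grp["conc_nM"].to_numpy(),
            )
        )
    return courses


def write_ed_csv(measurements: Sequence[tuple[float, float]], path: str | Path) -> None:
    pd.DataFrame(measurements, columns=["competitor_nM", "b_measured"]).to_csv(
        path, index=False
    )


def read_ed_csv(path: str | Path) -> list[tuple[float, float]]:
    df = pd.read_csv(path)
    required = {"competitor_nM", "b_measured"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"ED CSV missing columns: {sorted(missing)}")
    return [(float(c), float(b)) for c, b in zip(df["competitor_nM"], df["b_measured"])]


def write_json_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=str) + "\n")
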