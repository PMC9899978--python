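"""Spatial ischemia maps and per-animal, per-time-point summaries.

Zone classification follows the activation-delay rule: a lead whose
activation time during early ischemia (1, 2.5 or 5 min) exceeds its baseline
value by more than the delay threshold (default 5 ms) belongs to the core
ischemic zone; leads grid-adjacent to the core form the border zone; the
rest are remote.  An optional relative mode uses a >20% delay of the
baseline AT instead of the absolute threshold.

Summaries are cross-lead extrema per animal and time-point: maximal AT,
dispersion of repolarization (max - min RT), minimal/maximal/mean ARIc,
ECG extrema (maximal QT/QTc, minimal QTp/QTp_c) and the global
Tpeak-Tend dispersion.  Missing leads are excluded per metric, never
imputed.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .beats import EPICARDIAL, SURFACE_ECG, bazett
from .synth import frontier_leads

__all__ = [
    "classify_zones",
    "dispersion_of_repolarization",
    "tpeak_tend_dispersion",
    "rtc_map",
    "summarize_timepoint",
    "summarize_cohort",
    "flag_early_prolongation",
    "DELAY_THRESHOLD_MS",
    "PROLONGATION_THRESHOLD_MS",
]

logger = logging.getLogger(__name__)

DELAY_THRESHOLD_MS = 5.0
RELATIVE_DELAY_FRAC = 0.2
PROLONGATION_THRESHOLD_MS = 10.0
ISCHEMIA_TIME_POINTS = (1.0, 2.5, 5.0)
EARLY_TIME_POINTS = (1.0, 2.5)


def classify_zones(
    at_table: pd.DataFrame,
    grid: pd.DataFrame,
    delay_threshold: float = DELAY_THRESHOLD_MS,
    mode: str = "abs",
    ischemia_points: Sequence[float] = ISCHEMIA_TIME_POINTS,
    diagonal: bool = False,
) -> pd.Series:
    """Core/border/remote label per lead from baseline-vs-ischemia AT delay.

    ``at_table`` is indexed by lead with one column per time-point (baseline
    column 0 required).  A lead is core when its AT delay relative to
    baseline strictly exceeds ``delay_threshold`` ms (``mode='abs'``) or 20%
    of its baseline AT (``mode='rel'``) at *any* of ``ischemia_points``.
    Border leads are non-core leads grid-adjacent (4-neighborhood by default)
    to a core lead.  Leads with a missing baseline AT are excluded and
    logged.
    """
    if 0.0 not in at_table.columns:
        raise ValueError("at_table must contain a baseline (0 min) column")
    if mode not in ("abs", "rel"):
        raise ValueError("mode must be 'abs' or 'rel'")
    points = [t for t in ischemia_points if t in at_table.columns]
    if not points:
        raise ValueError("no ischemia time-points present in at_table")
    baseline = at_table[0.0]
    usable = at_table.loc[baseline.notna()]
    excluded = at_table.index.difference(usable.index)
    if len(excluded):
        logger.warning("classify_zones: excluding leads with missing baseline AT: %s",
                       list(excluded))
    delay = usable[points].sub(usable[0.0], axis=0)
    if mode == "abs":
        is_core = (delay > delay_threshold).any(axis=1)
    else:
        is_core = delay.gt(RELATIVE_DELAY_FRAC * usable[0.0], axis=0).any(axis=1)
    core = set(usable.index[is_core])
    border = frontier_leads(grid, core, diagonal) & set(usable.index)
    labels = pd.Series(
        ["core" if l in core else "border" if l in border else "remote"
         for l in usable.index],
        index=usable.index, name="zone")
    return labels


def dispersion_of_repolarization(rts: Iterable[float]) -> float:
    """DOR: maximal minus minimal repolarization time across leads (ms)."""
    vals = np.asarray([v for v in rts if v is not None and np.isfinite(v)], dtype=float)
    if vals.size < 2:
        raise ValueError("dispersion of repolarization needs >= 2 valid RTs")
    return float(vals.max() - vals.min())


def tpeak_tend_dispersion(
    t_peaks: Iterable[float], t_ends: Iterable[float], rr: float
) -> Tuple[float, float]:
    """Global Tpeak-Tend dispersion: latest T end minus earliest T peak.

    Returns the natural value and its Bazett-corrected counterpart.
    """
    peaks = np.asarray([v for v in t_peaks if np.isfinite(v)], dtype=float)
    ends = np.asarray([v for v in t_ends if np.isfinite(v)], dtype=float)
    if peaks.size == 0 or ends.size == 0:
        raise ValueError("no valid T-wave measurements")
    tpe = float(ends.max() - peaks.min())
    return tpe, float(bazett(tpe, rr))


def rtc_map(at: pd.Series, aric: pd.Series) -> pd.Series:
    """Rate-corrected repolarization time map: RTc = AT + ARIc, per lead."""
    if set(at.index) != set(aric.index):
        raise ValueError("AT and ARIc maps cover different lead sets")
    return (at + aric.reindex(at.index)).rename("rtc")


def _ext(series: pd.Series, fn) -> float:
    vals = series.dropna()
    return float(fn(vals)) if len(vals) else np.nan


def summarize_timepoint(measurements: pd.DataFrame) -> Dict[str, float]:
    """Cross-lead extrema for one animal at one time-point.

    Expects long-format measurement rows (both lead kinds may be present).
    Missing leads are skipped per metric; the count of contributing leads is
    logged.  DOR and Tpe need at least the minimal valid lead sets, else NaN.
    """
    if measurements.empty:
        raise ValueError("empty measurement set")
    epi = measurements[measurements["lead_kind"] == EPICARDIAL]
    ecg = measurements[measurements["lead_kind"] == SURFACE_ECG]
    rr = float(measurements["rr"].dropna().median())
    out: Dict[str, float] = {"rr": rr}
    out["at_max"] = _ext(epi["at"], np.max) if len(epi) else np.nan
    out["aric_min"] = _ext(epi["aric"], np.min) if len(epi) else np.nan
    out["aric_max"] = _ext(epi["aric"], np.max) if len(epi) else np.nan
    out["aric_mean"] = _ext(epi["aric"], np.mean) if len(epi) else np.nan
    try:
        out["dor"] = dispersion_of_repolarization(epi["rt"]) if len(epi) else np.nan
    except ValueError:
        out["dor"] = np.nan
    out["qt_max"] = _ext(ecg["qt"], np.max) if len(ecg) else np.nan
    out["qtc_max"] = _ext(ecg["qtc"], np.max) if len(ecg) else np.nan
    out["qtp_min"] = _ext(ecg["qtp"], np.min) if len(ecg) else np.nan
    out["qtp_c_min"] = _ext(ecg["qtp_c"], np.min) if len(ecg) else np.nan
    if len(ecg):
        try:
            out["tpe"], out["tpe_c"] = tpeak_tend_dispersion(
                ecg["t_peak"], ecg["t_end"], rr)
        except ValueError:
            out["tpe"] = out["tpe_c"] = np.nan
    else:
        out["tpe"] = out["tpe_c"] = np.nan
    logger.debug("summarize_timepoint: %d epicardial, %d ECG leads contributed",
                 epi["at"].notna().sum(), ecg["qt"].notna().sum())
    return out


def flag_early_prolongation(
    aric_max_by_time: Mapping[float, float],
    threshold: float = PROLONGATION_THRESHOLD_MS,
    early_points: Sequence[float] = EARLY_TIME_POINTS,
) -> bool:
    """True iff maximal ARIc rose strictly more than ``threshold`` ms above
    baseline at any of the early occlusion time-points (1 and/or 2.5 min)."""
    if 0.0 not in aric_max_by_time or not np.isfinite(aric_max_by_time[0.0]):
        raise ValueError("baseline (0 min) maximal ARIc is required")
    base = aric_max_by_time[0.0]
    present = [t for t in early_points if t in aric_max_by_time
               and np.isfinite(aric_max_by_time[t])]
    if not present:
        raise ValueError("no early time-point (1 / 2.5 min) available")
    return bool(any(aric_max_by_time[t] - base > threshold for t in present))


def summarize_cohort(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per-animal, per-time-point map summaries plus the prolongation flag.

    Returns one row per (animal, time_point) with the cross-lead extrema of
    :func:`summarize_timepoint` and a per-animal ``prolongation_flag`` column
    (NaN-safe: the flag is missing if baseline or both early points are)."""
    rows = []
    for (animal, t), grp in measurements.groupby(["animal", "time_point"], sort=True):
        row = {"animal": animal, "time_point": t}
        row.update(summarize_timepoint(grp))
        rows.append(row)
    out = pd.DataFrame(rows)
    flags = {}
    for animal, grp in out.groupby("animal"):
        by_time = dict(zip(grp["time_point"], grp["aric_max"]))
        try:
            flags[animal] = flag_early_prolongation(by_time)
        except ValueError:
            flags[animal] = np.nan
    out["prolongation_flag"] = out["animal"].map(flags)
    return out
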