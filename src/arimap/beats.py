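"""Per-beat fiducial detection on unipolar electrograms and surface ECG.

Conventions used throughout:

* Activation time (AT) is the instant of the steepest *negative* slope
  (dV/dt minimum) of the unipolar electrogram within the QRS window.
* Repolarization time (RT) is the instant of the steepest *positive* slope
  (dV/dt maximum) within the T-wave window (Wyatt method); the rule is the
  same for positive and negative T waves.
* All fiducials are reported in milliseconds relative to QRS onset; the
  onset itself is reported in milliseconds from the start of the trace.
* Derivatives are central differences of the low-pass-smoothed signal
  (zero-phase Gaussian smoothing, default half-power cutoff 40 Hz); raw
  finite differences at 4 kHz are noise-dominated.
* Rate correction is Bazett's: interval divided by the square root of the
  preceding RR interval expressed in seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "SignalTrace",
    "FiducialSet",
    "IntervalMeasurements",
    "NoBeatError",
    "WindowError",
    "smoothed",
    "slope",
    "bazett",
    "detect_qrs_onset",
    "detect_at",
    "detect_rt",
    "detect_t_peak_end",
    "measure_beat",
    "measure_dataset",
]

# -- analysis defaults (configurable per call) --------------------------------

DERIV_LPF_HZ = 40.0       # half-power cutoff of the derivative smoother (QRS)
T_DERIV_LPF_HZ = 20.0     # cutoff for the T-wave (Wyatt RT) derivative: the T
                          # upstroke is slow and shallow, so its derivative
                          # extremum needs heavier smoothing to be noise-stable
ECG_T_LPF_HZ = 15.0       # cutoff for ECG T-apex / tangent T-end detection
QRS_WIN_MS = 80.0         # QRS search window: onset .. onset + 80 ms
T_WIN_START_MS = 100.0    # T window starts at AT + 100 ms
T_WIN_END_FRAC = 0.9      # .. and ends at 90% of the RR interval (beat time)
ECG_T_START_MS = 120.0    # T search start for surface ECG (ms after onset)
ONSET_FRACTION = 0.1      # onset = first |dV/dt| crossing of this beat-max fraction
ONSET_QUIET_MS = 10.0     # required sub-threshold stretch preceding the onset
ISO_WINDOW_MS = 40.0      # PR-segment window for the isoelectric level

EPICARDIAL = "epicardial_unipolar"
SURFACE_ECG = "surface_ecg"


class NoBeatError(ValueError):
    """Raised when a trace contains no detectable beat (e.g. flat signal)."""


class WindowError(ValueError):
    """Raised for empty search windows or windows outside the trace."""


@dataclass
class SignalTrace:
    """One lead's sampled waveform plus the metadata the pipeline carries."""

    samples: np.ndarray
    fs: float
    lead_id: str
    lead_kind: str = EPICARDIAL
    animal_id: str = ""
    time_point: float = 0.0
    rr: Optional[float] = None  # preceding RR interval, ms

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("trace must be a 1-D array with at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")
        if self.lead_kind not in (EPICARDIAL, SURFACE_ECG):
            raise ValueError(f"unknown lead kind {self.lead_kind!r}")

    @property
    def duration_ms(self) -> float:
        return self.samples.size / self.fs * 1000.0

    def beat_rr(self) -> float:
        """RR interval in ms; falls back to the trace duration for one-beat traces."""
        return float(self.rr) if self.rr else self.duration_ms


@dataclass
class FiducialSet:
    """Per-beat landmark times. All times except ``qrs_onset`` are relative to it."""

    qrs_onset: float               # ms from trace start
    rr: float                      # ms
    at: Optional[float] = None     # epicardial leads
    rt: Optional[float] = None
    t_peak: Optional[float] = None  # ECG leads
    t_end: Optional[float] = None


@dataclass
class IntervalMeasurements:
    """Raw and Bazett-corrected interval measurements for one beat."""

    ari: Optional[float] = None
    aric: Optional[float] = None
    qt: Optional[float] = None
    qtc: Optional[float] = None
    qtp: Optional[float] = None
    qtp_c: Optional[float] = None


# -- derivative estimation ----------------------------------------------------


def lpf_sigma_ms(lpf_hz: float) -> float:
    """Gaussian-kernel sigma (ms) whose half-power frequency equals ``lpf_hz``."""
    return 1000.0 * math.sqrt(math.log(2.0)) / (2.0 * math.pi * lpf_hz)


def smoothed(samples: np.ndarray, fs: float, lpf_hz: float = DERIV_LPF_HZ) -> np.ndarray:
    """Zero-phase low-pass (Gaussian) smoothing of a sampled trace."""
    sigma = lpf_sigma_ms(lpf_hz) * fs / 1000.0
    return gaussian_filter1d(np.asarray(samples, dtype=float), sigma, mode="nearest")


def slope(samples: np.ndarray, fs: float, lpf_hz: float = DERIV_LPF_HZ) -> np.ndarray:
    """Smoothed first derivative in signal units per millisecond."""
    return np.gradient(smoothed(samples, fs, lpf_hz)) * fs / 1000.0


def _window_indices(trace: SignalTrace, start_ms: float, end_ms: float) -> tuple[int, int]:
    """Sample-index bounds [i0, i1] for a window given in ms from trace start."""
    n = trace.samples.size
    i0 = int(math.ceil(start_ms * trace.fs / 1000.0))
    i1 = int(math.floor(end_ms * trace.fs / 1000.0))
    if i1 >= n:
        raise WindowError(f"window [{start_ms}, {end_ms}] ms extends past trace end")
    i0 = max(i0, 0)
    if i1 <= i0:
        raise WindowError(f"empty search window [{start_ms}, {end_ms}] ms")
    return i0, i1


# -- detectors ----------------------------------------------------------------


def detect_qrs_onset(
    trace: SignalTrace,
    fraction: float = ONSET_FRACTION,
    quiet_ms: float = ONSET_QUIET_MS,
    lpf_hz: float = DERIV_LPF_HZ,
    deriv: Optional[np.ndarray] = None,
) -> float:
    """QRS onset in ms from trace start.

    The onset is the first instant at which the rectified smoothed derivative
    exceeds ``fraction`` of its beat maximum, located by walking backward from
    the global derivative extremum until the rectified derivative has stayed
    below threshold for ``quiet_ms``.  The crossing is linearly interpolated
    between samples, so the returned time has sub-sample resolution.  The rule
    is invariant to amplitude scaling and to constant offsets.
    """
    if deriv is None:
        deriv = slope(trace.samples, trace.fs, lpf_hz)
    a = np.abs(deriv)
    peak = int(np.argmax(a))
    if a[peak] <= 1e-12 * (np.ptp(trace.samples) + 1e-300) or np.ptp(trace.samples) == 0:
        raise NoBeatError("flat trace: no beat detected")
    thr = fraction * a[peak]
    below = a < thr
    quiet_n = max(int(round(quiet_ms * trace.fs / 1000.0)), 1)
    # run[i] = number of consecutive below-threshold samples ending at i
    idx = np.arange(a.size)
    last_above = np.maximum.accumulate(np.where(~below, idx, -1))
    run = np.where(below, idx - last_above, 0)
    # earliest threshold crossing (up to the extremum) preceded by a quiet
    # stretch -- skips brief sub-threshold dips inside the QRS complex while
    # ignoring the quiet ST gap between far-field and local QRS components
    cand = np.nonzero((run[:peak] >= quiet_n) & ~below[1 : peak + 1])[0] + 1
    onset_idx = int(cand[0]) if cand.size else None
    if onset_idx is None:
        # no quiet stretch (beat starts at trace edge): first crossing from start
        above = np.nonzero(~below[: peak + 1])[0]
        onset_idx = int(above[0]) if above.size else peak
    i = onset_idx
    if i == 0 or a[i] <= a[i - 1]:
        t = float(i)
    else:
        t = (i - 1) + (thr - a[i - 1]) / (a[i] - a[i - 1])
    return t / trace.fs * 1000.0


def detect_at(
    trace: SignalTrace,
    qrs_window: tuple[float, float] = (0.0, QRS_WIN_MS),
    onset: Optional[float] = None,
    lpf_hz: float = DERIV_LPF_HZ,
    deriv: Optional[np.ndarray] = None,
) -> float:
    """Activation time: dV/dt minimum within the QRS window, ms from QRS onset.

    ``qrs_window`` is given in ms relative to the QRS onset.  Ties are broken
    by the earliest sample.
    """
    if deriv is None:
        deriv = slope(trace.samples, trace.fs, lpf_hz)
    if onset is None:
        onset = detect_qrs_onset(trace, lpf_hz=lpf_hz, deriv=deriv)
    i0, i1 = _window_indices(trace, onset + qrs_window[0], onset + qrs_window[1])
    d = deriv
    idx = i0 + int(np.argmin(d[i0 : i1 + 1]))  # argmin -> earliest tie
    return idx / trace.fs * 1000.0 - onset


def detect_rt(
    trace: SignalTrace,
    t_window: Optional[tuple[float, float]] = None,
    onset: Optional[float] = None,
    at: Optional[float] = None,
    lpf_hz: float = T_DERIV_LPF_HZ,
    deriv: Optional[np.ndarray] = None,
) -> float:
    """Repolarization time (Wyatt): dV/dt maximum in the T window, ms from onset.

    The default window runs from AT + 100 ms to 90% of the RR interval
    (measured in beat time from the trace start).  The rule is polarity
    independent: for both positive and negative T waves the end of local
    repolarization is the steepest positive slope.
    """
    if onset is None:
        onset = detect_qrs_onset(trace)
    if t_window is None:
        if at is None:
            at = detect_at(trace, onset=onset)
        start = onset + at + T_WIN_START_MS
        end = T_WIN_END_FRAC * trace.beat_rr()
        t_window_abs = (start, end)
    else:
        t_window_abs = (onset + t_window[0], onset + t_window[1])
    i0, i1 = _window_indices(trace, *t_window_abs)
    if deriv is None:
        deriv = slope(trace.samples, trace.fs, lpf_hz)
    idx = i0 + int(np.argmax(deriv[i0 : i1 + 1]))
    return idx / trace.fs * 1000.0 - onset


def detect_t_peak_end(
    trace: SignalTrace,
    t_window: Optional[tuple[float, float]] = None,
    onset: Optional[float] = None,
    lpf_hz: float = ECG_T_LPF_HZ,
    iso_window_ms: float = ISO_WINDOW_MS,
) -> tuple[float, float]:
    """T-wave apex and terminus for a surface-ECG lead, ms from QRS onset.

    The apex is the largest absolute deflection from the isoelectric level
    (mean of the PR segment, the ``iso_window_ms`` preceding the QRS onset)
    within the T window.  The terminus uses the tangent method: the line
    through the steepest post-apex returning slope intersected with the
    isoelectric level.  Both rules are polarity independent; for a biphasic
    T the dominant deflection's apex is returned.
    """
    if trace.lead_kind != SURFACE_ECG:
        raise ValueError("T peak/end detection applies to surface ECG leads")
    if onset is None:
        onset = detect_qrs_onset(trace)
    s = smoothed(trace.samples, trace.fs, lpf_hz)
    d = np.gradient(s) * trace.fs / 1000.0
    j0, j1 = _window_indices(trace, max(onset - iso_window_ms, 0.0), onset)
    # the isoelectric level comes from the QRS-band signal: the heavier T-wave
    # smoothing smears QRS energy back into the PR segment and would bias it
    iso = float(np.mean(smoothed(trace.samples, trace.fs, DERIV_LPF_HZ)[j0 : j1 + 1]))
    if t_window is None:
        t_window_abs = (onset + ECG_T_START_MS, T_WIN_END_FRAC * trace.beat_rr())
    else:
        t_window_abs = (onset + t_window[0], onset + t_window[1])
    i0, i1 = _window_indices(trace, *t_window_abs)
    dev = np.abs(s[i0 : i1 + 1] - iso)
    ipk = i0 + int(np.argmax(dev))
    sign = 1.0 if s[ipk] >= iso else -1.0
    if ipk >= i1:
        raise WindowError("T apex at window edge: cannot place tangent")
    seg = -sign * d[ipk : i1 + 1]  # steepest slope returning toward baseline
    itan = ipk + int(np.argmax(seg))
    if abs(d[itan]) < 1e-12:
        raise NoBeatError("degenerate T wave: no returning slope")
    t_tan = itan / trace.fs * 1000.0
    t_end = t_tan + (s[itan] - iso) / (-d[itan])
    t_peak = ipk / trace.fs * 1000.0 - onset
    t_end -= onset
    if not t_peak < t_end:
        raise NoBeatError("T terminus does not follow the apex")
    return t_peak, t_end


# -- intervals ----------------------------------------------------------------


def bazett(interval, rr):
    """Bazett rate correction: ``interval / sqrt(rr in seconds)``.

    Applied identically to ARI, QT and QTp.  ``bazett(x, 1000) == x``.
    Accepts scalars or arrays.
    """
    rr_arr = np.asarray(rr, dtype=float)
    if np.any(rr_arr <= 0):
        raise ValueError("RR interval must be positive")
    out = np.asarray(interval, dtype=float) / np.sqrt(rr_arr / 1000.0)
    return float(out) if np.isscalar(interval) and np.isscalar(rr) else out


def measure_beat(
    trace: SignalTrace,
    lpf_hz: float = DERIV_LPF_HZ,
    t_lpf_hz: float = T_DERIV_LPF_HZ,
    ecg_t_lpf_hz: float = ECG_T_LPF_HZ,
    qrs_window: tuple[float, float] = (0.0, QRS_WIN_MS),
    t_window: Optional[tuple[float, float]] = None,
) -> tuple[FiducialSet, IntervalMeasurements]:
    """Full measurement chain for a single beat.

    Epicardial leads get AT, RT, ARI and ARIc; surface-ECG leads get
    T-peak/T-end, QT/QTc and QTp/QTp_c.  The beat's own preceding RR is used
    for rate correction.  Multi-beat traces are measured on the first beat.
    """
    rr = trace.beat_rr()
    n_beat = int(round(rr / 1000.0 * trace.fs))
    if trace.samples.size > n_beat + 1:
        trace = SignalTrace(
            trace.samples[: n_beat + 1], trace.fs, trace.lead_id, trace.lead_kind,
            trace.animal_id, trace.time_point, trace.rr,
        )
    d_qrs = slope(trace.samples, trace.fs, lpf_hz)
    onset = detect_qrs_onset(trace, lpf_hz=lpf_hz, deriv=d_qrs)
    fids = FiducialSet(qrs_onset=onset, rr=rr)
    meas = IntervalMeasurements()
    if trace.lead_kind == EPICARDIAL:
        fids.at = detect_at(trace, qrs_window, onset=onset, lpf_hz=lpf_hz, deriv=d_qrs)
        fids.rt = detect_rt(trace, t_window, onset=onset, at=fids.at, lpf_hz=t_lpf_hz)
        meas.ari = fids.rt - fids.at
        meas.aric = bazett(meas.ari, rr)
    else:
        fids.t_peak, fids.t_end = detect_t_peak_end(
            trace, t_window, onset=onset, lpf_hz=ecg_t_lpf_hz)
        meas.qt = fids.t_end
        meas.qtp = fids.t_peak
        meas.qtc = bazett(meas.qt, rr)
        meas.qtp_c = bazett(meas.qtp, rr)
    return fids, meas


_TABLE_COLUMNS = [
    "animal", "time_point", "lead", "lead_kind", "rr",
    "at", "rt", "ari", "aric", "qt", "qtc", "qtp", "qtp_c", "t_peak", "t_end", "ok",
]


def measure_dataset(traces: Sequence[SignalTrace], **opts) -> pd.DataFrame:
    """Measure every trace, returning the long-format measurement table.

    A lead on which detection fails is recorded with NaN measurements and
    ``ok == False`` rather than aborting the run.
    """
    rows = []
    for tr in traces:
        row = {
            "animal": tr.animal_id, "time_point": tr.time_point,
            "lead": tr.lead_id, "lead_kind": tr.lead_kind, "rr": tr.beat_rr(),
        }
        try:
            fids, meas = measure_beat(tr, **opts)
        except (NoBeatError, WindowError, ValueError):
            row.update({k: np.nan for k in _TABLE_COLUMNS[5:-1]})
            row["ok"] = False
        else:
            row.update(
                at=fids.at, rt=fids.rt, ari=meas.ari, aric=meas.aric,
                qt=meas.qt, qtc=meas.qtc, qtp=meas.qtp, qtp_c=meas.qtp_c,
                t_peak=fids.t_peak, t_end=fids.t_end, ok=True,
            )
            row = {k: (np.nan if v is None else v) for k, v in row.items()}
        rows.append(row)
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)
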