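"""Synthetic porcine coronary-occlusion cohort generator.

Emulates the data-generating process the analysis pipeline assumes: 32-64
unipolar epicardial leads on a rectangular plate sampled at 4 kHz, a 12-lead
surface ECG at 1028 Hz, snapshot recordings at baseline and at 1, 2.5, 5 and
10 min of occlusion, a contiguous core ischemic zone with activation delay
and ST elevation, a biphasic border-zone ARI time-course (early prolongation,
later shortening), and a ventricular-fibrillation outcome drawn from a
logistic model on the animal's true maximal rate-corrected QT at 2.5 min.

Beat morphology is parametric: every waveform is a sum of smooth Gaussian
steps (integrated Gaussian bumps), so the locations of the derivative extrema
-- which define the activation and repolarization fiducials -- are placed
exactly by construction.  Only those extremum locations, the ST-segment
offset and the T-wave polarity are contractual; the remaining shape constants
are cosmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from numpy.random import Generator, SeedSequence, default_rng
from scipy.special import expit, ndtr

from .beats import (
    EPICARDIAL,
    SURFACE_ECG,
    DERIV_LPF_HZ,
    ECG_T_LPF_HZ,
    SignalTrace,
    lpf_sigma_ms,
)

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "SyntheticDataset",
    "make_beat_waveform",
    "make_ecg_beat",
    "generate_cohort",
    "make_grid",
    "grid_neighbors",
    "frontier_leads",
    "snr_noise_sd",
    "vf_model_for",
    "NOMINAL_ONSET_MS",
    "MIN_TRUE_AT_MS",
]

# -- beat-shape constants (ms / mV unless noted) ------------------------------

NOMINAL_ONSET_MS = 70.0   # QRS onset position within every generated trace
MIN_TRUE_AT_MS = 24.0     # morphology floor: AT closer to onset than this would
                          # merge the intrinsic deflection with the far-field R wave
MIN_TRUE_ARI_MS = 120.0
_FIT_MARGIN_MS = 132.0    # trailing room required after RT for the T wave to finish

_EPI_SHAPE = dict(
    r_amp=1.0, r_sigma=3.0,          # far-field R upstroke at the QRS onset
    s_depth=0.6, qrs_sigma=3.5,      # intrinsic deflection (the AT marker)
    s_rec_delay=18.0, s_rec_sigma=5.0,
    t_amp=0.35, t_sigma=11.0,        # T upstroke (the Wyatt RT marker)
    t_fall_sigma=14.0, t_gap=60.0,
    close_sigma=10.0, close_from_end=45.0,
)

_ECG_SHAPE = dict(
    r_amp=0.8, r_sigma=3.0,
    s_depth=0.5, qrs_sigma=3.5,
    s_rec_delay=18.0, s_rec_sigma=5.0,
    defl_from_onset=30.0,
    t_amp=0.3, t_up_sigma=20.0, t_down_sigma=30.0, t_up_gap=45.0,
)


def _onset_lead_ms(r_amp: float, r_sigma: float, s_depth: float,
                   qrs_sigma: float, lpf_hz: float, fraction: float = 0.1) -> float:
    """Distance from the R-bump centre back to the fractional-threshold onset.

    The rectified smoothed derivative peaks at the intrinsic deflection with
    magnitude (r_amp + s_depth) / (sigma_eff * sqrt(2 pi)); the onset is where
    the R-limb Gaussian derivative first exceeds ``fraction`` of that.
    """
    sf = lpf_sigma_ms(lpf_hz)
    se = math.hypot(r_sigma, sf)
    sq = math.hypot(qrs_sigma, sf)
    thr = fraction * (r_amp + s_depth) / (sq * math.sqrt(2.0 * math.pi))
    arg = r_amp / (thr * se * math.sqrt(2.0 * math.pi))
    if arg <= 1.0:
        raise ValueError("onset threshold exceeds the R-limb peak slope")
    return se * math.sqrt(2.0 * math.log(arg))


def _steps_to_signal(t_ms: np.ndarray, comps: Sequence[Tuple[float, float, float]]) -> np.ndarray:
    """Evaluate a sum of smooth steps: sum of h * Phi((t - mu) / sigma).

    Each step is evaluated only inside mu +/- 8 sigma (it is 0 / h outside to
    well below float precision), which keeps cohort-scale synthesis fast.
    """
    v = np.zeros_like(t_ms)
    for mu, sigma, h in comps:
        i0 = int(np.searchsorted(t_ms, mu - 8.0 * sigma))
        i1 = int(np.searchsorted(t_ms, mu + 8.0 * sigma))
        v[i0:i1] += h * ndtr((t_ms[i0:i1] - mu) / sigma)
        v[i1:] += h
    return v


def _build_epi_components(true_at: float, true_ari: float, rr: float, st: float,
                          polarity: int, lpf_hz: float) -> List[Tuple[float, float, float]]:
    p = _EPI_SHAPE
    lead = _onset_lead_ms(p["r_amp"], p["r_sigma"], p["s_depth"], p["qrs_sigma"], lpf_hz)
    mu_r = NOMINAL_ONSET_MS + lead
    at_abs = NOMINAL_ONSET_MS + true_at
    rt_abs = at_abs + true_ari
    comps = [
        (mu_r, p["r_sigma"], p["r_amp"]),
        (at_abs, p["qrs_sigma"], -(p["r_amp"] + p["s_depth"])),
        (at_abs + p["s_rec_delay"], p["s_rec_sigma"], p["s_depth"] + st),
    ]
    if polarity >= 0:
        comps += [(rt_abs, p["t_sigma"], p["t_amp"]),
                  (rt_abs + p["t_gap"], p["t_fall_sigma"], -p["t_amp"])]
    else:
        comps += [(rt_abs - p["t_gap"], p["t_fall_sigma"], -p["t_amp"]),
                  (rt_abs, p["t_sigma"], p["t_amp"])]
    if st != 0.0:
        comps.append((rr - p["close_from_end"], p["close_sigma"], -st))
    return comps


def make_beat_waveform(
    true_at: float,
    true_ari: float,
    rr: float,
    st_shift: float = 0.0,
    fs: float = 4000.0,
    noise_sd: float = 0.0,
    rng: Optional[Generator] = None,
    t_polarity: int = 1,
    amplitude: float = 1.0,
    lead_id: str = "L00",
    animal_id: str = "",
    time_point: float = 0.0,
    n_beats: int = 1,
    lpf_hz: float = DERIV_LPF_HZ,
) -> SignalTrace:
    """Generate one (or ``n_beats`` repeated) unipolar epicardial beat(s).

    ``true_at`` and ``true_ari`` are in ms relative to the QRS onset, which is
    placed at ``NOMINAL_ONSET_MS`` from the trace start.  The noiseless
    waveform's steepest negative slope inside the QRS window falls at
    ``true_at`` and its steepest positive slope inside the T window at
    ``true_at + true_ari``, each to within a small fraction of a sample; the
    ST segment is offset by ``st_shift``.  Gaussian noise of SD ``noise_sd``
    is added when requested (``rng`` required).
    """
    if not (0.0 < true_at < true_at + true_ari < rr):
        raise ValueError("fiducials must satisfy 0 < AT < AT + ARI < RR")
    if true_at < MIN_TRUE_AT_MS:
        raise ValueError(f"true_at below the {MIN_TRUE_AT_MS} ms morphology floor")
    if true_ari < MIN_TRUE_ARI_MS:
        raise ValueError(f"true_ari below the {MIN_TRUE_ARI_MS} ms morphology floor")
    if NOMINAL_ONSET_MS + true_at + true_ari + _FIT_MARGIN_MS > rr:
        raise ValueError("AT + ARI too large for this RR: beat does not fit")
    comps = _build_epi_components(true_at, true_ari, rr, st_shift, t_polarity, lpf_hz)
    n = int(round(rr / 1000.0 * fs))
    t_ms = np.arange(n) / fs * 1000.0
    clean = amplitude * _steps_to_signal(t_ms, comps)
    if n_beats > 1:
        clean = np.tile(clean, n_beats)
    if noise_sd > 0.0:
        if rng is None:
            raise ValueError("rng is required when noise_sd > 0")
        clean = clean + rng.normal(0.0, noise_sd, clean.size)
    return SignalTrace(clean, fs, lead_id, EPICARDIAL, animal_id, time_point, rr)


def _build_ecg_components(qt_target: float, rr: float, polarity: int,
                          lpf_hz: float) -> List[Tuple[float, float, float]]:
    p = _ECG_SHAPE
    lead = _onset_lead_ms(p["r_amp"], p["r_sigma"], p["s_depth"], p["qrs_sigma"], lpf_hz)
    mu_r = NOMINAL_ONSET_MS + lead
    defl = NOMINAL_ONSET_MS + p["defl_from_onset"]
    sd_eff = math.hypot(p["t_down_sigma"], lpf_sigma_ms(ECG_T_LPF_HZ))
    # tangent method on a smooth step ends ~ sigma*sqrt(2*pi)/2 past the step centre
    t_down = NOMINAL_ONSET_MS + qt_target - 0.5 * math.sqrt(2.0 * math.pi) * sd_eff
    t_up = t_down - p["t_up_gap"]
    sgn = 1.0 if polarity >= 0 else -1.0
    return [
        (mu_r, p["r_sigma"], p["r_amp"]),
        (defl, p["qrs_sigma"], -(p["r_amp"] + p["s_depth"])),
        (defl + p["s_rec_delay"], p["s_rec_sigma"], p["s_depth"]),
        (t_up, p["t_up_sigma"], sgn * p["t_amp"]),
        (t_down, p["t_down_sigma"], -sgn * p["t_amp"]),
    ]


def _smoothed_eval(t: np.ndarray, comps: Sequence[Tuple[float, float, float]],
                   lpf_hz: float) -> Tuple[np.ndarray, np.ndarray]:
    """Analytically low-pass-smoothed signal and derivative on a time grid.

    Gaussian smoothing of a Gaussian step is a wider Gaussian step, so the
    smoothed waveform is exact, not a numerical convolution.
    """
    sf = lpf_sigma_ms(lpf_hz)
    s = np.zeros_like(t)
    d = np.zeros_like(t)
    for mu, sigma, h in comps:
        sig = math.hypot(sigma, sf)
        z = (t - mu) / sig
        s += h * ndtr(z)
        d += h * np.exp(-0.5 * z * z) / (sig * math.sqrt(2.0 * math.pi))
    return s, d


def _analytic_ecg_fiducials(comps: Sequence[Tuple[float, float, float]], rr: float,
                            grid_ms: float = 0.05) -> Dict[str, float]:
    """Reference fiducials of the noiseless ECG beat, on a fine analytic grid.

    Applies the same rules the detectors use -- fractional-threshold onset on
    the QRS-band derivative, apex / tangent T-end on the T-band smoothed
    waveform -- at 0.05 ms resolution.
    """
    t = np.arange(0.0, rr, grid_ms)
    s_qrs, d_qrs = _smoothed_eval(t, comps, DERIV_LPF_HZ)
    a = np.abs(d_qrs)
    thr = 0.1 * a.max()
    i = int(np.argmax(a >= thr))
    onset = t[i - 1] + grid_ms * (thr - a[i - 1]) / (a[i] - a[i - 1]) if i > 0 else t[0]
    s, d = _smoothed_eval(t, comps, ECG_T_LPF_HZ)
    j = (t >= onset - 40.0) & (t <= onset)
    iso = float(np.mean(s_qrs[j]))  # QRS-band signal: unbiased PR estimate
    w = (t >= onset + 120.0) & (t <= 0.9 * rr)
    tw, sw, dw = t[w], s[w], d[w]
    ipk = int(np.argmax(np.abs(sw - iso)))
    sgn = 1.0 if sw[ipk] >= iso else -1.0
    itan = ipk + int(np.argmax(-sgn * dw[ipk:]))
    t_end = tw[itan] + (sw[itan] - iso) / (-dw[itan])
    return {
        "qrs_onset": float(onset),
        "t_peak": float(tw[ipk] - onset),
        "t_end": float(t_end - onset),
    }


def make_ecg_beat(
    qt_target: float,
    rr: float,
    fs: float = 1028.0,
    noise_sd: float = 0.0,
    rng: Optional[Generator] = None,
    t_polarity: int = 1,
    amplitude: float = 1.0,
    lead_id: str = "ECG1",
    animal_id: str = "",
    time_point: float = 0.0,
    n_beats: int = 1,
    lpf_hz: float = DERIV_LPF_HZ,
) -> Tuple[SignalTrace, Dict[str, float]]:
    """Generate one surface-ECG beat aimed at a QT interval of ``qt_target`` ms.

    Returns the trace together with its reference fiducials (QRS onset,
    T apex and tangent-method T terminus) computed analytically on the
    noiseless waveform; those reference values -- not the nominal target --
    are the beat's ground truth.
    """
    if not 150.0 < qt_target < rr - _FIT_MARGIN_MS + 30.0:
        raise ValueError("QT target incompatible with this RR")
    comps = _build_ecg_components(qt_target, rr, t_polarity, lpf_hz)
    truth = _analytic_ecg_fiducials(comps, rr)
    n = int(round(rr / 1000.0 * fs))
    t_ms = np.arange(n) / fs * 1000.0
    clean = amplitude * _steps_to_signal(t_ms, comps)
    if n_beats > 1:
        clean = np.tile(clean, n_beats)
    if noise_sd > 0.0:
        if rng is None:
            raise ValueError("rng is required when noise_sd > 0")
        clean = clean + rng.normal(0.0, noise_sd, clean.size)
    trace = SignalTrace(clean, fs, lead_id, SURFACE_ECG, animal_id, time_point, rr)
    return trace, truth


def snr_noise_sd(samples: np.ndarray, snr_db: float) -> float:
    """Noise SD giving the requested signal-to-noise ratio for this waveform."""
    x = np.asarray(samples, dtype=float)
    rms = float(np.sqrt(np.mean((x - x.mean()) ** 2)))
    return rms * 10.0 ** (-snr_db / 20.0)


# -- lead grid ----------------------------------------------------------------


def make_grid(rows: int, cols: int) -> pd.DataFrame:
    """Rectangular electrode plate: lead_id with (row, col) placements."""
    leads = [
        {"lead": f"L{r * cols + c:02d}", "row": r, "col": c}
        for r in range(rows) for c in range(cols)
    ]
    return pd.DataFrame(leads)


def grid_neighbors(grid: pd.DataFrame, diagonal: bool = False) -> Dict[str, List[str]]:
    """Adjacency lists (4-neighborhood by default, 8 with ``diagonal``)."""
    pos = {(int(r), int(c)): l for l, r, c in zip(grid["lead"], grid["row"], grid["col"])}
    steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if diagonal:
        steps += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    out: Dict[str, List[str]] = {}
    for (r, c), l in pos.items():
        out[l] = [pos[(r + dr, c + dc)] for dr, dc in steps if (r + dr, c + dc) in pos]
    return out


def frontier_leads(grid: pd.DataFrame, core: Sequence[str], diagonal: bool = False) -> set:
    """Leads grid-adjacent to the core but not in it (the border zone)."""
    nbrs = grid_neighbors(grid, diagonal)
    core_set = set(core)
    out = set()
    for l in core_set:
        out.update(n for n in nbrs[l] if n not in core_set)
    return out


def _grow_core(rng: Generator, grid: pd.DataFrame, size: int) -> set:
    """Random contiguous patch of ``size`` leads grown by frontier accretion."""
    nbrs = grid_neighbors(grid)
    leads = list(grid["lead"])
    start = leads[int(rng.integers(len(leads)))]
    core = {start}
    frontier = set(nbrs[start])
    while len(core) < size and frontier:
        pick = sorted(frontier)[int(rng.integers(len(frontier)))]
        core.add(pick)
        frontier.update(nbrs[pick])
        frontier -= core
    return core


# -- configuration ------------------------------------------------------------


def vf_model_for(or_per_ms: float, center_qtc_ms: float = 458.0) -> Tuple[float, float]:
    """Logistic VF model (intercept, slope) with a given odds ratio per ms of
    maximal QTc and a 50% event probability at ``center_qtc_ms``."""
    slope = math.log(or_per_ms)
    return (-slope * center_qtc_ms, slope)


def _profile(d: Dict[float, float], t: float) -> float:
    return float(d.get(t, 0.0))


@dataclass
class GeneratorConfig:
    """Study-design parameters of the virtual occlusion experiment.

    Defaults emulate an 18-pig cohort: 48 epicardial leads on a 6x8 plate at
    4 kHz, 12 surface-ECG leads at 1028 Hz, snapshots at 0/1/2.5/5/10 min,
    RR ~534 ms, baseline AT ~27 ms and ARI ~241 ms (ARIc ~330 ms), a core
    activation delay reaching ~25 ms, a biphasic border ARI course peaking at
    +24 ms at 1-2.5 min, and a VF odds ratio of 1.024 per ms of maximal QTc.
    """

    n_animals: int = 18
    n_leads: int = 48
    grid_shape: Tuple[int, int] = (6, 8)
    fs_egm: float = 4000.0
    fs_ecg: float = 1028.0
    time_points: Tuple[float, ...] = (0.0, 1.0, 2.5, 5.0, 10.0)
    # cycle length: between-animal lognormal with a small within-animal drift
    rr_mean: float = 534.0
    rr_sd: float = 97.0
    rr_within_cv: float = 0.02
    # baseline fiducials: animal-level mean shift + per-lead spread (ms)
    baseline_at_mean: float = 27.0
    baseline_at_sd: float = 3.5
    at_animal_sd: float = 3.0
    baseline_ari_mean: float = 241.0
    baseline_ari_sd: float = 11.0
    ari_animal_sd: float = 23.0
    at_tp_jitter_sd: float = 0.5
    ari_tp_jitter_sd: float = 3.0
    # ischemia dynamics (ms added to the zone at each time-point)
    core_at_delay_profile: Dict[float, float] = field(
        default_factory=lambda: {0.0: 0.0, 1.0: 4.0, 2.5: 25.0, 5.0: 28.0, 10.0: 30.0})
    border_ari_delta_profile: Dict[float, float] = field(
        default_factory=lambda: {0.0: 0.0, 1.0: 24.0, 2.5: 24.0, 5.0: -10.0, 10.0: -30.0})
    core_ari_delta_profile: Dict[float, float] = field(
        default_factory=lambda: {0.0: 0.0, 1.0: -15.0, 2.5: -45.0, 5.0: -60.0, 10.0: -80.0})
    st_shift_mv: float = 0.2
    noise_sd: float = 0.02
    core_frac_range: Tuple[float, float] = (0.2, 0.4)
    neg_t_frac: float = 0.5
    # surface ECG
    n_ecg_leads: int = 12
    ecg_qt_offset_mean: float = 20.0
    ecg_qt_offset_sd: float = 8.0
    ecg_qt_jitter_sd: float = 2.0
    ecg_qtp_gap_mean: float = 60.0
    ecg_qtp_gap_sd: float = 6.0
    ecg_neg_t_frac: float = 0.2
    # outcome model: logit P(VF) = intercept + slope * (true maximal QTc at 2.5 min)
    vf_model: Tuple[float, float] = field(default_factory=lambda: vf_model_for(1.024))
    vf_reference_tp: float = 2.5
    vf_time_range: Tuple[float, float] = (1.0, 8.0)
    censor_time: float = 10.0
    n_beats: int = 1
    signals: bool = True
    include_ecg: bool = True
    seed: int = 0

    def validate(self) -> None:
        r, c = self.grid_shape
        if r * c != self.n_leads:
            raise ValueError("grid_shape inconsistent with n_leads")
        if not 32 <= self.n_leads <= 64:
            raise ValueError("n_leads must lie within 32-64")
        if self.fs_egm <= 0 or self.fs_ecg <= 0:
            raise ValueError("sampling rates must be positive")
        tps = tuple(self.time_points)
        if tps != tuple(sorted(tps)) or tps[0] != 0.0:
            raise ValueError("time_points must be sorted ascending with 0 first")
        if self.rr_mean <= 0:
            raise ValueError("rr_mean must be positive")
        if not 0 < self.core_frac_range[0] <= self.core_frac_range[1] < 1:
            raise ValueError("core_frac_range must lie inside (0, 1)")
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")


@dataclass
class GroundTruth:
    """Per-lead and per-ECG-lead true fiducials plus the zone labels."""

    epi: pd.DataFrame   # animal, lead, time_point, zone, rr, true_at, true_rt,
                        # true_ari, true_aric, st, t_polarity
    ecg: pd.DataFrame   # animal, lead, time_point, rr, true_qt, true_qtp,
                        # true_qtc, true_qtp_c, t_polarity


@dataclass
class SyntheticDataset:
    """Signals, ground truth and the outcome skeleton of one virtual cohort."""

    config: GeneratorConfig
    grid: pd.DataFrame
    truth: GroundTruth
    cohort: pd.DataFrame  # animal, occlusion_site, vf, vf_time, p_vf, true_max_qtc_ref
    traces: List[SignalTrace] = field(default_factory=list)


def generate_cohort(config: GeneratorConfig) -> SyntheticDataset:
    """Generate a fully ground-truthed virtual occlusion cohort.

    Identical configs (including the seed) regenerate bit-identical datasets.
    With ``config.signals`` false only the ground-truth tables and outcomes
    are produced (the cohort-level model without waveform synthesis), which
    is the fast path for large statistical simulations.
    """
    config.validate()
    rows, cols = config.grid_shape
    grid = make_grid(rows, cols)
    leads = list(grid["lead"])
    lead_arr = np.asarray(leads)
    ecg_lead_arr = np.asarray([f"ECG{j + 1:02d}" for j in range(config.n_ecg_leads)])
    n = config.n_leads
    tps = tuple(config.time_points)
    children = SeedSequence(config.seed).spawn(config.n_animals)

    epi_blocks: List[dict] = []
    ecg_blocks: List[dict] = []
    cohort_rows: List[dict] = []
    traces: List[SignalTrace] = []
    b0, b1 = config.vf_model
    ref_tp = config.vf_reference_tp if config.vf_reference_tp in tps else tps[min(2, len(tps) - 1)]

    for a_idx in range(config.n_animals):
        animal = f"A{a_idx:02d}"
        site = "LAD" if a_idx < (config.n_animals + 1) // 2 else "LCX"
        s_struct, s_noise, s_outcome = children[a_idx].spawn(3)
        rng = default_rng(s_struct)
        noise_rng = default_rng(s_noise)
        out_rng = default_rng(s_outcome)

        # spatial structure
        frac = rng.uniform(*config.core_frac_range)
        core_size = int(np.clip(round(frac * n), 1, n - 2))
        core = _grow_core(rng, grid, core_size)
        border = frontier_leads(grid, core)
        zone_arr = np.asarray(["core" if l in core else "border" if l in border
                               else "remote" for l in leads])

        # baseline electrophysiology
        at_shift = rng.normal(0.0, config.at_animal_sd)
        ari_shift = rng.normal(0.0, config.ari_animal_sd)
        at_base = np.clip(
            rng.normal(config.baseline_at_mean + at_shift, config.baseline_at_sd, n),
            MIN_TRUE_AT_MS, 42.0)
        ari_base = np.clip(
            rng.normal(config.baseline_ari_mean + ari_shift, config.baseline_ari_sd, n),
            150.0, 330.0)
        polarity = np.where(rng.uniform(size=n) < config.neg_t_frac, -1, 1)
        rr_animal = config.rr_mean * math.exp(rng.normal(0.0, config.rr_sd / config.rr_mean))
        core_mask = np.array([l in core for l in leads])
        border_mask = np.array([l in border for l in leads])

        ecg_offsets = rng.normal(config.ecg_qt_offset_mean, config.ecg_qt_offset_sd,
                                 config.n_ecg_leads)
        ecg_pol = np.where(rng.uniform(size=config.n_ecg_leads) < config.ecg_neg_t_frac, -1, 1)
        ecg_qtp_gap = np.clip(rng.normal(config.ecg_qtp_gap_mean, config.ecg_qtp_gap_sd,
                                         config.n_ecg_leads), 35.0, 90.0)

        qtc_ref = np.nan
        for t in tps:
            at = (at_base
                  + core_mask * _profile(config.core_at_delay_profile, t)
                  + rng.normal(0.0, config.at_tp_jitter_sd, n))
            ari = (ari_base
                   + core_mask * _profile(config.core_ari_delta_profile, t)
                   + border_mask * _profile(config.border_ari_delta_profile, t)
                   + rng.normal(0.0, config.ari_tp_jitter_sd, n))
            at = np.clip(at, MIN_TRUE_AT_MS, None)
            ari = np.clip(ari, MIN_TRUE_ARI_MS + 10.0, None)
            st = np.where(core_mask & (t > 0), config.st_shift_mv, 0.0)

            rt_max = float(np.max(at + ari))
            qt_true = rt_max + ecg_offsets + rng.normal(0.0, config.ecg_qt_jitter_sd,
                                                        config.n_ecg_leads)
            rr_t = rr_animal * math.exp(rng.normal(0.0, config.rr_within_cv))
            rr_t = max(rr_t,
                       NOMINAL_ONSET_MS + rt_max + _FIT_MARGIN_MS + 2.0,
                       float(np.max(qt_true)) + _FIT_MARGIN_MS + 2.0)
            sqrt_rr = math.sqrt(rr_t / 1000.0)

            epi_blocks.append({
                "animal": animal, "lead": lead_arr, "time_point": t,
                "zone": zone_arr, "rr": rr_t, "true_at": at,
                "true_rt": at + ari, "true_ari": ari, "true_aric": ari / sqrt_rr,
                "st": st, "t_polarity": polarity,
            })
            if config.signals:
                for i, lead in enumerate(leads):
                    traces.append(make_beat_waveform(
                        float(at[i]), float(ari[i]), rr_t, float(st[i]),
                        config.fs_egm, config.noise_sd, noise_rng,
                        int(polarity[i]), lead_id=lead, animal_id=animal,
                        time_point=t, n_beats=config.n_beats))

            if config.include_ecg:
                if config.signals:
                    qt_arr = np.empty(config.n_ecg_leads)
                    qtp_arr = np.empty(config.n_ecg_leads)
                    for j in range(config.n_ecg_leads):
                        trace, ref = make_ecg_beat(
                            float(qt_true[j]), rr_t, config.fs_ecg,
                            config.noise_sd, noise_rng, int(ecg_pol[j]),
                            lead_id=str(ecg_lead_arr[j]), animal_id=animal,
                            time_point=t, n_beats=config.n_beats)
                        traces.append(trace)
                        qt_arr[j], qtp_arr[j] = ref["t_end"], ref["t_peak"]
                else:
                    qt_arr = qt_true
                    qtp_arr = qt_true - ecg_qtp_gap
                ecg_blocks.append({
                    "animal": animal, "lead": ecg_lead_arr, "time_point": t,
                    "rr": rr_t, "true_qt": qt_arr, "true_qtp": qtp_arr,
                    "true_qtc": qt_arr / sqrt_rr, "true_qtp_c": qtp_arr / sqrt_rr,
                    "t_polarity": ecg_pol,
                })
                if t == ref_tp:
                    qtc_ref = float(np.max(qt_arr / sqrt_rr))
            elif t == ref_tp:
                # no ECG: fall back to the maximal epicardial RTc as the VF covariate
                qtc_ref = float(np.max((at + ari) / sqrt_rr))

        p_vf = float(expit(b0 + b1 * qtc_ref))
        vf = bool(out_rng.uniform() < p_vf)
        vf_time = float(out_rng.uniform(*config.vf_time_range)) if vf else config.censor_time
        cohort_rows.append({
            "animal": animal, "occlusion_site": site, "vf": vf,
            "vf_time": vf_time, "p_vf": p_vf, "true_max_qtc_ref": qtc_ref,
        })

    def _concat_blocks(blocks: List[dict], columns: List[str]) -> pd.DataFrame:
        if not blocks:
            return pd.DataFrame(columns=columns)
        data = {}
        for c in columns:
            parts = [np.broadcast_to(np.asarray(b[c]), np.asarray(b["lead"]).shape)
                     for b in blocks]
            data[c] = np.concatenate(parts)
        return pd.DataFrame(data)

    truth = GroundTruth(
        epi=_concat_blocks(epi_blocks, [
            "animal", "lead", "time_point", "zone", "rr", "true_at", "true_rt",
            "true_ari", "true_aric", "st", "t_polarity"]),
        ecg=_concat_blocks(ecg_blocks, [
            "animal", "lead", "time_point", "rr", "true_qt", "true_qtp",
            "true_qtc", "true_qtp_c", "t_polarity"]),
    )
    cohort = pd.DataFrame(cohort_rows)
    return SyntheticDataset(config=config, grid=grid, truth=truth,
                            cohort=cohort, traces=traces)
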