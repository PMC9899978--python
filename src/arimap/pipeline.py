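"""Pipeline orchestration: simulate -> measure -> map -> stats.

One plain-text YAML config governs all stages; every analysis default that
is a judgement call (detection windows, smoothing cutoff, zone thresholds,
the categorical QTc cutoff) lives here so a run is reproducible from its
manifest alone.  The immutable preset ``porcine18`` pins the study-design
values: 5 ms activation-delay threshold, 10 ms prolongation threshold,
time-points {0, 1, 2.5, 5, 10} min and a 460 ms categorical QTc cutoff.

Signals are exchanged as plain CSV records (one file per animal,
time-point and lead kind, wide format, plus an ``index.csv``); all tables
are CSV; the run manifest is JSON with SHA-256 digests of every output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .beats import EPICARDIAL, DERIV_LPF_HZ, QRS_WIN_MS, SignalTrace, measure_dataset
from .mapping import (
    DELAY_THRESHOLD_MS,
    PROLONGATION_THRESHOLD_MS,
    classify_zones,
    summarize_cohort,
)
from .stats import (
    PHASE_1A_PERIOD,
    cox_univariate,
    km_logrank,
    outcome_associations,
    roc_analysis,
    site_chisquare,
)
from .synth import GeneratorConfig, SyntheticDataset, generate_cohort

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "load_config",
    "run_pipeline",
    "write_signals",
    "read_signals",
    "PRESETS",
]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    # measurement
    lpf_hz: float = DERIV_LPF_HZ
    qrs_window_ms: float = QRS_WIN_MS
    # mapping
    delay_threshold: float = DELAY_THRESHOLD_MS
    zone_mode: str = "abs"              # "abs" (>5 ms) or "rel" (>20% of baseline AT)
    diagonal_adjacency: bool = False
    prolongation_threshold: float = PROLONGATION_THRESHOLD_MS
    # statistics
    period: Tuple[float, float] = PHASE_1A_PERIOD
    assoc_mode: str = "pooled"
    categorical_cutoff: float = 460.0   # ms of maximal QTc for the KM split
    roc_time_point: float = 2.5
    # io
    write_signals: bool = False

    def validate(self) -> None:
        self.generator.validate()
        if self.zone_mode not in ("abs", "rel"):
            raise ValueError("zone_mode must be 'abs' or 'rel'")
        if self.assoc_mode not in ("pooled", "per_animal_max"):
            raise ValueError("assoc_mode must be 'pooled' or 'per_animal_max'")
        if self.period[0] >= self.period[1]:
            raise ValueError("period must be an increasing (start, end)")


PRESETS: Dict[str, dict] = {
    # study-design defaults, immutable by construction (deep-copied on use)
    "porcine18": {
        "delay_threshold": 5.0,
        "prolongation_threshold": 10.0,
        "categorical_cutoff": 460.0,
        "generator": {"time_points": [0.0, 1.0, 2.5, 5.0, 10.0]},
    },
}


def _merge(dst: dict, src: dict) -> dict:
    for k, v in src.items():
        if isinstance(v, dict) and isinstance(dst.get(k), dict):
            _merge(dst[k], v)
        else:
            dst[k] = v
    return dst


def _config_from_mapping(raw: dict) -> PipelineConfig:
    raw = dict(raw or {})
    preset = raw.pop("preset", None)
    merged: dict = {}
    if preset:
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}")
        _merge(merged, json.loads(json.dumps(PRESETS[preset])))
    _merge(merged, raw)
    gen_raw = merged.pop("generator", {})
    for key in ("time_points", "grid_shape", "core_frac_range", "vf_model",
                "vf_time_range"):
        if key in gen_raw and isinstance(gen_raw[key], list):
            gen_raw[key] = tuple(gen_raw[key])
    for key in ("core_at_delay_profile", "border_ari_delta_profile",
                "core_ari_delta_profile"):
        if key in gen_raw:
            gen_raw[key] = {float(k): float(v) for k, v in gen_raw[key].items()}
    if "period" in merged and isinstance(merged["period"], list):
        merged["period"] = tuple(merged["period"])
    config = PipelineConfig(generator=GeneratorConfig(**gen_raw), **merged)
    config.validate()
    return config


def load_config(path) -> PipelineConfig:
    """Read the plain-text (YAML) pipeline configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return _config_from_mapping(raw)


# -- signal records -----------------------------------------------------------


def write_signals(dataset: SyntheticDataset, out_dir) -> Path:
    """Write signal records as CSV: one wide file per animal/time-point/kind."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    index_rows = []
    groups: Dict[Tuple[str, float, str], List[SignalTrace]] = {}
    for tr in dataset.traces:
        groups.setdefault((tr.animal_id, tr.time_point, tr.lead_kind), []).append(tr)
    for (animal, t, kind), trs in sorted(groups.items()):
        tag = "epi" if kind == EPICARDIAL else "ecg"
        name = f"{animal}_t{str(t).replace('.', 'p')}_{tag}.csv"
        frame = pd.DataFrame({tr.lead_id: tr.samples for tr in trs})
        frame.to_csv(out / name, index=False, float_format="%.6f")
        for tr in trs:
            index_rows.append({
                "animal": animal, "time_point": t, "lead": tr.lead_id,
                "lead_kind": kind, "fs": tr.fs, "rr": tr.rr, "file": name,
            })
    pd.DataFrame(index_rows).to_csv(out / "index.csv", index=False)
    return out


def read_signals(signals_dir) -> List[SignalTrace]:
    """Read CSV signal records written by :func:`write_signals`."""
    signals_dir = Path(signals_dir)
    index = pd.read_csv(signals_dir / "index.csv")
    traces: List[SignalTrace] = []
    for name, grp in index.groupby("file", sort=True):
        frame = pd.read_csv(signals_dir / name)
        for row in grp.itertuples():
            traces.append(SignalTrace(
                frame[row.lead].to_numpy(dtype=float), float(row.fs),
                str(row.lead), str(row.lead_kind), str(row.animal),
                float(row.time_point), float(row.rr)))
    return traces


# -- stages -------------------------------------------------------------------


def map_stage(measurements: pd.DataFrame, grid: pd.DataFrame,
              config: PipelineConfig) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Zone maps and per-animal summaries from a measurement table."""
    zone_rows = []
    epi = measurements[measurements["lead_kind"] == EPICARDIAL]
    for animal, grp in epi.groupby("animal", sort=True):
        at_table = grp.pivot_table(index="lead", columns="time_point", values="at")
        labels = classify_zones(at_table, grid, config.delay_threshold,
                                config.zone_mode, diagonal=config.diagonal_adjacency)
        for lead, z in labels.items():
            zone_rows.append({"animal": animal, "lead": lead, "zone": z})
    zones = pd.DataFrame(zone_rows)
    summaries = summarize_cohort(measurements)
    return zones, summaries


def stats_stage(summaries: pd.DataFrame, cohort: pd.DataFrame,
                config: PipelineConfig) -> pd.DataFrame:
    """Tidy results table: logistic screens, ROC, Cox, KM log-rank, chi-square."""
    rows = []
    assoc = outcome_associations(summaries, cohort, period=config.period,
                                 mode=config.assoc_mode)
    if len(assoc):
        rows.extend(assoc.to_dict("records"))

    ref = summaries[summaries["time_point"] == config.roc_time_point]
    per_animal = ref.set_index("animal")["qtc_max"].dropna()
    merged = cohort.set_index("animal").loc[per_animal.index]
    if per_animal.size >= 4 and merged["vf"].nunique() == 2:
        roc = roc_analysis(merged["vf"].astype(float), per_animal)
        rows.append({"analysis": "roc", "covariate": "qtc_max",
                     "time_point": config.roc_time_point, "estimate": roc.auc,
                     "p": roc.p_value, "n": roc.n_events + roc.n_nonevents,
                     "scale": "AUC",
                     "note": f"Youden cutoff >{roc.optimal_cutoff:.1f} ms "
                             f"(sens {roc.sens_at_cutoff:.3f}, spec {roc.spec_at_cutoff:.3f})"})
        cox = cox_univariate(merged["vf_time"], merged["vf"].astype(float), per_animal)
        rows.append({"analysis": "cox", "covariate": "qtc_max",
                     "time_point": config.roc_time_point, "estimate": cox.estimate,
                     "ci_low": cox.ci_low, "ci_high": cox.ci_high, "p": cox.p_value,
                     "n": cox.n, "scale": "HR", "note": cox.flag})
        groups = np.where(per_animal > config.categorical_cutoff,
                          f">{config.categorical_cutoff:g}", f"<={config.categorical_cutoff:g}")
        if len(np.unique(groups)) == 2:
            km = km_logrank(merged["vf_time"], merged["vf"].astype(bool), groups)
            rows.append({"analysis": "km_logrank", "covariate": "qtc_max",
                         "time_point": config.roc_time_point, "estimate": km.statistic,
                         "p": km.p_value, "n": len(per_animal), "scale": "chi2",
                         "note": f"groups split at {config.categorical_cutoff:g} ms"})
    if cohort["occlusion_site"].nunique() == 2 and cohort["vf"].nunique() == 2:
        chi = site_chisquare(cohort["occlusion_site"], cohort["vf"])
        rows.append({"analysis": "chi_square", "covariate": "occlusion_site",
                     "estimate": chi["chi2"], "p": chi["p"], "n": int(len(cohort)),
                     "scale": "chi2", "note": "VF incidence by occlusion site"})
    cols = ["analysis", "covariate", "time_point", "mode", "estimate",
            "ci_low", "ci_high", "p", "n", "scale", "note"]
    out = pd.DataFrame(rows)
    return out.reindex(columns=[c for c in cols if c in out.columns])


# -- orchestration ------------------------------------------------------------


@dataclass
class RunManifest:
    seed: int
    config: dict
    versions: Dict[str, str]
    outputs: Dict[str, str]          # relative path -> sha256
    exclusions: Dict[str, int]       # stage -> excluded-lead count

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def run_pipeline(config: PipelineConfig, out_dir, seed: Optional[int] = None) -> RunManifest:
    """Execute simulate -> measure -> map -> stats, writing all tables + manifest.

    A failing stage aborts with the stage named; outputs written up to that
    point are retained.  Identical (config, seed) pairs produce byte-identical
    CSV outputs, which the manifest digests make checkable.
    """
    config.validate()
    if seed is not None:
        config = dataclasses.replace(
            config, generator=dataclasses.replace(config.generator, seed=seed))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: Dict[str, str] = {}
    exclusions: Dict[str, int] = {}

    stage = "simulate"
    try:
        dataset = generate_cohort(config.generator)
        _write_csv(dataset.grid, out / "grid.csv")
        _write_csv(dataset.truth.epi, out / "truth_epicardial.csv")
        _write_csv(dataset.truth.ecg, out / "truth_ecg.csv")
        _write_csv(dataset.cohort, out / "cohort.csv")
        if config.write_signals:
            write_signals(dataset, out / "signals")

        stage = "measure"
        if not dataset.traces:
            raise ValueError("generator config has signals=False; nothing to measure")
        measurements = measure_dataset(dataset.traces, lpf_hz=config.lpf_hz)
        exclusions["measure"] = int((~measurements["ok"].astype(bool)).sum())
        _write_csv(measurements, out / "measurements.csv")

        stage = "map"
        zones, summaries = map_stage(measurements, dataset.grid, config)
        _write_csv(zones, out / "zones.csv")
        _write_csv(summaries, out / "summaries.csv")

        stage = "stats"
        results = stats_stage(summaries, dataset.cohort, config)
        _write_csv(results, out / "stats.csv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    for p in sorted(out.rglob("*.csv")):
        written[str(p.relative_to(out))] = _sha256(p)
    manifest = RunManifest(
        seed=config.generator.seed,
        config=dataclasses.asdict(config),
        versions={"arimap": __version__, "numpy": np.__version__,
                  "pandas": pd.__version__},
        outputs=written,
        exclusions=exclusions,
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
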