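"""Activity summaries, channel analysis, time courses and the full pipeline.

This module glues the stages together the way a screening experiment uses
them: per-recording activity statistics (spike counts, mean firing rate),
per-channel velocity and directionality, DIV time courses across repeated
sessions, and ``run_pipeline`` which goes from a configuration file (real
spike lists or a simulation) to a bundle of CSV outputs plus a run log.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .directionality import (
    DEFAULT_MAX_ISI_S,
    DEFAULT_MIN_BURST_SPIKES,
    DEFAULT_VELOCITY_BAND_MPS,
    DirectionalEvent,
    DirectionalitySummary,
    burst_directionality,
    build_match_window,
    compute_directionality,
    detect_bursts,
    match_directional_events,
)
from .io import load_yaml, read_geometry, read_spike_list, write_geometry, write_spike_list
from .propagation import (
    DEFAULT_BIN_S,
    DEFAULT_MAX_LAG_S,
    VelocityEstimate,
    channel_correlograms,
    estimate_velocity,
)
from .simulate import GroundTruth, SimulationConfig, simulate_recording
from .types import (
    ChannelGeometry,
    DetectionParams,
    Recording,
    tunnel_rows_geometry,
)

PathLike = Union[str, Path]

__all__ = [
    "ActivitySummary",
    "AnalysisParams",
    "ChannelAnalysis",
    "summarize_activity",
    "analyze_channel",
    "analyze_recording",
    "assemble_timecourse",
    "run_pipeline",
]


@dataclass
class ActivitySummary:
    """Spike-count statistics for one electrode or one well."""

    scope: str  # "electrode" or "well"
    scope_id: str
    n_spikes: int
    mean_firing_rate_hz: float
    n_active_electrodes: int
    div: Optional[int] = None


@dataclass(frozen=True)
class AnalysisParams:
    """Settings of the velocity + directionality analysis.

    ``velocity_band_mps`` is the admissible conduction-velocity range from
    which match windows are built; ``pad_samples`` widens each window edge by
    that many sample periods.  With ``use_measured_lag`` the greedy matcher
    centres on the channel's fitted lag (distance / estimated velocity)
    instead of the window midpoint.
    """

    velocity_band_mps: tuple[float, float] = DEFAULT_VELOCITY_BAND_MPS
    pad_samples: int = 1
    use_measured_lag: bool = True
    max_lag_s: float = DEFAULT_MAX_LAG_S
    bin_s: float = DEFAULT_BIN_S
    burst_max_isi_s: float = DEFAULT_MAX_ISI_S
    min_burst_spikes: int = DEFAULT_MIN_BURST_SPIKES
    active_threshold: int = 5


@dataclass
class ChannelAnalysis:
    """Everything the pipeline derives from one microtunnel."""

    geometry: ChannelGeometry
    velocity: VelocityEstimate
    spike_events: list[DirectionalEvent]
    burst_events: list[DirectionalEvent]

    def summary(self, kind: str, div: Optional[int] = None) -> DirectionalitySummary:
        events = self.spike_events if kind == "spike" else self.burst_events
        return compute_directionality(
            events, "channel", self.geometry.channel_id, kind=kind, div=div
        )


def summarize_activity(
    rec: Recording, active_threshold: int = 5
) -> list[ActivitySummary]:
    """Per-electrode and per-well activity summaries.

    Electrode mean firing rate is spikes / duration.  Well mean firing rate
    is total spikes / (duration x number of active electrodes), an electrode
    being active with at least ``active_threshold`` spikes in the recording.
    """
    if rec.duration_s <= 0:
        raise ValueError("recording duration must be positive")
    out: list[ActivitySummary] = []
    by_well: dict[str, list[int]] = {}
    for eid in sorted(rec.spike_trains):
        n = len(rec.spike_trains[eid])
        by_well.setdefault(eid.well_id, []).append(n)
        out.append(
            ActivitySummary(
                "electrode", f"{eid.well_id}:{eid.row},{eid.col}",
                n, n / rec.duration_s, int(n >= active_threshold), div=rec.div,
            )
        )
    for well, counts in sorted(by_well.items()):
        total = int(np.sum(counts))
        n_active = int(np.sum(np.asarray(counts) >= active_threshold))
        mfr = total / (rec.duration_s * n_active) if n_active else 0.0
        out.append(ActivitySummary("well", well, total, mfr, n_active, div=rec.div))
    return out


def analyze_channel(
    rec: Recording,
    geometry: ChannelGeometry,
    params: AnalysisParams = AnalysisParams(),
) -> ChannelAnalysis:
    """Velocity estimate and directional spike/burst events for one tunnel.

    Directionality uses the channel's most distant electrode pair (first vs
    last along the tunnel), which maximizes timing resolution.
    """
    sample_period = params.bin_s
    trains = {e: rec.train(e) for e in geometry.electrodes}
    correlograms = channel_correlograms(
        trains, geometry, params.max_lag_s, params.bin_s
    )
    velocity = estimate_velocity(correlograms, geometry.channel_id, sample_period)

    first, last = geometry.electrodes[0], geometry.electrodes[-1]
    span = geometry.span_um
    window = build_match_window(
        span, params.velocity_band_mps, params.pad_samples, sample_period
    )
    expected = None
    if params.use_measured_lag and np.isfinite(velocity.velocity_mps):
        lag = span * 1e-6 / velocity.velocity_mps
        if window.delta_min_s <= lag <= window.delta_max_s:
            expected = lag
    spike_events = match_directional_events(
        trains[first], trains[last], window, expected, geometry.channel_id
    )
    bursts_first = detect_bursts(
        trains[first], params.burst_max_isi_s, params.min_burst_spikes
    )
    bursts_last = detect_bursts(
        trains[last], params.burst_max_isi_s, params.min_burst_spikes
    )
    burst_events = burst_directionality(
        bursts_first, bursts_last, window, expected, geometry.channel_id
    )
    return ChannelAnalysis(geometry, velocity, spike_events, burst_events)


def analyze_recording(
    rec: Recording,
    params: AnalysisParams = AnalysisParams(),
) -> list[ChannelAnalysis]:
    """Analyze every channel of a recording's geometry."""
    if not rec.geometry:
        raise ValueError("recording carries no channel geometry")
    return [analyze_channel(rec, geom, params) for geom in rec.geometry]


def directionality_table(
    analyses: Sequence[ChannelAnalysis], div: Optional[int] = None
) -> pd.DataFrame:
    """Long-format directionality table: one row per channel and kind, plus
    pooled per-well and overall rows (pooled = summed counts, not averaged
    percentages)."""
    rows = []

    def row(scope, scope_id, well, channel, kind, n_ab, n_ba):
        total = n_ab + n_ba
        rows.append(
            {
                "scope": scope, "well": well, "channel": channel, "div": div,
                "kind": kind, "count_a_to_b": n_ab, "count_b_to_a": n_ba,
                "pct_a_to_b": 100.0 * n_ab / total if total else np.nan,
                "pct_b_to_a": 100.0 * n_ba / total if total else np.nan,
            }
        )

    pooled: dict[tuple[str, str], list[int]] = {}
    overall: dict[str, list[int]] = {"spike": [0, 0], "burst": [0, 0]}
    for an in analyses:
        well = an.geometry.well_id
        for kind in ("spike", "burst"):
            s = an.summary(kind, div)
            row("channel", an.geometry.channel_id, well, an.geometry.channel_id,
                kind, s.count_a_to_b, s.count_b_to_a)
            key = (well, kind)
            pooled.setdefault(key, [0, 0])
            pooled[key][0] += s.count_a_to_b
            pooled[key][1] += s.count_b_to_a
            overall[kind][0] += s.count_a_to_b
            overall[kind][1] += s.count_b_to_a
    for (well, kind), (n_ab, n_ba) in sorted(pooled.items()):
        row("well", well, well, "", kind, n_ab, n_ba)
    for kind, (n_ab, n_ba) in overall.items():
        row("all", "all", "", "", kind, n_ab, n_ba)
    return pd.DataFrame(rows)


def velocity_table(analyses: Sequence[ChannelAnalysis]) -> pd.DataFrame:
    rows = []
    for an in analyses:
        v = an.velocity
        rows.append(
            {
                "well": an.geometry.well_id,
                "channel": v.channel_id,
                "velocity_mps": v.velocity_mps,
                "slope_s_per_um": v.slope_s_per_um,
                "direction": v.direction,
                "n_pairs": v.n_pairs_used,
                "resolution_bound_mps": v.resolution_bound_mps,
                "no_propagation": v.no_propagation,
                "low_confidence": v.low_confidence,
            }
        )
    return pd.DataFrame(rows)


def activity_table(summaries: Sequence[ActivitySummary]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(s) for s in summaries])


def assemble_timecourse(records: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-well metrics over DIV into a time-course table.

    ``records`` needs columns ``condition, div, well, metric, value`` (one
    row per well per metric per session).  Returns mean and across-well s.d.
    per (condition, div, metric); the s.d. is NaN (missing) with a single
    well, never 0.  Duplicate (condition, div, well, metric) rows raise.
    """
    required = {"condition", "div", "well", "metric", "value"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns {sorted(missing)}")
    keys = ["condition", "div", "well", "metric"]
    if records.duplicated(subset=keys).any():
        dupes = records[records.duplicated(subset=keys, keep=False)]
        raise ValueError(f"duplicate (condition, div, well, metric) rows:\n{dupes}")
    grouped = (
        records.groupby(["condition", "div", "metric"], sort=True)["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n_wells="count")
        .reset_index()
    )
    return grouped


def _geometry_from_config(sim_cfg: dict) -> list[ChannelGeometry]:
    wells = sim_cfg.get("wells", 1)
    well_ids = (
        [f"W{k + 1}" for k in range(wells)] if isinstance(wells, int) else list(wells)
    )
    geoms: list[ChannelGeometry] = []
    for well in well_ids:
        geoms.extend(
            tunnel_rows_geometry(
                str(well),
                n_channels=int(sim_cfg.get("channels_per_well", 8)),
                n_electrodes=int(sim_cfg.get("electrodes_per_channel", 8)),
                spacing_um=float(sim_cfg.get("spacing_um", 200.0)),
            )
        )
    return geoms


_SIM_FIELDS = (
    "duration_s", "sampling_rate_hz", "rate_a_to_b_hz", "rate_b_to_a_hz",
    "velocity_mps", "velocity_jitter_frac", "background_rate_hz",
    "burst_prob", "burst_size", "burst_isi_s", "noise_sd_uv",
    "spike_amplitude_uv",
)


def simulation_config_from_dict(sim_cfg: dict, seed: int) -> SimulationConfig:
    geometry = _geometry_from_config(sim_cfg)
    kwargs = {k: sim_cfg[k] for k in _SIM_FIELDS if k in sim_cfg}
    return SimulationConfig(geometry=tuple(geometry), seed=seed, **kwargs)


def ground_truth_table(truth: GroundTruth) -> pd.DataFrame:
    rows = [
        {
            "channel": e.channel_id,
            "origin_side": e.origin_side,
            "t_first_s": float(e.times_s.min()),
            "velocity_mps": e.velocity_mps,
            "burst_id": -1 if e.burst_id is None else e.burst_id,
        }
        for e in truth.propagating_events
    ]
    return pd.DataFrame(
        rows,
        columns=["channel", "origin_side", "t_first_s", "velocity_mps", "burst_id"],
    )


@dataclass
class PipelineResult:
    recording: Recording
    analyses: list[ChannelAnalysis]
    directionality: pd.DataFrame
    velocity: pd.DataFrame
    activity: pd.DataFrame
    truth: Optional[GroundTruth] = None
    output_dir: Optional[Path] = None


def run_pipeline(
    config: Union[dict, PathLike],
    output_dir: Optional[PathLike] = None,
    seed: Optional[int] = None,
) -> PipelineResult:
    """Execute the full analysis from a configuration.

    The configuration (dict or YAML path) provides either a ``simulation``
    section or an ``inputs`` section with ``spikes`` and ``geometry`` paths;
    optional ``detection`` and ``analysis`` sections override defaults.  With
    ``detect_from_raw: true`` under ``simulation``, raw traces are
    synthesized electrode by electrode and spikes re-detected through the
    6-SD filter-and-threshold chain; otherwise the simulated event lists are
    analyzed directly.

    Writes spikes, velocity, directionality and activity CSVs plus a run log
    into ``output_dir`` when given.
    """
    if not isinstance(config, dict):
        config_path = Path(config)
        config = load_yaml(config_path)
        if config is None:
            raise ValueError(f"empty configuration file: {config_path}")
    seed = int(config.get("seed", 0)) if seed is None else int(seed)
    analysis_cfg = dict(config.get("analysis", {}))
    if "velocity_band_mps" in analysis_cfg:
        analysis_cfg["velocity_band_mps"] = tuple(analysis_cfg["velocity_band_mps"])
    params = AnalysisParams(**analysis_cfg)
    det_params = DetectionParams(**config.get("detection", {}))

    truth = None
    if "simulation" in config:
        sim_cfg = dict(config["simulation"])
        detect_from_raw = bool(sim_cfg.pop("detect_from_raw", False))
        sim = simulation_config_from_dict(sim_cfg, seed)
        rec, truth = simulate_recording(sim)
        if detect_from_raw:
            from .detection import detect_simulated

            rec = detect_simulated(rec, sim, det_params)
    elif "inputs" in config:
        inputs = config["inputs"]
        if "geometry" not in inputs or "spikes" not in inputs:
            raise ValueError("inputs section needs 'spikes' and 'geometry' paths")
        geom_path = Path(inputs["geometry"])
        if not geom_path.exists():
            raise FileNotFoundError(f"geometry file not found: {geom_path}")
        spikes_path = Path(inputs["spikes"])
        if not spikes_path.exists():
            raise FileNotFoundError(f"spike list not found: {spikes_path}")
        geometry = read_geometry(geom_path)
        rec = read_spike_list(spikes_path)
        rec = dataclasses.replace(rec, geometry=tuple(geometry))
    else:
        raise ValueError("configuration needs a 'simulation' or 'inputs' section")

    if config.get("div") is not None:
        rec = dataclasses.replace(rec, div=int(config["div"]))
    if config.get("condition"):
        rec = dataclasses.replace(rec, condition=str(config["condition"]))

    analyses = analyze_recording(rec, params)
    direction = directionality_table(analyses, div=rec.div)
    velocity = velocity_table(analyses)
    activity = activity_table(summarize_activity(rec, params.active_threshold))

    out_dir: Optional[Path] = None
    if output_dir is not None:
        out_dir = Path(output_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_spike_list(rec, out_dir / "spikes.csv")
        write_geometry(rec.geometry, out_dir / "geometry.yaml")
        direction.to_csv(out_dir / "directionality.csv", index=False)
        velocity.to_csv(out_dir / "velocity.csv", index=False)
        activity.to_csv(out_dir / "activity.csv", index=False)
        if truth is not None:
            ground_truth_table(truth).to_csv(out_dir / "ground_truth.csv", index=False)
        log = {
            "tunnelmea_version": __version__,
            "seed": seed,
            "config": _jsonable(config),
            "n_events": int(rec.n_events),
            "n_channels": len(analyses),
        }
        (out_dir / "run_log.yaml").write_text(yaml.safe_dump(log, sort_keys=False))

    return PipelineResult(rec, analyses, direction, velocity, activity, truth, out_dir)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    return obj
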