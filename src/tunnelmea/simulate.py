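"""Ground-truth-annotated synthetic microtunnel recordings.

The generator emulates the statistical structure the downstream analysis
assumes: each microtunnel carries two independent homogeneous Poisson streams
of propagating events (one initiated on each compartment side), every event
travels the tunnel at its own velocity drawn from a truncated normal — the
in-vitro recordings show a distribution of conduction velocities, attributed
to a distribution of axonal path lengths — and every electrode additionally
fires independent non-propagating background events.  Optionally each spike
is rendered into a raw voltage trace as a stereotyped biphasic waveform on
white Gaussian noise, so the full filter-and-threshold detection path can be
exercised against known truth.

All emitted event times are quantized to the acquisition sample grid
(12.5 kHz by default).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .types import (
    ChannelGeometry,
    ElectrodeId,
    RawTrace,
    Recording,
    SpikeTrain,
    DEFAULT_SAMPLING_RATE_HZ,
)

__all__ = [
    "SimulationConfig",
    "PropagatingEvent",
    "GroundTruth",
    "ConfigError",
    "simulate_recording",
    "synthesize_trace",
    "spike_template",
    "truth_direction_fraction",
]

VELOCITY_FLOOR_MPS = 0.1


class ConfigError(ValueError):
    """A simulation configuration is internally inconsistent."""


@dataclass
class SimulationConfig:
    """Parameters of one synthetic recording.

    Defaults reproduce a healthy-assembloid-like regime: MO-side-dominated
    traffic (2.0 Hz A->B vs 0.5 Hz B->A per tunnel), conduction at 1.75 m/s
    with 10% per-event velocity jitter, and 1 Hz of uncorrelated background
    per electrode.  Spike amplitude 30 uV on 3 uV noise gives the ~10 sigma
    signal-to-noise typical of axonal signals confined in microtunnels.
    """

    geometry: tuple[ChannelGeometry, ...]
    duration_s: float = 300.0
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ
    rate_a_to_b_hz: float = 2.0
    rate_b_to_a_hz: float = 0.5
    velocity_mps: float = 1.75
    velocity_jitter_frac: float = 0.1
    background_rate_hz: float = 1.0
    burst_prob: float = 0.0
    burst_size: int = 5
    burst_isi_s: float = 0.05
    noise_sd_uv: float = 3.0
    spike_amplitude_uv: float = 30.0
    emit_raw: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.geometry = tuple(self.geometry)
        if self.duration_s <= 0:
            raise ConfigError("duration_s must be positive")
        if min(self.rate_a_to_b_hz, self.rate_b_to_a_hz, self.background_rate_hz) < 0:
            raise ConfigError("rates must be nonnegative")
        if self.velocity_mps <= 0:
            raise ConfigError("velocity_mps must be positive")
        if not 0 <= self.velocity_jitter_frac < 1:
            raise ConfigError("velocity_jitter_frac must be in [0, 1)")
        if not 0 <= self.burst_prob <= 1:
            raise ConfigError("burst_prob must be in [0, 1]")
        for geom in self.geometry:
            traversal = geom.span_um * 1e-6 / max(self.velocity_floor_mps, 1e-12)
            if traversal >= self.duration_s:
                raise ConfigError(
                    f"channel {geom.channel_id}: tunnel traversal at the velocity "
                    f"floor ({traversal:.3g}s) exceeds duration {self.duration_s}s"
                )

    @property
    def velocity_floor_mps(self) -> float:
        return VELOCITY_FLOOR_MPS

    @property
    def sample_period_s(self) -> float:
        return 1.0 / self.sampling_rate_hz


@dataclass
class PropagatingEvent:
    """One tunnel-traversing spike: true arrival time at every electrode.

    ``times_s`` are the exact (unquantized) arrival times ``t0 + d/v``; the
    emitted recording carries them rounded to the sample grid.
    """

    channel_id: str
    origin_side: str  # "A" or "B"
    times_s: np.ndarray  # aligned with the channel's electrode order
    velocity_mps: float
    burst_id: Optional[int] = None  # shared by spikes of one burst

    def quantized_times(self, sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ) -> np.ndarray:
        return _quantize(self.times_s, sampling_rate_hz)


@dataclass
class GroundTruth:
    """True event record of a simulated recording."""

    propagating_events: list[PropagatingEvent]
    background_events: dict[ElectrodeId, np.ndarray]
    spike_counts: dict[str, dict[str, int]]  # channel -> {"A": n, "B": n}
    burst_counts: dict[str, dict[str, int]]

    def events_in(self, channel_id: str) -> list[PropagatingEvent]:
        return [e for e in self.propagating_events if e.channel_id == channel_id]


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lower: float, size: int
) -> np.ndarray:
    """Normal(mean, sd) conditioned on >= lower, by rejection."""
    if sd == 0:
        return np.full(size, max(mean, lower))
    out = rng.normal(mean, sd, size)
    bad = out < lower
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out < lower
    return out


def _quantize(times: np.ndarray, fs: float) -> np.ndarray:
    return np.round(np.asarray(times) * fs) / fs


def _channel_rng(seed: int, channel_id: str) -> np.random.Generator:
    key = zlib.crc32(channel_id.encode())
    return np.random.default_rng(np.random.SeedSequence([seed, key]))


def _noise_seed_seq(seed: int, electrode: ElectrodeId) -> np.random.SeedSequence:
    key = zlib.crc32(electrode.well_id.encode())
    return np.random.SeedSequence([seed, 0x6E015E, key, electrode.index])


def simulate_recording(config: SimulationConfig) -> tuple[Recording, GroundTruth]:
    """Simulate one recording; deterministic for a fixed ``config.seed``.

    Returns the recording (spike trains from truth, raw traces if
    ``config.emit_raw``) and the ground-truth annotation.
    """
    fs = config.sampling_rate_hz
    per_electrode: dict[ElectrodeId, list[float]] = {}
    events: list[PropagatingEvent] = []
    background: dict[ElectrodeId, np.ndarray] = {}
    spike_counts: dict[str, dict[str, int]] = {}
    burst_counts: dict[str, dict[str, int]] = {}
    next_burst_id = 0

    for geom in config.geometry:
        rng = _channel_rng(config.seed, geom.channel_id)
        positions = np.asarray(geom.positions_um)
        spike_counts[geom.channel_id] = {"A": 0, "B": 0}
        burst_counts[geom.channel_id] = {"A": 0, "B": 0}

        for side, rate in (("A", config.rate_a_to_b_hz), ("B", config.rate_b_to_a_hz)):
            n_init = rng.poisson(rate * config.duration_s)
            t0s = np.sort(rng.uniform(0.0, config.duration_s, n_init))
            velocities = _truncated_normal(
                rng,
                config.velocity_mps,
                config.velocity_jitter_frac * config.velocity_mps,
                config.velocity_floor_mps,
                n_init,
            )
            is_burst = rng.random(n_init) < config.burst_prob
            if side == "A":
                travel_um = positions - positions[0]
            else:
                travel_um = positions[-1] - positions
            for t0, v, burst in zip(t0s, velocities, is_burst):
                if burst:
                    onsets = t0 + config.burst_isi_s * np.arange(config.burst_size)
                    burst_id: Optional[int] = next_burst_id
                    next_burst_id += 1
                else:
                    onsets = np.array([t0])
                    burst_id = None
                kept_any = False
                for onset in onsets:
                    exact = onset + travel_um * 1e-6 / v
                    quantized = _quantize(exact, fs)
                    if quantized.max() > config.duration_s or quantized.min() < 0:
                        continue
                    kept_any = True
                    events.append(
                        PropagatingEvent(geom.channel_id, side, exact, float(v), burst_id)
                    )
                    spike_counts[geom.channel_id][side] += 1
                    for eid, t in zip(geom.electrodes, quantized):
                        per_electrode.setdefault(eid, []).append(float(t))
                if burst_id is not None and kept_any:
                    burst_counts[geom.channel_id][side] += 1

        for eid in geom.electrodes:
            n_bg = rng.poisson(config.background_rate_hz * config.duration_s)
            bg = _quantize(np.sort(rng.uniform(0.0, config.duration_s, n_bg)), fs)
            background[eid] = bg
            if n_bg:
                per_electrode.setdefault(eid, []).extend(bg.tolist())

    trains: dict[ElectrodeId, SpikeTrain] = {}
    for geom in config.geometry:
        for eid in geom.electrodes:
            times = np.asarray(per_electrode.get(eid, []), dtype=float)
            trains[eid] = SpikeTrain.from_times(eid, times, sampling_rate_hz=fs)

    raw = None
    if config.emit_raw:
        raw = {
            eid: synthesize_trace(eid, trains[eid].times_s, config)
            for eid in trains
        }

    rec = Recording(
        spike_trains=trains,
        duration_s=config.duration_s,
        geometry=config.geometry,
        raw=raw,
    )
    truth = GroundTruth(events, background, spike_counts, burst_counts)
    return rec, truth


def spike_template(sampling_rate_hz: float, amplitude_uv: float) -> tuple[np.ndarray, int]:
    """Stereotyped biphasic extracellular waveform, 1 ms long.

    Returns the template samples and the offset (in samples) of its
    negative extremum, which is aligned with the nominal event time.
    """
    n = int(round(0.001 * sampling_rate_hz)) + 1
    phase = np.arange(n) / max(n - 1, 1)
    w = -np.sin(2 * np.pi * phase) * amplitude_uv
    return w, int(np.argmin(w))


def synthesize_trace(
    electrode: ElectrodeId,
    times_s: np.ndarray,
    config: SimulationConfig,
) -> RawTrace:
    """Render one electrode's events into a noisy raw voltage trace.

    The noise stream is keyed by (seed, well, electrode) only, so traces can
    be synthesized one electrode at a time, in any order, with identical
    results.
    """
    fs = config.sampling_rate_hz
    n_samples = int(round(config.duration_s * fs)) + 1
    rng = np.random.default_rng(_noise_seed_seq(config.seed, electrode))
    samples = rng.standard_normal(n_samples) * config.noise_sd_uv
    if len(times_s):
        template, peak_offset = spike_template(fs, config.spike_amplitude_uv)
        idx = np.round(np.asarray(times_s) * fs).astype(int) - peak_offset
        for start in idx:
            lo = max(start, 0)
            hi = min(start + len(template), n_samples)
            if hi > lo:
                samples[lo:hi] += template[lo - start : hi - start]
    return RawTrace(electrode, samples, fs)


def truth_direction_fraction(truth: GroundTruth, channel_id: str) -> float:
    """Fraction of a channel's propagating spikes initiated on side A.

    Returns NaN (undefined) when the channel generated no propagating events;
    an absent channel raises ``KeyError``.
    """
    counts = truth.spike_counts[channel_id]
    total = counts["A"] + counts["B"]
    if total == 0:
        return float("nan")
    return counts["A"] / total
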