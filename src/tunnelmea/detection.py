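"""Filter-and-threshold spike detection.

The detection chain mirrors standard extracellular practice: Butterworth
band-pass between 200 Hz and 3 kHz, then events wherever the filtered signal
exceeds 6 estimated noise standard deviations.  The filter is applied
forward-backward (zero phase): any phase lag would bias the inter-electrode
delays on which velocity and directionality rest.

The noise s.d. is estimated robustly by default (median absolute deviation
scaled by 1/0.6745), so that the spikes themselves do not inflate the
threshold.  Both polarities cross the threshold by default; extracellular
axonal spikes are typically negative-going, but the polarity is configurable.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .simulate import SimulationConfig, synthesize_trace
from .types import (
    DetectionParams,
    ElectrodeId,
    RawTrace,
    Recording,
    SpikeTrain,
)

MAD_TO_SD = 1.0 / 0.6745

__all__ = [
    "design_bandpass",
    "bandpass_filter",
    "estimate_noise_sd",
    "detect_spikes",
    "detect_recording",
    "detect_simulated",
]


def design_bandpass(params: DetectionParams, sampling_rate_hz: float) -> np.ndarray:
    """Second-order sections for the band-pass (HP and LP cascaded)."""
    params.validate_for_rate(sampling_rate_hz)
    sos_hp = signal.butter(
        params.filter_order, params.hp_cutoff_hz, "highpass",
        fs=sampling_rate_hz, output="sos",
    )
    sos_lp = signal.butter(
        params.filter_order, params.lp_cutoff_hz, "lowpass",
        fs=sampling_rate_hz, output="sos",
    )
    return np.vstack([sos_hp, sos_lp])


def bandpass_filter(trace: RawTrace, params: DetectionParams) -> RawTrace:
    """Zero-phase band-pass; same length, rate and start time as the input."""
    sos = design_bandpass(params, trace.sampling_rate_hz)
    if len(trace.samples) == 0:
        return RawTrace(trace.electrode, trace.samples.copy(),
                        trace.sampling_rate_hz, trace.t0_s)
    filtered = signal.sosfiltfilt(sos, trace.samples)
    return RawTrace(trace.electrode, filtered, trace.sampling_rate_hz, trace.t0_s)


def estimate_noise_sd(trace: RawTrace | np.ndarray, params: DetectionParams) -> float:
    """Background-noise standard deviation of a filtered trace, in uV."""
    samples = trace.samples if isinstance(trace, RawTrace) else np.asarray(trace)
    if samples.size == 0:
        raise ValueError("cannot estimate noise from an empty trace")
    if params.noise_estimator == "mad_robust":
        return float(np.median(np.abs(samples - np.median(samples))) * MAD_TO_SD)
    return float(np.std(samples))


def _excursion_events(
    y: np.ndarray, threshold: float, polarity: str
) -> tuple[np.ndarray, np.ndarray]:
    """Sample index and signed amplitude of the extremum of each
    supra-threshold excursion."""
    if polarity == "both":
        score = np.abs(y)
    elif polarity == "negative":
        score = -y
    else:
        score = y
    above = score >= threshold
    if not above.any():
        return np.empty(0, dtype=int), np.empty(0)
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [len(y)]])
    idx = np.empty(len(starts), dtype=int)
    for k, (s, e) in enumerate(zip(starts, ends)):
        idx[k] = s + int(np.argmax(score[s:e]))
    return idx, y[idx]


def detect_spikes(
    trace: RawTrace,
    params: DetectionParams,
    assume_filtered: bool = False,
) -> SpikeTrain:
    """Detect spikes on one trace.

    One event per excursion of the filtered signal beyond
    ``threshold_sd x noise s.d.``, timestamped at the excursion's extremum,
    with successive events at least ``dead_time_s`` apart.  Detected times lie
    on the trace's sample grid.
    """
    filtered = trace if assume_filtered else bandpass_filter(trace, params)
    y = filtered.samples
    if y.size == 0:
        return SpikeTrain(trace.electrode, np.empty(0), np.empty(0))
    sd = estimate_noise_sd(y, params)
    if sd == 0.0:
        # silent trace: nothing can rise above the noise
        return SpikeTrain(trace.electrode, np.empty(0), np.empty(0))
    idx, amps = _excursion_events(y, params.threshold_sd * sd, params.polarity)
    if params.dead_time_s > 0 and len(idx) > 1:
        min_gap = params.dead_time_s * trace.sampling_rate_hz
        keep = [0]
        for k in range(1, len(idx)):
            if idx[k] - idx[keep[-1]] >= min_gap:
                keep.append(k)
        idx, amps = idx[keep], amps[keep]
    times = trace.t0_s + idx / trace.sampling_rate_hz
    return SpikeTrain(trace.electrode, times, amps)


def detect_recording(rec: Recording, params: DetectionParams) -> Recording:
    """Replace a recording's spike trains with ones detected from its raw
    traces.  Raises if the recording carries no raw data."""
    if not rec.raw:
        raise ValueError("recording has no raw traces to detect from")
    trains = {eid: detect_spikes(tr, params) for eid, tr in rec.raw.items()}
    return rec.with_trains(trains)


def detect_simulated(
    rec: Recording,
    config: SimulationConfig,
    params: DetectionParams,
) -> Recording:
    """Run detection over a simulated recording, synthesizing each raw trace
    on the fly so that arbitrarily many electrodes fit in memory.

    ``rec`` must come from :func:`tunnelmea.simulate.simulate_recording` with
    the same ``config``; the per-electrode noise streams are reproduced from
    the config seed.
    """
    trains: dict[ElectrodeId, SpikeTrain] = {}
    for eid, truth_train in rec.spike_trains.items():
        trace = synthesize_trace(eid, truth_train.times_s, config)
        trains[eid] = detect_spikes(trace, params)
    return rec.with_trains(trains)
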