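# tunnelmea

Analysis of multielectrode-array (MEA) recordings from **two-compartment
organoid assembloids connected by axon microtunnels**: spike detection,
axonal propagation velocity, and — the headline statistic — the percentage
of spikes and bursts initiated on each compartment side.

## The problem

When two region-specific brain organoids (a midbrain organoid, **MO**, and a
hindbrain organoid, **HBO**) are fused into an assembloid on a microtunnel
MEA device, their axons grow through narrow PDMS tunnels that run over rows
of electrodes (an 8 × 8 array at 200 µm pitch, sampled at 12.5 kHz; up to
eight electrodes per tunnel). A spike travelling along a tunnel axon appears
on successive electrodes with a conduction delay, so the *direction* of each
action potential — and hence which population drives the communication —
can be inferred from inter-electrode timing. `tunnelmea` implements that
inference as a reusable, tested pipeline:

1. **Spike detection** — zero-phase Butterworth band-pass (200 Hz – 3 kHz),
   events at excursions beyond 6 estimated noise standard deviations
   (robust MAD estimator by default).
2. **Propagation velocity** — event trains of all electrode pairs in a
   tunnel are cross-correlated as discrete point processes on the sample
   grid; the peak lags are fitted against electrode distance through the
   origin, and the velocity is the inverse slope:
   `v = 1 / slope`, with a quantization bound `v² · T / d_max`
   (T = 80 µs sample period). Fitting over the full 1400 µm span matters: a
   single adjacent pair at this resolution can only represent the discrete
   velocities 200 µm / (k · 80 µs).
3. **Directionality** — for each tunnel's outermost electrode pair a match
   window of admissible travel times `[d/v_max, d/v_min]` (velocity band
   0.5–5 m/s by default, centred on the measured lag when available) filters
   the event lists down to pairs with a corresponding event on the other
   electrode. The windowed matching is greedy and one-to-one; the surviving
   directional events are counted per direction and reported as
   `pct_a_to_b` (MO-origin) and `pct_b_to_a` (HBO-origin). Bursts (≥ 5
   spikes with inter-spike intervals ≤ 100 ms) are matched by onset with the
   same rule.
4. **Summaries** — spike counts and mean firing rates per electrode and
   well, and DIV (days in vitro) time-course tables (mean ± SD across
   wells).

A **synthetic-data generator** produces ground-truth-annotated recordings
with the geometry and statistical structure the analysis assumes —
Poisson streams of tunnel-propagating events from either side, per-event
velocity jitter, independent background spikes, and optionally raw traces
(biphasic waveforms on Gaussian noise) — so every stage is validated by
parameter recovery without any experimental data.

## Worked example

Simulate one well of eight microtunnels for 300 s with MO-dominated traffic
(2.0 Hz MO→HBO vs 0.5 Hz HBO→MO per tunnel, 1.75 m/s ± 10 % conduction,
1 Hz background per electrode) and analyze it:

```python
from tunnelmea.reporting import run_pipeline

config = {
    "seed": 1,
    "simulation": {
        "wells": 1, "channels_per_well": 8, "duration_s": 300.0,
        "rate_a_to_b_hz": 2.0, "rate_b_to_a_hz": 0.5,
        "velocity_mps": 1.75, "velocity_jitter_frac": 0.1,
        "background_rate_hz": 1.0,
    },
}
result = run_pipeline(config)

d = result.directionality
pooled = d[(d.scope == "all") & (d.kind == "spike")].iloc[0]
print(f"directional spikes: {pooled.count_a_to_b} MO-origin, "
      f"{pooled.count_b_to_a} HBO-origin")
print(f"initiated at MO side: {pooled.pct_a_to_b:.1f}%  "
      f"HBO side: {pooled.pct_b_to_a:.1f}%")
v = result.velocity
print(f"velocity: {v.velocity_mps.mean():.2f} m/s "
      f"(range {v.velocity_mps.min():.2f}-{v.velocity_mps.max():.2f})")
```

which prints

```
directional spikes: 4815 MO-origin, 1189 HBO-origin
initiated at MO side: 80.2%  HBO side: 19.8%
velocity: 1.77 m/s (range 1.74-1.79)
```

i.e. the pipeline recovers the simulated 80/20 initiation split and the
1.75 m/s conduction velocity from event timing alone. Passing
`"detect_from_raw": True` in the simulation section additionally renders
raw voltage traces and re-detects every spike through the 6-SD
filter-and-threshold chain before the analysis.

The same stages are available from the shell:

```bash
tunnelmea simulate --config sim.yaml --output-dir out/
tunnelmea velocity --spikes out/spikes.csv --geometry out/geometry.yaml --output velocity.csv
tunnelmea directionality --spikes out/spikes.csv --geometry out/geometry.yaml --output direction.csv
tunnelmea run --config run.yaml --output-dir out/     # full pipeline + run log
```

Spike lists are plain CSV (`time_s, well, electrode_row, electrode_col,
amplitude_uv` under a `# tunnelmea-spikelist v1` header; vendor exports can
be ingested with a column mapping), geometry and run configuration are YAML,
and all outputs are CSV. See `docs/methods.md` for the model, parameter
defaults and numerical choices.

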