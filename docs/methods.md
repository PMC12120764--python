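# Methods

This note documents the models, parameter choices and numerical decisions
behind `tunnelmea`, and what the synthetic-data validation does and does not
establish about real recordings.

## Recording model and geometry

A recording is a set of per-electrode event trains (`SpikeTrain`) plus
optional raw voltage traces, on an 8 × 8 electrode array at 200 µm pitch
sampled at 12.5 kHz (80 µs period). A `ChannelGeometry` lists the
electrodes of one microtunnel in order from side A (the MO compartment,
seeded on the left) to side B (HBO, right), with strictly increasing axial
positions; positions default to k · 200 µm. All event times are treated as
points on the sample grid: sub-sample duplicates on one electrode are
physically indistinguishable and are collapsed to the earlier time.

Spike lists are serialized as CSV with times printed to 1 µs. Because the
sample period is exactly 80 µs = 8 × 10⁻⁵ s, every on-grid time is exactly
representable in six decimals and write → read round trips are lossless.

## Spike detection

* **Filter**: Butterworth high-pass at 200 Hz and low-pass at 3 kHz,
  2nd-order sections, applied forward–backward (`sosfiltfilt`). Zero-phase
  filtering is essential here: a causal filter's group delay would shift
  event times by an amount that varies with waveform shape, biasing exactly
  the inter-electrode lags the later stages measure.
* **Noise s.d.**: median absolute deviation ÷ 0.6745 by default
  (`mad_robust`); a plain standard deviation is available but is inflated
  by the spikes themselves on active electrodes. ≥ 1 s of signal is
  recommended for a stable estimate.
* **Threshold**: |filtered signal| ≥ 6 × noise s.d. (both polarities by
  default, configurable to one polarity, since extracellular axonal spikes
  are typically negative-going). One event per supra-threshold excursion,
  timestamped at the excursion's extremum — the most noise-stable landmark.
* **Dead time**: 1 ms default, the refractory-period scale; prevents one
  biphasic waveform from being counted twice.

Raising the threshold can only remove detections (monotonicity), and
identical input yields identical output; both are property-tested.

## Propagation velocity

Event trains are cross-correlated as discrete point processes: the
correlogram counts event pairs per lag bin, with bin width equal to the
sample period (finer binning is meaningless for on-grid events) and a
default lag range of ±2 ms, which covers the 1400 µm tunnel span down to
0.7 m/s. The peak lag is the modal bin; ties break deterministically toward
the smallest |lag|, then the smaller (more negative) lag. Because of that
tie rule, the mirror symmetry between (i, j) and (j, i) correlograms is
exact for the counts, and exact for the peak whenever the modal bin is
unique.

A peak enters the velocity fit only if it is **significant against chance
coincidences**: under independent trains the per-bin counts are
approximately Poisson with mean `total_pairs / n_bins`, and a peak must
exceed that distribution's 99.9 % quantile and an absolute floor of 3
pairs. This is what lets a background-only channel report "no resolvable
propagation" instead of a velocity fitted to noise.

Velocity is estimated from *all* electrode pairs of a channel, not one
pair: a through-origin least-squares fit of peak lag vs distance, with
`v = 1/|slope|` and the slope's sign giving the dominant direction. At
12.5 kHz a single 200 µm pair quantizes velocity to {2.5, 1.25, 0.83, …}
m/s and cannot resolve the physiological 1.5–2 m/s range; the 1400 µm span
restores the resolution, and each estimate carries the quantization bound
`v² · T / d_max`. Estimates from fewer than two significant pairs, or from
pairs with inconsistent lag signs, are flagged low-confidence. Note the fit
summarizes a channel with a single velocity; when traffic in the two
directions is comparable in rate, per-pair modal lags can flip sign between
the two populations and the flag, not the number, is the reliable output.

## Directionality

For each channel the outermost electrode pair (first vs last, the default,
maximizing timing resolution) is matched through a travel-time window
`[d/v_max − pad, d/v_min + pad]` built from an admissible velocity band
(default 0.5–5 m/s, pad of one sample period, floor at one sample period).
The band form is robust when a channel's correlogram is noisy; when a
significant velocity estimate exists, the matcher centres its preference on
the measured lag `d/v̂` instead of the window midpoint.

Matching is greedy and one-to-one: every pair `(t_i, t_j)` with
`t_j − t_i` inside the window is an A→B candidate (symmetrically B→A),
candidates are consumed in increasing |lag − expected lag| order with
deterministic ties toward the earlier event pair, and unmatched events are
discarded. Consequences, all property-tested against a brute-force
implementation: no event is used twice, at most `min(n_i, n_j)` directional
events arise from a pair, and swapping the electrodes (with the side
labels) exactly swaps the two percentages.

Bursts are maximal runs of ≥ 5 spikes with inter-spike intervals ≤ 100 ms
(a standard fixed-ISI rule; the parameters are exposed in the analysis
configuration) and are matched by their onset times with the same windowed
rule, giving a burst-level directionality alongside the spike-level one.

Percentages are `100 × count / total` per direction. Well- and
recording-level figures pool *counts* across channels rather than averaging
per-channel percentages — unbiased when channels differ in activity. A
scope with zero directional events reports undefined (missing) percentages,
never 50/50, and is excluded from time-course averages.

## Synthetic recordings

The generator emulates exactly the structure the analysis assumes:

| parameter | default | meaning |
|---|---|---|
| `rate_a_to_b_hz` / `rate_b_to_a_hz` | 2.0 / 0.5 Hz | Poisson rates of tunnel-propagating events per channel, per origin side |
| `velocity_mps` | 1.75 m/s | mean conduction velocity (centre of the observed 1.5–2 m/s band) |
| `velocity_jitter_frac` | 0.10 | per-event velocity s.d. as a fraction of the mean (truncated normal, ≥ 0.1 m/s) — a simple stand-in for the spread of axonal path lengths |
| `background_rate_hz` | 1.0 Hz | independent non-propagating events per electrode |
| `burst_prob`, `burst_size`, `burst_isi_s` | 0, 5, 50 ms | an initiating event becomes a burst of equally spaced events sharing one velocity |
| `noise_sd_uv`, `spike_amplitude_uv` | 3, 30 µV | trace noise and biphasic waveform peak (~10 σ, typical of tunnel-confined axonal signals) |

Each propagating event arrives at electrode positions `x` at
`t₀ + (x − x₀)/v` (A-origin; mirrored for B-origin); ground truth keeps the
exact times while the emitted trains are grid-quantized. Randomness comes
from one root seed with per-channel substreams keyed by channel id and
per-electrode noise streams keyed by (well, electrode), so raw traces can
be synthesized one electrode at a time — in any order, or streamed through
detection without holding all traces in memory (`detect_simulated`).

Background rate, burst structure and amplitudes are testing defaults, not
biological claims: the real cultures' background statistics are unknown.
The generator also omits spike sorting confounds (overlapping units,
waveform variability), electrode impedance and drift. Recovery tests
therefore show the *inference chain* is correct under its stated
assumptions; they do not certify performance on recordings that violate
them.

## Validation and problem sizes

The test suite checks every stage against an independent oracle: O(n²)
enumeration for correlograms and greedy matching, `sosfreqz` frequency
response for the filter, Monte-Carlo for noise estimation, analytic
(family-corrected) Poisson quantiles for flat correlograms, and ground
truth for end-to-end recovery. Headline regimes run at 6 wells × 8
channels × 300 s on event lists (where detection adds nothing to what the
smaller detection-recovery scenarios already establish), the exact-recovery
limit (zero jitter, zero background) at one channel × 120 s, and velocity
recovery over 20 seeded replicate channels. `scripts/acceptance.py` runs
the full raw-trace path — synthesis, 6-SD detection, matching, counting —
at 2 wells × 8 channels × 300 s per rate regime; the pooled percentage is
invariant to the number of wells, which only narrows its binomial error.

## Known limitations

* One velocity per channel: the fit does not decompose the velocity
  *distribution* across axons that the correlograms superpose.
* Bidirectional channels with near-equal traffic yield sign-ambiguous
  per-pair peaks; the estimate is flagged rather than decomposed.
* The matcher resolves ambiguity greedily; a globally optimal assignment
  (e.g. Hungarian) could differ on pathological inputs, but agreement with
  the brute-force greedy oracle is exact by construction.
* Burst detection is a fixed-ISI stand-in; adaptive methods (e.g.
  rank-surprise) are out of scope.
* No spike sorting: all threshold crossings on an electrode are treated as
  one population, which is the operating assumption of tunnel recordings.
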