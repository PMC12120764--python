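"""Directional event matching and initiation-side statistics.

The measure of inter-compartment communication is built in three steps:

1. A per-pair *match window* — the admissible travel time between two
   electrodes, derived from their distance and a velocity band (optionally
   centred on the measured correlogram lag).
2. *Windowed matching*: events on one electrode are kept only if a
   corresponding event occurs on the other electrode with a lag inside the
   window, producing an event list containing only directional events.  The
   matching is one-to-one and greedy, resolving ambiguity by closeness to the
   expected lag.
3. *Counting*: directional events travelling each way are tallied, and the
   percentage initiated on each compartment side (MO vs HBO) summarizes which
   population drives the communication.

Bursts (runs of spikes with short inter-spike intervals on one electrode)
are matched by their onset times with the same windowed rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .types import ElectrodeId, ParameterError, SpikeTrain

DEFAULT_VELOCITY_BAND_MPS = (0.5, 5.0)
DEFAULT_SAMPLE_PERIOD_S = 8e-5
DEFAULT_MAX_ISI_S = 0.1
DEFAULT_MIN_BURST_SPIKES = 5

__all__ = [
    "MatchWindow",
    "DirectionalEvent",
    "Burst",
    "DirectionalitySummary",
    "build_match_window",
    "match_directional_events",
    "detect_bursts",
    "burst_directionality",
    "compute_directionality",
]


@dataclass(frozen=True)
class MatchWindow:
    """Admissible travel-time range between an electrode pair.

    A lag ``t_j - t_i`` in ``[delta_min_s, delta_max_s]`` is consistent with
    travel i -> j; symmetrically ``t_i - t_j`` in the same range with j -> i.
    """

    distance_um: float
    delta_min_s: float
    delta_max_s: float

    def __post_init__(self) -> None:
        if not 0 < self.delta_min_s < self.delta_max_s:
            raise ParameterError(
                f"window [{self.delta_min_s}, {self.delta_max_s}] must satisfy "
                "0 < delta_min < delta_max"
            )

    @property
    def midpoint_s(self) -> float:
        return 0.5 * (self.delta_min_s + self.delta_max_s)


@dataclass(frozen=True)
class DirectionalEvent:
    """A matched event pair implying travel in one direction."""

    channel_id: str
    t_i: float
    t_j: float
    direction: str  # "A_to_B" (i before j) or "B_to_A"
    kind: str = "spike"  # or "burst"

    @property
    def lag_s(self) -> float:
        return self.t_j - self.t_i


@dataclass(frozen=True)
class Burst:
    """A run of >= min_burst_spikes spikes with inter-spike intervals below
    the ISI ceiling, on one electrode."""

    electrode: ElectrodeId
    start_s: float
    end_s: float
    n_spikes: int


@dataclass
class DirectionalitySummary:
    """Directional event counts and percentages for one scope.

    Percentages are ``None`` (undefined) when there are no directional
    events; they are never defaulted to 50/50.
    """

    scope: str  # "channel", "well" or "condition"
    scope_id: str
    kind: str  # "spike" or "burst"
    count_a_to_b: int
    count_b_to_a: int
    div: Optional[int] = None

    @property
    def total(self) -> int:
        return self.count_a_to_b + self.count_b_to_a

    @property
    def pct_a_to_b(self) -> Optional[float]:
        return 100.0 * self.count_a_to_b / self.total if self.total else None

    @property
    def pct_b_to_a(self) -> Optional[float]:
        return 100.0 * self.count_b_to_a / self.total if self.total else None


def build_match_window(
    distance_um: float,
    velocity_band_mps: tuple[float, float] = DEFAULT_VELOCITY_BAND_MPS,
    pad_samples: int = 0,
    sample_period_s: float = DEFAULT_SAMPLE_PERIOD_S,
) -> MatchWindow:
    """Window of admissible travel times for a pair ``distance_um`` apart.

    ``delta_min = distance / v_max - pad`` (floored at one sample period) and
    ``delta_max = distance / v_min + pad``, with ``pad = pad_samples`` sample
    periods.
    """
    v_min, v_max = velocity_band_mps
    if not 0 < v_min < v_max:
        raise ParameterError("velocity band must satisfy 0 < v_min < v_max")
    if distance_um <= 0:
        raise ParameterError("distance_um must be positive")
    pad = pad_samples * sample_period_s
    d_m = distance_um * 1e-6
    delta_min = max(d_m / v_max - pad, sample_period_s)
    delta_max = d_m / v_min + pad
    return MatchWindow(distance_um, delta_min, delta_max)


def match_directional_events(
    train_i: SpikeTrain,
    train_j: SpikeTrain,
    window: MatchWindow,
    expected_lag_s: Optional[float] = None,
    channel_id: str = "",
    kind: str = "spike",
) -> list[DirectionalEvent]:
    """Greedy one-to-one windowed matching of two event trains.

    Every pair ``(t_i, t_j)`` with ``t_j - t_i`` inside the window is an
    i->j (A->B) candidate, and with ``t_i - t_j`` inside the window a j->i
    (B->A) candidate.  Candidates are consumed greedily in increasing
    ``|lag - expected_lag|`` order (ties toward the earlier event pair), each
    underlying event at most once; unmatched events are discarded.

    ``expected_lag_s`` defaults to the window midpoint; pass
    ``distance / velocity_estimate`` when a measured velocity is available.
    """
    expected = window.midpoint_s if expected_lag_s is None else expected_lag_s
    ti, tj = train_i.times_s, train_j.times_s
    if not len(ti) or not len(tj):
        return []

    cands: list[tuple[float, float, float, int, int, str]] = []
    # i -> j: t_j in [t_i + dmin, t_i + dmax]
    lo = np.searchsorted(tj, ti + window.delta_min_s - 1e-12, side="left")
    hi = np.searchsorted(tj, ti + window.delta_max_s + 1e-12, side="right")
    for a, (s, e) in enumerate(zip(lo, hi)):
        for b in range(s, e):
            lag = tj[b] - ti[a]
            cands.append((abs(lag - expected), ti[a], tj[b], a, b, "A_to_B"))
    # j -> i: t_j in [t_i - dmax, t_i - dmin]
    lo = np.searchsorted(tj, ti - window.delta_max_s - 1e-12, side="left")
    hi = np.searchsorted(tj, ti - window.delta_min_s + 1e-12, side="right")
    for a, (s, e) in enumerate(zip(lo, hi)):
        for b in range(s, e):
            lag = ti[a] - tj[b]
            cands.append((abs(lag - expected), ti[a], tj[b], a, b, "B_to_A"))

    cands.sort(key=lambda c: (c[0], min(c[1], c[2]), max(c[1], c[2]), c[5]))
    used_i = np.zeros(len(ti), dtype=bool)
    used_j = np.zeros(len(tj), dtype=bool)
    out: list[DirectionalEvent] = []
    for _, t_i, t_j, a, b, direction in cands:
        if used_i[a] or used_j[b]:
            continue
        used_i[a] = used_j[b] = True
        out.append(DirectionalEvent(channel_id, float(t_i), float(t_j), direction, kind))
    out.sort(key=lambda e: (min(e.t_i, e.t_j), e.t_i))
    return out


def detect_bursts(
    train: SpikeTrain,
    max_isi_s: float = DEFAULT_MAX_ISI_S,
    min_burst_spikes: int = DEFAULT_MIN_BURST_SPIKES,
) -> list[Burst]:
    """Maximal runs of consecutive spikes with ISI <= ``max_isi_s`` and at
    least ``min_burst_spikes`` members.  Bursts never overlap."""
    times = train.times_s
    if len(times) < min_burst_spikes:
        return []
    gaps = np.diff(times) > max_isi_s
    # run boundaries: indices where a new run starts
    starts = np.concatenate([[0], np.flatnonzero(gaps) + 1])
    ends = np.concatenate([np.flatnonzero(gaps), [len(times) - 1]])
    bursts = []
    for s, e in zip(starts, ends):
        n = e - s + 1
        if n >= min_burst_spikes:
            bursts.append(Burst(train.electrode, float(times[s]), float(times[e]), int(n)))
    return bursts


def burst_directionality(
    bursts_i: Sequence[Burst],
    bursts_j: Sequence[Burst],
    window: MatchWindow,
    expected_lag_s: Optional[float] = None,
    channel_id: str = "",
) -> list[DirectionalEvent]:
    """Match bursts between the two electrodes of a pair by their onset
    times, with the same windowed greedy rule as spikes."""
    def onsets(bursts: Sequence[Burst], electrode) -> SpikeTrain:
        times = np.array(sorted(b.start_s for b in bursts))
        return SpikeTrain(electrode, times)

    if not bursts_i or not bursts_j:
        return []
    train_i = onsets(bursts_i, bursts_i[0].electrode)
    train_j = onsets(bursts_j, bursts_j[0].electrode)
    return match_directional_events(
        train_i, train_j, window, expected_lag_s, channel_id, kind="burst"
    )


def compute_directionality(
    events: Sequence[DirectionalEvent],
    scope: str,
    scope_id: str,
    kind: str = "spike",
    div: Optional[int] = None,
) -> DirectionalitySummary:
    """Pooled directional counts and percentages over ``events``.

    Events of other kinds are ignored; with zero matching events the
    percentages are undefined (``None``), never 50/50.
    """
    selected = [e for e in events if e.kind == kind]
    n_ab = sum(1 for e in selected if e.direction == "A_to_B")
    n_ba = sum(1 for e in selected if e.direction == "B_to_A")
    return DirectionalitySummary(scope, scope_id, kind, n_ab, n_ba, div=div)
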