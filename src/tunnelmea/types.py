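"""Core domain types for microtunnel MEA recordings.

The recording geometry is a commercial multiwell MEA: each well carries an
8 x 8 planar electrode array at 200 um pitch, overlaid by a PDMS microtunnel
device so that every row of electrodes sits under one axon-guiding tunnel
connecting the two organoid compartments (side A, midbrain organoid "MO" on
the left; side B, hindbrain organoid "HBO" on the right).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np

ARRAY_ROWS = 8
ARRAY_COLS = 8
DEFAULT_SAMPLING_RATE_HZ = 12_500.0
DEFAULT_PITCH_UM = 200.0

__all__ = [
    "ARRAY_ROWS",
    "ARRAY_COLS",
    "DEFAULT_SAMPLING_RATE_HZ",
    "DEFAULT_PITCH_UM",
    "ElectrodeId",
    "ChannelGeometry",
    "RawTrace",
    "SpikeTrain",
    "Recording",
    "DetectionParams",
    "GeometryError",
    "ParameterError",
    "SpikeListFormatError",
]


class GeometryError(ValueError):
    """A channel-geometry description violates its invariants."""


class ParameterError(ValueError):
    """An analysis parameter is out of its admissible range."""


class SpikeListFormatError(ValueError):
    """A spike-list file cannot be parsed under the declared dialect."""


@dataclass(frozen=True, order=True)
class ElectrodeId:
    """One electrode of the 8 x 8 array, addressed by well and (row, col)."""

    well_id: str
    row: int
    col: int

    def __post_init__(self) -> None:
        if not (0 <= self.row < ARRAY_ROWS and 0 <= self.col < ARRAY_COLS):
            raise GeometryError(
                f"electrode ({self.row}, {self.col}) outside the "
                f"{ARRAY_ROWS}x{ARRAY_COLS} array"
            )

    @property
    def index(self) -> int:
        """Flat array index, ``8 * row + col``, in 0..63."""
        return ARRAY_COLS * self.row + self.col

    @classmethod
    def from_index(cls, well_id: str, index: int) -> "ElectrodeId":
        if not 0 <= index < ARRAY_ROWS * ARRAY_COLS:
            raise GeometryError(f"electrode index {index} outside 0..63")
        return cls(well_id, index // ARRAY_COLS, index % ARRAY_COLS)

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"{self.well_id}:({self.row},{self.col})"


@dataclass(frozen=True)
class ChannelGeometry:
    """Ordered electrodes along one microtunnel.

    The first electrode is nearest side A (by convention the MO compartment,
    seeded on the left), the last nearest side B (HBO, right).  Positions are
    measured along the tunnel axis in micrometres and must be strictly
    increasing; the nominal electrode pitch is 200 um but irregular spacing is
    allowed.
    """

    channel_id: str
    electrodes: tuple[ElectrodeId, ...]
    positions_um: tuple[float, ...] = ()
    side_a_label: str = "MO"
    side_b_label: str = "HBO"
    spacing_um: float = DEFAULT_PITCH_UM

    def __post_init__(self) -> None:
        electrodes = tuple(self.electrodes)
        if not 2 <= len(electrodes) <= ARRAY_COLS:
            raise GeometryError(
                f"channel {self.channel_id!r}: need 2..{ARRAY_COLS} electrodes, "
                f"got {len(electrodes)}"
            )
        if len(set(electrodes)) != len(electrodes):
            raise GeometryError(
                f"channel {self.channel_id!r}: duplicate electrode in channel"
            )
        wells = {e.well_id for e in electrodes}
        if len(wells) != 1:
            raise GeometryError(
                f"channel {self.channel_id!r}: electrodes span wells {sorted(wells)}"
            )
        positions = tuple(float(p) for p in self.positions_um)
        if not positions:
            positions = tuple(k * self.spacing_um for k in range(len(electrodes)))
        if len(positions) != len(electrodes):
            raise GeometryError(
                f"channel {self.channel_id!r}: {len(positions)} positions for "
                f"{len(electrodes)} electrodes"
            )
        if any(b - a <= 0 for a, b in zip(positions, positions[1:])):
            raise GeometryError(
                f"channel {self.channel_id!r}: positions must be strictly increasing"
            )
        object.__setattr__(self, "electrodes", electrodes)
        object.__setattr__(self, "positions_um", positions)

    @property
    def well_id(self) -> str:
        return self.electrodes[0].well_id

    @property
    def n_electrodes(self) -> int:
        return len(self.electrodes)

    @property
    def span_um(self) -> float:
        """Distance between the outermost electrodes."""
        return self.positions_um[-1] - self.positions_um[0]

    def distance_um(self, i: int, j: int) -> float:
        """Axial distance between electrodes at ordinal indices ``i`` and ``j``."""
        return abs(self.positions_um[j] - self.positions_um[i])


@dataclass
class RawTrace:
    """A raw extracellular voltage trace from one electrode, in microvolts."""

    electrode: ElectrodeId
    samples: np.ndarray
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ParameterError("sampling_rate_hz must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ParameterError("samples must be one-dimensional")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sampling_rate_hz

    @property
    def sample_period_s(self) -> float:
        return 1.0 / self.sampling_rate_hz


@dataclass
class SpikeTrain:
    """Sorted event times (seconds) for one electrode.

    Times are strictly increasing after construction: events closer than one
    sample period at 12.5 kHz are physically indistinguishable and are
    collapsed to the earlier time.
    """

    electrode: ElectrodeId
    times_s: np.ndarray
    amplitudes_uv: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times_s, dtype=float)
        if times.size and times.min() < 0:
            raise ValueError("negative event times")
        amps = self.amplitudes_uv
        if amps is not None:
            amps = np.asarray(amps, dtype=float)
            if amps.shape != times.shape:
                raise ValueError("amplitudes and times differ in length")
        self.times_s = times
        self.amplitudes_uv = amps

    @classmethod
    def from_times(
        cls,
        electrode: ElectrodeId,
        times_s: Sequence[float],
        amplitudes_uv: Optional[Sequence[float]] = None,
        sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ,
    ) -> "SpikeTrain":
        """Build a train from possibly unsorted times, collapsing sub-sample
        duplicates to the earlier event (keeping its amplitude)."""
        times = np.asarray(times_s, dtype=float)
        amps = None if amplitudes_uv is None else np.asarray(amplitudes_uv, float)
        order = np.argsort(times, kind="stable")
        times = times[order]
        if amps is not None:
            amps = amps[order]
        if times.size:
            keep = np.empty(times.size, dtype=bool)
            keep[0] = True
            # strictly-less-than one sample period counts as a duplicate
            np.greater_equal(np.diff(times), 1.0 / sampling_rate_hz - 1e-12, out=keep[1:])
            times = times[keep]
            if amps is not None:
                amps = amps[keep]
        return cls(electrode, times, amps)

    def __len__(self) -> int:
        return int(self.times_s.size)

    @property
    def n_events(self) -> int:
        return len(self)


@dataclass
class Recording:
    """One MEA recording session: spike trains per electrode plus metadata."""

    spike_trains: dict[ElectrodeId, SpikeTrain]
    duration_s: float
    geometry: tuple[ChannelGeometry, ...] = ()
    raw: Optional[Mapping[ElectrodeId, RawTrace]] = None
    div: Optional[int] = None
    condition: str = ""

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        self.geometry = tuple(self.geometry)
        for eid, train in self.spike_trains.items():
            if train.electrode != eid:
                raise ValueError(f"train keyed by {eid} carries electrode {train.electrode}")
            if len(train) and train.times_s[-1] > self.duration_s + 1e-9:
                raise ValueError(
                    f"electrode {eid}: event at {train.times_s[-1]:.6f}s exceeds "
                    f"duration {self.duration_s:.6f}s"
                )

    @property
    def n_events(self) -> int:
        return sum(len(t) for t in self.spike_trains.values())

    @property
    def wells(self) -> tuple[str, ...]:
        return tuple(sorted({e.well_id for e in self.spike_trains}))

    def train(self, electrode: ElectrodeId) -> SpikeTrain:
        """Train for ``electrode``; an empty train if it never fired."""
        try:
            return self.spike_trains[electrode]
        except KeyError:
            return SpikeTrain(electrode, np.empty(0))

    def with_trains(self, trains: dict[ElectrodeId, SpikeTrain]) -> "Recording":
        return replace(self, spike_trains=trains, raw=None)


@dataclass(frozen=True)
class DetectionParams:
    """Filter-and-threshold spike detection settings.

    The detector band-pass filters (Butterworth, zero-phase) between
    ``hp_cutoff_hz`` and ``lp_cutoff_hz`` and marks one event per excursion of
    the filtered signal beyond ``threshold_sd`` estimated noise standard
    deviations.
    """

    hp_cutoff_hz: float = 200.0
    lp_cutoff_hz: float = 3000.0
    filter_order: int = 2
    threshold_sd: float = 6.0
    noise_estimator: str = "mad_robust"  # or "plain_sd"
    dead_time_s: float = 0.001
    polarity: str = "both"  # "both", "negative" or "positive"

    def __post_init__(self) -> None:
        if not 0 < self.hp_cutoff_hz < self.lp_cutoff_hz:
            raise ParameterError("need 0 < hp_cutoff_hz < lp_cutoff_hz")
        if self.threshold_sd <= 0:
            raise ParameterError("threshold_sd must be positive")
        if self.dead_time_s < 0:
            raise ParameterError("dead_time_s must be nonnegative")
        if self.noise_estimator not in ("mad_robust", "plain_sd"):
            raise ParameterError(f"unknown noise estimator {self.noise_estimator!r}")
        if self.polarity not in ("both", "negative", "positive"):
            raise ParameterError(f"unknown polarity {self.polarity!r}")

    def validate_for_rate(self, sampling_rate_hz: float) -> None:
        if self.lp_cutoff_hz >= sampling_rate_hz / 2:
            raise ParameterError(
                f"lp_cutoff_hz={self.lp_cutoff_hz} not below Nyquist "
                f"({sampling_rate_hz / 2} Hz)"
            )


def full_array(well_id: str) -> list[ElectrodeId]:
    """All 64 electrodes of one well, row-major."""
    return [ElectrodeId(well_id, r, c) for r in range(ARRAY_ROWS) for c in range(ARRAY_COLS)]


def tunnel_rows_geometry(
    well_id: str,
    n_channels: int = ARRAY_ROWS,
    n_electrodes: int = ARRAY_COLS,
    spacing_um: float = DEFAULT_PITCH_UM,
    side_a_label: str = "MO",
    side_b_label: str = "HBO",
) -> list[ChannelGeometry]:
    """Standard microtunnel layout: each array row is one tunnel, columns
    ordered left (side A) to right (side B)."""
    return [
        ChannelGeometry(
            channel_id=f"{well_id}-t{r}",
            electrodes=tuple(ElectrodeId(well_id, r, c) for c in range(n_electrodes)),
            positions_um=tuple(c * spacing_um for c in range(n_electrodes)),
            side_a_label=side_a_label,
            side_b_label=side_b_label,
            spacing_um=spacing_um,
        )
        for r in range(n_channels)
    ]
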