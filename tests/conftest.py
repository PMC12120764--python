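"""Shared fixtures: small geometries, trains and simulation configs."""

import numpy as np
import pytest

import tunnelmea as tm

SAMPLE_PERIOD = 8e-5  # 12.5 kHz


@pytest.fixture
def channel8():
    """One microtunnel with 8 electrodes at 200 um pitch (row 0 of well W1)."""
    return tm.tunnel_rows_geometry("W1", n_channels=1)[0]


@pytest.fixture
def channel_pair_geometry():
    """Two-electrode channel, 1400 um apart (outermost pair)."""
    return tm.ChannelGeometry(
        channel_id="W1-pair",
        electrodes=(tm.ElectrodeId("W1", 0, 0), tm.ElectrodeId("W1", 0, 7)),
        positions_um=(0.0, 1400.0),
    )


def train(times, well="W1", row=0, col=0):
    eid = tm.ElectrodeId(well, row, col)
    return tm.SpikeTrain.from_times(eid, np.asarray(times, dtype=float))


@pytest.fixture
def make_train():
    return train
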