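"""Shared fixtures: small simulated sessions with known ground truth."""

import numpy as np
import pytest

from streamsync.config import SyncConfig
from streamsync.simulator import (
    DeviceSpec,
    NetworkSpec,
    VirtualClock,
    ZERO_NETWORK,
    simulate_session,
)
from streamsync.streams import StreamInfo


@pytest.fixture
def zero_network():
    return ZERO_NETWORK


@pytest.fixture
def small_session():
    """Two-device 20 s session: drifting EEG-like stream + marker stream."""
    devices = [
        DeviceSpec(
            info=StreamInfo(
                name="eeg", type="EEG", nominal_srate=250.0, channel_count=2,
                source_id="eeg-01",
            ),
            timestamp_noise_std=1e-4,
            signal=lambda t: np.sin(2 * np.pi * 3.0 * t),
        ),
        DeviceSpec(
            info=StreamInfo(
                name="markers", type="Markers", nominal_srate=0.0,
                channel_format="string", source_id="mk-01",
            ),
            event_times=np.arange(0.5, 20.0, 1.0),
            marker_labels=[f"ev{i}" for i in range(20)],
        ),
    ]
    clocks = [VirtualClock(epoch_offset=0.5, drift=1e-5), VirtualClock(epoch_offset=-0.3)]
    return simulate_session(
        devices, clocks, NetworkSpec(), cfg=SyncConfig(), duration=20.0, seed=11
    )


@pytest.fixture
def noiseless_session():
    """One ideal device against an ideal recorder: exact-recovery limit."""
    devices = [
        DeviceSpec(
            info=StreamInfo(name="clean", type="EEG", nominal_srate=100.0, source_id="c1"),
            signal=lambda t: np.cos(t),
        )
    ]
    clocks = [VirtualClock()]
    return simulate_session(
        devices, clocks, ZERO_NETWORK, cfg=SyncConfig(), duration=10.0, seed=5
    )
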