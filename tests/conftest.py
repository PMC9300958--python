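"""Shared fixtures: layouts, configs, and cached synthetic recordings."""

from __future__ import annotations

import numpy as np
import pytest

from qeeg.io import StudyConfig
from qeeg.layout import ChannelLayout, default_layout, delaunay_adjacency
from qeeg.preprocess import EpochSet


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def cfg():
    return StudyConfig()


@pytest.fixture
def toy_layout():
    """Four scalp channels on a unit square (fully triangulated) + 2 EOG."""
    pos = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
    adj = delaunay_adjacency(pos, prune_factor=10.0)
    return ChannelLayout(
        labels=("A", "B", "C", "D", "EOG1", "EOG2"),
        positions=pos,
        adjacency=adj,
        channel_kind=("scalp",) * 4 + ("eog",) * 2,
    )


def make_epochset(
    data: np.ndarray, fs: float = 256.0, epoch_length: float = 2.0,
    labels: tuple[str, ...] | None = None,
) -> EpochSet:
    """Wrap a [n_epochs, n_channels, n_samples] array as an EpochSet."""
    labels = labels or tuple(f"ch{i}" for i in range(data.shape[1]))
    return EpochSet(epochs=data, fs=fs, epoch_length=epoch_length,
                    channel_labels=labels)


@pytest.fixture(scope="session")
def clean_recording(layout):
    """One artifact-free synthetic recording, shared across tests."""
    from qeeg.synth import SyntheticStudyConfig, simulate_recording

    scfg = SyntheticStudyConfig(
        duration=30.0, fs=512.0, blink_rate=0.0, emg_rate=0.0, seed=11
    )
    rec, gt = simulate_recording(scfg, 0, "air_baseline", "eyes_open", layout)
    return rec, gt


@pytest.fixture(scope="session")
def clean_epochs(clean_recording, cfg):
    from qeeg.preprocess import preprocess_recording

    ep, _ = preprocess_recording(clean_recording[0], cfg)
    return ep
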