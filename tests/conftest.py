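"""Shared fixtures.

The expensive fixtures (trained networks) are session-scoped and sized
so the whole suite stays well inside a laptop-scale budget; all
randomness is seeded.
"""

from __future__ import annotations

import numpy as np
import pytest

from memlstm.device import MemristorParams
from memlstm.lstm import TrainConfig, train
from memlstm.signalprep import Recording, WindowedDataset, make_windows


@pytest.fixture()
def params() -> MemristorParams:
    return MemristorParams()


@pytest.fixture(scope="session")
def sine_dataset() -> tuple[WindowedDataset, WindowedDataset]:
    """Noiseless sine forecasting task: (train windows, test windows)."""
    n = 2000
    t = np.arange(n)
    x = np.sin(2 * np.pi * t / 40.0)
    cut = int(0.8 * n)
    train_ds = make_windows(Recording(x[:cut]), L=20)
    test_ds = make_windows(Recording(x[cut:]), L=20)
    return train_ds, test_ds


@pytest.fixture(scope="session")
def sine_net(sine_dataset):
    """Small network trained to convergence on the sine task."""
    train_ds, _ = sine_dataset
    hyper = TrainConfig(hidden=16, feature_dim=16, max_epochs=200,
                        batch_size=64, patience=15)
    network, history = train(train_ds, hyper, seed=0)
    return network, history
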