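import numpy as np
import pytest

from modadvice.network import NODE_NAMES, EmaMatrix


def ema_from_columns(columns: dict[str, np.ndarray], pid: str = "P1") -> EmaMatrix:
    """Build a full EmaMatrix, defaulting unspecified nodes to well-behaved
    independent noise around mid-scale (sd comfortably above the pruning
    threshold)."""
    n = len(next(iter(columns.values())))
    rng = np.random.default_rng(987654)
    values = np.empty((n, len(NODE_NAMES)))
    for j, name in enumerate(NODE_NAMES):
        if name in columns:
            values[:, j] = columns[name]
        else:
            values[:, j] = np.clip(50 + 15 * rng.standard_normal(n), 0, 100)
    return EmaMatrix(pid, values)


@pytest.fixture
def rng():
    return np.random.default_rng(20230929)


@pytest.fixture
def full_ema(rng):
    """84 complete beeps, all columns fluctuating, well-conditioned."""
    values = np.clip(50 + 15 * rng.standard_normal((84, len(NODE_NAMES))), 0, 100)
    return EmaMatrix("P1", values)
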