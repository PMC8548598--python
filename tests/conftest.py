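import numpy as np
import pandas as pd
import pytest

from circaflux import TraceSet, default_grid


@pytest.fixture
def grid_6d():
    """30-min sampling grid over 6 days (the standard recording length)."""
    return default_grid(144.0, 0.5)


@pytest.fixture
def design_6x4():
    """Sample annotation of the standard 6-timepoint x 4-replicate design."""
    tp = np.array([0.0, 4, 8, 12, 16, 20])
    samples = [f"t{int(t):02d}_r{r}" for t in tp for r in range(1, 5)]
    tvec = np.array([t for t in tp for _ in range(4)])
    annot = pd.DataFrame({"sample": samples, "timepoint_h": tvec,
                          "replicate": list(range(1, 5)) * 6})
    return samples, tvec, annot


def cosine_gene(tvec, baseline=100.0, rel_amp=0.5, lag=6.0, period=24.0):
    """Noise-free rhythmic gene values on a per-sample timepoint vector."""
    return baseline * (1 + rel_amp * np.cos(2 * np.pi * (tvec - lag) / period))


@pytest.fixture
def make_traceset():
    def _make(t, *columns, names=None):
        vals = np.column_stack(columns)
        names = names or [f"x{i}" for i in range(vals.shape[1])]
        return TraceSet(t, vals, names)
    return _make
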