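import numpy as np
import pandas as pd
import pytest

from refstab import AnalysisConfig, CqTable


def make_cq(values: dict[str, list[float]], samples: list[str] | None = None,
            group: list[str] | None = None,
            condition: list[str] | None = None) -> CqTable:
    """Small-fixture helper: wide Cq dict -> validated CqTable."""
    genes = list(values)
    n = len(values[genes[0]])
    samples = samples or [f"S{i+1}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "group": group or ["g1"] * n,
            "condition": condition or ["control"] * n,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    cq = pd.DataFrame(values, index=samples).T.astype(float)
    cq.index.name = "gene"
    return CqTable(cq, meta)


@pytest.fixture
def config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture
def four_sample_cq() -> CqTable:
    """Three genes whose pairwise Cq differences are known by hand."""
    return make_cq({
        "A": [20.0, 21.0, 22.0, 23.0],
        "B": [25.0, 26.0, 27.0, 28.0],
        "C": [20.0, 23.0, 22.0, 25.0],
    })


def quantize_dyadic(x, grid: int = 1024):
    """Round onto an exactly representable binary grid (multiples of 1/grid).

    On that grid, adding a grid-aligned constant is exact in IEEE doubles,
    so loading-shift cancellation can be asserted bit-for-bit.
    """
    return np.round(np.asarray(x, dtype=float) * grid) / grid
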