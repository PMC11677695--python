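import numpy as np
import pytest

from semark import FPKM_TISSUES, FpkmMatrix, RunConfig
from semark.io import CtDataset, CtRecord


@pytest.fixture
def config():
    return RunConfig()


@pytest.fixture
def make_matrix():
    """Build an FpkmMatrix from {transcript: {tissue: fpkm}} rows (0 default)."""

    def _make(rows: dict[str, dict[str, float]]) -> FpkmMatrix:
        ids = tuple(rows)
        values = np.array(
            [[rows[t].get(tissue, 0.0) for tissue in FPKM_TISSUES] for t in ids]
        )
        return FpkmMatrix(ids, FPKM_TISSUES, values)

    return _make


@pytest.fixture
def make_ct_dataset():
    """Build a CtDataset from (tissue, gene, replicate, ct-or-None) tuples."""

    def _make(rows) -> CtDataset:
        return CtDataset(tuple(CtRecord(*r) for r in rows))

    return _make


@pytest.fixture
def random_fpkm_values():
    """Seeded random FPKM rows mixing skewed values, zeros and rule-boundary ratios."""

    def _make(n: int, seed: int = 0) -> np.ndarray:
        rng = np.random.default_rng(seed)
        vals = rng.lognormal(np.log(2.0), 1.5, size=(n, 6))
        zero_mask = rng.random(size=vals.shape) < 0.15
        vals[zero_mask] = 0.0
        # plant exact 8x / equality boundaries in a slice of rows
        boundary = rng.random(n) < 0.2
        for i in np.flatnonzero(boundary):
            j, k = rng.choice(6, size=2, replace=False)
            vals[i, j] = 8.0 * vals[i, k]
        return vals

    return _make
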