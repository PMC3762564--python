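import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from rohmap.geno_io import GenotypeDataset, Marker, Sample


def make_dataset(calls, phenotypes=None, chrom="25", spacing_bp=10_000, start_bp=100_000):
    """Small dataset builder: calls is (n_samples, n_markers) of codes."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_markers = calls.shape
    phenotypes = phenotypes or ["case"] * n_samples
    samples = [Sample(f"s{i + 1}", p) for i, p in enumerate(phenotypes)]
    markers = [
        Marker(f"m{j + 1}", chrom, start_bp + j * spacing_bp, "A", "G")
        for j in range(n_markers)
    ]
    return GenotypeDataset(samples, markers, calls)


@pytest.fixture
def six_three_dataset():
    """6 cases / 3 controls with a perfectly segregating marker.

    Marker m1 fixes cases hom A and controls hom G (the complete
    separation pattern); m2 is uninformative.
    """
    calls = np.array(
        [[0, 1]] * 6 + [[2, 1]] * 3, dtype=np.int8
    )
    return make_dataset(calls, ["case"] * 6 + ["control"] * 3)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
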