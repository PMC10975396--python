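"""Shared fixtures: small genetic maps, founders, and a miniature benchmark."""

import numpy as np
import pandas as pd
import pytest

from bcnam import benchmark, simpop
from bcnam.genotypes import MarkerMatrix


@pytest.fixture(scope="session")
def small_map():
    return simpop.make_genetic_map(3, 20, 100.0)


@pytest.fixture(scope="session")
def founders(small_map):
    return simpop.make_founders(small_map, {"D1": 0.5, "D2": 0.4}, seed=11)


@pytest.fixture(scope="session")
def mini_benchmark():
    """A very small end-to-end benchmark for pipeline and CV plumbing tests."""
    return benchmark.make_benchmark(
        seed=3, n_families=4, lines_per_family=6, n_chrom=4,
        markers_per_chrom=50, n_envs=2, n_testers=2,
    )


def marker_matrix(values, lines=None, markers=None, is_indel=None):
    """Build a MarkerMatrix from a plain array of -1/0/1/NaN codes."""
    values = np.asarray(values, dtype=float)
    lines = lines or [f"L{i}" for i in range(values.shape[0])]
    markers = markers or [f"m{j}" for j in range(values.shape[1])]
    meta = pd.DataFrame(
        {
            "chrom": ".",
            "pos": -1,
            "is_indel": is_indel if is_indel is not None else False,
        },
        index=pd.Index(markers),
    )
    return MarkerMatrix(pd.DataFrame(values, index=lines, columns=markers), meta)
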