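"""Shared fixtures and independent oracles for the test suite."""
from __future__ import annotations

import numpy as np
import pytest

import ppgdtw as pp


def brute_dtw(x, y) -> float:
    """Independent full-matrix DTW distance (plain Python lists, no reuse).

    Fixed-start/fixed-end boundary: first row and column accumulate.
    Deliberately written differently from the package kernels so it can serve
    as an oracle.
    """
    n, m = len(x), len(y)
    D = [[0.0] * m for _ in range(n)]
    D[0][0] = abs(x[0] - y[0])
    for j in range(1, m):
        D[0][j] = D[0][j - 1] + abs(x[0] - y[j])
    for i in range(1, n):
        D[i][0] = D[i - 1][0] + abs(x[i] - y[0])
        for j in range(1, m):
            D[i][j] = abs(x[i] - y[j]) + min(D[i - 1][j], D[i][j - 1], D[i - 1][j - 1])
    return D[n - 1][m - 1]


@pytest.fixture(scope="session")
def classic_spec() -> pp.SimulationSpec:
    return pp.SimulationSpec(duration_s=60.0, hr_bpm=60.0)


@pytest.fixture(scope="session")
def classic_noiseless(classic_spec) -> pp.SimulationResult:
    return pp.simulate(classic_spec)


@pytest.fixture(scope="session")
def classic_template(classic_spec) -> pp.AnnotatedTemplate:
    return pp.make_prime_template(classic_spec)
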