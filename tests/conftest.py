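"""Shared fixtures: a session-wide cache of PDE solutions.

Several tests exercise the same (K, G, n) systems; solving each once and
sharing the curve keeps the suite fast without weakening any check.
"""

from __future__ import annotations

import numpy as np
import pytest

from matrixrelease.core import DimensionlessParams
from matrixrelease.pde import Mesh, SolverOptions, solve


@pytest.fixture(scope="session")
def solve_cached():
    """Memoized solver: solve_cached(params, mesh_n, rtol, grid) -> (curve, states)."""
    cache: dict = {}

    def _solve(params: DimensionlessParams, mesh_n: int, rtol: float,
               grid: np.ndarray):
        key = (params.K, params.G, params.n, mesh_n, rtol,
               float(grid[0]), float(grid[-1]), len(grid))
        if key not in cache:
            cache[key] = solve(
                params,
                Mesh(mesh_n),
                SolverOptions(rel_tol=rtol, output_tau=np.asarray(grid, float)),
            )
        return cache[key]

    return _solve
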