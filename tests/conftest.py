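"""Shared fixtures and independent oracles for the spacol test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from spacol import default_design_matrix, load_reference_spectra

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def design():
    """The packaged five-wavelength, three-chromophore design matrix."""
    return default_design_matrix()


@pytest.fixture(scope="session")
def reference_spectra():
    return load_reference_spectra()


# ---------------------------------------------------------------------------
# Brute-force simplex grid-search oracle (independent of the package solver)
# ---------------------------------------------------------------------------


def _simplex_grid(resolution: float) -> np.ndarray:
    """All points of the 2-simplex lattice with the given spacing."""
    n = int(round(1.0 / resolution))
    pts = []
    for i in range(n + 1):
        for j in range(n + 1 - i):
            pts.append((i, j, n - i - j))
    return np.asarray(pts, dtype=float) / n


def simplex_grid_oracle(
    A: np.ndarray,
    b: np.ndarray,
    coarse: float = 1e-2,
    fine: float = 1e-3,
    finest: float = 1e-4,
) -> tuple[np.ndarray, float]:
    """Exhaustive grid search over the simplex minimizing ||A c - b||.

    Coarse global sweep at ``coarse`` spacing, then two local box refinements
    (at ``fine`` and ``finest`` spacing) around the running best, each box
    re-projected onto the simplex. Returns (c_best, residual_norm).
    """
    grid = _simplex_grid(coarse)
    r = np.linalg.norm(grid @ A.T - b, axis=1)
    best = grid[np.argmin(r)]

    for step, halfwidth in ((fine, coarse), (finest, fine)):
        offsets = np.arange(-halfwidth, halfwidth + step / 2, step)
        da, db = np.meshgrid(offsets, offsets)
        c0 = best[0] + da.ravel()
        c1 = best[1] + db.ravel()
        c2 = 1.0 - c0 - c1
        cand = np.column_stack([c0, c1, c2])
        ok = np.all(cand >= -1e-12, axis=1)
        cand = np.clip(cand[ok], 0.0, None)
        cand /= cand.sum(axis=1, keepdims=True)
        rc = np.linalg.norm(cand @ A.T - b, axis=1)
        best = cand[np.argmin(rc)]

    return best, float(np.linalg.norm(A @ best - b))
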