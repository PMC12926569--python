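"""Per-pixel linear spectral unmixing into relative chromophore concentrations.

Model: after fluence normalization, the pixel intensity vector across the W
imaging wavelengths is a non-negative linear mixture of the normalized
chromophore spectra, ``I = k * A @ c + noise``, where ``A`` is the design
matrix, ``c`` the relative concentrations (non-negative, summing to 1) and
``k`` an arbitrary global scale (arbitrary pixel units times the constant
Grueneisen factor). The solver estimates ``c``; the unknown scale is removed
by construction, so the output is a *relative* concentration. For display and
quantification, relative concentrations are rescaled so that 1000 a.u. equals
a relative concentration of 1.

Three solvers are provided:

``ols-clip`` (default)
    The sequential recipe: unconstrained least squares, negative entries
    replaced by 0, then renormalized to sum 1. Exactly invariant to the
    global intensity scale (the renormalization is radial), which is the
    right property for arbitrary-unit photoacoustic data.
``nnls``
    Non-negative least squares followed by the same renormalization; also
    exactly scale-invariant (the non-negativity cone is scale-free).
``simplex``
    Exact least squares constrained to the probability simplex, computed by
    enumerating the faces of the simplex and solving the equality-constrained
    problem on each (closed-form KKT; exact for the small chromophore counts
    used here). This solver treats the intensity vector as being on the
    relative-concentration scale (mixture sums to 1 in the data units); it is
    the maximally accurate estimator when that calibration holds, e.g. for
    synthetic mixtures, but it is not scale-invariant.

All three satisfy non-negativity and sum-to-one at the output and agree
exactly on noiseless unit-scale mixtures; they differ in how noise interacts
with the constraints (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.optimize import nnls as _scipy_nnls

from .chromophore_spectra import DesignMatrix
from .exceptions import SpacolError, StackStateError
from .pa_preprocess import MultispectralStack

#: Rescaling factor: relative concentration 1 corresponds to 1000 a.u.
AU_PER_UNIT_CONCENTRATION = 1000.0

SOLVERS = ("ols-clip", "nnls", "simplex")
DEFAULT_SOLVER = "ols-clip"


@dataclass
class ConcentrationMap:
    """Per-pixel relative chromophore concentrations in rescaled a.u.

    ``maps[f, c]`` is the image of chromophore ``chromophores[c]`` in frame
    ``f``. At every non-degenerate pixel the channel sum equals 1000 a.u.
    (relative concentrations sum to 1); degenerate pixels (no signal to
    attribute) are zero in all channels and flagged in ``degenerate_mask``.
    """

    maps: np.ndarray  # (F, C, H, W), a.u.
    chromophores: tuple[str, ...]
    degenerate_mask: np.ndarray  # (F, H, W) bool
    units: str = "a.u. (1000 a.u. = relative concentration 1)"
    solver: str = DEFAULT_SOLVER

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        self.degenerate_mask = np.asarray(self.degenerate_mask, dtype=bool)
        if self.maps.ndim != 4 or self.maps.shape[1] != len(self.chromophores):
            raise SpacolError("maps must be (frame, chromophore, row, col)")
        if self.degenerate_mask.shape != (
            self.maps.shape[0], self.maps.shape[2], self.maps.shape[3]
        ):
            raise SpacolError("degenerate_mask must be (frame, row, col)")

    def channel(self, name: str) -> np.ndarray:
        """The (F, H, W) a.u. image of one chromophore."""
        return self.maps[:, self.chromophores.index(name)]

    def validate(self, rtol: float = 1e-6) -> None:
        """Check non-negativity and the 1000-a.u. channel-sum invariant."""
        if np.any(self.maps < 0):
            raise SpacolError("negative concentration value")
        sums = self.maps.sum(axis=1)
        ok = ~self.degenerate_mask
        if not np.allclose(sums[ok], AU_PER_UNIT_CONCENTRATION,
                           rtol=rtol, atol=0):
            raise SpacolError("channel sum != 1000 a.u. at a non-degenerate pixel")
        if np.any(sums[self.degenerate_mask] != 0):
            raise SpacolError("degenerate pixel with non-zero channels")


@dataclass
class OxygenationMap:
    """Blood oxygen saturation sO2 = HbO2 / (HbO2 + Hb), per pixel.

    ``so2`` is NaN where the total hemoglobin signal is zero; ``defined``
    marks the complementary pixels, whose values lie in [0, 1].
    """

    so2: np.ndarray  # (F, H, W), NaN where undefined
    defined: np.ndarray  # (F, H, W) bool
    definition: str = "HbO2/(HbO2+Hb)"

    def mean_so2(self) -> float:
        """Mean saturation over defined pixels."""
        if not self.defined.any():
            return float("nan")
        return float(np.nanmean(self.so2[self.defined]))


class _SimplexSolver:
    """Exact least squares on the probability simplex by face enumeration.

    For each non-empty support S of the C chromophores, the minimizer of
    ``||A_S c_S - b||`` subject to ``sum(c_S) = 1`` has the closed KKT form
    ``c_S = B_S b + d_S``; the global simplex minimizer lies in the relative
    interior of some face, so taking the feasible candidate with the smallest
    residual over all supports is exact.
    """

    def __init__(self, A: np.ndarray):
        self.A = A
        C = A.shape[1]
        self.supports: list[tuple[int, ...]] = []
        self.B: list[np.ndarray] = []
        self.d: list[np.ndarray] = []
        for k in range(1, C + 1):
            for S in combinations(range(C), k):
                As = A[:, S]
                G = As.T @ As
                M = np.zeros((k + 1, k + 1))
                M[:k, :k] = G
                M[:k, k] = 1.0
                M[k, :k] = 1.0
                Minv = np.linalg.inv(M)
                self.supports.append(S)
                self.B.append(Minv[:k, :k] @ As.T)
                self.d.append(Minv[:k, k].copy())

    def solve(self, b: np.ndarray) -> np.ndarray:
        """Batch solve: b is (N, W); returns (N, C) simplex minimizers."""
        N, C = b.shape[0], self.A.shape[1]
        best_c = np.zeros((N, C))
        best_r = np.full(N, np.inf)
        for S, B, d in zip(self.supports, self.B, self.d):
            cs = b @ B.T + d  # (N, k)
            feasible = np.all(cs >= -1e-12, axis=1)
            if not feasible.any():
                continue
            resid = np.einsum(
                "ij,ij->i", b - cs @ self.A[:, S].T, b - cs @ self.A[:, S].T
            )
            better = feasible & (resid < best_r - 1e-15)
            if better.any():
                best_r[better] = resid[better]
                full = np.zeros((better.sum(), C))
                full[:, list(S)] = np.clip(cs[better], 0.0, None)
                best_c[better] = full
        # exact renormalization absorbs the clip of -1e-12-grade slack
        s = best_c.sum(axis=1, keepdims=True)
        return np.where(s > 0, best_c / s, 0.0)


def _solve_batch(b: np.ndarray, A: np.ndarray, solver: str) -> tuple[np.ndarray, np.ndarray]:
    """Core batch solve. b: (N, W) non-negative finite intensities.

    Returns (concentrations (N, C) on the simplex, degenerate mask (N,)).
    """
    pinv = np.linalg.pinv(A)
    if solver == "simplex":
        degenerate = ~np.any(b > 0, axis=1)
        c = np.zeros((b.shape[0], A.shape[1]))
        if (~degenerate).any():
            c[~degenerate] = _SimplexSolver(A).solve(b[~degenerate])
    elif solver == "ols-clip":
        c = np.clip(b @ pinv.T, 0.0, None)
        s = c.sum(axis=1)
        degenerate = ~(s > 0)
        c = np.where(s[:, None] > 0, c / np.where(s > 0, s, 1.0)[:, None], 0.0)
    elif solver == "nnls":
        c = np.empty((b.shape[0], A.shape[1]))
        for i, bi in enumerate(b):
            c[i], _ = _scipy_nnls(A, bi)
        s = c.sum(axis=1)
        degenerate = ~(s > 0)
        c = np.where(s[:, None] > 0, c / np.where(s > 0, s, 1.0)[:, None], 0.0)
    else:
        raise SpacolError(f"unknown solver {solver!r}; choose from {SOLVERS}")
    c[degenerate] = 0.0
    return c, degenerate


def unmix_pixel(
    intensities: np.ndarray,
    design: DesignMatrix,
    solver: str = DEFAULT_SOLVER,
) -> tuple[np.ndarray, bool]:
    """Unmix one pixel's intensity vector into relative concentrations.

    Parameters
    ----------
    intensities
        Length-W vector of fluence-normalized intensities, finite and >= 0.
    design
        Full-rank design matrix whose rows match the intensity wavelengths.
    solver
        ``ols-clip`` (default), ``nnls`` or ``simplex``.

    Returns
    -------
    (concentrations, degenerate)
        Relative concentrations in [0, 1] summing to 1, and a flag that is
        True when no signal could be attributed (all-zero output).
    """
    b = np.asarray(intensities, dtype=float)
    if b.shape != (design.matrix.shape[0],):
        raise SpacolError(
            f"expected {design.matrix.shape[0]} intensities, got shape {b.shape}"
        )
    if not np.all(np.isfinite(b)):
        raise SpacolError("non-finite intensity value")
    if np.any(b < 0):
        raise SpacolError("negative intensity value; intensities must be >= 0")
    c, deg = _solve_batch(b[None, :], design.matrix, solver)
    return c[0], bool(deg[0])


def rescale_au(relative: np.ndarray | float) -> np.ndarray | float:
    """Rescale relative concentrations in [0, 1] to a.u. (1 -> 1000 a.u.)."""
    rel = np.asarray(relative, dtype=float)
    if np.any(rel < -1e-12) or np.any(rel > 1 + 1e-12):
        raise SpacolError("relative concentrations must lie in [0, 1]")
    out = rel * AU_PER_UNIT_CONCENTRATION
    return float(out) if np.isscalar(relative) else out


def unmix_stack(
    stack: MultispectralStack,
    design: DesignMatrix,
    solver: str = DEFAULT_SOLVER,
) -> ConcentrationMap:
    """Unmix every pixel of a fluence-normalized stack.

    Equivalent to :func:`unmix_pixel` at each pixel followed by the 1000 a.u.
    rescale; vectorized over the whole stack.

    Raises
    ------
    StackStateError
        If the stack has not been fluence-normalized.
    SpacolError
        If the stack and design wavelengths disagree.
    """
    if not stack.fluence_normalized:
        raise StackStateError("stack must be fluence-normalized before unmixing")
    if stack.wavelengths_nm != design.imaging_wavelengths_nm:
        raise SpacolError(
            f"stack wavelengths {stack.wavelengths_nm} do not match design "
            f"wavelengths {design.imaging_wavelengths_nm}"
        )
    F, W, H, Wd = stack.frames.shape
    b = stack.frames.reshape(F, W, H * Wd).transpose(0, 2, 1).reshape(F * H * Wd, W)
    c, deg = _solve_batch(b, design.matrix, solver)
    au = rescale_au(c)
    maps = au.reshape(F, H, Wd, len(design.chromophores)).transpose(0, 3, 1, 2)
    return ConcentrationMap(
        maps=maps,
        chromophores=design.chromophores,
        degenerate_mask=deg.reshape(F, H, Wd),
        solver=solver,
    )


def so2_map(conc: ConcentrationMap) -> OxygenationMap:
    """Blood oxygen saturation map from the HbO2 and Hb channels."""
    hbo2 = conc.channel("HbO2")
    hb = conc.channel("Hb")
    total = hbo2 + hb
    defined = total > 0
    so2 = np.full(total.shape, np.nan)
    so2[defined] = hbo2[defined] / total[defined]
    return OxygenationMap(so2=so2, defined=defined)
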