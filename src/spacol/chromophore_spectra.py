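"""Reference absorption spectra and the spectral-unmixing design matrix.

The unmixing model treats each fluence-normalized photoacoustic pixel as a
non-negative mixture of three NIR-I chromophores: collagen, oxygenated
hemoglobin (HbO2) and deoxygenated hemoglobin (Hb). Because hemoglobin absorbs
orders of magnitude more strongly than collagen, each chromophore's molar
absorptivity spectrum is min-max normalized to [0, 1] over the NIR-I window
before the mixing matrix is assembled, so the solver weights all three signal
contributions equally.

The packaged spectra are synthetic stand-ins (see the ``# source:`` header of
each data file): smooth curves reproducing the canonical NIR-I shapes of the
three chromophores, including the collagen features that motivate the default
imaging wavelengths — the NIR-I absorption maximum at 690 nm, the local
minimum near 850 nm, the local maximum near 910 nm and the local minimum near
940 nm. Min-max normalization removes absolute scale, so only these shapes
enter the unmixing system.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

from .exceptions import (
    DegenerateSpectrumError,
    IdentifiabilityError,
    SpectrumLoadError,
    SpectrumValidationError,
    WavelengthRangeError,
)

#: Fixed chromophore column order of every design matrix built by this module.
CHROMOPHORES: tuple[str, ...] = ("collagen", "HbO2", "Hb")

#: Default imaging wavelengths (nm) of the five-wavelength NIR-I protocol.
DEFAULT_WAVELENGTHS_NM: tuple[float, ...] = (690.0, 750.0, 850.0, 910.0, 940.0)

#: Wavelength window (nm) that packaged spectra must cover, and the default
#: min-max normalization window (the NIR-I window).
NIR1_WINDOW_NM: tuple[float, float] = (650.0, 1000.0)

_DATA_FILES = {
    "collagen": "collagen_absorptivity_synthetic.tsv",
    "Hb": "hb_absorptivity_synthetic.tsv",
    "HbO2": "hbo2_absorptivity_synthetic.tsv",
}


@dataclass(frozen=True)
class AbsorptionSpectrum:
    """Tabulated molar absorptivity versus wavelength for one chromophore.

    Attributes
    ----------
    chromophore_name
        One of ``collagen``, ``Hb``, ``HbO2`` (other labels are allowed for
        user-supplied spectra but cannot enter the default design matrix).
    wavelengths_nm
        Strictly increasing wavelength grid in nanometres.
    absorptivity
        Molar absorptivity values (cm^-1 M^-1), finite and non-negative.
    source
        Free-text provenance tag.
    """

    chromophore_name: str
    wavelengths_nm: np.ndarray
    absorptivity: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        ab = np.asarray(self.absorptivity, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "absorptivity", ab)
        if wl.ndim != 1 or ab.ndim != 1 or wl.size != ab.size:
            raise SpectrumValidationError(
                f"{self.chromophore_name}: wavelength and absorptivity grids "
                f"must be 1-D and of equal length"
            )
        if wl.size < 2:
            raise SpectrumValidationError(
                f"{self.chromophore_name}: at least two tabulated points required"
            )
        if not np.all(np.diff(wl) > 0):
            raise SpectrumValidationError(
                f"{self.chromophore_name}: wavelengths must be strictly increasing"
            )
        if not np.all(np.isfinite(ab)) or np.any(ab < 0):
            raise SpectrumValidationError(
                f"{self.chromophore_name}: absorptivities must be finite and >= 0"
            )

    def interpolate(self, wavelengths_nm: Sequence[float]) -> np.ndarray:
        """Piecewise-linear absorptivity at the requested wavelengths.

        Raises
        ------
        WavelengthRangeError
            If any requested wavelength lies outside the tabulated grid.
        """
        w = np.atleast_1d(np.asarray(wavelengths_nm, dtype=float))
        lo, hi = self.wavelengths_nm[0], self.wavelengths_nm[-1]
        bad = w[(w < lo) | (w > hi)]
        if bad.size:
            raise WavelengthRangeError(
                f"{self.chromophore_name}: wavelength(s) {bad.tolist()} nm outside "
                f"tabulated coverage [{lo:g}, {hi:g}] nm"
            )
        return np.interp(w, self.wavelengths_nm, self.absorptivity)


@dataclass(frozen=True)
class NormalizedSpectrum:
    """A min-max normalized spectrum: unitless values in [0, 1].

    ``normalization_range_nm`` records the window over which the min and max
    were taken; over that window the minimum maps to 0 and the maximum to 1.
    """

    chromophore_name: str
    wavelengths_nm: np.ndarray
    values: np.ndarray
    normalization_range_nm: tuple[float, float]

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", v)
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise SpectrumValidationError(
                f"{self.chromophore_name}: normalized values outside [0, 1]"
            )

    def interpolate(self, wavelengths_nm: Sequence[float]) -> np.ndarray:
        w = np.atleast_1d(np.asarray(wavelengths_nm, dtype=float))
        lo, hi = self.wavelengths_nm[0], self.wavelengths_nm[-1]
        bad = w[(w < lo) | (w > hi)]
        if bad.size:
            raise WavelengthRangeError(
                f"{self.chromophore_name}: wavelength(s) {bad.tolist()} nm outside "
                f"coverage [{lo:g}, {hi:g}] nm"
            )
        return np.interp(w, self.wavelengths_nm, self.values)


@dataclass(frozen=True)
class DesignMatrix:
    """Wavelengths x chromophores matrix of normalized absorptivities.

    Rows follow ``imaging_wavelengths_nm``; columns follow ``chromophores``
    (always in the fixed global order ``(collagen, HbO2, Hb)`` when built via
    :func:`build_design_matrix`). The matrix must have full column rank for
    the mixture to be identifiable.
    """

    imaging_wavelengths_nm: tuple[float, ...]
    chromophores: tuple[str, ...]
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        w, c = m.shape
        if w < c:
            raise IdentifiabilityError(
                f"need at least as many wavelengths ({w}) as chromophores ({c})"
            )
        if np.linalg.matrix_rank(m) < c:
            raise IdentifiabilityError(
                "design matrix is rank deficient; collinear columns: "
                + ", ".join(_collinear_pairs(m, self.chromophores))
            )

    @property
    def condition_number(self) -> float:
        """2-norm condition number of the mixing system (finite by invariant)."""
        return float(np.linalg.cond(self.matrix))


def _collinear_pairs(m: np.ndarray, names: Sequence[str]) -> list[str]:
    pairs = []
    for i in range(m.shape[1]):
        for j in range(i + 1, m.shape[1]):
            a, b = m[:, i], m[:, j]
            na, nb = np.linalg.norm(a), np.linalg.norm(b)
            if na == 0 or nb == 0 or abs(a @ b) / (na * nb) > 1 - 1e-10:
                pairs.append(f"{names[i]}~{names[j]}")
    return pairs or ["(higher-order collinearity)"]


def _read_spectrum_file(path: Path, name: str) -> AbsorptionSpectrum:
    if not path.is_file():
        raise SpectrumLoadError(f"missing spectrum file for {name!r}: {path}")
    source = ""
    rows: list[tuple[float, float]] = []
    try:
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.lower().startswith("# source:"):
                    source = line.split(":", 1)[1].strip()
                continue
            parts = line.replace(",", " ").split()
            rows.append((float(parts[0]), float(parts[1])))
    except (ValueError, IndexError) as exc:
        raise SpectrumLoadError(f"malformed spectrum file for {name!r}: {path}") from exc
    if not rows:
        raise SpectrumLoadError(f"empty spectrum file for {name!r}: {path}")
    wl, ab = map(np.asarray, zip(*rows))
    try:
        return AbsorptionSpectrum(name, wl, ab, source=source)
    except SpectrumValidationError as exc:
        raise SpectrumLoadError(f"invalid spectrum for {name!r} in {path}: {exc}") from exc


def load_reference_spectra(data_dir: str | Path | None = None) -> list[AbsorptionSpectrum]:
    """Load the three packaged chromophore spectra.

    Parameters
    ----------
    data_dir
        Directory holding one two-column text table per chromophore (see the
        packaged files for the format). ``None`` loads the packaged spectra.

    Returns
    -------
    list of AbsorptionSpectrum
        In the fixed chromophore order ``(collagen, HbO2, Hb)``, each covering
        at least 650-1000 nm.
    """
    if data_dir is None:
        base = resources.files("spacol") / "data"
    else:
        base = Path(data_dir)
    spectra = []
    for name in CHROMOPHORES:
        path = Path(str(base / _DATA_FILES[name]))
        spec = _read_spectrum_file(path, name)
        lo, hi = NIR1_WINDOW_NM
        if spec.wavelengths_nm[0] > lo or spec.wavelengths_nm[-1] < hi:
            raise SpectrumValidationError(
                f"{name}: coverage [{spec.wavelengths_nm[0]:g}, "
                f"{spec.wavelengths_nm[-1]:g}] nm does not span "
                f"[{lo:g}, {hi:g}] nm"
            )
        spectra.append(spec)
    return spectra


def mass_to_molar_absorptivity(
    wavelengths_nm: Sequence[float],
    mu_a: Sequence[float],
    mass_density_g_per_cm3: float,
    molar_mass_g_per_mol: float,
    chromophore_name: str = "collagen",
    source: str = "",
) -> AbsorptionSpectrum:
    """Convert a mass-basis absorption coefficient to molar absorptivity.

    The molar concentration of the pure substance is ``density / molar_mass``
    (mol per cm^3), so ``epsilon(lambda) = mu_a(lambda) / (density / molar_mass)``.
    The conversion is a global scale factor: it cannot change the spectrum's
    shape, and min-max normalization later removes it entirely.

    Parameters
    ----------
    wavelengths_nm, mu_a
        Wavelength grid (nm) and absorption coefficient (cm^-1), elementwise >= 0.
    mass_density_g_per_cm3, molar_mass_g_per_mol
        Both strictly positive.
    """
    if mass_density_g_per_cm3 <= 0:
        raise SpectrumValidationError("mass density must be > 0")
    if molar_mass_g_per_mol <= 0:
        raise SpectrumValidationError("molar mass must be > 0")
    mu = np.asarray(mu_a, dtype=float)
    if np.any(mu < 0):
        raise SpectrumValidationError("absorption coefficient must be >= 0 elementwise")
    eps = mu / (mass_density_g_per_cm3 / molar_mass_g_per_mol)
    return AbsorptionSpectrum(chromophore_name, np.asarray(wavelengths_nm, float), eps,
                              source=source)


def minmax_normalize(
    spectrum: AbsorptionSpectrum | NormalizedSpectrum,
    range_nm: tuple[float, float] = NIR1_WINDOW_NM,
) -> NormalizedSpectrum:
    """Min-max normalize a spectrum to [0, 1] over ``range_nm``.

    The returned grid is restricted to the tabulated points inside the window,
    so the recorded minimum/maximum are exactly 0 and 1 on the output grid.

    Raises
    ------
    WavelengthRangeError
        If the window is not inside the spectrum's coverage.
    DegenerateSpectrumError
        If the spectrum is constant over the window (max == min).
    """
    lo, hi = float(range_nm[0]), float(range_nm[1])
    wl = spectrum.wavelengths_nm
    vals = spectrum.values if isinstance(spectrum, NormalizedSpectrum) else spectrum.absorptivity
    if lo >= hi:
        raise WavelengthRangeError(f"invalid normalization window ({lo:g}, {hi:g})")
    if wl[0] > lo or wl[-1] < hi:
        raise WavelengthRangeError(
            f"{spectrum.chromophore_name}: window [{lo:g}, {hi:g}] nm outside "
            f"coverage [{wl[0]:g}, {wl[-1]:g}] nm"
        )
    sel = (wl >= lo) & (wl <= hi)
    w, v = wl[sel], vals[sel]
    vmin, vmax = v.min(), v.max()
    if vmax == vmin:
        raise DegenerateSpectrumError(
            f"{spectrum.chromophore_name}: constant over [{lo:g}, {hi:g}] nm; "
            f"min-max normalization undefined"
        )
    return NormalizedSpectrum(spectrum.chromophore_name, w, (v - vmin) / (vmax - vmin),
                              normalization_range_nm=(lo, hi))


def build_design_matrix(
    normalized: Sequence[NormalizedSpectrum],
    imaging_wavelengths_nm: Sequence[float] = DEFAULT_WAVELENGTHS_NM,
) -> DesignMatrix:
    """Assemble the W x C unmixing design matrix ``A[w, c] = s_c(lambda_w)``.

    When the supplied spectra are exactly the three canonical chromophores,
    the columns are reordered to the fixed global order ``(collagen, HbO2,
    Hb)``; otherwise the supplied order is kept. Values between tabulated
    wavelengths are obtained by piecewise-linear interpolation.

    Raises
    ------
    WavelengthRangeError
        If an imaging wavelength falls outside any spectrum's grid.
    IdentifiabilityError
        If the resulting matrix is rank deficient.
    """
    specs = list(normalized)
    names = [s.chromophore_name for s in specs]
    if sorted(names) == sorted(CHROMOPHORES):
        specs = [specs[names.index(n)] for n in CHROMOPHORES]
        names = list(CHROMOPHORES)
    wl = tuple(float(w) for w in imaging_wavelengths_nm)
    cols = [s.interpolate(wl) for s in specs]
    return DesignMatrix(wl, tuple(names), np.column_stack(cols))


def default_design_matrix(
    imaging_wavelengths_nm: Sequence[float] = DEFAULT_WAVELENGTHS_NM,
    range_nm: tuple[float, float] = NIR1_WINDOW_NM,
) -> DesignMatrix:
    """Packaged spectra -> normalization -> design matrix, in one call."""
    spectra = load_reference_spectra()
    normalized = [minmax_normalize(s, range_nm) for s in spectra]
    return build_design_matrix(normalized, imaging_wavelengths_nm)


def spectral_features(
    spectrum: AbsorptionSpectrum | NormalizedSpectrum,
    range_nm: tuple[float, float] = NIR1_WINDOW_NM,
) -> dict:
    """Locate the in-range argmax and all interior local extrema of a spectrum.

    Returns a dict with ``argmax_nm`` and sorted lists ``local_minima_nm`` /
    ``local_maxima_nm`` (wavelengths of strict-on-one-side interior extrema on
    the tabulated grid). Used to verify the collagen wavelength-selection
    features and by the CLI inspector.
    """
    wl = spectrum.wavelengths_nm
    vals = spectrum.values if isinstance(spectrum, NormalizedSpectrum) else spectrum.absorptivity
    sel = (wl >= range_nm[0]) & (wl <= range_nm[1])
    w, v = wl[sel], vals[sel]
    mins, maxs = [], []
    for k in range(1, len(v) - 1):
        if v[k] < v[k - 1] and v[k] <= v[k + 1]:
            mins.append(float(w[k]))
        if v[k] > v[k - 1] and v[k] >= v[k + 1]:
            maxs.append(float(w[k]))
    return {
        "argmax_nm": float(w[np.argmax(v)]),
        "local_minima_nm": mins,
        "local_maxima_nm": maxs,
    }
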