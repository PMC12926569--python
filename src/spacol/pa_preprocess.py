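"""Multispectral photoacoustic stacks, pulse-energy logs and fluence normalization.

A scan is a stack of co-registered frames, each acquired at W optical
wavelengths. Pixel values are photoacoustic signal amplitudes in arbitrary
units; the Grueneisen parameter is assumed constant and absorbed into those
units. Per-pulse laser energy is logged during the scan; dividing by the beam
area at the focal point (default 0.51 cm^2) gives the per-pulse fluence, and
the scan-average fluence per wavelength is used to normalize the images so
that wavelength-to-wavelength energy differences do not bias the unmixing.

On disk a stack is a directory of one multi-page TIFF per frame (32-bit float
grayscale, W pages ordered by the metadata wavelength list) plus a JSON
metadata sidecar recording wavelengths, beam area, scan step, pixel size and
the normalization state.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

from .exceptions import FluenceError, StackFormatError, StackStateError

ENERGY_LOG_COLUMNS = ("pulse_index", "wavelength_nm", "energy_mJ")


@dataclass(frozen=True)
class AcquisitionConfig:
    """Scan geometry and optical constants.

    Attributes
    ----------
    beam_area_cm2
        Area of the laser beam at the focal point; divides pulse energy to
        give fluence. Default 0.51 cm^2.
    imaging_wavelengths_nm
        Ordered imaging wavelengths.
    frame_step_mm
        Elevational scan-motor step between frames. Default 0.032 mm.
    gruneisen
        Dimensionless thermoelastic constant; assumed 1.0 and absorbed into
        the arbitrary pixel units.
    pixel_size_mm
        In-plane pixel pitch recorded for downstream geometry.
    """

    beam_area_cm2: float = 0.51
    imaging_wavelengths_nm: tuple[float, ...] = (690.0, 750.0, 850.0, 910.0, 940.0)
    frame_step_mm: float = 0.032
    gruneisen: float = 1.0
    pixel_size_mm: float = 0.05

    def __post_init__(self) -> None:
        if self.beam_area_cm2 <= 0:
            raise FluenceError("beam_area_cm2 must be > 0")
        if self.frame_step_mm <= 0:
            raise StackFormatError("frame_step_mm must be > 0")
        object.__setattr__(
            self, "imaging_wavelengths_nm",
            tuple(float(w) for w in self.imaging_wavelengths_nm),
        )


@dataclass(frozen=True)
class PulseRecord:
    """One laser pulse: index, wavelength and measured energy (mJ)."""

    pulse_index: int
    wavelength_nm: float
    energy_mJ: float

    def __post_init__(self) -> None:
        if self.pulse_index < 0:
            raise FluenceError("pulse_index must be >= 0")
        if not np.isfinite(self.energy_mJ) or self.energy_mJ < 0:
            raise FluenceError(
                f"pulse {self.pulse_index}: energy must be finite and >= 0"
            )


@dataclass(frozen=True)
class FluenceEstimate:
    """Scan-average fluence for one wavelength (mJ/cm^2) and its pulse count."""

    wavelength_nm: float
    mean_fluence_mJ_per_cm2: float
    n_pulses: int

    def __post_init__(self) -> None:
        if self.n_pulses < 1:
            raise FluenceError("n_pulses must be >= 1")


@dataclass
class MultispectralStack:
    """F x W x H x Wd array of per-wavelength photoacoustic frames.

    ``frames[f, w]`` is the image of frame ``f`` at wavelength
    ``wavelengths_nm[w]``. All intensities must be finite and >= 0.
    ``fluence_normalized`` tracks whether :func:`fluence_normalize` has been
    applied.
    """

    frames: np.ndarray
    wavelengths_nm: tuple[float, ...]
    fluence_normalized: bool = False
    config: AcquisitionConfig = field(default_factory=AcquisitionConfig)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.wavelengths_nm = tuple(float(w) for w in self.wavelengths_nm)
        if self.frames.ndim != 4:
            raise StackFormatError(
                f"frames must be 4-D (frame, wavelength, row, col); got {self.frames.ndim}-D"
            )
        if self.frames.shape[1] != len(self.wavelengths_nm):
            raise StackFormatError(
                f"{self.frames.shape[1]} wavelength planes but "
                f"{len(self.wavelengths_nm)} wavelengths declared"
            )
        if not np.all(np.isfinite(self.frames)):
            f, w = np.argwhere(~np.isfinite(self.frames).all(axis=(2, 3)))[0]
            raise StackFormatError(
                f"non-finite pixel in frame {f}, wavelength {self.wavelengths_nm[w]:g} nm"
            )
        if np.any(self.frames < 0):
            f, w = np.argwhere((self.frames < 0).any(axis=(2, 3)))[0]
            raise StackFormatError(
                f"negative pixel in frame {f}, wavelength {self.wavelengths_nm[w]:g} nm"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.frames.shape[2], self.frames.shape[3]


def pulse_fluence(record: PulseRecord, config: AcquisitionConfig) -> float:
    """Fluence of one pulse: measured energy / beam area (mJ/cm^2)."""
    return record.energy_mJ / config.beam_area_cm2


def mean_fluence(
    records: Iterable[PulseRecord], config: AcquisitionConfig
) -> list[FluenceEstimate]:
    """Scan-average fluence per wavelength (mean of per-pulse fluences).

    Returns one :class:`FluenceEstimate` per configured imaging wavelength, in
    the configured order; the estimate is invariant to pulse ordering.

    Raises
    ------
    FluenceError
        If a configured wavelength has no pulses, or only zero-energy pulses
        (the image at that wavelength could not be normalized).
    """
    by_wl: dict[float, list[float]] = {w: [] for w in config.imaging_wavelengths_nm}
    for rec in records:
        if rec.wavelength_nm not in by_wl:
            raise FluenceError(
                f"pulse {rec.pulse_index}: wavelength {rec.wavelength_nm:g} nm not in "
                f"the declared set {config.imaging_wavelengths_nm}"
            )
        by_wl[rec.wavelength_nm].append(pulse_fluence(rec, config))
    out = []
    for w, fl in by_wl.items():
        if not fl:
            raise FluenceError(f"no pulses recorded at {w:g} nm")
        m = float(np.mean(fl))
        if m <= 0:
            raise FluenceError(
                f"all-zero pulse energies at {w:g} nm; cannot fluence-normalize"
            )
        out.append(FluenceEstimate(w, m, len(fl)))
    return out


def fluence_normalize(
    stack: MultispectralStack, fluences: Sequence[FluenceEstimate]
) -> MultispectralStack:
    """Divide every image by the scan-average fluence of its wavelength.

    Returns a new stack with the ``fluence_normalized`` flag set; the input
    stack is left unmodified.

    Raises
    ------
    StackStateError
        If the stack is already normalized.
    FluenceError
        If a stack wavelength is missing from ``fluences`` or has fluence <= 0.
    """
    if stack.fluence_normalized:
        raise StackStateError("stack is already fluence-normalized")
    lookup = {f.wavelength_nm: f.mean_fluence_mJ_per_cm2 for f in fluences}
    phi = []
    for w in stack.wavelengths_nm:
        if w not in lookup:
            raise FluenceError(f"no fluence estimate for {w:g} nm")
        if lookup[w] <= 0:
            raise FluenceError(f"non-positive fluence at {w:g} nm")
        phi.append(lookup[w])
    phi_arr = np.asarray(phi, dtype=float)[None, :, None, None]
    return MultispectralStack(
        stack.frames / phi_arr,
        stack.wavelengths_nm,
        fluence_normalized=True,
        config=stack.config,
    )


# ---------------------------------------------------------------------------
# On-disk format: directory of multi-page TIFFs + JSON metadata sidecar
# ---------------------------------------------------------------------------

_METADATA_NAME = "stack_metadata.json"


def write_stack(stack: MultispectralStack, directory: str | Path) -> Path:
    """Write a stack as frame TIFFs plus a metadata sidecar; returns the dir.

    Frames are stored as 32-bit float multi-page TIFFs (``frame_0000.tif``,
    one page per wavelength, in metadata order).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for f in range(stack.n_frames):
        tifffile.imwrite(
            directory / f"frame_{f:04d}.tif",
            stack.frames[f].astype(np.float32),
            photometric="minisblack",
        )
    meta = {
        "wavelengths_nm": list(stack.wavelengths_nm),
        "fluence_normalized": stack.fluence_normalized,
        "n_frames": stack.n_frames,
        "beam_area_cm2": stack.config.beam_area_cm2,
        "frame_step_mm": stack.config.frame_step_mm,
        "gruneisen": stack.config.gruneisen,
        "pixel_size_mm": stack.config.pixel_size_mm,
        "coordinate_convention": "row-major, 0-based, pixel (0,0) top-left, depth "
                                 "increases with row index",
    }
    (directory / _METADATA_NAME).write_text(json.dumps(meta, indent=1))
    return directory


def read_stack(directory: str | Path) -> MultispectralStack:
    """Read a stack written by :func:`write_stack`, validating its invariants."""
    directory = Path(directory)
    meta_path = directory / _METADATA_NAME
    if not meta_path.is_file():
        raise StackFormatError(f"missing metadata sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    wavelengths = tuple(float(w) for w in meta["wavelengths_nm"])
    paths = sorted(directory.glob("frame_*.tif"))
    if len(paths) != int(meta["n_frames"]):
        raise StackFormatError(
            f"metadata declares {meta['n_frames']} frames; found {len(paths)} TIFFs"
        )
    frames = []
    for p in paths:
        img = tifffile.imread(p)
        if img.ndim == 2:
            img = img[None]
        if img.shape[0] != len(wavelengths):
            raise StackFormatError(
                f"{p.name}: {img.shape[0]} pages but {len(wavelengths)} wavelengths declared"
            )
        frames.append(img)
    config = AcquisitionConfig(
        beam_area_cm2=meta["beam_area_cm2"],
        imaging_wavelengths_nm=wavelengths,
        frame_step_mm=meta["frame_step_mm"],
        gruneisen=meta["gruneisen"],
        pixel_size_mm=meta["pixel_size_mm"],
    )
    return MultispectralStack(
        np.stack(frames),
        wavelengths,
        fluence_normalized=bool(meta["fluence_normalized"]),
        config=config,
    )


def read_energy_log(path: str | Path) -> list[PulseRecord]:
    """Read a pulse-energy CSV (columns pulse_index, wavelength_nm, energy_mJ)."""
    df = pd.read_csv(path)
    missing = set(ENERGY_LOG_COLUMNS) - set(df.columns)
    if missing:
        raise StackFormatError(f"energy log {path} missing columns {sorted(missing)}")
    return [
        PulseRecord(int(r.pulse_index), float(r.wavelength_nm), float(r.energy_mJ))
        for r in df.itertuples()
    ]


def write_energy_log(records: Sequence[PulseRecord], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(path, index=False)
    return path
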