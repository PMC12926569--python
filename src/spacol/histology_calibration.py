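"""Masson's-trichrome color deconvolution and sPA-vs-histology calibration.

Trichrome stains collagen fibers blue; the blue area fraction of a tissue
section is the histological ground truth against which sPA collagen
estimates are calibrated. RGB section images are separated into per-stain
density channels with the Ruifrok-Johnston optical-density method: each
pixel's OD vector ``-log10(I / I0)`` is expressed in a basis of unit-length
stain vectors, giving one density image per stain. The collagen measurement
is then the fraction of tissue-mask pixels whose blue-stain density exceeds
a threshold (Otsu within the tissue by default), and the calibration is an
ordinary least-squares regression of sPA organ means on area fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skimage.filters import threshold_otsu

from .exceptions import (
    DegenerateFitError,
    EmptyMaskError,
    SampleSizeError,
    StainMatrixError,
)
from .roi_quantify import OrganSummary

#: White point of brightfield microscopy images (8-bit).
I0 = 255.0

#: Total-OD threshold separating tissue from white background.
DEFAULT_TISSUE_OD_THRESHOLD = 0.05

#: Below this OD dynamic range within the tissue the blue channel is treated
#: as single-class (uniformly positive or uniformly negative) and Otsu is not
#: attempted; also the minimum density for the single-class "positive" call.
MIN_OTSU_DYNAMIC_RANGE = 0.15
MIN_POSITIVE_OD = 0.10


@dataclass(frozen=True)
class StainMatrix:
    """Unit-length optical-density stain vectors (rows), RGB components.

    Row order matches ``stain_names``; the matrix must be invertible for
    deconvolution. When built from two measured stains, the third row is
    completed as the unit-normalized cross product (Ruifrok's convention).
    """

    stain_names: tuple[str, str, str]
    vectors: np.ndarray  # (3, 3)

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        if v.shape != (3, 3):
            raise StainMatrixError("stain matrix must be 3x3")
        norms = np.linalg.norm(v, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise StainMatrixError("each stain vector must have unit Euclidean norm")
        if abs(np.linalg.det(v)) < 1e-8:
            raise StainMatrixError("stain matrix is singular (collinear stain vectors)")
        object.__setattr__(self, "vectors", v)

    @classmethod
    def from_two_stains(
        cls, name1: str, v1: Sequence[float], name2: str, v2: Sequence[float],
        residual_name: str = "residual",
    ) -> "StainMatrix":
        a = np.asarray(v1, float); a = a / np.linalg.norm(a)
        b = np.asarray(v2, float); b = b / np.linalg.norm(b)
        c = np.cross(a, b)
        n = np.linalg.norm(c)
        if n < 1e-8:
            raise StainMatrixError("stain vectors are collinear; cannot complete basis")
        return cls((name1, name2, residual_name), np.vstack([a, b, c / n]))


def default_masson_trichrome() -> StainMatrix:
    """The Masson-trichrome stain vectors of Fiji's color-deconvolution plugin.

    Row 0 is the aniline/methyl blue (collagen) stain, row 1 the
    Ponceau-fuchsin cytoplasm stain, row 2 the completed residual direction.
    """
    return StainMatrix.from_two_stains(
        "collagen_blue", (0.7995107, 0.5913521, 0.10528667),
        "cytoplasm_red", (0.09997159, 0.73738605, 0.6680326),
    )


def _to_od(rgb: np.ndarray) -> np.ndarray:
    img = np.asarray(rgb, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise StainMatrixError("expected an H x W x 3 RGB image")
    if np.any(img <= 0) or np.any(img > I0):
        raise StainMatrixError(f"RGB intensities must lie in (0, {I0:g}]")
    return -np.log10(img / I0)


def color_deconvolve(rgb_image: np.ndarray, stains: StainMatrix) -> dict[str, np.ndarray]:
    """Separate an RGB image into per-stain density channels.

    Implements Beer-Lambert separation: per-pixel OD vector times the inverse
    stain matrix, clipped at zero. Returns ``{stain_name: H x W density}``.
    """
    od = _to_od(rgb_image)
    dens = od @ np.linalg.inv(stains.vectors)
    dens = np.clip(dens, 0.0, None)
    return {name: dens[..., i] for i, name in enumerate(stains.stain_names)}


def tissue_mask(
    rgb_image: np.ndarray, od_threshold: float = DEFAULT_TISSUE_OD_THRESHOLD
) -> np.ndarray:
    """True where the summed RGB optical density exceeds the background level."""
    return _to_od(rgb_image).sum(axis=2) > od_threshold


@dataclass(frozen=True)
class HistologyMeasurement:
    """Blue (collagen) area fraction of the tissue in one section."""

    animal_id: str
    organ: str
    area_fraction: float
    n_tissue_pixels: int
    threshold_used: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.area_fraction <= 1.0:
            raise EmptyMaskError("area_fraction must lie in [0, 1]")
        if self.n_tissue_pixels < 1:
            raise EmptyMaskError("n_tissue_pixels must be >= 1")


def collagen_area_fraction(
    blue_channel: np.ndarray,
    mask: np.ndarray,
    threshold: float | str = "otsu",
    animal_id: str = "",
    organ: str = "uterus",
) -> HistologyMeasurement:
    """Fraction of tissue pixels whose blue-stain density is above threshold.

    ``threshold='otsu'`` (default) computes Otsu's threshold on the blue
    densities within the tissue mask; when the in-tissue densities are nearly
    constant (dynamic range below ``MIN_OTSU_DYNAMIC_RANGE`` OD) the section
    is treated as single-class: fully positive if the common density exceeds
    ``MIN_POSITIVE_OD``, otherwise fully negative. A float threshold applies
    a fixed cut instead.

    Raises
    ------
    EmptyMaskError
        If the tissue mask has no true pixel.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("tissue mask is empty")
    vals = np.asarray(blue_channel, dtype=float)[mask]
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown threshold mode {threshold!r}")
        if vals.max() - vals.min() < MIN_OTSU_DYNAMIC_RANGE:
            thr = MIN_POSITIVE_OD
        else:
            thr = float(threshold_otsu(vals))
    else:
        thr = float(threshold)
    frac = float(np.mean(vals > thr))
    return HistologyMeasurement(animal_id, organ, frac, int(mask.sum()), thr)


@dataclass(frozen=True)
class CalibrationFit:
    """OLS fit of sPA collagen means (a.u.) on histology area fractions."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise SampleSizeError("calibration needs >= 3 matched points")
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise DegenerateFitError("r_squared outside [0, 1]")


def calibrate(
    spa_means: Sequence[OrganSummary],
    hist: Sequence[HistologyMeasurement],
) -> CalibrationFit:
    """Regress sPA organ means on histology area fractions over matched pairs.

    Pairs are matched on ``(animal_id, organ)``. The fit is ordinary least
    squares of the sPA mean (a.u., response) on the blue area fraction
    (predictor); the p-value is the two-sided slope test on n - 2 df.

    Raises
    ------
    SampleSizeError
        Fewer than 3 matched pairs.
    DegenerateFitError
        Zero variance in the area fractions.
    """
    spa = {(s.animal_id, s.organ): s.mean_collagen_au for s in spa_means}
    pairs = [
        (h.area_fraction, spa[(h.animal_id, h.organ)])
        for h in hist
        if (h.animal_id, h.organ) in spa
    ]
    if len(pairs) < 3:
        raise SampleSizeError(
            f"only {len(pairs)} matched (animal, organ) pairs; need >= 3"
        )
    x, y = map(np.asarray, zip(*pairs))
    if np.ptp(x) == 0:
        raise DegenerateFitError("zero variance in histology area fractions")
    fit = stats.linregress(x, y)
    return CalibrationFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue ** 2),
        p_value=float(fit.pvalue),
        n_points=len(pairs),
    )


def measurements_to_frame(hist: Sequence[HistologyMeasurement]) -> pd.DataFrame:
    """Tidy DataFrame view of histology measurements (for CSV export)."""
    return pd.DataFrame(
        [
            {"animal_id": h.animal_id, "organ": h.organ,
             "area_fraction": h.area_fraction,
             "n_tissue_pixels": h.n_tissue_pixels,
             "threshold_used": h.threshold_used}
            for h in hist
        ]
    )


def read_image(path: str | Path) -> np.ndarray:
    """Read an RGB section image (TIFF/PNG) as uint8 H x W x 3."""
    import imageio.v3 as iio

    img = iio.imread(Path(path))
    if img.ndim == 3 and img.shape[2] == 4:  # drop alpha
        img = img[..., :3]
    return img
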