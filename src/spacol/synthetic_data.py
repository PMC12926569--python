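"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators, all deterministic given their seed:

* :func:`generate_phantom` — multispectral photoacoustic stacks from the
  forward model ``I(lambda, x) = Phi(lambda) * sum_c A[lambda, c] * c*(c, x)
  + N(0, sigma)`` (negative draws truncated at 0), together with a matching
  pulse-energy log (per-pulse multiplicative jitter, re-centred so the scan
  mean equals the true fluence), ROI annotations tracing the phantom regions,
  and the ground-truth concentration map.
* :func:`generate_histology` — trichrome-like RGB sections rendered through
  Beer-Lambert optics from known stain densities, with an exactly prescribed
  blue (collagen) area fraction.
* :func:`generate_cohort` — animal x organ tables with prescribed per-group
  age slopes, between-animal effects and residual noise, emulating the
  structure of a two-genotype aging cohort.

The default phantom layout names its four regions after the four organ
cross-sections with collagen fractions ordered uterus < internal_os <
external_os ~ vagina; this is a documented fixture, not a claim about real
tissue. See docs/methods.md for what these generators do and do not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chromophore_spectra import DEFAULT_WAVELENGTHS_NM, DesignMatrix
from .exceptions import SpecificationError
from .histology_calibration import I0, StainMatrix, default_masson_trichrome
from .pa_preprocess import AcquisitionConfig, MultispectralStack, PulseRecord
from .roi_quantify import ORGANS, RoiAnnotation, rasterize
from .spectral_unmix import AU_PER_UNIT_CONCENTRATION, ConcentrationMap

#: Default per-region true chromophore fractions (collagen, HbO2, Hb).
DEFAULT_REGION_FRACTIONS: dict[str, tuple[float, float, float]] = {
    "uterus": (0.15, 0.35, 0.50),
    "internal_os": (0.30, 0.28, 0.42),
    "external_os": (0.45, 0.22, 0.33),
    "vagina": (0.44, 0.26, 0.30),
}

#: Default true mean fluence per wavelength (mJ/cm^2); highest at 750 nm,
#: the wavelength where OPO output typically peaks.
DEFAULT_FLUENCES: dict[float, float] = {
    690.0: 18.0, 750.0: 24.0, 850.0: 20.0, 910.0: 16.0, 940.0: 14.0
}


@dataclass(frozen=True)
class PhantomRegion:
    """A labeled polygonal region with true chromophore fractions."""

    name: str
    polygon: tuple[tuple[float, float], ...]
    fractions: tuple[float, float, float]  # (collagen, HbO2, Hb)

    def __post_init__(self) -> None:
        fr = tuple(float(f) for f in self.fractions)
        object.__setattr__(self, "fractions", fr)
        if any(f < 0 for f in fr):
            raise SpecificationError(f"{self.name}: fractions must be >= 0")
        if sum(fr) > 1 + 1e-12:
            raise SpecificationError(f"{self.name}: fraction sum {sum(fr):g} > 1")


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of a synthetic multiwavelength phantom."""

    image_size: tuple[int, int] = (64, 64)
    regions: tuple[PhantomRegion, ...] = ()
    fluences: Mapping[float, float] = field(default_factory=lambda: dict(DEFAULT_FLUENCES))
    noise_sigma: float = 0.0
    n_frames: int = 4
    pulses_per_frame: int = 1
    energy_jitter: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise SpecificationError("noise_sigma must be >= 0")
        if any(phi <= 0 for phi in self.fluences.values()):
            raise SpecificationError("fluences must be > 0")
        h, w = self.image_size
        for r in self.regions:
            xs = [p[0] for p in r.polygon]
            ys = [p[1] for p in r.polygon]
            if min(xs) < -0.5 or min(ys) < -0.5 or max(xs) > w - 0.5 or max(ys) > h - 0.5:
                raise SpecificationError(f"region {r.name}: polygon outside image bounds")


def default_phantom_spec(
    image_size: tuple[int, int] = (64, 64),
    n_frames: int = 4,
    noise_sigma: float = 0.0,
    seed: int = 0,
    fractions: Mapping[str, tuple[float, float, float]] | None = None,
) -> PhantomSpec:
    """Four-organ quadrant layout scaled to the requested image size."""
    h, w = image_size
    fr = dict(DEFAULT_REGION_FRACTIONS if fractions is None else fractions)
    # quadrant rectangles inset from the borders and the midlines
    mx, my = 0.08 * w, 0.08 * h
    boxes = {
        "uterus": (mx, my, w / 2 - mx / 2, h / 2 - my / 2),
        "internal_os": (w / 2 + mx / 2, my, w - mx, h / 2 - my / 2),
        "external_os": (mx, h / 2 + my / 2, w / 2 - mx / 2, h - my),
        "vagina": (w / 2 + mx / 2, h / 2 + my / 2, w - mx, h - my),
    }
    regions = tuple(
        PhantomRegion(
            name,
            ((x0, y0), (x1, y0), (x1, y1), (x0, y1)),
            fr[name],
        )
        for name, (x0, y0, x1, y1) in boxes.items()
    )
    return PhantomSpec(image_size=image_size, regions=regions,
                       n_frames=n_frames, noise_sigma=noise_sigma, seed=seed)


def generate_phantom(
    spec: PhantomSpec, design: DesignMatrix
) -> tuple[MultispectralStack, ConcentrationMap, list[PulseRecord], list[RoiAnnotation]]:
    """Simulate a raw (un-normalized) stack from the forward model.

    Returns the stack, the ground-truth concentration map (a.u.; degenerate
    where the true fractions sum to zero), the pulse-energy log whose
    per-wavelength scan means reproduce the true fluences exactly, and one
    ROI annotation per region per frame.
    """
    wavelengths = design.imaging_wavelengths_nm
    missing = [w for w in wavelengths if w not in spec.fluences]
    if missing:
        raise SpecificationError(f"no true fluence for wavelengths {missing}")
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    C = len(design.chromophores)

    truth_rel = np.zeros((C, h, w))
    annotations: list[RoiAnnotation] = []
    for region in spec.regions:
        ann0 = RoiAnnotation(0, region.name, region.polygon)
        mask = rasterize(ann0, h, w)
        for ci in range(C):
            truth_rel[ci][mask] = region.fractions[ci]
        for f in range(spec.n_frames):
            annotations.append(RoiAnnotation(f, region.name, region.polygon))

    phi = np.array([spec.fluences[wl] for wl in wavelengths])
    clean = phi[:, None, None] * np.tensordot(design.matrix, truth_rel, axes=(1, 0))
    frames = np.empty((spec.n_frames, len(wavelengths), h, w))
    for f in range(spec.n_frames):
        noisy = clean + rng.normal(0.0, spec.noise_sigma, clean.shape) \
            if spec.noise_sigma > 0 else clean
        frames[f] = np.clip(noisy, 0.0, None)

    config = AcquisitionConfig(imaging_wavelengths_nm=wavelengths)
    pulses: list[PulseRecord] = []
    idx = 0
    n_pulses = spec.n_frames * spec.pulses_per_frame
    for wi, wl in enumerate(wavelengths):
        jitter = rng.uniform(-spec.energy_jitter, spec.energy_jitter, n_pulses)
        jitter -= jitter.mean()  # scan-mean energy is exact
        base = spec.fluences[wl] * config.beam_area_cm2
        for j in jitter:
            pulses.append(PulseRecord(idx, wl, base * (1.0 + float(j))))
            idx += 1

    stack = MultispectralStack(frames, wavelengths, fluence_normalized=False,
                               config=config)
    sums = truth_rel.sum(axis=0)
    degenerate = np.broadcast_to(sums == 0, (spec.n_frames, h, w)).copy()
    truth_au = np.broadcast_to(
        truth_rel * AU_PER_UNIT_CONCENTRATION, (spec.n_frames, C, h, w)
    ).copy()
    truth = ConcentrationMap(truth_au, design.chromophores, degenerate,
                             solver="ground-truth")
    return stack, truth, pulses, annotations


# ---------------------------------------------------------------------------
# Histology sections
# ---------------------------------------------------------------------------


def generate_histology(
    section_size: tuple[int, int] = (128, 128),
    blue_fraction: float = 0.3,
    stains: StainMatrix | None = None,
    seed: int = 0,
    tissue_footprint: np.ndarray | None = None,
    blue_density: float = 0.8,
    red_density: float = 0.7,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Render a trichrome-like section with a known blue area fraction.

    A centered elliptical tissue footprint (or the supplied boolean mask) is
    painted with cytoplasm-stain density everywhere; an exact
    ``round(blue_fraction * n_tissue)``-pixel random subset additionally
    receives collagen-blue stain. The section is rendered through the
    Beer-Lambert model with the given stain vectors and quantized to 8 bits
    on a white background.

    Returns the uint8 RGB image and ``{"tissue": mask, "blue": mask}`` truth.
    """
    if not 0.0 <= blue_fraction <= 1.0:
        raise SpecificationError("blue_fraction must lie in [0, 1]")
    stains = stains or default_masson_trichrome()
    h, w = section_size
    if tissue_footprint is None:
        yy, xx = np.mgrid[0:h, 0:w]
        tissue = (((xx - (w - 1) / 2) / (0.4 * w)) ** 2
                  + ((yy - (h - 1) / 2) / (0.4 * h)) ** 2) <= 1.0
    else:
        tissue = np.asarray(tissue_footprint, dtype=bool)
        if tissue.shape != (h, w):
            raise SpecificationError("tissue_footprint shape must match section_size")
    n_tissue = int(tissue.sum())
    if n_tissue == 0:
        raise SpecificationError("empty tissue footprint")
    rng = np.random.default_rng(seed)
    n_blue = int(round(blue_fraction * n_tissue))
    flat_idx = np.flatnonzero(tissue.ravel())
    blue_idx = rng.choice(flat_idx, size=n_blue, replace=False)
    blue = np.zeros(h * w, dtype=bool)
    blue[blue_idx] = True
    blue = blue.reshape(h, w)

    densities = np.zeros((h, w, 3))
    densities[..., 1][tissue] = red_density
    densities[..., 0][blue] = blue_density
    rgb = I0 * 10.0 ** (-(densities @ stains.vectors))
    rgb = np.clip(np.round(rgb), 1, I0).astype(np.uint8)
    return rgb, {"tissue": tissue, "blue": blue}


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

#: Default per-organ baseline collagen (a.u.) at age 0 extrapolation.
DEFAULT_BASELINES: dict[str, float] = {
    "uterus": 150.0, "internal_os": 250.0, "external_os": 300.0, "vagina": 320.0
}
#: Default age slopes (a.u. per month): collagen rises with age in normal
#: animals and falls in prolapsed animals, steepest in the external os.
DEFAULT_SLOPES: dict[str, dict[str, float]] = {
    "normal": {"uterus": 10.0, "internal_os": 15.0, "external_os": 40.0,
               "vagina": 12.0},
    "prolapsed": {"uterus": -5.0, "internal_os": -10.0, "external_os": -20.0,
                  "vagina": -8.0},
}


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic two-group aging cohort."""

    n_per_group: int = 8
    age_range_months: tuple[float, float] = (2.0, 12.0)
    baselines_au: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BASELINES))
    slopes_au_per_month: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {g: dict(s) for g, s in DEFAULT_SLOPES.items()}
    )
    prolapsed_shift_au: Mapping[str, float] = field(default_factory=dict)
    between_animal_sigma: float = 40.0
    residual_sigma: float = 55.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise SpecificationError("n_per_group must be >= 2")
        if self.between_animal_sigma < 0 or self.residual_sigma < 0:
            raise SpecificationError("noise scales must be >= 0")
        lo, hi = self.age_range_months
        if not (0 < lo <= hi):
            raise SpecificationError("age range must satisfy 0 < lo <= hi")


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, dict]:
    """Simulate one animal x organ cohort table.

    Response model per record: ``baseline[organ] (+ prolapsed shift) +
    slope[group][organ] * age + animal_effect + residual``, with the animal
    effect shared by the four organs of each animal. Responses are not
    clipped; baselines should keep them positive at realistic noise.

    Returns the tidy table (cohort CSV schema) and the truth parameters.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.age_range_months
    rows = []
    for group, tag, geno in (("normal", "N", "Fbln5_het"), ("prolapsed", "P", "Fbln5_ko")):
        ages = rng.uniform(lo, hi, spec.n_per_group)
        animal_fx = rng.normal(0.0, spec.between_animal_sigma, spec.n_per_group)
        for i in range(spec.n_per_group):
            for organ in ORGANS:
                mean = (
                    spec.baselines_au[organ]
                    + (spec.prolapsed_shift_au.get(organ, 0.0) if group == "prolapsed" else 0.0)
                    + spec.slopes_au_per_month[group][organ] * ages[i]
                    + animal_fx[i]
                    + rng.normal(0.0, spec.residual_sigma)
                )
                rows.append({
                    "animal_id": f"{tag}{i + 1:02d}",
                    "genotype": geno,
                    "prolapse": group == "prolapsed",
                    "age_months": float(ages[i]),
                    "organ": organ,
                    "mean_collagen_au": float(mean),
                })
    truth = {
        "baselines_au": dict(spec.baselines_au),
        "slopes_au_per_month": {g: dict(s) for g, s in spec.slopes_au_per_month.items()},
        "prolapsed_shift_au": dict(spec.prolapsed_shift_au),
        "between_animal_sigma": spec.between_animal_sigma,
        "residual_sigma": spec.residual_sigma,
    }
    return pd.DataFrame(rows), truth
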