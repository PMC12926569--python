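"""Organ ROIs: polygon annotations, rasterization and per-organ collagen means.

Organ cross-sections (uterus, internal cervical os, external cervical os,
vagina) are outlined per frame on the co-registered B-mode image; the
polygons are rasterized onto the photoacoustic grid and the collagen channel
of the unmixed concentration map is averaged over the union of ROI pixels
across the organ's frames. Degenerate pixels (where unmixing attributed no
signal) are excluded from the mean — their zeros are imputed, not measured.

Coordinate convention (recorded in annotation files): 0-based pixel indices,
pixel (0, 0) at top-left, polygon vertices ``(x, y) = (col, row)`` in pixel
units, pixel centers at integer coordinates. A pixel belongs to the ROI when
its center falls inside the closed polygon under the even-odd rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon

from .exceptions import AnnotationError, EmptyRoiError, VocabularyError
from .spectral_unmix import ConcentrationMap

#: Controlled vocabulary of organ labels along the reproductive tract.
ORGANS: tuple[str, ...] = ("uterus", "internal_os", "external_os", "vagina")

COORDINATE_CONVENTION = (
    "0-based pixel indices; (x, y) = (col, row); pixel centers at integer "
    "coordinates; even-odd interior rule"
)

_SUGGESTIONS = {"cervix": "internal_os or external_os"}


def _check_organ(organ: str) -> str:
    if organ not in ORGANS:
        hint = _SUGGESTIONS.get(organ.lower())
        msg = f"unknown organ label {organ!r}; expected one of {ORGANS}"
        if hint:
            msg += f" (did you mean {hint}?)"
        raise VocabularyError(msg)
    return organ


@dataclass(frozen=True)
class RoiAnnotation:
    """One organ outline on one frame.

    ``polygon`` is an ordered list of (x, y) vertices in pixel coordinates;
    it must have at least 3 vertices and be simple (non-self-intersecting,
    positive area) after closing.
    """

    frame_index: int
    organ: str
    polygon: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        _check_organ(self.organ)
        if self.frame_index < 0:
            raise AnnotationError("frame_index must be >= 0")
        poly = tuple((float(x), float(y)) for x, y in self.polygon)
        object.__setattr__(self, "polygon", poly)
        if len(poly) < 3:
            raise AnnotationError(
                f"{self.organ} frame {self.frame_index}: polygon needs >= 3 vertices"
            )
        shp = _ShapelyPolygon(poly)
        if not shp.is_valid or shp.area <= 0:
            raise AnnotationError(
                f"{self.organ} frame {self.frame_index}: polygon must be simple "
                f"with positive area"
            )


def rasterize(annotation: RoiAnnotation, height: int, width: int) -> np.ndarray:
    """Boolean mask of pixels whose centers lie inside the closed polygon.

    Uses an even-odd (crossing-number) test on pixel centers at integer
    coordinates; deterministic and independent of vertex orientation.
    """
    verts = np.asarray(annotation.polygon, dtype=float)
    xs, ys = np.meshgrid(np.arange(width, dtype=float),
                         np.arange(height, dtype=float))
    px, py = xs.ravel(), ys.ravel()
    inside = np.zeros(px.shape, dtype=bool)
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        # edge crosses the horizontal ray to +x iff it spans py (half-open)
        crosses = (y1 > py) != (y2 > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_at = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (px < x_at)
    return inside.reshape(height, width)


@dataclass(frozen=True)
class OrganSummary:
    """Mean collagen concentration (a.u.) of one organ in one animal."""

    animal_id: str
    organ: str
    mean_collagen_au: float
    n_pixels: int
    n_frames: int

    def __post_init__(self) -> None:
        _check_organ(self.organ)
        if self.n_pixels < 1:
            raise EmptyRoiError(f"{self.animal_id}/{self.organ}: n_pixels must be >= 1")
        if self.mean_collagen_au < 0:
            raise EmptyRoiError(f"{self.animal_id}/{self.organ}: mean must be >= 0")


def organ_mean(
    conc: ConcentrationMap,
    annotations: Iterable[RoiAnnotation],
    organ: str,
    animal_id: str,
) -> OrganSummary:
    """Pixel-pooled mean collagen a.u. over an organ's ROIs.

    Pools the union of ROI pixels across all frames annotated for the organ
    (equivalently: the pixel-count-weighted mean of per-frame ROI means) and
    excludes degenerate pixels.

    Raises
    ------
    EmptyRoiError
        If no annotation exists for the organ or no eligible pixel remains.
    AnnotationError
        If an annotation's frame index is outside the stack.
    """
    _check_organ(organ)
    collagen = conc.channel("collagen")
    F, H, W = collagen.shape
    total, count, frames = 0.0, 0, set()
    found = False
    for ann in annotations:
        if ann.organ != organ:
            continue
        found = True
        if ann.frame_index >= F:
            raise AnnotationError(
                f"{organ}: frame index {ann.frame_index} outside stack of {F} frames"
            )
        mask = rasterize(ann, H, W) & ~conc.degenerate_mask[ann.frame_index]
        if mask.any():
            total += float(collagen[ann.frame_index][mask].sum())
            count += int(mask.sum())
            frames.add(ann.frame_index)
    if not found:
        raise EmptyRoiError(f"no annotations for organ {organ!r}")
    if count == 0:
        raise EmptyRoiError(f"{organ}: ROI contains no eligible (non-degenerate) pixels")
    return OrganSummary(animal_id, organ, total / count, count, len(frames))


def summarize_organs(
    conc: ConcentrationMap,
    annotations: Sequence[RoiAnnotation],
    animal_id: str,
) -> list[OrganSummary]:
    """One :class:`OrganSummary` per organ present in the annotations."""
    present = sorted({a.organ for a in annotations}, key=ORGANS.index)
    return [organ_mean(conc, annotations, organ, animal_id) for organ in present]


# ---------------------------------------------------------------------------
# Annotation file I/O (JSON sidecar)
# ---------------------------------------------------------------------------


def write_annotations(annotations: Sequence[RoiAnnotation], path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "coordinate_convention": COORDINATE_CONVENTION,
        "rois": [
            {"frame": a.frame_index, "organ": a.organ,
             "polygon": [[x, y] for x, y in a.polygon]}
            for a in annotations
        ],
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_annotations(path: str | Path) -> list[RoiAnnotation]:
    payload = json.loads(Path(path).read_text())
    return [
        RoiAnnotation(int(r["frame"]), r["organ"],
                      tuple((float(x), float(y)) for x, y in r["polygon"]))
        for r in payload["rois"]
    ]
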