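"""Landmark-based FHOC size measurement from binary segmentation masks.

The femoral head ossification center (FHOC) size is defined as the maximum
transverse diameter of the ossified capital femoral epiphysis: the linear
distance from the medial margin to the outermost lateral point.  On an AP
radiograph those two cortical landmarks are the horizontal (image-column)
extremes of the segmented region, so measurement proceeds as

1. reduce the mask to its largest 8-connected component (speckle robustness),
2. locate the extreme-column boundary points at subpixel precision: within
   each extreme column the landmark row is the lower median of the foreground
   rows (which tracks the tangent point of a smooth convex boundary), and the
   landmark column is pushed half a pixel outward to account for the pixel
   footprint,
3. report the Euclidean distance between the two landmarks times the isotropic
   pixel spacing.

Coordinates are ``(row, col)``, 0-based, with pixel centers at integer
coordinates; row 0 is the top of the image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from PIL import Image
from skimage.measure import label as sk_label

Side = Literal["left", "right", "unknown"]


class NoOssificationCenterError(ValueError):
    """Raised when a mask has no foreground: no ossification center is visible.

    Clinically meaningful rather than a mere edge case — the FHOC only appears
    at around 4 months of age in half of infants.
    """


class MultiComponentError(ValueError):
    """Raised when an operation requiring a single component receives several."""


@dataclass(frozen=True)
class Mask:
    """A binary segmentation mask with isotropic pixel spacing.

    Parameters
    ----------
    pixels : 2-D bool array, ``(row, col)`` indexed, row 0 at top.
    spacing_mm : isotropic pixel spacing in mm/pixel.  Anisotropic spacings
        are rejected; resample the image first.
    """

    pixels: np.ndarray
    spacing_mm: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"mask must be 2-D, got ndim={px.ndim}")
        object.__setattr__(self, "pixels", px.astype(bool))
        if np.ndim(self.spacing_mm) != 0:
            raise ValueError("spacing_mm must be a scalar (isotropic); anisotropic spacing is not supported")
        if not float(self.spacing_mm) > 0:
            raise ValueError(f"spacing_mm must be > 0, got {self.spacing_mm}")

    @property
    def n_foreground(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class LandmarkPair:
    """Medial and lateral cortical landmarks on a mask boundary.

    For ``side="unknown"`` the labels mean image-left (medial) and image-right
    (lateral) rather than anatomical sides.
    """

    medial: tuple[float, float]
    lateral: tuple[float, float]
    side: Side = "unknown"


@dataclass(frozen=True)
class MeasurementResult:
    landmarks: LandmarkPair
    size_mm: float
    n_components_found: int
    component_mask: Mask = field(repr=False)


# ---------------------------------------------------------------------------
# mask I/O (8-bit PNG, 0 background / 255 foreground)

def save_mask(mask: Mask, path: str | Path) -> None:
    img = Image.fromarray(np.where(mask.pixels, 255, 0).astype(np.uint8), mode="L")
    img.save(Path(path), format="PNG")


def load_mask(path: str | Path, spacing_mm: float) -> Mask:
    arr = np.asarray(Image.open(Path(path)).convert("L"))
    return Mask(pixels=arr >= 128, spacing_mm=spacing_mm)


# ---------------------------------------------------------------------------
# operations

def largest_component(mask: Mask) -> tuple[Mask, int]:
    """Retain only the largest 8-connected foreground component.

    Returns ``(mask, n_components_found)``.  Area ties are broken by keeping
    the component whose top-left-most pixel comes first in ``(row, col)``
    lexicographic order (i.e. first in row-major scan order).

    Raises
    ------
    NoOssificationCenterError
        If the mask has no foreground pixel.
    """
    if mask.n_foreground == 0:
        raise NoOssificationCenterError(
            "no ossification center: mask has no foreground pixels"
        )
    labels, n = sk_label(mask.pixels, connectivity=2, return_num=True)
    if n == 1:
        return mask, 1
    areas = np.bincount(labels.ravel())[1:]  # skip background label 0
    best_area = areas.max()
    tied = np.flatnonzero(areas == best_area) + 1
    if len(tied) == 1:
        keep = tied[0]
    else:
        # row-major first occurrence == (row, col) lexicographic minimum
        flat = labels.ravel()
        first = {lab: np.argmax(flat == lab) for lab in tied}
        keep = min(tied, key=lambda lab: first[lab])
    return Mask(pixels=labels == keep, spacing_mm=mask.spacing_mm), n


def detect_landmarks(mask: Mask, side: Side = "unknown") -> LandmarkPair:
    """Locate the medial and lateral cortical landmarks on a single-component mask.

    Candidates are the foreground pixels attaining the minimal and maximal
    column index.  Within each extreme column the landmark row is the lower
    median of the candidate rows — for a convex boundary this approximates
    the vertical-tangent point, where the extreme chord actually touches —
    and the landmark column is extended half a pixel outward (pixel centers
    sit at integer coordinates, so the physical boundary lies half a pixel
    beyond the outermost center).  A single-column mask degenerates to two
    equal landmarks (zero size).  The (min-col, max-col) pair is labeled
    medial/lateral according to ``side``: on a patient's right hip the
    image-left (min-col) point is the lateral cortex; on the left hip it is
    the medial margin.
    """
    if side not in ("left", "right", "unknown"):
        raise ValueError(f"side must be 'left', 'right' or 'unknown', got {side!r}")
    if mask.n_foreground == 0:
        raise NoOssificationCenterError("no ossification center: cannot detect landmarks on an empty mask")
    _, n = sk_label(mask.pixels, connectivity=2, return_num=True)
    if n > 1:
        raise MultiComponentError(
            f"mask has {n} connected components; apply largest_component first"
        )
    rows, cols = np.nonzero(mask.pixels)
    single_column = cols.min() == cols.max()

    def pick(col: int, outward: float) -> tuple[float, float]:
        cand_rows = np.sort(rows[cols == col])
        best = cand_rows[(len(cand_rows) - 1) // 2]  # lower median
        c = float(col) if single_column else float(col) + outward
        return (float(best), c)

    p_min = pick(cols.min(), -0.5)
    p_max = pick(cols.max(), +0.5)
    if side == "right":
        medial, lateral = p_max, p_min
    else:  # "left" and "unknown": min-col point is medial / image-left
        medial, lateral = p_min, p_max
    return LandmarkPair(medial=medial, lateral=lateral, side=side)


def measure_size(pair: LandmarkPair, spacing_mm: float) -> float:
    """Euclidean landmark distance in pixels times spacing, in mm."""
    if not spacing_mm > 0:
        raise ValueError(f"spacing_mm must be > 0, got {spacing_mm}")
    d = np.hypot(pair.medial[0] - pair.lateral[0], pair.medial[1] - pair.lateral[1])
    return float(d * spacing_mm)


def measure_mask(mask: Mask, side: Side = "unknown", spacing_mm: float | None = None) -> MeasurementResult:
    """Full measurement: largest component -> landmarks -> size.

    ``spacing_mm`` overrides the spacing stored on the mask when given.
    """
    spacing = float(spacing_mm) if spacing_mm is not None else mask.spacing_mm
    if not spacing > 0:
        raise ValueError(f"spacing_mm must be > 0, got {spacing}")
    component, n_found = largest_component(mask)
    pair = detect_landmarks(component, side=side)
    size = measure_size(pair, spacing)
    return MeasurementResult(
        landmarks=pair, size_mm=size, n_components_found=n_found,
        component_mask=component,
    )
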