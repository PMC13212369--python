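"""Stage-wise evaluation metrics: Dice, Hausdorff, MRE and SDR.

Segmentation quality is summarized by the Dice similarity coefficient (region
overlap) and the exact Hausdorff distance between mask boundaries (worst-case
boundary deviation, in mm).  Landmark localization is summarized by the mean
radial error (MRE) and the successful detection rate (SDR): the percentage of
cases whose radial error falls at or below each of a fixed set of thresholds
(1, 2, 2.5, 3 and 4 mm by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import directed_hausdorff

from .measurement import Mask

DEFAULT_SDR_THRESHOLDS_MM = (1.0, 2.0, 2.5, 3.0, 4.0)


def _pixels(m) -> np.ndarray:
    return m.pixels if isinstance(m, Mask) else np.asarray(m, bool)


def dice(a, b) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|); 1.0 when both empty."""
    pa, pb = _pixels(a), _pixels(b)
    if pa.shape != pb.shape:
        raise ValueError(f"mask shapes differ: {pa.shape} vs {pb.shape}")
    denom = pa.sum() + pb.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(pa, pb).sum() / denom)


def boundary_points(mask) -> np.ndarray:
    """(n, 2) array of boundary pixel coordinates (row, col).

    A boundary pixel is a foreground pixel with at least one background
    4-neighbor; pixels on the image edge count the outside as background.
    """
    px = _pixels(mask)
    padded = np.pad(px, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    edge = px & ~interior
    return np.argwhere(edge)


def hausdorff(a, b, spacing_mm: float = 1.0) -> float:
    """Exact symmetric Hausdorff distance between mask boundaries, in mm."""
    if not spacing_mm > 0:
        raise ValueError(f"spacing_mm must be > 0, got {spacing_mm}")
    pa, pb = _pixels(a), _pixels(b)
    if pa.shape != pb.shape:
        raise ValueError(f"mask shapes differ: {pa.shape} vs {pb.shape}")
    if pa.sum() == 0 or pb.sum() == 0:
        raise ValueError("Hausdorff distance requires two non-empty masks")
    ba, bb = boundary_points(pa).astype(float), boundary_points(pb).astype(float)
    d = max(directed_hausdorff(ba, bb)[0], directed_hausdorff(bb, ba)[0])
    return float(d * spacing_mm)


@dataclass(frozen=True)
class SDRResult:
    """Landmark localization summary: per-case radial errors (mm), their mean
    (MRE), and successful detection rates (%) at each threshold."""

    thresholds_mm: tuple[float, ...]
    rates_pct: tuple[float, ...]
    mre_mm: float
    per_case_errors_mm: tuple[float, ...]


def radial_errors(
    pred: np.ndarray,
    truth: np.ndarray,
    spacing_mm: float = 1.0,
    thresholds_mm: tuple[float, ...] = DEFAULT_SDR_THRESHOLDS_MM,
) -> SDRResult:
    """Per-case radial (Euclidean) landmark errors with MRE and SDR.

    ``pred`` and ``truth`` are (n, 2) point arrays paired by index, in pixel
    coordinates; errors are converted to mm via ``spacing_mm``.
    SDR(t) = 100 x fraction of cases with error <= t.
    """
    p = np.asarray(pred, float)
    t = np.asarray(truth, float)
    if p.shape != t.shape:
        raise ValueError(f"pred and truth shapes differ: {p.shape} vs {t.shape}")
    if p.ndim != 2 or p.shape[1] != 2:
        raise ValueError(f"expected (n, 2) point arrays, got {p.shape}")
    if len(p) == 0:
        raise ValueError("need at least one landmark pair")
    err = np.hypot(*(p - t).T) * spacing_mm
    rates = tuple(float(100.0 * np.mean(err <= th)) for th in thresholds_mm)
    return SDRResult(
        thresholds_mm=tuple(float(th) for th in thresholds_mm),
        rates_pct=rates,
        mre_mm=float(err.mean()),
        per_case_errors_mm=tuple(float(e) for e in err),
    )
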