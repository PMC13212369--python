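"""Synthetic FHOC masks and measurement cohorts with known ground truth.

Real study material — pediatric AP pelvic radiographs with expert annotations —
is private, so every downstream stage (mask morphometry, agreement statistics,
growth-chart fitting) is exercised on synthetic data whose true answers are
known by construction:

* ``gen_fhoc_mask`` renders an elliptical ossification-center silhouette
  (optionally rotated, boundary-perturbed, and with an inferior crescent
  removed to mimic partial ossification) together with the analytically
  computed extreme-column landmarks and true transverse diameter.
* ``gen_cohort`` draws a bilateral measurement cohort whose per-age size
  distribution reproduces published 5th/50th/95th percentile reference values
  exactly: the latent size at age ``a`` follows a two-piece (split) normal
  centered on the monotone (PCHIP) interpolation of the median anchors, with
  half-widths ``sigma_lo = (q50 - q5) / z_0.95`` below the median and
  ``sigma_hi = (q95 - q50) / z_0.95`` above it.  The split accommodates the
  mild skew of the anchor tables; for symmetric anchors it reduces to a plain
  normal with ``sigma = (q95 - q5) / (2 * z_0.95)``.  Left and right hips are
  drawn jointly with a configurable correlation.
* ``gen_paired_measurements`` adds a simulated human-reader re-measurement
  with configurable bias and noise, emulating an AI-vs-reader agreement study.

All randomness flows from explicit integer seeds; no global RNG state is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.stats import norm

from .measurement import Mask, largest_component
from .reference import (
    DEFAULT_AGE_BINS,
    SEXES,
    SIDES,
    default_anchor_table,
    validate_anchor_table,
)

#: 95th standard-normal quantile used to convert the (q5, q95) spread into a
#: per-age standard deviation.
Z95 = float(norm.ppf(0.95))


# ---------------------------------------------------------------------------
# mask generation

@dataclass(frozen=True)
class ShapeParams:
    """Geometry of a synthetic ossification-center silhouette.

    ``semi_axis_a`` is the transverse (column-direction) semi-axis before
    rotation, ``semi_axis_b`` the vertical one, both in pixels.
    ``crescent_fraction`` in [0, 0.5] removes that fraction of the shape's
    inferior vertical extent, mimicking a partially ossified center.
    """

    semi_axis_a: float
    semi_axis_b: float
    center: tuple[float, float]  # (row, col)
    rotation_deg: float = 0.0
    boundary_noise_sd: float = 0.0
    crescent_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not self.semi_axis_a > 0:
            raise ValueError(f"semi_axis_a must be > 0, got {self.semi_axis_a}")
        if not self.semi_axis_b > 0:
            raise ValueError(f"semi_axis_b must be > 0, got {self.semi_axis_b}")
        if not 0.0 <= self.crescent_fraction <= 0.5:
            raise ValueError(f"crescent_fraction must be in [0, 0.5], got {self.crescent_fraction}")
        if self.boundary_noise_sd < 0:
            raise ValueError(f"boundary_noise_sd must be >= 0, got {self.boundary_noise_sd}")


@dataclass(frozen=True)
class GroundTruth:
    """Analytic truth for a generated mask: noiseless extreme-column landmarks
    (row, col) and the true transverse diameter."""

    point_min_col: tuple[float, float]
    point_max_col: tuple[float, float]
    diameter_px: float
    diameter_mm: float


def _ellipse_point(params: ShapeParams, t: float) -> tuple[float, float]:
    """Boundary point (row, col) of the rotated ellipse at parameter t."""
    th = math.radians(params.rotation_deg)
    a, b = params.semi_axis_a, params.semi_axis_b
    col = params.center[1] + a * math.cos(t) * math.cos(th) - b * math.sin(t) * math.sin(th)
    row = params.center[0] + a * math.cos(t) * math.sin(th) + b * math.sin(t) * math.cos(th)
    return (row, col)


def _crescent_row_cut(params: ShapeParams) -> float:
    """Row below which pixels are removed (inferior crescent). +inf if none."""
    if params.crescent_fraction == 0.0:
        return math.inf
    th = math.radians(params.rotation_deg)
    a, b = params.semi_axis_a, params.semi_axis_b
    half_row_extent = math.hypot(a * math.sin(th), b * math.cos(th))
    return params.center[0] + half_row_extent * (1.0 - 2.0 * params.crescent_fraction)


def analytic_landmarks(params: ShapeParams) -> GroundTruth:
    """Extreme-column landmarks and diameter of the noiseless shape.

    Candidates are the unconstrained column extremes of the rotated ellipse
    plus, when a crescent cut is active, the intersections of the cut line
    with the ellipse boundary; invalid (cut-away) candidates are discarded.
    """
    th = math.radians(params.rotation_deg)
    a, b = params.semi_axis_a, params.semi_axis_b
    row_cut = _crescent_row_cut(params)

    # d(col)/dt = 0  =>  tan t = -(b/a) tan(th)
    t_star = math.atan2(-b * math.sin(th), a * math.cos(th))
    candidates = [_ellipse_point(params, t) for t in (t_star, t_star + math.pi)]
    candidates = [p for p in candidates if p[0] <= row_cut + 1e-9]

    if math.isfinite(row_cut):
        # row(t) = row_cut:  A cos t + B sin t = d
        A, B = a * math.sin(th), b * math.cos(th)
        d = row_cut - params.center[0]
        R = math.hypot(A, B)
        if abs(d) <= R:
            phi = math.atan2(B, A)
            delta = math.acos(max(-1.0, min(1.0, d / R)))
            candidates += [_ellipse_point(params, phi + s * delta) for s in (+1, -1)]

    if not candidates:
        raise ValueError("crescent cut removed the whole shape")
    p_min = min(candidates, key=lambda p: p[1])
    p_max = max(candidates, key=lambda p: p[1])
    diameter_px = math.hypot(p_min[0] - p_max[0], p_min[1] - p_max[1])
    return GroundTruth(point_min_col=p_min, point_max_col=p_max,
                       diameter_px=diameter_px, diameter_mm=diameter_px)


def gen_fhoc_mask(
    params: ShapeParams,
    image_shape: tuple[int, int],
    spacing_mm: float,
    seed: int = 0,
) -> tuple[Mask, GroundTruth]:
    """Render a synthetic FHOC mask and return it with its analytic truth.

    The mask is a rotated ellipse rasterized on ``image_shape``; boundary
    noise perturbs the contour radially by a smooth periodic field with
    standard deviation ``boundary_noise_sd`` pixels.  Exactly one 8-connected
    foreground component is guaranteed.  GroundTruth is computed analytically
    from the noiseless shape; ``diameter_mm = chord length * spacing_mm``.
    """
    if not spacing_mm > 0:
        raise ValueError(f"spacing_mm must be > 0, got {spacing_mm}")
    th = math.radians(params.rotation_deg)
    a, b = params.semi_axis_a, params.semi_axis_b
    half_col = math.hypot(a * math.cos(th), b * math.sin(th))
    half_row = math.hypot(a * math.sin(th), b * math.cos(th))
    margin = 3.0 * params.boundary_noise_sd + 1.0
    n_rows, n_cols = image_shape
    if params.center[0] - half_row - margin < 0 or params.center[0] + half_row + margin > n_rows - 1:
        raise ValueError(
            f"shape exceeds image bounds along the row axis: needs rows "
            f"[{params.center[0] - half_row - margin:.1f}, {params.center[0] + half_row + margin:.1f}] "
            f"in an image with {n_rows} rows"
        )
    if params.center[1] - half_col - margin < 0 or params.center[1] + half_col + margin > n_cols - 1:
        raise ValueError(
            f"shape exceeds image bounds along the col axis: needs cols "
            f"[{params.center[1] - half_col - margin:.1f}, {params.center[1] + half_col + margin:.1f}] "
            f"in an image with {n_cols} cols"
        )

    rows = np.arange(n_rows, dtype=float)[:, None]
    cols = np.arange(n_cols, dtype=float)[None, :]
    dr = rows - params.center[0]
    dc = cols - params.center[1]
    # rotate into the ellipse frame
    u = dc * math.cos(th) + dr * math.sin(th)   # along semi_axis_a
    v = -dc * math.sin(th) + dr * math.cos(th)  # along semi_axis_b
    rho = np.hypot(u / a, v / b)  # 1.0 on the noiseless boundary

    if params.boundary_noise_sd > 0:
        rng = np.random.default_rng(seed)
        t = np.arctan2(v / b, u / a)
        # smooth zero-mean periodic perturbation, unit sd over angle
        k = np.arange(2, 7)
        amp = rng.normal(size=k.size)
        phase = rng.uniform(0, 2 * math.pi, size=k.size)
        eps = np.zeros_like(t)
        for ki, ai, pi in zip(k, amp, phase):
            eps += ai * np.cos(ki * t + pi)
        eps *= params.boundary_noise_sd / math.sqrt(k.size / 2.0)
        # local boundary radius converts the normalized offset to ~pixels
        r_local = np.sqrt((a * np.cos(t)) ** 2 + (b * np.sin(t)) ** 2)
        inside = (rho - 1.0) * r_local <= eps
    else:
        inside = rho <= 1.0

    row_cut = _crescent_row_cut(params)
    if math.isfinite(row_cut):
        inside &= rows <= row_cut

    if not inside.any():
        raise ValueError("generated mask is empty (noise or crescent removed the whole shape)")
    mask, _ = largest_component(Mask(pixels=inside, spacing_mm=spacing_mm))

    truth = analytic_landmarks(params)
    truth = GroundTruth(
        point_min_col=truth.point_min_col,
        point_max_col=truth.point_max_col,
        diameter_px=truth.diameter_px,
        diameter_mm=truth.diameter_px * spacing_mm,
    )
    return mask, truth


# ---------------------------------------------------------------------------
# cohort generation

@dataclass
class GeneratorConfig:
    """Configuration of the synthetic measurement cohort.

    Defaults emulate the anchor-table study conditions: ages 0.5-11 years in
    twelve bins, both sexes, bilateral hips with correlation 0.98, and a
    simulated reader with zero bias and 0.96 mm noise so that Bland-Altman
    95% limits of agreement land near +/-1.9 mm.
    """

    n_per_sex_per_agegroup: int = 25
    age_bins: tuple[tuple[float, float], ...] = DEFAULT_AGE_BINS
    anchor_table: dict[str, pd.DataFrame] = field(default_factory=default_anchor_table)
    bilateral_corr: float = 0.98
    reader_bias_mm: float = 0.0
    reader_noise_sd_mm: float = 0.96
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_sex_per_agegroup < 1:
            raise ValueError("n_per_sex_per_agegroup must be >= 1")
        if not -1.0 <= self.bilateral_corr <= 1.0:
            raise ValueError(f"bilateral_corr must be in [-1, 1], got {self.bilateral_corr}")
        if self.reader_noise_sd_mm < 0:
            raise ValueError(f"reader_noise_sd_mm must be >= 0, got {self.reader_noise_sd_mm}")
        validate_anchor_table(self.anchor_table)


@dataclass(frozen=True)
class AnchorCurves:
    """Smooth per-age distribution parameters interpolated from an anchor table.

    ``mu`` is the median, ``sigma_lo``/``sigma_hi`` the two-piece normal
    half-widths below/above it, and ``sigma`` their mean, which equals the
    single-normal value ``(q95 - q5) / (2 * z_0.95)``.
    """

    mu: PchipInterpolator
    _q5: PchipInterpolator = field(repr=False)
    _q95: PchipInterpolator = field(repr=False)

    def sigma_lo(self, a):
        return (self.mu(a) - self._q5(a)) / Z95

    def sigma_hi(self, a):
        return (self._q95(a) - self.mu(a)) / Z95

    def sigma(self, a):
        return (self._q95(a) - self._q5(a)) / (2.0 * Z95)

    def quantile(self, a, tau):
        """True latent quantile at age ``a`` and level ``tau`` in (0, 1)."""
        z = norm.ppf(tau)
        half = self.sigma_lo(a) if z < 0 else self.sigma_hi(a)
        return self.mu(a) + half * z


def anchor_interpolators(anchors: pd.DataFrame) -> AnchorCurves:
    """Monotone (PCHIP) interpolation of one sex's anchor table.

    PCHIP preserves the monotonicity of the anchors, so no spurious dips
    appear between table rows.
    """
    ages = np.asarray(anchors["age_years"], float)
    return AnchorCurves(
        mu=PchipInterpolator(ages, np.asarray(anchors["q50_mm"], float)),
        _q5=PchipInterpolator(ages, np.asarray(anchors["q5_mm"], float)),
        _q95=PchipInterpolator(ages, np.asarray(anchors["q95_mm"], float)),
    )


def gen_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Draw a bilateral measurement cohort anchored to the percentile table.

    Ages are uniform within each bin.  For each child the left/right latent
    sizes share a bivariate standard normal with correlation
    ``bilateral_corr``, mapped through the per-age two-piece normal quantile
    transform (so each side's marginal reproduces the anchor quantiles
    exactly); draws are floored at a small positive size.  Deterministic given
    ``config.seed``.

    Returns a DataFrame with columns
    ``child_id, age_years, sex, side, size_mm`` (two rows per child).
    """
    rng = np.random.default_rng(config.seed)
    rho = config.bilateral_corr
    chol_21 = rho
    chol_22 = math.sqrt(max(0.0, 1.0 - rho * rho))

    records: list[dict] = []
    for sex in SEXES:
        curves = anchor_interpolators(config.anchor_table[sex])
        child_ix = 0
        for lo, hi in config.age_bins:
            n = config.n_per_sex_per_agegroup
            ages = rng.uniform(lo, hi, size=n)
            z = rng.standard_normal(size=(n, 2))
            left = z[:, 0]
            right = chol_21 * z[:, 0] + chol_22 * z[:, 1]
            mu = curves.mu(ages)
            sd_lo = curves.sigma_lo(ages)
            sd_hi = curves.sigma_hi(ages)
            half_l = np.where(left < 0, sd_lo, sd_hi)
            half_r = np.where(right < 0, sd_lo, sd_hi)
            size_l = np.maximum(mu + half_l * left, 0.01)
            size_r = np.maximum(mu + half_r * right, 0.01)
            for i in range(n):
                cid = f"{sex[0].upper()}{child_ix:05d}"
                child_ix += 1
                for side, size in (("left", size_l[i]), ("right", size_r[i])):
                    records.append({
                        "child_id": cid,
                        "age_years": float(ages[i]),
                        "sex": sex,
                        "side": side,
                        "size_mm": float(size),
                    })
    return pd.DataFrame.from_records(records)


def gen_paired_measurements(
    cohort: pd.DataFrame,
    bias_mm: float = 0.0,
    noise_sd_mm: float = 0.96,
    seed: int = 0,
) -> pd.DataFrame:
    """Attach a simulated reader re-measurement as ``reference_mm``.

    ``reference_mm = size_mm + bias_mm + Normal(0, noise_sd_mm)`` per row,
    deterministic given ``seed``.  Returns a copy of the cohort.
    """
    if noise_sd_mm < 0:
        raise ValueError(f"noise_sd_mm must be >= 0, got {noise_sd_mm}")
    if "size_mm" not in cohort.columns:
        raise ValueError("cohort must have a size_mm column")
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    noise = rng.normal(0.0, noise_sd_mm, size=len(out)) if noise_sd_mm > 0 else 0.0
    out["reference_mm"] = out["size_mm"].to_numpy() + bias_mm + noise
    return out


# ---------------------------------------------------------------------------
# cohort I/O

COHORT_COLUMNS = ("child_id", "age_years", "sex", "side", "size_mm", "reference_mm")


def save_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in COHORT_COLUMNS if c in cohort.columns]
    cohort.to_csv(Path(path), index=False, columns=cols)


def load_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path))
    missing = {"child_id", "age_years", "sex", "side", "size_mm"} - set(df.columns)
    if missing:
        raise ValueError(f"cohort file missing columns {sorted(missing)}")
    return df


def validate_cohort(cohort: pd.DataFrame) -> None:
    """Check cohort invariants: age range, positive sizes, unique (child, side)."""
    ages = cohort["age_years"].to_numpy(float)
    if np.any(ages < 0.5) or np.any(ages > 12.0):
        raise ValueError("age_years must lie in [0.5, 12]")
    if np.any(cohort["size_mm"].to_numpy(float) <= 0):
        raise ValueError("size_mm must be > 0")
    if cohort.duplicated(subset=["child_id", "side"]).any():
        raise ValueError("each (child_id, side) pair must be unique")
    bad_sex = set(cohort["sex"].unique()) - set(SEXES)
    if bad_sex:
        raise ValueError(f"unknown sex values: {sorted(bad_sex)}")
    bad_side = set(cohort["side"].unique()) - set(SIDES)
    if bad_side:
        raise ValueError(f"unknown side values: {sorted(bad_side)}")
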