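"""Monotone polynomial quantile-regression growth charts for FHOC size.

For each sex, quantile curves of FHOC size versus age are fitted by
minimizing the pinball (check) loss

    sum_i rho_tau(y_i - p(a_i)),   rho_tau(u) = u * (tau - 1{u < 0}),

over polynomial coefficients, subject to a biological-plausibility constraint
that the curve be non-decreasing in age: p'(a) >= 0 is imposed at a grid of
ages (default step 0.25 y) and the problem is solved exactly as a linear
program (HiGHS).  Fitted quantiles are then rearranged — sorted across
quantile levels at each evaluation age — so reported percentile curves never
cross.  The module also produces percentile reference tables, a clinical
percentile lookup for an individual measurement, adjusted R-squared of the
median curve, and per-age-bin prediction errors (in-sample residuals) with
bootstrap confidence intervals.

Ages are internally rescaled to [0, 1] before building the polynomial basis;
the rescaling is affine and order-preserving, so the monotonicity constraint
is unchanged.  Fitting is fully deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import linprog

from .agreement import EstimateCI, error_metrics
from .reference import DEFAULT_AGE_BINS, DEFAULT_TAUS

#: Feasibility tolerance passed to the LP solver.
LP_TOL = 1e-7

DEFAULT_TABLE_AGES = (0.5, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11)


class FitError(RuntimeError):
    """Raised when the constrained quantile fit cannot be solved."""


@dataclass
class QuantileModel:
    """Fitted monotone polynomial quantile curves for one sex.

    ``coefficients[tau]`` holds the polynomial coefficients (ascending powers)
    in the rescaled age variable ``t = (age - lo) / (hi - lo)`` with
    ``(lo, hi) = age_domain`` in years; predictions map back automatically.
    """

    sex: str
    taus: tuple[float, ...]
    degree: int
    coefficients: dict[float, np.ndarray]
    age_domain: tuple[float, float]
    constraint_grid: tuple[float, ...] = field(repr=False)

    def _scale(self, ages: np.ndarray) -> np.ndarray:
        lo, hi = self.age_domain
        return (np.asarray(ages, float) - lo) / (hi - lo)

    def _check_domain(self, ages: np.ndarray) -> None:
        lo, hi = self.age_domain
        a = np.asarray(ages, float)
        if np.any(a < lo - 1e-9) or np.any(a > hi + 1e-9):
            raise ValueError(
                f"age outside fitted domain [{lo}, {hi}] years; "
                "reference values are not extrapolated"
            )

    def predict_raw(self, ages) -> np.ndarray:
        """Quantile predictions before rearrangement, shape (n_taus, n_ages)."""
        self._check_domain(ages)
        t = np.atleast_1d(self._scale(ages))
        V = np.vander(t, self.degree + 1, increasing=True)
        return np.stack([V @ self.coefficients[tau] for tau in self.taus])

    def predict(self, ages) -> np.ndarray:
        """Rearranged (non-crossing) quantile predictions, (n_taus, n_ages).

        Rearrangement sorts predictions across quantile levels at each age,
        which is order-preserving and removes any residual curve crossing.
        """
        return np.sort(self.predict_raw(ages), axis=0)

    def predict_median(self, ages) -> np.ndarray:
        q = self.predict(ages)
        i = self.taus.index(0.5) if 0.5 in self.taus else len(self.taus) // 2
        return q[i]

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "sex": self.sex,
            "taus": list(self.taus),
            "degree": self.degree,
            "coefficients": {str(tau): list(map(float, c)) for tau, c in self.coefficients.items()},
            "age_domain_years": list(self.age_domain),
            "constraint_grid_years": list(self.constraint_grid),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QuantileModel":
        taus = tuple(float(t) for t in d["taus"])
        return cls(
            sex=d["sex"], taus=taus, degree=int(d["degree"]),
            coefficients={float(t): np.asarray(c, float) for t, c in d["coefficients"].items()},
            age_domain=tuple(d["age_domain_years"]),
            constraint_grid=tuple(d["constraint_grid_years"]),
        )


def save_models(models: dict[str, QuantileModel], path: str | Path) -> None:
    Path(path).write_text(json.dumps({s: m.to_dict() for s, m in models.items()}, indent=1))


def load_models(path: str | Path) -> dict[str, QuantileModel]:
    raw = json.loads(Path(path).read_text())
    return {s: QuantileModel.from_dict(d) for s, d in raw.items()}


# ---------------------------------------------------------------------------
# fitting

def _pinball_lp(t: np.ndarray, y: np.ndarray, tau: float, degree: int,
                t_grid: np.ndarray) -> np.ndarray:
    """Solve one constrained pinball-loss fit as a linear program.

    Variables are [beta (degree+1, free), u (n, >=0), v (n, >=0)] with
    residual split y - V beta = u - v and objective tau*sum(u) +
    (1-tau)*sum(v).  Monotonicity enters as -V'(t_g) beta <= 0 at every
    constraint-grid point.
    """
    n, p = len(y), degree + 1
    V = np.vander(t, p, increasing=True)
    A_eq = sp.hstack([sp.csr_matrix(V), sp.eye(n, format="csr"), -sp.eye(n, format="csr")],
                     format="csr")
    c = np.concatenate([np.zeros(p), np.full(n, tau), np.full(n, 1.0 - tau)])
    bounds = [(None, None)] * p + [(0, None)] * (2 * n)
    if degree >= 1 and len(t_grid):
        powers = np.arange(1, p)
        D = np.vander(t_grid, p - 1, increasing=True) * powers  # d/dt of t^1..t^degree
        A_ub = sp.hstack([sp.csr_matrix((len(t_grid), 1)), sp.csr_matrix(-D),
                          sp.csr_matrix((len(t_grid), 2 * n))], format="csr")
        b_ub = np.zeros(len(t_grid))
    else:
        A_ub, b_ub = None, None
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=y, bounds=bounds,
                  method="highs",
                  options={"primal_feasibility_tolerance": LP_TOL,
                           "dual_feasibility_tolerance": LP_TOL})
    if not res.success:
        raise FitError(
            f"quantile LP failed for tau={tau} (status {res.status}: {res.message}); "
            f"monotonicity was enforced at {len(t_grid)} grid ages"
        )
    return res.x[:p]


def fit_quantile_model(
    ages,
    sizes,
    taus: Sequence[float] = DEFAULT_TAUS,
    degree: int = 3,
    grid_step: float = 0.25,
    sex: str = "unknown",
    monotone: bool = True,
    age_domain: tuple[float, float] | None = None,
) -> QuantileModel:
    """Fit monotone polynomial quantile curves for one group of (age, size) data.

    ``age_domain`` sets the model's reference range (and rescaling interval);
    it defaults to the data's age span and must cover it.
    """
    ages = np.asarray(ages, float)
    sizes = np.asarray(sizes, float)
    if ages.shape != sizes.shape:
        raise ValueError("ages and sizes must have equal length")
    if len(ages) < degree + 1:
        raise FitError(f"need at least degree+1={degree + 1} points, got {len(ages)}")
    if len(np.unique(ages)) < degree + 2 and degree >= 1:
        raise FitError(
            f"need at least degree+2={degree + 2} distinct ages for a stable "
            f"degree-{degree} fit, got {len(np.unique(ages))}"
        )
    if np.any(sizes <= 0):
        raise ValueError("sizes must be > 0 mm")
    if age_domain is None:
        lo, hi = float(ages.min()), float(ages.max())
    else:
        lo, hi = float(age_domain[0]), float(age_domain[1])
        if lo > ages.min() or hi < ages.max():
            raise ValueError(
                f"age_domain [{lo}, {hi}] must cover the data span "
                f"[{ages.min():.3g}, {ages.max():.3g}]"
            )
    if hi <= lo:
        raise FitError("degenerate age range: all ages equal")
    t = (ages - lo) / (hi - lo)
    if monotone and degree >= 1:
        grid_ages = np.arange(lo, hi + 1e-9, grid_step)
        if grid_ages[-1] < hi:
            grid_ages = np.append(grid_ages, hi)
        t_grid = (grid_ages - lo) / (hi - lo)
    else:
        grid_ages = np.array([])
        t_grid = np.array([])
    coeffs = {}
    for tau in taus:
        if not 0.0 < tau < 1.0:
            raise ValueError(f"quantile level must be in (0, 1), got {tau}")
        coeffs[float(tau)] = _pinball_lp(t, sizes, float(tau), degree, t_grid)
    return QuantileModel(
        sex=sex, taus=tuple(float(x) for x in taus), degree=degree,
        coefficients=coeffs, age_domain=(lo, hi),
        constraint_grid=tuple(float(a) for a in grid_ages),
    )


def fit_quantile_curves(
    cohort: pd.DataFrame,
    taus: Sequence[float] = DEFAULT_TAUS,
    degree: int = 3,
    grid_step: float = 0.25,
    per_child_average: bool = False,
    age_domain: tuple[float, float] | None = (0.5, 11.0),
) -> dict[str, QuantileModel]:
    """Fit one QuantileModel per sex from a measurement cohort.

    By default every hip contributes a row (bilateral framing); with
    ``per_child_average`` left/right sizes are averaged per child first.
    The default reference range is ages 0.5-11 years; pass ``age_domain=None``
    to use each sex's data span instead.
    """
    df = cohort
    if per_child_average:
        df = (cohort.groupby(["child_id", "sex"], as_index=False)
              .agg(age_years=("age_years", "mean"), size_mm=("size_mm", "mean")))
    models = {}
    for sex, sub in df.groupby("sex", sort=True):
        dom = age_domain
        if dom is not None:
            # widen if the data happen to exceed the requested reference range
            dom = (min(dom[0], float(sub["age_years"].min())),
                   max(dom[1], float(sub["age_years"].max())))
        models[str(sex)] = fit_quantile_model(
            sub["age_years"], sub["size_mm"], taus=taus, degree=degree,
            grid_step=grid_step, sex=str(sex), age_domain=dom,
        )
    return models


# ---------------------------------------------------------------------------
# downstream products

def predict_percentiles(model: QuantileModel, ages: Sequence[float] = DEFAULT_TABLE_AGES) -> pd.DataFrame:
    """Percentile reference table at the requested ages (no extrapolation).

    Columns are ``age_years`` plus ``q{level}_mm`` for each fitted quantile,
    e.g. ``q5_mm, q10_mm, ..., q95_mm``.
    """
    ages = np.asarray(ages, float)
    q = model.predict(ages)
    out = {"age_years": ages}
    for tau, row in zip(model.taus, q):
        out[f"q{round(tau * 100):d}_mm"] = row
    return pd.DataFrame(out)


@dataclass(frozen=True)
class PercentileResult:
    """Percentile position of one measurement on the fitted chart.

    ``percentile`` is None outside the fitted 5th-95th band; ``flag`` is one
    of ``"in_range"``, ``"below_p5"``, ``"above_p95"`` and ``display`` renders
    the clinical string (e.g. ``"62.3"``, ``"<5"``, ``">95"``).
    """

    percentile: float | None
    flag: str
    display: str


def percentile_of(model: QuantileModel, age: float, size_mm: float) -> PercentileResult:
    """Locate a measurement on the chart by monotone interpolation across the
    fitted quantiles at the given age; values outside the 5th-95th band are
    flagged rather than extrapolated."""
    q = model.predict([age])[:, 0]
    levels = np.asarray(model.taus) * 100.0
    if size_mm < q[0]:
        return PercentileResult(None, "below_p5", f"<{levels[0]:g}")
    if size_mm > q[-1]:
        return PercentileResult(None, "above_p95", f">{levels[-1]:g}")
    pct = float(np.interp(size_mm, q, levels))
    return PercentileResult(pct, "in_range", f"{pct:.1f}")


def adjusted_r2(model: QuantileModel, ages, sizes) -> float:
    """Adjusted R-squared of the fitted median curve.

    R^2 = 1 - SSE/SST from median-curve residuals, adjusted as
    1 - (1 - R^2)(n - 1)/(n - p - 1) with p = polynomial degree.
    """
    ages = np.asarray(ages, float)
    sizes = np.asarray(sizes, float)
    n, p = len(sizes), model.degree
    if n < p + 3:
        raise ValueError(f"adjusted R^2 requires at least degree+3={p + 3} points")
    resid = sizes - model.predict_median(ages)
    sst = float(((sizes - sizes.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("adjusted R^2 undefined: response has zero variance")
    r2 = 1.0 - float((resid**2).sum()) / sst
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def group_errors(
    model: QuantileModel,
    cohort: pd.DataFrame,
    bins: Sequence[tuple[float, float]] = DEFAULT_AGE_BINS,
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """In-sample MAE/RMSE of the median curve per age bin, with bootstrap CIs.

    Empty bins are reported with ``n=0`` and missing (NaN) errors rather than
    zeros.  Returns a DataFrame with columns
    ``bin_lo_years, bin_hi_years, n, mae_mm, mae_ci_low_mm, mae_ci_high_mm,
    rmse_mm, rmse_ci_low_mm, rmse_ci_high_mm``.
    """
    ages = cohort["age_years"].to_numpy(float)
    sizes = cohort["size_mm"].to_numpy(float)
    pred = model.predict_median(ages)
    rows = []
    last_hi = bins[-1][1]
    for i, (lo, hi) in enumerate(bins):
        in_bin = (ages >= lo) & ((ages < hi) | ((hi == last_hi) & (ages == hi)))
        n = int(in_bin.sum())
        row = {"bin_lo_years": lo, "bin_hi_years": hi, "n": n,
               "mae_mm": np.nan, "mae_ci_low_mm": np.nan, "mae_ci_high_mm": np.nan,
               "rmse_mm": np.nan, "rmse_ci_low_mm": np.nan, "rmse_ci_high_mm": np.nan}
        if n >= 2:
            mae, rmse = error_metrics(sizes[in_bin], pred[in_bin],
                                      n_boot=n_boot, seed=seed + i)
            row.update({"mae_mm": mae.value, "mae_ci_low_mm": mae.ci_low,
                        "mae_ci_high_mm": mae.ci_high,
                        "rmse_mm": rmse.value, "rmse_ci_low_mm": rmse.ci_low,
                        "rmse_ci_high_mm": rmse.ci_high})
        elif n == 1:
            err = abs(float(sizes[in_bin][0] - pred[in_bin][0]))
            row.update({"mae_mm": err, "rmse_mm": err})
        rows.append(row)
    return pd.DataFrame(rows)


def plot_growth_chart(
    model: QuantileModel,
    cohort: pd.DataFrame | None = None,
    ax=None,
    n_grid: int = 200,
):
    """Plot fitted percentile curves (5th-95th), optionally over raw points."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4.5))
    lo, hi = model.age_domain
    grid = np.linspace(lo, hi, n_grid)
    q = model.predict(grid)
    if cohort is not None:
        sub = cohort[cohort["sex"] == model.sex] if "sex" in cohort.columns else cohort
        ax.plot(sub["age_years"], sub["size_mm"], ".", color="0.6", ms=2, alpha=0.5,
                label="measurements")
    for tau, row in zip(model.taus, q):
        emph = tau == 0.5
        ax.plot(grid, row, lw=1.8 if emph else 1.0, color="C0" if emph else "C1",
                label=f"P{round(tau * 100)}")
    ax.set_xlabel("age (years)")
    ax.set_ylabel("FHOC size (mm)")
    ax.set_title(f"FHOC growth chart — {model.sex}")
    ax.legend(fontsize=7, ncol=2)
    return ax
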