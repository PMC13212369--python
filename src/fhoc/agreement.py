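"""Agreement statistics between paired measurement methods.

Quantifies how well automated (AI-derived) FHOC size measurements agree with a
reference reader: Lin's concordance correlation coefficient (agreement around
the identity line), Pearson's r (linear association irrespective of bias),
MAE/RMSE with bootstrap confidence intervals, Bland-Altman bias and 95% limits
of agreement with a proportional-bias check, a supplementary paired t-test,
and Fisher's Z-test for comparing correlations between subgroups.  A
stratified driver produces one report per sex / side / age-bin stratum.

Sign convention: differences are ``x - y`` with ``x`` the automatic and ``y``
the reference measurement, so a positive Bland-Altman bias means the automatic
method overestimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .reference import DEFAULT_AGE_BINS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EstimateCI:
    """A point estimate with a 95% confidence interval."""

    value: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class BlandAltmanResult:
    bias_mm: float
    loa_low_mm: float
    loa_high_mm: float
    sd_diff_mm: float
    pct_within_loa: float
    prop_bias_slope: float  # mm of difference per mm of mean
    prop_bias_p: float


@dataclass(frozen=True)
class AgreementReport:
    n: int
    mean_x: float
    sd_x: float
    mean_y: float
    sd_y: float
    ccc: EstimateCI
    r: EstimateCI
    mae_mm: EstimateCI
    rmse_mm: EstimateCI
    paired_t: float
    paired_t_p: float


@dataclass(frozen=True)
class StratumResult:
    """Agreement results for one stratum; ``insufficient`` marks strata with
    n < 3, which are reported rather than silently dropped."""

    label: dict
    n: int
    report: AgreementReport | None
    bland_altman: BlandAltmanResult | None
    insufficient: bool


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"x and y lengths differ: {len(x)} vs {len(y)}")
    return x, y


def ccc(x, y, alpha: float = 0.05) -> EstimateCI:
    """Lin's concordance correlation coefficient with a 95% CI.

    CCC = 2*cov(x,y) / (var(x) + var(y) + (mean(x) - mean(y))^2) using
    population (1/n) moments.  The CI uses the Fisher z-transform with Lin's
    asymptotic variance.
    """
    x, y = _paired(x, y)
    n = len(x)
    if n < 3:
        raise ValueError(f"CCC requires n >= 3, got {n}")
    mx, my = x.mean(), y.mean()
    sx2, sy2 = x.var(), y.var()  # population moments
    sxy = ((x - mx) * (y - my)).mean()
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0:
        raise ValueError("CCC undefined: both inputs constant with equal means")
    rho_c = 2.0 * sxy / denom

    zcrit = stats.norm.ppf(1 - alpha / 2)
    if sx2 == 0 or sy2 == 0 or abs(rho_c) >= 1 - 1e-12:
        return EstimateCI(float(rho_c), float(rho_c), float(rho_c))
    r = sxy / np.sqrt(sx2 * sy2)
    u = (mx - my) / (sx2 * sy2) ** 0.25
    one_m = 1.0 - rho_c**2
    var_z = (
        (1 - r**2) * rho_c**2 / (one_m * r**2)
        + 4 * rho_c**3 * (1 - rho_c) * u**2 / (r * one_m**2)
        - 2 * rho_c**4 * u**4 / (r**2 * one_m**2)
    ) / (n - 2)
    var_z = max(var_z, 0.0)
    z = np.arctanh(rho_c)
    lo, hi = np.tanh(z - zcrit * np.sqrt(var_z)), np.tanh(z + zcrit * np.sqrt(var_z))
    return EstimateCI(float(rho_c), float(lo), float(hi))


def pearson_ci(x, y, alpha: float = 0.05) -> EstimateCI:
    """Pearson r with the Fisher-transform 95% CI tanh(atanh(r) +/- z/sqrt(n-3))."""
    x, y = _paired(x, y)
    n = len(x)
    if n < 4:
        raise ValueError(f"Pearson CI requires n >= 4, got {n}")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("Pearson r undefined for constant input")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1 - 1e-15:
        return EstimateCI(r, r, r)
    zcrit = stats.norm.ppf(1 - alpha / 2)
    half = zcrit / np.sqrt(n - 3)
    z = np.arctanh(r)
    return EstimateCI(r, float(np.tanh(z - half)), float(np.tanh(z + half)))


def error_metrics(
    x, y, n_boot: int = 2000, seed: int = 0, alpha: float = 0.05
) -> tuple[EstimateCI, EstimateCI]:
    """MAE and RMSE of x - y with nonparametric percentile-bootstrap CIs.

    Case resampling with ``n_boot`` replicates, reproducible given ``seed``.
    Returns ``(mae, rmse)``.
    """
    x, y = _paired(x, y)
    if len(x) < 2:
        raise ValueError("error metrics require n >= 2")
    if n_boot < 100:
        logger.warning("n_boot=%d is small; bootstrap CIs will be unstable", n_boot)
    d = np.abs(x - y)
    mae = float(d.mean())
    rmse = float(np.sqrt((d**2).mean()))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(d), size=(n_boot, len(d)))
    boot = d[idx]
    mae_b = boot.mean(axis=1)
    rmse_b = np.sqrt((boot**2).mean(axis=1))
    qs = (100 * alpha / 2, 100 * (1 - alpha / 2))
    mae_ci = np.percentile(mae_b, qs)
    rmse_ci = np.percentile(rmse_b, qs)
    return (
        EstimateCI(mae, float(mae_ci[0]), float(mae_ci[1])),
        EstimateCI(rmse, float(rmse_ci[0]), float(rmse_ci[1])),
    )


def bland_altman(x, y) -> BlandAltmanResult:
    """Bland-Altman bias and 95% limits of agreement for differences x - y.

    LoA = bias +/- 1.96 * sd(diff) with the n-1 sample sd and the fixed 1.96
    normal multiplier.  Proportional bias is the least-squares slope of the
    differences on the pairwise means, with its two-sided p-value.
    """
    x, y = _paired(x, y)
    if len(x) < 3:
        raise ValueError("Bland-Altman requires n >= 3")
    d = x - y
    means = (x + y) / 2.0
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = bias - 1.96 * sd, bias + 1.96 * sd
    pct = float(100.0 * np.mean((d >= lo) & (d <= hi)))
    if sd == 0 or np.ptp(means) == 0:
        slope, p = 0.0, 1.0
    else:
        fit = stats.linregress(means, d)
        slope, p = float(fit.slope), float(fit.pvalue)
    return BlandAltmanResult(
        bias_mm=bias, loa_low_mm=float(lo), loa_high_mm=float(hi),
        sd_diff_mm=sd, pct_within_loa=pct, prop_bias_slope=slope, prop_bias_p=p,
    )


def paired_t(x, y) -> tuple[float, float]:
    """Paired t-test on x - y; returns (t, two-sided p)."""
    x, y = _paired(x, y)
    n = len(x)
    if n < 2:
        raise ValueError("paired t-test requires n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("paired t-test undefined: differences have zero variance")
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t), n - 1))
    return t, p


def fisher_z(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Fisher's Z-test comparing two independent correlations.

    Z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)), two-sided normal p.
    """
    for r, n in ((r1, n1), (r2, n2)):
        if abs(r) >= 1.0:
            raise ValueError(f"|r| must be < 1, got {r}")
        if n <= 3:
            raise ValueError(f"group size must exceed 3, got {n}")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return float(z), p


def agreement_report(x, y, n_boot: int = 2000, seed: int = 0) -> AgreementReport:
    """Full agreement battery for one stratum of paired measurements."""
    x, y = _paired(x, y)
    mae, rmse = error_metrics(x, y, n_boot=n_boot, seed=seed)
    t, p = paired_t(x, y)
    return AgreementReport(
        n=len(x),
        mean_x=float(x.mean()), sd_x=float(x.std(ddof=1)),
        mean_y=float(y.mean()), sd_y=float(y.std(ddof=1)),
        ccc=ccc(x, y), r=pearson_ci(x, y),
        mae_mm=mae, rmse_mm=rmse,
        paired_t=t, paired_t_p=p,
    )


_STRATUM_KEYS = ("sex", "side", "age")


def _age_bin_label(bins: Sequence[tuple[float, float]], age: float):
    for lo, hi in bins:
        if lo <= age < hi or (hi == bins[-1][1] and age == hi):
            return (lo, hi)
    return None


def stratified_agreement(
    cohort: pd.DataFrame,
    by: str | Sequence[str] | None = None,
    age_bins: Sequence[tuple[float, float]] = DEFAULT_AGE_BINS,
    n_boot: int = 2000,
    seed: int = 0,
) -> list[StratumResult]:
    """Agreement reports per stratum of a paired-measurement cohort.

    ``by`` names the stratification keys: any of ``"sex"``, ``"side"`` and
    ``"age"`` (age bins), alone or combined (e.g. ``("age", "sex")`` yields
    the 12 x 2 = 24 age-sex subgroups).  ``by=None`` gives a single overall
    report.  Strata with fewer than 3 pairs are reported with
    ``insufficient=True`` rather than dropped.
    """
    if "reference_mm" not in cohort.columns:
        raise ValueError("cohort must have a reference_mm column (paired measurements)")
    keys: tuple[str, ...]
    if by is None:
        keys = ()
    elif isinstance(by, str):
        keys = (by,)
    else:
        keys = tuple(by)
    unknown = set(keys) - set(_STRATUM_KEYS)
    if unknown:
        raise ValueError(f"unknown stratum keys {sorted(unknown)}; valid: {_STRATUM_KEYS}")

    df = cohort.copy()
    group_cols = []
    for key in keys:
        if key == "age":
            bins = list(age_bins)
            df["_age_bin"] = [_age_bin_label(bins, a) for a in df["age_years"]]
            df = df[df["_age_bin"].notna()]
            group_cols.append("_age_bin")
        else:
            group_cols.append(key)

    def levels(col: str) -> Iterable:
        if col == "_age_bin":
            return list(age_bins)
        order = {"sex": ("female", "male"), "side": ("left", "right")}[col]
        present = list(pd.unique(df[col]))
        return [v for v in order if v in present] + [v for v in present if v not in order]

    def label_key(col: str) -> str:
        return "age_bin" if col == "_age_bin" else col

    # cartesian product of requested strata, every one reported
    combos: list[dict] = [dict()]
    for col in group_cols:
        combos = [{**c, label_key(col): v} for c in combos for v in levels(col)]

    out: list[StratumResult] = []
    for combo in combos:
        sel = np.ones(len(df), bool)
        for col in group_cols:
            val = combo[label_key(col)]
            if col == "_age_bin":
                sel &= df["_age_bin"].map(lambda b, v=val: b == v).to_numpy()
            else:
                sel &= (df[col] == val).to_numpy()
        sub = df[sel]
        n = len(sub)
        if n < 3:
            out.append(StratumResult(label=combo, n=n, report=None,
                                     bland_altman=None, insufficient=True))
            continue
        x = sub["size_mm"].to_numpy(float)
        y = sub["reference_mm"].to_numpy(float)
        out.append(StratumResult(
            label=combo, n=n,
            report=agreement_report(x, y, n_boot=n_boot, seed=seed),
            bland_altman=bland_altman(x, y),
            insufficient=False,
        ))
    return out


def strata_to_frame(results: list[StratumResult]) -> pd.DataFrame:
    """Flatten stratified results into a tidy DataFrame (units in headers)."""
    rows = []
    for res in results:
        row: dict = {"stratum": "all" if not res.label else
                     "/".join(f"{k}={v}" for k, v in res.label.items()),
                     "n": res.n, "insufficient": res.insufficient}
        if res.report is not None:
            r = res.report
            row.update({
                "mean_auto_mm": r.mean_x, "sd_auto_mm": r.sd_x,
                "mean_ref_mm": r.mean_y, "sd_ref_mm": r.sd_y,
                "ccc": r.ccc.value, "ccc_ci_low": r.ccc.ci_low, "ccc_ci_high": r.ccc.ci_high,
                "r": r.r.value, "r_ci_low": r.r.ci_low, "r_ci_high": r.r.ci_high,
                "mae_mm": r.mae_mm.value, "mae_ci_low_mm": r.mae_mm.ci_low,
                "mae_ci_high_mm": r.mae_mm.ci_high,
                "rmse_mm": r.rmse_mm.value, "rmse_ci_low_mm": r.rmse_mm.ci_low,
                "rmse_ci_high_mm": r.rmse_mm.ci_high,
                "paired_t": r.paired_t, "paired_t_p": r.paired_t_p,
            })
        if res.bland_altman is not None:
            b = res.bland_altman
            row.update({
                "ba_bias_mm": b.bias_mm, "ba_loa_low_mm": b.loa_low_mm,
                "ba_loa_high_mm": b.loa_high_mm, "ba_pct_within_loa": b.pct_within_loa,
                "ba_prop_bias_slope": b.prop_bias_slope, "ba_prop_bias_p": b.prop_bias_p,
            })
        rows.append(row)
    return pd.DataFrame(rows)
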