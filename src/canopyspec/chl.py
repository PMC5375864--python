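"""Chlorophyll bookkeeping and the sunlit-vs-shaded regression comparison.

Leaf chlorophyll content (LCC, ug/cm^2) comes from SPAD meter readings
through the calibration line LCC = 1.4498 * SPAD - 22.014; canopy
chlorophyll content (CCC, g/m^2) is LCC x LAI with the 0.01 unit factor
(ug/cm^2 -> g/m^2).  Vegetation indices averaged over sunlit-leaf and
shaded-leaf pixels of each scene are related to CCC by rank correlation
(squared Spearman rho) and by linear / exponential least-squares models,
fitted per group and for the pooled data, before and after per-group
z-score normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigurationError, FitError, UndefinedValueError

SPAD_SLOPE = 1.4498
SPAD_INTERCEPT = -22.014


def spad_to_lcc(spad) -> float:
    """SPAD reading -> leaf chlorophyll content (ug/cm^2)."""
    return SPAD_SLOPE * np.asarray(spad, dtype=float) + SPAD_INTERCEPT


def plant_mean_spad(readings) -> float:
    """Representative SPAD of a plant: mean of the three per-leaf means
    (three readings per leaf on the three uppermost expanded leaves)."""
    r = np.asarray(readings, dtype=float)
    if r.shape != (3, 3) or not np.all(np.isfinite(r)):
        raise ConfigurationError("need a finite 3 leaves x 3 readings array")
    return float(r.mean(axis=1).mean())


def canopy_chl(lcc: float, lai: float) -> float:
    """CCC (g/m^2) = LCC (ug/cm^2) x LAI (m^2/m^2) x 0.01."""
    if lcc < 0 or lai < 0:
        raise ConfigurationError("lcc and lai must be >= 0")
    return lcc * lai * 1e-2


@dataclass
class CorrelationResult:
    spearman_rho: float
    r2_spearman: float
    p_value: float
    n: int


@dataclass
class RegressionResult:
    """model='linear': y = c0 + c1 x; model='exponential': y = a e^{b x}."""

    model: str
    coefficients: tuple
    r2: float
    n: int


def spearman_r2(x, y) -> CorrelationResult:
    """Squared Spearman rank correlation with its large-sample p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ConfigurationError("need equal-length 1-D vectors, n >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise UndefinedValueError("zero rank variance; correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(float(rho), float(rho) ** 2, float(p), len(x))


def paired_ttest(a, b):
    """Classic paired t-test on the differences; two-sided p."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or len(a) < 2:
        raise ConfigurationError("need equal-length vectors, n >= 2")
    d = a - b
    if np.std(d, ddof=1) == 0:
        if np.allclose(d, 0):
            return 0.0, 1.0
        raise FitError("zero-variance nonzero differences: t undefined")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def zscore(values) -> np.ndarray:
    """(v - mean) / sd with the n-1 denominator; output has mean 0, sd 1."""
    v = np.asarray(values, float)
    if len(v) < 2:
        raise ConfigurationError("z-score needs n >= 2")
    sd = np.std(v, ddof=1)
    if sd == 0:
        raise UndefinedValueError("zero standard deviation; cannot z-score")
    return (v - v.mean()) / sd


def _r2(y, yhat) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        # constant y: a model reproducing it exactly is a perfect fit
        return 1.0 if ss_res < 1e-20 else 0.0
    return 1.0 - ss_res / ss_tot


def fit_linear(x, y) -> RegressionResult:
    """Ordinary least squares y = c0 + c1 x."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3 or x.shape != y.shape:
        raise ConfigurationError("need equal-length vectors, n >= 3")
    if np.std(x) == 0:
        raise FitError("zero variance in x")
    c1, c0 = np.polyfit(x, y, 1)
    return RegressionResult("linear", (float(c0), float(c1)), _r2(y, c0 + c1 * x), len(x))


def fit_exponential(x, y, maxfev: int = 10000) -> RegressionResult:
    """Nonlinear least squares y = a e^{b x}, initialized from the
    log-linear fit of ln y on x; r^2 on the original scale."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3 or x.shape != y.shape:
        raise ConfigurationError("need equal-length vectors, n >= 3")
    if np.any(y <= 0):
        raise FitError("exponential fit needs y > 0 for initialization")
    b0, loga0 = np.polyfit(x, np.log(y), 1)
    try:
        popt, _ = optimize.curve_fit(
            lambda t, a, b: a * np.exp(b * t),
            x,
            y,
            p0=(float(np.exp(loga0)), float(b0)),
            maxfev=maxfev,
        )
    except RuntimeError as exc:
        raise FitError(f"exponential fit did not converge: {exc}") from exc
    a, b = float(popt[0]), float(popt[1])
    return RegressionResult("exponential", (a, b), _r2(y, a * np.exp(b * x)), len(x))


VI_COLUMNS = ("NDVI", "TCARI", "PRI", "CI_red_edge")


def compare_groups(
    samples: pd.DataFrame,
    vi_names=VI_COLUMNS,
    normalize: str = "zscore",
) -> pd.DataFrame:
    """The SL / SHL / Combined model comparison.

    ``samples`` holds one row per scene x leaf group with columns
    ``group`` (SL or SHL), ``ccc`` and one column per VI (the per-scene
    mean VI over that group's pixels).  Each group's VI values are
    z-scored separately (``normalize='none'`` skips this); linear and
    exponential CCC-vs-VI models are fitted per group and for the pooled
    data.  Returns a tidy table: vi, group, model, r2, c0, c1, n.
    """
    if normalize not in ("zscore", "none"):
        raise ConfigurationError("normalize must be 'zscore' or 'none'")
    rows = []
    for vi in vi_names:
        frames = {}
        for group in ("SL", "SHL"):
            sub = samples[samples["group"] == group]
            if sub.empty:
                raise ConfigurationError(f"no samples for group {group}")
            x = sub[vi].to_numpy(float)
            if normalize == "zscore":
                x = zscore(x)
            frames[group] = (x, sub["ccc"].to_numpy(float))
        frames["Combined"] = (
            np.concatenate([frames["SL"][0], frames["SHL"][0]]),
            np.concatenate([frames["SL"][1], frames["SHL"][1]]),
        )
        for group, (x, y) in frames.items():
            for fit in (fit_linear, fit_exponential):
                try:
                    res = fit(x, y)
                except FitError:
                    continue
                rows.append(
                    {
                        "vi": vi,
                        "group": group,
                        "model": res.model,
                        "r2": res.r2,
                        "c0": res.coefficients[0],
                        "c1": res.coefficients[1],
                        "n": res.n,
                    }
                )
    return pd.DataFrame(rows)


def correlation_table(samples: pd.DataFrame, vi_names=VI_COLUMNS) -> pd.DataFrame:
    """Squared Spearman correlations of per-group VI means with LCC and
    CCC, one row per VI x group."""
    rows = []
    for vi in vi_names:
        for group in ("SL", "SHL"):
            sub = samples[samples["group"] == group]
            for target in ("lcc", "ccc"):
                if target not in sub.columns:
                    continue
                res = spearman_r2(sub[vi].to_numpy(float), sub[target].to_numpy(float))
                rows.append(
                    {
                        "vi": vi,
                        "group": group,
                        "target": target.upper(),
                        "r2_spearman": res.r2_spearman,
                        "p_value": res.p_value,
                        "n": res.n,
                    }
                )
    return pd.DataFrame(rows)
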