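"""Fermentation kinetics, bioassay calibration, and group statistics.

Rates are estimated transparently by central finite differences (with
optional 3-point moving-average pre-smoothing), so they can be checked
against closed-form derivatives of generated curves: the specific
growth rate mu(t) = d ln(OD)/dt in h^-1, and the volumetric product
formation rate dP/dt in ng mL^-1 h^-1. An exponential-window log-linear
regression mode for mu_max is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TimeCourse",
    "CalibrationCurve",
    "BelowDetection",
    "RateSeries",
    "specific_growth_rate",
    "production_rate",
    "bioassay_quantify",
    "two_way_anova_tukey",
    "summary_stats",
]


@dataclass
class TimeCourse:
    """An ordered fermentation time course.

    ``data`` must contain a strictly increasing ``time`` column (hours)
    and an ``od600`` column; substrate and product columns (e.g.
    ``riboflavin``, ``lactose``, ``acetate``) are free-form.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        for col in ("time", "od600"):
            if col not in df.columns:
                raise ValueError(f"time course lacks column {col!r}")
        t = df["time"].to_numpy(dtype=float)
        if np.isnan(t).any():
            raise ValueError("missing time values")
        if not (np.diff(t) > 0).all():
            raise ValueError("time must be strictly increasing")
        if (df["od600"].to_numpy(dtype=float) < 0).any():
            raise ValueError("OD600 must be non-negative")


@dataclass(frozen=True)
class BelowDetection:
    """A concentration below the assay's lowest quantifiable standard."""

    limit: float

    def __str__(self) -> str:
        return f"< {self.limit:g}"


@dataclass
class RateSeries:
    """A derivative series with its maximum and the time it occurs."""

    time: np.ndarray
    rate: np.ndarray
    max_rate: float
    t_max: float


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    pad = window // 2
    padded = np.concatenate([np.repeat(y[0], pad), y, np.repeat(y[-1], pad)])
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def _central_diff(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    # np.gradient implements the 3-point central difference on
    # non-uniform grids with one-sided differences at the edges
    return np.gradient(y, t)


def specific_growth_rate(
    tc: TimeCourse,
    smoothing_window: int = 1,
    *,
    mode: str = "finite_difference",
    regression_points: int = 4,
) -> RateSeries:
    """mu(t) = d ln(OD)/dt and its maximum mu_max (h^-1).

    ``mode='finite_difference'`` (default) takes central differences of
    ln(OD) after optional moving-average smoothing of OD, and reports
    the maximum over interior points. ``mode='regression'`` slides a
    log-linear regression window of ``regression_points`` samples and
    reports the steepest slope, the classical exponential-phase fit.
    """
    t = tc.data["time"].to_numpy(dtype=float)
    od = tc.data["od600"].to_numpy(dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 time points")
    if (od <= 0).any():
        raise ValueError("growth-rate estimation requires OD600 > 0 at all points")
    od_s = _moving_average(od, smoothing_window)
    ln_od = np.log(od_s)
    if mode == "finite_difference":
        mu = _central_diff(t, ln_od)
        interior = slice(1, -1)
        idx = int(np.argmax(mu[interior])) + 1
        return RateSeries(t, mu, float(mu[idx]), float(t[idx]))
    if mode == "regression":
        k = max(regression_points, 2)
        best_slope, best_t = -np.inf, t[0]
        for i in range(len(t) - k + 1):
            slope, _, _, _, _ = stats.linregress(t[i : i + k], ln_od[i : i + k])
            if slope > best_slope:
                best_slope, best_t = slope, float(np.mean(t[i : i + k]))
        mu = _central_diff(t, ln_od)
        return RateSeries(t, mu, float(best_slope), best_t)
    raise ValueError(f"unknown mode {mode!r}")


def production_rate(
    tc: TimeCourse, column: str = "riboflavin", smoothing_window: int = 1
) -> RateSeries:
    """dP/dt by central differences, with its maximum (units of P per h)."""
    if column not in tc.data.columns:
        raise ValueError(f"time course lacks product column {column!r}")
    t = tc.data["time"].to_numpy(dtype=float)
    p = tc.data[column].to_numpy(dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 time points")
    rate = _central_diff(t, _moving_average(p, smoothing_window))
    interior = slice(1, -1)
    idx = int(np.argmax(rate[interior])) + 1
    return RateSeries(t, rate, float(rate[idx]), float(t[idx]))


@dataclass
class CalibrationCurve:
    """A microbiological-assay standard curve, response vs concentration.

    ``concentrations`` (ng mL^-1, ascending, typically spanning 0-300)
    and the measured ``responses`` must be jointly monotone
    non-decreasing, so the inverse is a well-defined piecewise-linear
    interpolation. ``detection_limit`` is the concentration reported for
    responses that fall below the span of the standards (default 0.2
    ng mL^-1, the assay's quantification limit).
    """

    concentrations: np.ndarray
    responses: np.ndarray
    detection_limit: float = 0.2

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.size != self.responses.size:
            raise ValueError("concentrations and responses differ in length")
        if self.concentrations.size < 2:
            raise ValueError("need at least two standards")
        if not (np.diff(self.concentrations) > 0).all():
            raise ValueError("standard concentrations must be strictly increasing")
        if not (np.diff(self.responses) >= 0).all():
            raise ValueError("fitted response must be monotone non-decreasing")


def bioassay_quantify(
    curve: CalibrationCurve, response: float, dilution_factor: float = 1.0
) -> float | BelowDetection:
    """Concentration from an assay response by inverse interpolation.

    Responses below the lowest standard return a
    :class:`BelowDetection` flag carrying the limit; responses above the
    top standard raise, suggesting a higher dilution.
    """
    if not np.isfinite(response):
        raise ValueError("response must be finite")
    if response < curve.responses[0]:
        return BelowDetection(curve.detection_limit)
    if response > curve.responses[-1]:
        raise ValueError(
            "response above the top standard; assay a higher dilution"
        )
    conc = float(np.interp(response, curve.responses, curve.concentrations))
    return conc * dilution_factor


def two_way_anova_tukey(
    values, factor_a, factor_b
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-way ANOVA (type-II SS) plus Tukey HSD on the factor cells.

    Returns ``(anova_table, tukey_table)``. The Tukey comparison runs on
    the a:b cell means with studentized-range p-values; a constant
    response short-circuits to F = 0 / p = 1 throughout.
    """
    df = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "a": pd.Categorical(factor_a),
            "b": pd.Categorical(factor_b),
        }
    )
    for fac in ("a", "b"):
        if df[fac].nunique() < 2:
            raise ValueError(f"factor {fac!r} has a single level")
    cells = df.groupby(["a", "b"], observed=True).size()
    interaction = (cells >= 2).all()
    if df["value"].var(ddof=0) == 0:
        terms = ["a", "b"] + (["a:b"] if interaction else [])
        anova = pd.DataFrame(
            {"sum_sq": 0.0, "df": np.nan, "F": 0.0, "PR(>F)": 1.0}, index=terms
        )
        pairs = sorted(
            str(a) + ":" + str(b) for (a, b) in cells.index
        )
        tukey = pd.DataFrame(
            [
                (g1, g2, 0.0, 1.0)
                for i, g1 in enumerate(pairs)
                for g2 in pairs[i + 1 :]
            ],
            columns=["group1", "group2", "meandiff", "p_adj"],
        )
        return anova, tukey

    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    formula = "value ~ C(a) + C(b)"
    if interaction:
        formula += " + C(a):C(b)"
    model = smf.ols(formula, data=df).fit()
    anova = anova_lm(model, typ=2)
    cell_label = df["a"].astype(str) + ":" + df["b"].astype(str)
    hsd = pairwise_tukeyhsd(df["value"], cell_label, alpha=0.05)
    tukey = pd.DataFrame(
        hsd.summary().data[1:], columns=[c for c in hsd.summary().data[0]]
    ).rename(columns={"p-adj": "p_adj"})
    return anova, tukey


def summary_stats(values) -> dict[str, float]:
    """Mean, median, min, max of a sample."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    return {
        "mean": float(v.mean()),
        "median": float(np.median(v)),
        "min": float(v.min()),
        "max": float(v.max()),
    }
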