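"""Selection-coefficient estimation from in vivo competition assays.

A mutant and a reference strain are co-inoculated 1:1; plates are scored
over ~3 days.  The per-hour selection coefficient s is the OLS slope of
ln(mutant/reference) against time in hours — under exponential growth
the log-ratio is linear in time with slope equal to the fitness
difference.  Group comparisons (host genotype x housing/microbiota) use
ANOVA with Tukey HSD; antagonistic pleiotropy shows up as excess
across-host variance, compared with a two-sided F test.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import StatTestResult

__all__ = [
    "CompetitionSeries",
    "CompetitionResult",
    "estimate_selection_coefficient",
    "cohort_selection_coefficients",
    "variance_ratio_test",
    "AnovaResult",
    "group_anova",
]


@dataclass
class CompetitionSeries:
    """Mutant vs reference colony counts over hours in one host."""

    mouse_id: str
    host: str
    housing: str  # independent | cohoused | germfree
    times_h: np.ndarray
    mutant: np.ndarray
    reference: np.ndarray

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.mutant = np.asarray(self.mutant)
        self.reference = np.asarray(self.reference)
        if not np.all(np.diff(self.times_h) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.mutant < 0) or np.any(self.reference < 0):
            raise ValueError("counts must be >= 0")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> list:
        out = []
        cols = ["mouse_id", "host"] + (["housing"] if "housing" in df.columns else [])
        for key, g in df.groupby(cols, sort=True):
            g = g.sort_values("time_h")
            out.append(
                cls(
                    mouse_id=str(key[0]),
                    host=str(key[1]),
                    housing=str(key[2]) if len(key) > 2 else "independent",
                    times_h=g["time_h"].to_numpy(),
                    mutant=g["mutant"].to_numpy(),
                    reference=g["reference"].to_numpy(),
                )
            )
        return out


@dataclass
class CompetitionResult:
    mouse_id: str
    host: str
    housing: str
    s_per_hour: float
    intercept: float
    slope_se: float
    n_points: int


def estimate_selection_coefficient(series: CompetitionSeries) -> CompetitionResult:
    """OLS slope of ln(mutant/reference) on time (hours).

    Time points where either competitor has a zero count are dropped with
    a warning; fewer than 3 remaining points is an error.
    """
    ok = (series.mutant > 0) & (series.reference > 0)
    if not ok.all():
        warnings.warn(
            f"{series.mouse_id}: dropping {int((~ok).sum())} time point(s) with a zero count",
            stacklevel=2,
        )
    t = series.times_h[ok]
    if len(t) < 3:
        raise ValueError(
            f"{series.mouse_id}: need >= 3 time points with both competitors present, have {len(t)}"
        )
    y = np.log(series.mutant[ok].astype(float) / series.reference[ok].astype(float))
    lr = sps.linregress(t, y)
    return CompetitionResult(
        mouse_id=series.mouse_id,
        host=series.host,
        housing=series.housing,
        s_per_hour=float(lr.slope),
        intercept=float(lr.intercept),
        slope_se=float(lr.stderr),
        n_points=len(t),
    )


def cohort_selection_coefficients(df: pd.DataFrame) -> pd.DataFrame:
    """Per-host s for a competition table (one row per mouse)."""
    rows = []
    for series in CompetitionSeries.from_dataframe(df):
        r = estimate_selection_coefficient(series)
        rows.append(
            (r.mouse_id, r.host, r.housing, r.s_per_hour, r.intercept, r.slope_se, r.n_points)
        )
    return pd.DataFrame(
        rows,
        columns=["mouse_id", "host", "housing", "s_per_hour", "intercept", "slope_se", "n_points"],
    )


def variance_ratio_test(s_a, s_b) -> StatTestResult:
    """Two-sided F test of equal variances, F = var(a)/var(b).

    Sample variances use denominator n-1; the two-sided p doubles the
    smaller of the two F tails (capped at 1).
    """
    a = np.asarray(s_a, dtype=float)
    b = np.asarray(s_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 observations")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if vb == 0:
        raise ValueError("zero variance in denominator group")
    f = va / vb
    dist = sps.f(len(a) - 1, len(b) - 1)
    p = min(1.0, 2.0 * min(dist.cdf(f), dist.sf(f)))
    return StatTestResult(
        name="F", statistic=float(f), p_value=float(p), df=(len(a) - 1, len(b) - 1),
        n=(len(a), len(b)),
    )


@dataclass
class AnovaResult:
    table: pd.DataFrame  # statsmodels-style ANOVA table
    tukey: pd.DataFrame | None  # pairwise comparisons (one-way only)

    @property
    def f(self) -> float:
        return float(self.table["F"].iloc[0])

    @property
    def p_value(self) -> float:
        return float(self.table["PR(>F)"].iloc[0])


def group_anova(values, factor1, factor2=None, tukey: bool = True) -> AnovaResult:
    """One- or two-way fixed-effects ANOVA on selection coefficients.

    One-way (``factor2 is None``): F test across levels of ``factor1``
    plus Tukey HSD (studentized-range) adjusted pairwise p-values.
    Two-way: type-II ANOVA with the ``factor1:factor2`` interaction; the
    factorial layout must be complete (an empty cell is an error naming
    the missing combination).
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    values = np.asarray(values, dtype=float)
    f1 = np.asarray(factor1).astype(str)
    if len(values) != len(f1):
        raise ValueError("values and factor1 differ in length")
    levels1, counts1 = np.unique(f1, return_counts=True)
    if len(levels1) < 2:
        raise ValueError("need >= 2 groups")
    if counts1.min() < 2:
        raise ValueError("each group needs n >= 2")
    df = pd.DataFrame({"y": values, "f1": f1})
    if factor2 is None:
        model = ols("y ~ C(f1)", data=df).fit()
        if model.ssr <= 1e-12 * max(1.0, float(np.abs(values).max()) ** 2):
            raise ValueError("zero residual (within-group) variance: F undefined")
        table = sm.stats.anova_lm(model, typ=1)
        table = table.rename(index={"C(f1)": "group"})
        tk = None
        if tukey:
            from statsmodels.stats.multicomp import pairwise_tukeyhsd

            res = pairwise_tukeyhsd(values, f1)
            tk = pd.DataFrame(
                res._results_table.data[1:], columns=res._results_table.data[0]
            )
        return AnovaResult(table=table, tukey=tk)

    f2 = np.asarray(factor2).astype(str)
    if len(values) != len(f2):
        raise ValueError("values and factor2 differ in length")
    cells = pd.crosstab(f1, f2)
    if (cells.values == 0).any():
        i, j = np.argwhere(cells.values == 0)[0]
        raise ValueError(
            f"incomplete factorial layout: empty cell ({cells.index[i]!r}, {cells.columns[j]!r})"
        )
    df["f2"] = f2
    model = ols("y ~ C(f1) * C(f2)", data=df).fit()
    scale = 1e-12 * max(1.0, float(np.abs(values).max()) ** 2)
    if model.df_resid > 0 and model.ssr <= scale:
        # exact-fit data: terms with zero sum of squares contribute nothing
        # (F -> 0), terms with positive SS are unboundedly significant
        table = sm.stats.anova_lm(model, typ=2)
        ss = table["sum_sq"]
        table["F"] = np.where(ss <= scale, 0.0, np.inf)
        table["PR(>F)"] = np.where(ss <= scale, 1.0, 0.0)
        table.loc["Residual", ["F", "PR(>F)"]] = np.nan
    else:
        table = sm.stats.anova_lm(model, typ=2)
    table = table.rename(
        index={
            "C(f1)": "factor1",
            "C(f2)": "factor2",
            "C(f1):C(f2)": "interaction",
        }
    )
    return AnovaResult(table=table, tukey=None)
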