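"""In vivo division-rate inference from ribosomal-content fluorescence.

Bacterial rRNA content correlates with division rate, so the median
fluorescence of a 23S rRNA probe hybridized to cells reports how fast
they were growing.  The workflow is:

1. fit exponential growth rates to in vitro OD curves in media spanning
   a range of rates (``fit_exponential_rate``);
2. regress rate on median hybridization fluorescence across those
   conditions (``fit_calibration`` — a linear map; the cited
   rRNA-content method is near-linear over moderate rates);
3. invert the calibration for cells sampled from faeces to get an in
   vivo doubling time in minutes (``infer_doubling_time``), with a
   delta-method standard error and an extrapolation warning outside the
   calibrated fluorescence range.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GrowthCurve",
    "ExponentialFit",
    "CalibrationModel",
    "DoublingTime",
    "fit_exponential_rate",
    "fit_calibration",
    "average_hybridizations",
    "infer_doubling_time",
]

LN2 = math.log(2.0)


@dataclass
class GrowthCurve:
    medium: str
    times_h: np.ndarray
    od: np.ndarray

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if not np.all(np.diff(self.times_h) > 0):
            raise ValueError("times must be strictly increasing")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> list:
        out = []
        for medium, g in df.groupby("medium", sort=True):
            g = g.sort_values("time_h")
            out.append(cls(str(medium), g["time_h"].to_numpy(), g["od"].to_numpy()))
        return out


@dataclass
class ExponentialFit:
    rate_per_hour: float
    intercept: float
    r_squared: float
    window: tuple  # (t_first, t_last) of the fitted window
    n_points: int


def fit_exponential_rate(
    curve: GrowthCurve,
    window: int = 5,
    od_min: float = 0.02,
    od_max: float = 0.5,
) -> ExponentialFit:
    """Exponential growth rate: OLS slope of ln(OD) vs time over the
    maximal-R^2 sliding window of ``window`` consecutive points, among
    points with od_min <= OD <= od_max.

    The OD bounds restrict the fit to exponential phase (above detection
    noise, below saturation); the sliding window then picks the most
    log-linear stretch.  If fewer points than ``window`` qualify, all of
    them are used (minimum 4).
    """
    mask = (curve.od >= od_min) & (curve.od <= od_max)
    t = curve.times_h[mask]
    y = np.log(curve.od[mask])
    n = len(t)
    if n < 4:
        raise ValueError(
            f"{curve.medium}: only {n} points within OD bounds [{od_min}, {od_max}]; need >= 4"
        )
    w = min(window, n)
    best = None
    for i in range(n - w + 1):
        lr = sps.linregress(t[i : i + w], y[i : i + w])
        r2 = lr.rvalue**2
        if best is None or r2 > best[0] + 1e-15:
            best = (r2, lr, t[i], t[i + w - 1])
    r2, lr, t0, t1 = best
    return ExponentialFit(
        rate_per_hour=float(lr.slope),
        intercept=float(lr.intercept),
        r_squared=float(r2),
        window=(float(t0), float(t1)),
        n_points=w,
    )


@dataclass
class CalibrationModel:
    """Linear map rate_per_hour = intercept + slope * fluorescence."""

    slope: float
    intercept: float
    residual_sd: float
    n: int
    f_mean: float
    f_sxx: float
    f_range: tuple

    def predict_rate(self, fluorescence: float) -> float:
        return self.intercept + self.slope * fluorescence

    def rate_se(self, fluorescence: float) -> float:
        # prediction se of the mean response at this fluorescence
        return self.residual_sd * math.sqrt(
            1.0 / self.n + (fluorescence - self.f_mean) ** 2 / self.f_sxx
        )


def average_hybridizations(hyb: pd.DataFrame) -> pd.DataFrame:
    """Average replicate hybridizations per sample (two per sample in the
    assay design); returns columns sample, median_fluorescence."""
    col = "median_fluorescence" if "median_fluorescence" in hyb.columns else "fluorescence"
    out = hyb.groupby("sample", sort=True)[col].mean().reset_index()
    return out.rename(columns={col: "median_fluorescence"})


def fit_calibration(rates, fluorescences) -> CalibrationModel:
    """OLS of growth rate (per hour) on median fluorescence (a.u.).

    Replicate hybridizations should be averaged per condition first
    (:func:`average_hybridizations`).  Needs >= 3 distinct fluorescence
    values; a rank-deficient design is an error.
    """
    r = np.asarray(rates, dtype=float)
    f = np.asarray(fluorescences, dtype=float)
    if len(r) != len(f):
        raise ValueError("rates and fluorescences differ in length")
    if len(np.unique(f)) < 3:
        raise ValueError("need >= 3 distinct fluorescence values")
    lr = sps.linregress(f, r)
    if lr.slope == 0:
        raise ValueError("zero calibration slope: model not invertible")
    resid = r - (lr.intercept + lr.slope * f)
    dof = len(r) - 2
    residual_sd = float(np.sqrt((resid**2).sum() / dof)) if dof > 0 else 0.0
    return CalibrationModel(
        slope=float(lr.slope),
        intercept=float(lr.intercept),
        residual_sd=residual_sd,
        n=len(r),
        f_mean=float(f.mean()),
        f_sxx=float(((f - f.mean()) ** 2).sum()),
        f_range=(float(f.min()), float(f.max())),
    )


@dataclass
class DoublingTime:
    minutes: float
    se_minutes: float
    rate_per_hour: float
    fluorescence: float
    extrapolated: bool


def infer_doubling_time(fluorescence: float, model: CalibrationModel) -> DoublingTime:
    """Doubling time (minutes) from fluorescence via the calibration model.

    doubling_min = 60 ln2 / rate with rate = intercept + slope * F; the
    standard error propagates the calibration prediction error by the
    delta method.  Warns when F lies outside the calibrated range.
    """
    rate = model.predict_rate(fluorescence)
    if rate <= 0:
        raise ValueError(
            f"predicted growth rate {rate:.4g}/h is not positive at fluorescence {fluorescence}"
        )
    lo, hi = model.f_range
    extrapolated = not (lo <= fluorescence <= hi)
    if extrapolated:
        warnings.warn(
            f"fluorescence {fluorescence:.4g} outside calibrated range [{lo:.4g}, {hi:.4g}]",
            stacklevel=2,
        )
    minutes = 60.0 * LN2 / rate
    se_rate = model.rate_se(fluorescence)
    se_minutes = 60.0 * LN2 * se_rate / rate**2
    return DoublingTime(
        minutes=float(minutes),
        se_minutes=float(se_minutes),
        rate_per_hour=float(rate),
        fluorescence=float(fluorescence),
        extrapolated=extrapolated,
    )
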