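"""Neutral fluorescent-marker dynamics and early sweep detection.

Two isogenic strains carrying neutral YFP/CFP tags are inoculated 1:1;
beneficial mutations arising on either background drag their marker
along, so a significant trend in ln(YFP/CFP) during early colonization
flags a selective sweep.  Hosts are then compared by the number of lines
whose marker trajectories diverged.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import StatTestResult

__all__ = [
    "FrequencyEstimate",
    "Trajectory",
    "DivergenceResult",
    "estimate_frequency",
    "divergence_test",
    "divergence_table",
    "compare_diverged_counts",
]


@dataclass(frozen=True)
class FrequencyEstimate:
    """Marker frequency with its colony-sampling standard error.

    sem = sqrt(p(1-p)/n) for 0 < p < 1; at the boundaries (p = 0 or 1)
    the binomial formula degenerates to zero, so 1/n is reported instead
    (roughly the outer half-width of an exact interval at the boundary).
    """

    p: float
    n: int
    sem: float


def estimate_frequency(count_a: int, count_b: int) -> FrequencyEstimate:
    """Frequency of category A among A+B colonies, with sampling sem."""
    if count_a < 0 or count_b < 0:
        raise ValueError("colony counts must be >= 0")
    n = count_a + count_b
    if n < 1:
        raise ValueError("total colony count must be >= 1")
    p = count_a / n
    if 0.0 < p < 1.0:
        sem = math.sqrt(p * (1.0 - p) / n)
    else:
        sem = 1.0 / n
    return FrequencyEstimate(p=p, n=n, sem=sem)


@dataclass
class Trajectory:
    """Daily YFP/CFP colony counts for one line (mouse)."""

    mouse_id: str
    host: str
    days: np.ndarray
    yfp: np.ndarray
    cfp: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.yfp = np.asarray(self.yfp)
        self.cfp = np.asarray(self.cfp)
        if not np.all(np.diff(self.days) > 0):
            raise ValueError("days must be strictly increasing")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> list:
        """Split a marker table (mouse_id, host, day, yfp, cfp) into trajectories."""
        out = []
        for (mouse, host), g in df.groupby(["mouse_id", "host"], sort=True):
            g = g.sort_values("day")
            out.append(
                cls(
                    mouse_id=str(mouse),
                    host=str(host),
                    days=g["day"].to_numpy(),
                    yfp=g["yfp"].to_numpy(),
                    cfp=g["cfp"].to_numpy(),
                )
            )
        return out

    def frequencies(self) -> list:
        return [estimate_frequency(a, b) for a, b in zip(self.yfp, self.cfp)]


@dataclass
class DivergenceResult:
    mouse_id: str
    host: str
    slope: float
    slope_se: float
    p_value: float
    n_points: int
    diverged: bool | None  # None when not evaluable
    evaluable: bool
    excluded_days: tuple


def divergence_test(
    traj: Trajectory,
    day_window: tuple = (1, 6),
    alpha: float = 0.05,
    pseudocount: float = 0.0,
) -> DivergenceResult:
    """OLS of ln(YFP/CFP) on day within ``day_window``; diverged at p < alpha.

    Days with a zero count for either marker are excluded with a warning
    (the log-ratio is undefined), unless ``pseudocount`` > 0, in which
    case it is added to both counts on every in-window day.  Fewer than
    4 usable days yields a not-evaluable result (``diverged is None``),
    which is distinct from "not diverged".
    """
    lo, hi = day_window
    mask = (traj.days >= lo) & (traj.days <= hi)
    days = traj.days[mask]
    yfp = traj.yfp[mask].astype(float)
    cfp = traj.cfp[mask].astype(float)
    excluded = ()
    if pseudocount > 0:
        yfp = yfp + pseudocount
        cfp = cfp + pseudocount
    else:
        ok = (yfp > 0) & (cfp > 0)
        if not ok.all():
            excluded = tuple(days[~ok])
            warnings.warn(
                f"{traj.mouse_id}: excluding days {list(excluded)} with a zero marker count",
                stacklevel=2,
            )
        days, yfp, cfp = days[ok], yfp[ok], cfp[ok]
    if len(days) < 4:
        return DivergenceResult(
            mouse_id=traj.mouse_id,
            host=traj.host,
            slope=float("nan"),
            slope_se=float("nan"),
            p_value=float("nan"),
            n_points=len(days),
            diverged=None,
            evaluable=False,
            excluded_days=excluded,
        )
    lr = sps.linregress(days, np.log(yfp / cfp))
    return DivergenceResult(
        mouse_id=traj.mouse_id,
        host=traj.host,
        slope=float(lr.slope),
        slope_se=float(lr.stderr),
        p_value=float(lr.pvalue),
        n_points=len(days),
        diverged=bool(lr.pvalue < alpha),
        evaluable=True,
        excluded_days=excluded,
    )


def divergence_table(
    df: pd.DataFrame,
    day_window: tuple = (1, 6),
    alpha: float = 0.05,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Per-line divergence results for a marker table."""
    rows = []
    for traj in Trajectory.from_dataframe(df):
        r = divergence_test(traj, day_window=day_window, alpha=alpha, pseudocount=pseudocount)
        rows.append(
            (
                r.mouse_id,
                r.host,
                r.slope,
                r.slope_se,
                r.p_value,
                r.n_points,
                r.diverged,
                r.evaluable,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "mouse_id",
            "host",
            "slope",
            "slope_se",
            "p_value",
            "n_points",
            "diverged",
            "evaluable",
        ],
    )


def compare_diverged_counts(
    k1: int, n1: int, k2: int, n2: int, method: str = "conditional-binomial"
) -> StatTestResult:
    """Compare the number of diverged lines between two host groups.

    Default is a conditional binomial test: given K = k1 + k2 diverged
    lines in total, under the null each is equally likely to fall in
    either group in proportion to group size, so X1 ~ Binomial(K,
    n1/(n1+n2)); the two-sided p doubles the smaller tail (capped at 1).
    ``method="fisher"`` gives Fisher's exact test on the 2x2 table as an
    alternative exact construction.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if not 0 <= k <= n:
            raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if method == "fisher":
        res = sps.fisher_exact([[k1, n1 - k1], [k2, n2 - k2]])
        return StatTestResult(
            name="fisher-exact", statistic=float(res.statistic), p_value=float(res.pvalue),
            n=(n1, n2), extra={"k": (k1, k2)},
        )
    if method != "conditional-binomial":
        raise ValueError(f"unknown method {method!r}")
    K = k1 + k2
    if K == 0:
        return StatTestResult(
            name="conditional-binomial", statistic=0.0, p_value=1.0, n=(n1, n2),
            extra={"k": (k1, k2)},
        )
    q = n1 / (n1 + n2)
    lower = sps.binom.cdf(k1, K, q)
    upper = sps.binom.sf(k1 - 1, K, q)
    p = min(1.0, 2.0 * min(lower, upper))
    return StatTestResult(
        name="conditional-binomial",
        statistic=float(k1),
        p_value=float(p),
        n=(n1, n2),
        extra={"k": (k1, k2), "K": K, "tail_lower": float(lower), "tail_upper": float(upper)},
    )
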