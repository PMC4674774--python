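"""gat-phenotype sweep dynamics across host genotypes.

The frequency of galactitol-negative (white) colonies sweeps as the
first beneficial mutations rise.  The cross-host model is a binomial
GLM on the logit scale,

    logit(p) = beta0 + (beta1 + beta2 * I[fast genotype]) * day,

with the intercept (initial frequency) shared between genotypes — both
cohorts start from the same gavage mix — counts as binomial
denominators, and mouse-level dependence absorbed by cluster-robust
(sandwich) standard errors rather than a random-intercept GLMM.  The
interaction z = beta2 / se(beta2) measures how much faster the sweep
runs in the fast genotype; beta2 > 0 means WT sweeps faster under the
default coding.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PhenotypeSeries", "SweepFit", "fit_sweep", "phenotype_variance"]


@dataclass
class PhenotypeSeries:
    mouse_id: str
    host: str
    days: np.ndarray
    gat_neg: np.ndarray
    total: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.gat_neg = np.asarray(self.gat_neg, dtype=float)
        self.total = np.asarray(self.total, dtype=float)
        if not np.all(np.diff(self.days) > 0):
            raise ValueError("days must be strictly increasing")
        if np.any(self.gat_neg < 0) or np.any(self.gat_neg > self.total):
            raise ValueError("need 0 <= gat_neg <= total")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> list:
        out = []
        for (mouse, host), g in df.groupby(["mouse_id", "host"], sort=True):
            g = g.sort_values("day")
            out.append(
                cls(
                    str(mouse),
                    str(host),
                    g["day"].to_numpy(),
                    g["gat_neg"].to_numpy(),
                    g["total"].to_numpy(),
                )
            )
        return out


@dataclass
class SweepFit:
    intercepts: dict          # genotype -> logit initial frequency (equal when shared)
    slope_per_day: dict       # genotype -> per-day logit slope
    interaction: float | None # beta2 (fast - reference slope); None for one genotype
    interaction_se: float | None
    interaction_se_naive: float | None
    z: float | None
    p_value: float | None
    reference: str
    fast: str | None
    shared_intercept: bool
    n_obs: int
    n_mice: int
    converged: bool
    separation: bool


def fit_sweep(
    series,
    shared_intercept: bool = True,
    fast_genotype: str = "WT",
    maxiter: int = 200,
) -> SweepFit:
    """Binomial ML fit of the sweep model over one or two host genotypes.

    ``series`` is a list of :class:`PhenotypeSeries` or a phenotype
    table (mouse_id, host, day, gat_neg, total).  With two genotypes the
    slope difference beta2 (fast minus reference genotype) is tested
    with a cluster-robust z; ``shared_intercept=False`` frees one
    intercept per genotype (used to check the constraint).  Complete
    separation is flagged when any coefficient runs away.
    """
    import statsmodels.api as sm

    if isinstance(series, pd.DataFrame):
        series = PhenotypeSeries.from_dataframe(series)
    rows = []
    for s in series:
        for d, k, n in zip(s.days, s.gat_neg, s.total):
            if n < 1:
                raise ValueError(f"{s.mouse_id}: total count < 1 at day {d}")
            rows.append((s.mouse_id, s.host, d, k, n))
    df = pd.DataFrame(rows, columns=["mouse_id", "host", "day", "k", "n"])
    genotypes = sorted(df["host"].unique())
    if len(genotypes) > 2:
        raise ValueError(f"at most 2 host genotypes supported, got {genotypes}")
    for g in genotypes:
        if df.loc[df.host == g, "day"].nunique() < 2:
            raise ValueError(f"genotype {g}: need >= 2 distinct days")
    two = len(genotypes) == 2
    if two:
        fast = fast_genotype if fast_genotype in genotypes else genotypes[-1]
        ref = next(g for g in genotypes if g != fast)
        ind = (df["host"] == fast).astype(float).to_numpy()
    else:
        fast, ref = None, genotypes[0]
        ind = np.zeros(len(df))

    day = df["day"].to_numpy()
    cols = {}
    if shared_intercept or not two:
        cols["const"] = np.ones(len(df))
    else:
        cols[f"const[{ref}]"] = 1.0 - ind
        cols[f"const[{fast}]"] = ind
    cols["day"] = day
    if two:
        cols["day:fast"] = day * ind
    X = pd.DataFrame(cols)
    endog = np.column_stack([df["k"].to_numpy(), (df["n"] - df["k"]).to_numpy()])
    groups = df["mouse_id"].to_numpy()

    model = sm.GLM(endog, X, family=sm.families.Binomial())
    fit_naive = model.fit(maxiter=maxiter)
    n_clusters = len(np.unique(groups))
    if n_clusters > 1:
        fit_rob = model.fit(
            maxiter=maxiter, cov_type="cluster", cov_kwds={"groups": pd.Series(groups)}
        )
    else:
        fit_rob = fit_naive
    if not fit_naive.converged:
        raise RuntimeError(
            f"sweep GLM did not converge after {maxiter} iterations; "
            f"deviance={fit_naive.deviance:.4g}"
        )
    params = fit_rob.params
    separation = bool(np.any(np.abs(params.to_numpy()) > 30))

    if shared_intercept or not two:
        b0 = float(params["const"])
        intercepts = {g: b0 for g in genotypes}
    else:
        intercepts = {g: float(params[f"const[{g}]"]) for g in genotypes}
    b1 = float(params["day"])
    if two:
        b2 = float(params["day:fast"])
        se = float(fit_rob.bse["day:fast"])
        se_naive = float(fit_naive.bse["day:fast"])
        z = b2 / se if se > 0 else float("nan")
        from scipy import stats as sps

        p = float(2 * sps.norm.sf(abs(z)))
        slope = {ref: b1, fast: b1 + b2}
    else:
        b2 = se = se_naive = z = p = None
        slope = {ref: b1}
    return SweepFit(
        intercepts=intercepts,
        slope_per_day=slope,
        interaction=b2,
        interaction_se=se,
        interaction_se_naive=se_naive,
        z=z,
        p_value=p,
        reference=ref,
        fast=fast,
        shared_intercept=bool(shared_intercept or not two),
        n_obs=len(df),
        n_mice=n_clusters,
        converged=bool(fit_naive.converged),
        separation=separation,
    )


def phenotype_variance(series) -> pd.DataFrame:
    """Across-mouse sample variance of the gat-negative frequency per day.

    Days observed in fewer than 2 mice get variance NaN.  A variance
    collapsing to ~0 marks the sweep completing (all mice fixed).
    """
    if isinstance(series, pd.DataFrame):
        series = PhenotypeSeries.from_dataframe(series)
    rows = []
    for s in series:
        for d, k, n in zip(s.days, s.gat_neg, s.total):
            rows.append((s.host, d, k / n))
    df = pd.DataFrame(rows, columns=["host", "day", "freq"])
    out = (
        df.groupby(["host", "day"])["freq"]
        .agg(n_mice="count", variance=lambda x: x.var(ddof=1) if len(x) > 1 else np.nan)
        .reset_index()
    )
    return out
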