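"""Mutation- and transposition-frequency estimation at mutation-selection balance.

Slightly deleterious resistance alleles (rifampicin, nalidixic acid,
furazolidone) recur by mutation and are purged by selection, so their
equilibrium frequency in a large colonizing population is proportional
to the mutation rate.  The primary output is therefore the log10
resistant *frequency*; inversion to a rate per generation
(mu = f* x s_d) requires a user-supplied cost and is model-dependent.

Transposition frequency is the resistant frequency scaled by the typed
fraction of resistant clones carrying an insertion-sequence hit.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import StatTestResult

__all__ = [
    "ResistanceCount",
    "MutationRateEstimate",
    "TranspositionEstimate",
    "resistant_fraction",
    "summarize_frequency",
    "transposition_frequency",
    "mann_whitney",
]


@dataclass(frozen=True)
class ResistanceCount:
    """One day x mouse selective-plating observation.

    ``dilution_*`` and ``vol_*`` are the plated fractions for the
    resistant (selective) and total (permissive) plates; counts are
    rescaled to a common basis as (count / dilution / vol).
    """

    mouse_id: str
    host: str
    day: float
    antibiotic: str
    resistant: int
    total: int
    dilution_r: float = 1.0
    vol_r: float = 1.0
    dilution_t: float = 1.0
    vol_t: float = 1.0

    def __post_init__(self) -> None:
        if self.resistant < 0 or self.total < 0:
            raise ValueError("counts must be >= 0")
        for d in (self.dilution_r, self.vol_r, self.dilution_t, self.vol_t):
            if not d > 0:
                raise ValueError("dilution/volume factors must be > 0")


def resistant_fraction(rc: ResistanceCount, pseudocount: float = 0.0) -> float | None:
    """log10 resistant fraction for one observation.

    Returns ``None`` (censored) when no resistant colonies were seen and
    no pseudocount is applied: a zero is a detection limit, not a zero
    frequency.  ``pseudocount`` adds that many colonies to the resistant
    count (sensitivity-analysis mode).
    """
    if rc.total <= 0:
        raise ValueError("total count must be > 0")
    r = rc.resistant + pseudocount
    if r <= 0:
        return None
    frac = (r / rc.dilution_r / rc.vol_r) / (rc.total / rc.dilution_t / rc.vol_t)
    if frac <= 0:
        raise ValueError("non-positive resistant fraction after scaling")
    return math.log10(frac)


@dataclass
class MutationRateEstimate:
    antibiotic: str
    mean_log10_frequency: float
    per_mouse: dict  # mouse_id -> mean of daily log10 fractions
    n_mice: int
    n_censored: int
    mu: float | None = None  # only when a cost s_d was supplied


def summarize_frequency(
    records, s_d: float | None = None, pseudocount: float = 0.0
) -> MutationRateEstimate:
    """Hierarchical average of log10 resistant fractions for one antibiotic.

    Daily log10 fractions are averaged within mouse first, then
    unweighted across mice (each mouse contributes equally regardless of
    how many of its days were censored).  With a cost ``s_d`` the
    mutation-selection-balance inversion mu = 10^mean x s_d is reported.
    """
    records = list(records)
    if not records:
        raise ValueError("no records")
    abx = {rc.antibiotic for rc in records}
    if len(abx) != 1:
        raise ValueError(f"records span multiple antibiotics: {sorted(abx)}")
    per_mouse_vals: dict = {}
    n_censored = 0
    for rc in records:
        v = resistant_fraction(rc, pseudocount=pseudocount)
        if v is None:
            n_censored += 1
            continue
        per_mouse_vals.setdefault(rc.mouse_id, []).append(v)
    if not per_mouse_vals:
        raise ValueError("all records censored (no resistant colonies observed)")
    per_mouse = {m: float(np.mean(v)) for m, v in sorted(per_mouse_vals.items())}
    mean = float(np.mean(list(per_mouse.values())))
    mu = 10**mean * s_d if s_d is not None else None
    return MutationRateEstimate(
        antibiotic=abx.pop(),
        mean_log10_frequency=mean,
        per_mouse=per_mouse,
        n_mice=len(per_mouse),
        n_censored=n_censored,
        mu=mu,
    )


def records_from_dataframe(df: pd.DataFrame) -> list:
    """ResistanceCount records from a resistance table."""
    out = []
    for row in df.itertuples(index=False):
        out.append(
            ResistanceCount(
                mouse_id=str(row.mouse_id),
                host=str(row.host),
                day=float(row.day),
                antibiotic=str(row.antibiotic),
                resistant=int(row.resistant),
                total=int(row.total),
                dilution_r=float(getattr(row, "dilution_r", 1.0)),
                dilution_t=float(getattr(row, "dilution_t", 1.0)),
            )
        )
    return out


@dataclass
class TranspositionEstimate:
    log10_frequency: float
    n_is: int
    n_typed: int
    upper_bound: bool  # True when n_is = 0: frequency is below this value


def transposition_frequency(
    n_is: int, n_typed: int, est: MutationRateEstimate
) -> TranspositionEstimate:
    """log10 transposition frequency: resistant frequency scaled by the
    typed IS fraction.

    With ``n_is = 0`` the estimate is censored: the value reported (using
    one IS clone in the numerator) is an upper bound on the frequency.
    """
    if n_typed < 1:
        raise ValueError("n_typed must be >= 1")
    if not 0 <= n_is <= n_typed:
        raise ValueError("need 0 <= n_is <= n_typed")
    upper = n_is == 0
    frac = max(n_is, 1) / n_typed
    return TranspositionEstimate(
        log10_frequency=est.mean_log10_frequency + math.log10(frac),
        n_is=n_is,
        n_typed=n_typed,
        upper_bound=upper,
    )


# ----------------------------------------------------------------------
# Mann-Whitney


_ENUM_CAP = 200_000


def mann_whitney(a, b) -> StatTestResult:
    """Two-sided Mann-Whitney rank-sum test.

    The statistic W is the rank sum (midranks for ties) of the first
    sample, matching the convention of common statistical software.
    The p-value is exact when both groups have n <= 12: a tie-aware
    enumeration over group assignments when C(n1+n2, n1) <= 2e5,
    otherwise (tie-free only) the exact network recursion; everything
    else uses the normal approximation with tie correction.  Two-sided
    p doubles the smaller tail, capped at 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    W = float(ranks[:n1].sum())
    has_ties = len(np.unique(pooled)) < n1 + n2
    method = "asymptotic"
    if n1 <= 12 and n2 <= 12 and comb(n1 + n2, n1) <= _ENUM_CAP:
        method = "enumeration"
        p = _enumeration_p(ranks, n1, W)
    elif n1 <= 12 and n2 <= 12 and not has_ties:
        method = "exact"
        p = float(sps.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue)
    else:
        p = float(
            sps.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic", use_continuity=True
            ).pvalue
        )
    return StatTestResult(
        name="W",
        statistic=W,
        p_value=min(1.0, p),
        n=(n1, n2),
        extra={"method": method, "U1": W - n1 * (n1 + 1) / 2.0, "ties": bool(has_ties)},
    )


def _enumeration_p(ranks: np.ndarray, n1: int, W: float) -> float:
    """Exact two-sided p for the rank sum by enumerating all C(N, n1)
    assignments of the (mid)ranks to the first group."""
    N = len(ranks)
    sums = np.fromiter(
        (sum(c) for c in itertools.combinations(ranks, n1)),
        dtype=float,
        count=comb(N, n1),
    )
    eps = 1e-9
    lower = np.mean(sums <= W + eps)
    upper = np.mean(sums >= W - eps)
    return float(min(1.0, 2.0 * min(lower, upper)))
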