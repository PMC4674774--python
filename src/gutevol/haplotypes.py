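"""Clone typing, clonal interference, and parallel-target statistics.

End-of-experiment clones are typed at a fixed panel of adaptive loci
(gat phenotype, IS insertions near focA/ycaO and dcuB/dcuR, srlR SNPs)
and assigned haplotype labels.  Clonal interference is called when two
haplotypes with non-nested mutation sets co-segregate — they cannot be
on the same genealogical path, so they are competing for fixation.

Population resequencing yields per-population variant frequencies; the
module applies the segregating-frequency cutoff, calls parallel targets
(hit in >= 2 populations, reaching >= 10% in at least one), tabulates
per-host prevalence with sampling uncertainty, and tests host
specificity of each target with an exact hypergeometric test.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats as sps

from .stats import StatTestResult

__all__ = [
    "LOCUS_PANEL",
    "ADAPTATION_TARGET_COUNTS",
    "CloneTyping",
    "HaplotypeCall",
    "VariantRecord",
    "TargetPrevalence",
    "call_haplotype",
    "haplotype_frequencies",
    "detect_clonal_interference",
    "filter_variants",
    "parallel_targets",
    "target_prevalence",
    "prevalence_table",
    "host_specificity_test",
]

#: canonical order of the typing panel (labels join in this order)
LOCUS_PANEL = ("gat", "focA/ycaO", "dcuB/dcuR", "srlR")

#: Parallel mutational targets from whole-population resequencing of the
#: mouse cohorts (14 WT and 15 Rag2-/- populations): per-target counts of
#: populations carrying the mutation at segregating frequency, keyed
#: target -> (hits_wt, hits_rag2).  Reconstructed from the published
#: per-host prevalence percentages.
N_POPULATIONS = {"WT": 14, "RAG2KO": 15}
ADAPTATION_TARGET_COUNTS = {
    "gat operon": (14, 15),
    "srlR": (7, 9),
    "focA/ycaO": (4, 6),
    "yjjP/yjjQ": (8, 2),
    "kdgR": (2, 2),
    "dcuB/dcuR": (7, 0),
    "yeaR": (2, 0),
    "arcB": (0, 2),
    "frlR": (0, 2),
    "rimJ": (0, 2),
}


@dataclass
class CloneTyping:
    """Per-locus typing state for one clone: present | absent | untyped."""

    mouse_id: str
    clone_id: str
    states: dict  # locus -> state

    def __post_init__(self) -> None:
        bad = {v for v in self.states.values()} - {"present", "absent", "untyped"}
        if bad:
            raise ValueError(f"invalid typing states: {sorted(bad)}")
        if all(v == "untyped" for v in self.states.values()) or not self.states:
            raise ValueError(f"clone {self.clone_id}: no typed locus")


@dataclass(frozen=True)
class HaplotypeCall:
    loci: frozenset
    label: str
    untyped: tuple


def _label(loci: Iterable[str]) -> str:
    loci = set(loci)
    ordered = [l for l in LOCUS_PANEL if l in loci]
    ordered += sorted(loci - set(LOCUS_PANEL))
    return "+".join(ordered) if ordered else "ancestral"


def call_haplotype(t: CloneTyping) -> HaplotypeCall:
    """Haplotype of a typed clone: the set of loci scored present.

    Untyped loci are excluded from the set and flagged in ``untyped``;
    the label joins present loci in the fixed panel order ("ancestral"
    when empty), so it is deterministic given the set.
    """
    present = frozenset(l for l, s in t.states.items() if s == "present")
    untyped = tuple(sorted(l for l, s in t.states.items() if s == "untyped"))
    return HaplotypeCall(loci=present, label=_label(present), untyped=untyped)


def haplotype_frequencies(typings: Sequence[CloneTyping]) -> dict:
    """Haplotype frequency spectrum of one population's typed clones,
    keyed by the frozenset of mutated loci."""
    if not typings:
        raise ValueError("no clones")
    counts: dict = {}
    for t in typings:
        call = call_haplotype(t)
        counts[call.loci] = counts.get(call.loci, 0) + 1
    n = sum(counts.values())
    return {k: v / n for k, v in counts.items()}


def detect_clonal_interference(
    frequencies: Mapping, threshold: float = 0.10
) -> tuple:
    """Flag clonal interference in one population.

    ``frequencies`` maps haplotypes (frozensets of mutated loci, or
    "+"-joined labels) to frequencies summing to 1 (+- 0.01).  Returns
    ``(flag, competing_pairs)``: interference is called when at least
    two haplotypes with non-nested mutation sets (neither a subset of
    the other — so neither can be the other's ancestor) each reach
    ``threshold``.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    freqs = {}
    for k, v in frequencies.items():
        if isinstance(k, str):
            key = frozenset() if k == "ancestral" else frozenset(k.split("+"))
        else:
            key = frozenset(k)
        if v < 0:
            raise ValueError("negative haplotype frequency")
        freqs[key] = freqs.get(key, 0.0) + float(v)
    total = sum(freqs.values())
    if abs(total - 1.0) > 0.01:
        raise ValueError(f"haplotype frequencies sum to {total:.4f}, not 1 +- 0.01")
    candidates = sorted((k for k, v in freqs.items() if v >= threshold), key=_label)
    pairs = [
        (_label(a), _label(b))
        for a, b in combinations(candidates, 2)
        if not (a <= b or b <= a)
    ]
    return (len(pairs) > 0, pairs)


@dataclass(frozen=True)
class VariantRecord:
    """One mutation segregating in one evolved population."""

    population: str
    host: str
    target: str
    mutation_class: str  # SNP | IS insertion | deletion | nonsense
    frequency: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError(f"frequency must be in [0, 1], got {self.frequency}")


def filter_variants(records: Iterable[VariantRecord], min_freq: float = 0.05) -> list:
    """Keep variants with frequency >= ``min_freq`` (inclusive boundary)."""
    if not 0 < min_freq < 1:
        raise ValueError("min_freq must be in (0, 1)")
    return [r for r in records if r.frequency >= min_freq]


def parallel_targets(
    records: Iterable[VariantRecord],
    min_populations: int = 2,
    peak_freq: float = 0.10,
) -> list:
    """Targets mutated in >= ``min_populations`` populations (pooled over
    host genotypes) and reaching >= ``peak_freq`` in at least one."""
    by_target: dict = {}
    for r in records:
        pops, peak = by_target.get(r.target, (set(), 0.0))
        pops.add(r.population)
        by_target[r.target] = (pops, max(peak, r.frequency))
    return sorted(
        t
        for t, (pops, peak) in by_target.items()
        if len(pops) >= min_populations and peak >= peak_freq
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class TargetPrevalence:
    target: str
    hits: dict          # host group -> k
    totals: dict        # host group -> n
    percent: dict       # host group -> rounded percent
    sem_percent: dict   # host group -> rounded sem (percent points)
    specificity: StatTestResult | None


def target_prevalence(
    target: str,
    hits: Mapping[str, int],
    totals: Mapping[str, int],
    uncertainty: str = "binomial",
) -> TargetPrevalence:
    """Per-host-group prevalence of a parallel target, with sampling sem.

    percent = 100k/n; sem(percent) = 100*sqrt(p(1-p)/n) for 0 < k < n,
    degenerating to 100/n at the boundaries (the binomial formula gives
    an implausible 0 there).  ``uncertainty="wilson"`` reports half the
    95% Wilson interval width instead.  With exactly two host groups the
    exact hypergeometric host-specificity test is attached.
    """
    percent: dict = {}
    sem: dict = {}
    for g, n in totals.items():
        if n <= 0:
            raise ValueError(f"group {g}: n must be > 0")
        k = hits[g]
        if not 0 <= k <= n:
            raise ValueError(f"group {g}: need 0 <= k <= n")
        p = k / n
        percent[g] = _round_half_up(100.0 * p)
        if uncertainty == "wilson":
            lo, hi = sps.binomtest(k, n).proportion_ci(method="wilson")
            sem[g] = _round_half_up(100.0 * (hi - lo) / 2.0)
        elif uncertainty == "binomial":
            raw = math.sqrt(p * (1.0 - p) / n) if 0 < k < n else 1.0 / n
            sem[g] = _round_half_up(100.0 * raw)
        else:
            raise ValueError(f"unknown uncertainty rule {uncertainty!r}")
    spec = None
    if len(totals) == 2:
        (g1, n1), (g2, n2) = totals.items()
        spec = host_specificity_test(hits[g1], n1, hits[g2], n2)
    return TargetPrevalence(
        target=target,
        hits=dict(hits),
        totals=dict(totals),
        percent=percent,
        sem_percent=sem,
        specificity=spec,
    )


def prevalence_table(
    counts: Mapping[str, tuple] | None = None,
    totals: Mapping[str, int] | None = None,
    uncertainty: str = "binomial",
) -> pd.DataFrame:
    """Prevalence table over targets (defaults to the published cohort counts)."""
    if counts is None:
        counts = ADAPTATION_TARGET_COUNTS
        totals = N_POPULATIONS
    if totals is None:
        raise ValueError("totals required with custom counts")
    groups = list(totals.keys())
    rows = []
    for target, ks in counts.items():
        hits = dict(zip(groups, ks))
        tp = target_prevalence(target, hits, totals, uncertainty=uncertainty)
        row = {"target": target}
        for g in groups:
            row[f"percent_{g}"] = tp.percent[g]
            row[f"sem_{g}"] = tp.sem_percent[g]
            row[f"hits_{g}"] = hits[g]
        if tp.specificity is not None:
            row["p_one_sided"] = tp.specificity.extra["p_one_sided"]
            row["p_two_sided"] = tp.specificity.p_value
        rows.append(row)
    return pd.DataFrame(rows)


def host_specificity_test(k1: int, n1: int, k2: int, n2: int) -> StatTestResult:
    """Exact hypergeometric test of hit concentration in group 1.

    Conditioning on the total number of hit populations K = k1 + k2,
    under the null every arrangement of the K hits among the n1 + n2
    populations is equally likely; the one-sided p is the probability of
    at least k1 hits in group 1.  The reported two-sided p doubles the
    smaller tail (capped at 1); both are returned.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if not 0 <= k <= n:
            raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    K = k1 + k2
    N = n1 + n2
    upper = float(sps.hypergeom.sf(k1 - 1, N, K, n1))  # P(X >= k1)
    lower = float(sps.hypergeom.cdf(k1, N, K, n1))
    two = min(1.0, 2.0 * min(upper, lower))
    return StatTestResult(
        name="hypergeometric",
        statistic=float(k1),
        p_value=two,
        n=(n1, n2),
        extra={"p_one_sided": upper, "K": K},
    )
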