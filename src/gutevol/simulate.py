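"""Haplotype-class Wright-Fisher simulator of *E. coli* colonizing individual hosts.

The simulator tracks classes of cells defined by (fluorescent marker,
set of beneficial mutations, set of resistance mutations) rather than
individual cells: gut populations of 1e7-1e10 cells preclude per-cell
simulation, and class-based multinomial resampling has the exact same
marginal law as individual-based Wright-Fisher sampling.

Each generation applies, in order:

1. deterministic selection  x_i <- x_i * w_i / sum_j x_j w_j, with
   Malthusian class fitness w_i = exp(sum of per-generation effects);
2. mutation flux, Poisson with expectation N * x_i * mu per (class,
   target) pair (deterministic flux x_i * mu in deterministic mode);
3. multinomial resampling of N cells (skipped in deterministic mode).

Per-hour selection coefficients are converted to per-generation effects
via s_gen = s_per_hour * gen_time_min / 60.  With the exponential
fitness parameterization a single-mutant deterministic sweep follows the
haploid logistic closed form p0*e^{s t} / (1 - p0 + p0*e^{s t}) exactly,
and the slope of ln(mutant/ancestor) against time equals s by
construction -- matching how the competition assays define s.

Host-to-host variation in selective effects (antagonistic pleiotropy)
is modeled as a single Gaussian draw of s per host per beneficial locus,
held constant within the host.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BeneficialLocusSpec",
    "ResistanceLocusSpec",
    "SimConfig",
    "HaplotypeClass",
    "PlateCount",
    "HostRun",
    "SimOutput",
    "gens_per_day",
    "msb_equilibrium",
    "run_simulation",
    "sample_plate",
    "simulate_competition_cohort",
    "simulate_resistance_cohort",
    "simulate_calibration_table",
    "simulate_hybridization_table",
    "simulate_growth_curve",
]

MARKERS = ("YFP", "CFP")
POINT = "point"
IS = "IS"

#: class key: (marker, frozenset of beneficial locus names,
#:             frozenset of (antibiotic, channel) pairs)
ClassKey = tuple


def gens_per_day(gen_time_min: float) -> float:
    """Generations per day for a given generation time in minutes."""
    if not gen_time_min > 0:
        raise ValueError(f"gen_time_min must be > 0, got {gen_time_min}")
    return 1440.0 / gen_time_min


def msb_equilibrium(mu_r: float, s_d: float) -> float:
    """Deterministic mutation-selection balance frequency mu_r / s_d.

    The equilibrium frequency of a deleterious allele maintained by
    recurrent mutation at rate ``mu_r`` against selective cost ``s_d``
    (both per generation).
    """
    if not s_d > 0:
        raise ValueError(f"s_d must be > 0, got {s_d}")
    if mu_r < 0:
        raise ValueError(f"mu_r must be >= 0, got {mu_r}")
    return mu_r / s_d


@dataclass(frozen=True)
class BeneficialLocusSpec:
    """A target of beneficial mutation.

    ``s_mean_per_hour``/``s_sd_per_hour`` describe the across-host
    distribution of the selective advantage; a large sd relative to the
    mean permits draws <= 0 (antagonistic pleiotropy). ``p0`` optionally
    seeds the mutant class at a starting frequency (used for competition
    assays against a pre-existing mutant).
    """

    name: str
    mu_b: float = 0.0
    s_mean_per_hour: float = 0.0
    s_sd_per_hour: float = 0.0
    p0: float = 0.0
    mutation_class: str = "SNP"

    def __post_init__(self) -> None:
        if self.mu_b < 0:
            raise ValueError(f"mu_b must be >= 0, got {self.mu_b}")
        if self.s_sd_per_hour < 0:
            raise ValueError(f"s_sd_per_hour must be >= 0, got {self.s_sd_per_hour}")
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError(f"p0 must be in [0, 1], got {self.p0}")


@dataclass(frozen=True)
class ResistanceLocusSpec:
    """A deleterious resistance target kept at mutation-selection balance.

    ``is_fraction`` is the fraction of resistance events arising through
    insertion-sequence transposition (the remainder are point mutations);
    the two channels are tracked separately so typed clones can be split
    into IS vs point classes downstream.
    """

    name: str
    mu_r: float
    s_d: float
    is_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.mu_r < 0:
            raise ValueError(f"mu_r must be >= 0, got {self.mu_r}")
        if not self.s_d > 0:
            raise ValueError(f"s_d must be > 0, got {self.s_d}")
        if not 0.0 <= self.is_fraction <= 1.0:
            raise ValueError(f"is_fraction must be in [0, 1], got {self.is_fraction}")


@dataclass(frozen=True)
class SimConfig:
    n_hosts: int = 1
    host_genotype: str = "WT"  # WT | RAG2KO | GF_WT | GF_RAG2KO
    pop_size: int = 10**8
    gen_time_min: float = 72.0
    days: int = 3
    samples_per_day: int = 1
    plate_depth: int = 200
    resistance_plate_depth: int = 10**7
    beneficial_loci: tuple = ()
    resistance_loci: tuple = ()
    initial_marker_ratio: float = 0.5
    mutant_marker: str | None = None
    mode: str = "stochastic"
    seed: int = 0
    max_classes: int = 20000
    mouse_prefix: str = "m"

    def __post_init__(self) -> None:
        if self.pop_size < 1:
            raise ValueError(f"pop_size must be >= 1, got {self.pop_size}")
        if not self.gen_time_min > 0:
            raise ValueError(f"gen_time_min must be > 0, got {self.gen_time_min}")
        if not 0.0 <= self.initial_marker_ratio <= 1.0:
            raise ValueError("initial_marker_ratio must be in [0, 1]")
        if self.plate_depth < 1:
            raise ValueError(f"plate_depth must be >= 1, got {self.plate_depth}")
        if self.mode not in ("stochastic", "deterministic"):
            raise ValueError(f"mode must be 'stochastic' or 'deterministic', got {self.mode!r}")
        if self.mutant_marker is not None and self.mutant_marker not in MARKERS:
            raise ValueError(f"mutant_marker must be one of {MARKERS}")

    def replace(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class HaplotypeClass:
    """One class of cells sharing marker and mutation content."""

    marker: str
    beneficial_set: frozenset
    resistance_set: frozenset
    count: float

    @property
    def key(self) -> ClassKey:
        return (self.marker, self.beneficial_set, self.resistance_set)


@dataclass
class PlateCount:
    """One day x mouse plating observation.

    ``marker_counts`` and ``locus_counts`` come from a single multinomial
    draw of ``depth`` colonies; resistant colonies are drawn on a
    simulated selective plate with the much larger ``resistant_depth``
    (rare classes are invisible at a few hundred colonies).
    """

    mouse_id: str
    host: str
    day: float
    depth: int
    marker_counts: dict
    locus_counts: dict
    gat_neg: int
    resistant_counts: dict
    resistant_depth: int


@dataclass
class HostRun:
    mouse_id: str
    host: str
    realized_s_per_hour: dict
    sample_days: list
    sample_gens: list
    class_freqs: list  # list of {ClassKey: frequency}, one per sample time
    plates: list


@dataclass
class SimOutput:
    config: SimConfig
    hosts: list

    # ---- serialization (deterministic ordering, used for the seed contract)
    def to_json(self) -> str:
        def _key(k: ClassKey) -> str:
            marker, ben, res = k
            ben_s = "+".join(sorted(ben)) or "-"
            res_s = "+".join(f"{a}:{c}" for a, c in sorted(res)) or "-"
            return f"{marker}|{ben_s}|{res_s}"

        payload = {
            "host_genotype": self.config.host_genotype,
            "seed": self.config.seed,
            "hosts": [
                {
                    "mouse_id": h.mouse_id,
                    "realized_s_per_hour": dict(sorted(h.realized_s_per_hour.items())),
                    "sample_days": h.sample_days,
                    "sample_gens": h.sample_gens,
                    "class_freqs": [
                        {_key(k): v for k, v in sorted(f.items(), key=lambda kv: _key(kv[0]))}
                        for f in h.class_freqs
                    ],
                    "plates": [
                        {
                            "day": p.day,
                            "depth": p.depth,
                            "marker_counts": dict(sorted(p.marker_counts.items())),
                            "locus_counts": dict(sorted(p.locus_counts.items())),
                            "resistant_counts": dict(sorted(p.resistant_counts.items())),
                        }
                        for p in h.plates
                    ],
                }
                for h in self.hosts
            ],
        }
        return json.dumps(payload, sort_keys=True)

    # ---- tidy exports ------------------------------------------------
    def to_plate_table(self) -> pd.DataFrame:
        """Tidy plate-count table: mouse_id, host, day, category, count, depth."""
        rows = []
        for h in self.hosts:
            for p in h.plates:
                for m, c in sorted(p.marker_counts.items()):
                    rows.append((h.mouse_id, h.host, p.day, f"marker:{m}", c, p.depth))
                for loc, c in sorted(p.locus_counts.items()):
                    rows.append((h.mouse_id, h.host, p.day, f"locus:{loc}", c, p.depth))
                for ab, c in sorted(p.resistant_counts.items()):
                    rows.append(
                        (h.mouse_id, h.host, p.day, f"resistant:{ab}", c, p.resistant_depth)
                    )
        return pd.DataFrame(
            rows, columns=["mouse_id", "host", "day", "category", "count", "depth"]
        )

    def to_marker_table(self) -> pd.DataFrame:
        """Wide marker table: mouse_id, host, day, yfp, cfp."""
        rows = []
        for h in self.hosts:
            for p in h.plates:
                rows.append(
                    (
                        h.mouse_id,
                        h.host,
                        p.day,
                        p.marker_counts.get("YFP", 0),
                        p.marker_counts.get("CFP", 0),
                    )
                )
        return pd.DataFrame(rows, columns=["mouse_id", "host", "day", "yfp", "cfp"])

    def to_competition_table(self, locus: str, housing: str = "independent") -> pd.DataFrame:
        """Competition table: mutant = colonies carrying ``locus``."""
        rows = []
        for h in self.hosts:
            for p in h.plates:
                mut = p.locus_counts.get(locus, 0)
                rows.append(
                    (h.mouse_id, h.host, housing, 24.0 * p.day, mut, p.depth - mut)
                )
        return pd.DataFrame(
            rows, columns=["mouse_id", "host", "housing", "time_h", "mutant", "reference"]
        )

    def to_phenotype_table(self) -> pd.DataFrame:
        """gat-phenotype table: white (galactitol-negative) colonies, i.e.
        colonies carrying a mutation at any locus whose name contains
        'gat', out of the plated total."""
        rows = []
        for h in self.hosts:
            for p in h.plates:
                rows.append((h.mouse_id, h.host, p.day, p.gat_neg, p.depth))
        return pd.DataFrame(rows, columns=["mouse_id", "host", "day", "gat_neg", "total"])

    def to_resistance_table(self) -> pd.DataFrame:
        rows = []
        for h in self.hosts:
            for p in h.plates:
                for ab, c in sorted(p.resistant_counts.items()):
                    rows.append(
                        (h.mouse_id, h.host, p.day, ab, c, p.resistant_depth, 1.0, 1.0)
                    )
        return pd.DataFrame(
            rows,
            columns=[
                "mouse_id",
                "host",
                "day",
                "antibiotic",
                "resistant",
                "total",
                "dilution_r",
                "dilution_t",
            ],
        )

    def to_trajectory_table(self) -> pd.DataFrame:
        """True (unsampled) per-locus frequencies at every sample time."""
        rows = []
        loci = [b.name for b in self.config.beneficial_loci]
        abs_ = [r.name for r in self.config.resistance_loci]
        for h in self.hosts:
            for day, freqs in zip(h.sample_days, h.class_freqs):
                yfp = sum(v for k, v in freqs.items() if k[0] == "YFP")
                rows.append((h.mouse_id, h.host, day, "marker:YFP", yfp))
                for loc in loci:
                    f = sum(v for k, v in freqs.items() if loc in k[1])
                    rows.append((h.mouse_id, h.host, day, f"locus:{loc}", f))
                for ab in abs_:
                    f = sum(
                        v for k, v in freqs.items() if any(a == ab for a, _ in k[2])
                    )
                    rows.append((h.mouse_id, h.host, day, f"resistant:{ab}", f))
        return pd.DataFrame(rows, columns=["mouse_id", "host", "day", "category", "frequency"])


class ClassTableOverflow(RuntimeError):
    """Raised when the number of haplotype classes exceeds the configured cap."""


# ----------------------------------------------------------------------
# core engine


def _class_fitness(key: ClassKey, s_gen: Mapping[str, float], cost_gen: Mapping[str, float]) -> float:
    _, ben, res = key
    log_w = sum(s_gen[b] for b in ben) - sum(cost_gen[a] for a, _ in res)
    return math.exp(log_w)


def _initial_state(config: SimConfig) -> dict:
    """Initial class frequencies.

    Seeded beneficial classes (p0 > 0) carry ``mutant_marker`` when set,
    with ancestral cells on the opposite marker (a competition layout:
    the overall marker ratio is then implied by the seeded fraction).
    Otherwise every class is split across markers by
    ``initial_marker_ratio``.
    """
    seeded = [(b.name, b.p0) for b in config.beneficial_loci if b.p0 > 0]
    p_seeded = sum(p for _, p in seeded)
    if p_seeded > 1.0 + 1e-12:
        raise ValueError("sum of beneficial p0 exceeds 1")
    state: dict = {}
    empty = frozenset()
    if config.mutant_marker is not None and seeded:
        anc_marker = "CFP" if config.mutant_marker == "YFP" else "YFP"
        for name, p in seeded:
            state[(config.mutant_marker, frozenset([name]), empty)] = p
        state[(anc_marker, empty, empty)] = 1.0 - p_seeded
    else:
        ratio = config.initial_marker_ratio
        for marker, w in (("YFP", ratio), ("CFP", 1.0 - ratio)):
            if w <= 0:
                continue
            for name, p in seeded:
                state[(marker, frozenset([name]), empty)] = w * p
            if 1.0 - p_seeded > 0:
                state[(marker, empty, empty)] = w * (1.0 - p_seeded)
    return state


def _mutation_step(
    state: dict,
    config: SimConfig,
    rng: np.random.Generator | None,
) -> dict:
    """Apply one generation of mutation flux; returns a new frequency dict."""
    N = config.pop_size
    stochastic = rng is not None
    new = dict(state)
    for key, x in state.items():
        if x <= 0:
            continue
        marker, ben, res = key
        moved = 0.0
        for b in config.beneficial_loci:
            if b.mu_b <= 0 or b.name in ben:
                continue
            if stochastic:
                flux = rng.poisson(N * x * b.mu_b) / N
            else:
                flux = x * b.mu_b
            flux = min(flux, x - moved)
            if flux <= 0:
                continue
            tgt = (marker, ben | {b.name}, res)
            new[tgt] = new.get(tgt, 0.0) + flux
            moved += flux
        res_names = {a for a, _ in res}
        for r in config.resistance_loci:
            if r.mu_r <= 0 or r.name in res_names:
                continue
            for channel, mu in (
                (POINT, r.mu_r * (1.0 - r.is_fraction)),
                (IS, r.mu_r * r.is_fraction),
            ):
                if mu <= 0:
                    continue
                if stochastic:
                    flux = rng.poisson(N * x * mu) / N
                else:
                    flux = x * mu
                flux = min(flux, x - moved)
                if flux <= 0:
                    continue
                tgt = (marker, ben, res | {(r.name, channel)})
                new[tgt] = new.get(tgt, 0.0) + flux
                moved += flux
        if moved > 0:
            new[key] = new[key] - moved
    return {k: v for k, v in new.items() if v > 0}


def sample_plate(
    state: Mapping[ClassKey, float],
    depth: int,
    rng: np.random.Generator | int | None = None,
    *,
    resistance_plate_depth: int = 10**7,
    antibiotics: Sequence[str] = (),
    mouse_id: str = "m0",
    host: str = "WT",
    day: float = 0.0,
) -> PlateCount:
    """Multinomial draw of ``depth`` colonies over haplotype classes.

    Marker and per-locus colony counts come from one multinomial draw, so
    categories are consistent within a plate.  Resistant colonies are
    drawn independently at ``resistance_plate_depth`` cells equivalent
    (a selective plate; rare resistant classes would be invisible at
    200-colony depth).
    """
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    keys = sorted(state.keys(), key=repr)
    total = float(sum(state[k] for k in keys))
    if not keys or total <= 0:
        raise ValueError("empty population: cannot sample a plate")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    probs = np.array([state[k] / total for k in keys])
    probs = probs / probs.sum()
    draw = rng.multinomial(depth, probs)
    marker_counts = {m: 0 for m in MARKERS}
    locus_counts: dict = {}
    gat_neg = 0
    for k, c in zip(keys, draw):
        marker, ben, _res = k
        marker_counts[marker] = marker_counts.get(marker, 0) + int(c)
        for loc in ben:
            locus_counts[loc] = locus_counts.get(loc, 0) + int(c)
        if any("gat" in l.lower() for l in ben):
            gat_neg += int(c)
    resistant_counts = {}
    for ab in antibiotics:
        p_res = sum(v / total for k, v in state.items() if any(a == ab for a, _ in k[2]))
        resistant_counts[ab] = int(rng.binomial(int(resistance_plate_depth), min(p_res, 1.0)))
    return PlateCount(
        mouse_id=mouse_id,
        host=host,
        day=day,
        depth=depth,
        marker_counts=marker_counts,
        locus_counts=locus_counts,
        gat_neg=gat_neg,
        resistant_counts=resistant_counts,
        resistant_depth=int(resistance_plate_depth),
    )


def _run_host(config: SimConfig, idx: int) -> HostRun:
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(idx,))
    rng = np.random.default_rng(ss)
    stochastic = config.mode == "stochastic"

    # one s draw per beneficial locus, constant within the host
    realized = {}
    for b in config.beneficial_loci:
        realized[b.name] = float(rng.normal(b.s_mean_per_hour, b.s_sd_per_hour))
    s_gen = {n: s * config.gen_time_min / 60.0 for n, s in realized.items()}
    cost_gen = {r.name: r.s_d for r in config.resistance_loci}

    gpd = gens_per_day(config.gen_time_min)
    total_gens = int(round(config.days * gpd))
    sample_days = [0.0]
    for d in range(config.days):
        for j in range(1, config.samples_per_day + 1):
            sample_days.append(d + j / config.samples_per_day)
    sample_gens = [int(round(t * gpd)) for t in sample_days]
    # dedupe (rounding collisions at samples_per_day > gpd), keep order
    seen: dict = {}
    for t, g in zip(sample_days, sample_gens):
        if g not in seen:
            seen[g] = t
    sample_gens = sorted(seen.keys())
    sample_days = [seen[g] for g in sample_gens]
    sample_set = set(sample_gens)

    antibiotics = [r.name for r in config.resistance_loci]
    mouse_id = f"{config.mouse_prefix}{idx + 1}"

    state = _initial_state(config)
    freq_log: list = []
    plates: list = []

    def _record(gen: int, day: float) -> None:
        freq_log.append(dict(state))
        plates.append(
            sample_plate(
                state,
                config.plate_depth,
                rng,
                resistance_plate_depth=config.resistance_plate_depth,
                antibiotics=antibiotics,
                mouse_id=mouse_id,
                host=config.host_genotype,
                day=day,
            )
        )

    if 0 in sample_set:
        _record(0, 0.0)

    w_cache = {k: _class_fitness(k, s_gen, cost_gen) for k in state}
    for gen in range(1, total_gens + 1):
        # selection
        for k in list(state.keys()):
            if k not in w_cache:
                w_cache[k] = _class_fitness(k, s_gen, cost_gen)
            state[k] = state[k] * w_cache[k]
        tot = sum(state.values())
        state = {k: v / tot for k, v in state.items()}
        # mutation
        state = _mutation_step(state, config, rng if stochastic else None)
        if len(state) > config.max_classes:
            raise ClassTableOverflow(
                f"class table grew to {len(state)} (> max_classes={config.max_classes})"
            )
        # resampling
        if stochastic:
            keys = sorted(state.keys(), key=repr)
            probs = np.array([state[k] for k in keys])
            probs = probs / probs.sum()
            draw = rng.multinomial(config.pop_size, probs)
            state = {
                k: c / config.pop_size for k, c in zip(keys, draw) if c > 0
            }
        else:
            tot = sum(state.values())
            state = {k: v / tot for k, v in state.items()}
        if gen in sample_set:
            day = sample_days[sample_gens.index(gen)]
            _record(gen, day)

    return HostRun(
        mouse_id=mouse_id,
        host=config.host_genotype,
        realized_s_per_hour=realized,
        sample_days=sample_days[: len(freq_log)],
        sample_gens=sample_gens[: len(freq_log)],
        class_freqs=freq_log,
        plates=plates,
    )


def run_simulation(config: SimConfig) -> SimOutput:
    """Run the class-based Wright-Fisher simulation for every host.

    Fully reproducible from ``config.seed``: each host uses an
    independent substream spawned from the root seed, so results do not
    depend on host execution order.
    """
    hosts = [_run_host(config, i) for i in range(config.n_hosts)]
    return SimOutput(config=config, hosts=hosts)


# ----------------------------------------------------------------------
# cohort-level generators (the synthetic counterparts of each assay)


def simulate_competition_cohort(
    preset: str | SimConfig = "wt-competition",
    n_hosts: int = 10,
    depth: int = 600,
    days: int = 3,
    seed: int = 0,
    housing: str = "independent",
) -> pd.DataFrame:
    """Simulate a 1:1 competition assay cohort; returns the competition table.

    One host = one mouse gavaged with a 1:1 mutant:ancestor mix; plates
    of ``depth`` colonies are scored at 0/24/.../24*days h.
    """
    from .presets import get_preset

    cfg = get_preset(preset) if isinstance(preset, str) else preset
    cfg = cfg.replace(n_hosts=n_hosts, plate_depth=depth, days=days, seed=seed)
    out = run_simulation(cfg)
    locus = next(b.name for b in cfg.beneficial_loci if b.p0 > 0)
    return out.to_competition_table(locus, housing=housing)


def simulate_resistance_cohort(
    preset: str | SimConfig = "fzd-wt",
    n_mice: int = 6,
    days: int = 15,
    burn_in_days: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate daily resistant/total plating over ``days`` days at balance.

    The population is run for ``burn_in_days`` extra days first so the
    resistant classes reach mutation-selection equilibrium before the
    sampled window; burn-in days are dropped from the output.
    """
    from .presets import get_preset

    cfg = get_preset(preset) if isinstance(preset, str) else preset
    cfg = cfg.replace(n_hosts=n_mice, days=days + burn_in_days, seed=seed)
    out = run_simulation(cfg)
    df = out.to_resistance_table()
    df = df[df["day"] > burn_in_days].copy()
    df["day"] = df["day"] - burn_in_days
    return df.reset_index(drop=True)


def simulate_calibration_table(
    rng: np.random.Generator | int | None = None,
    *,
    slope: float = 0.001,
    intercept: float = 0.1,
    rates: Sequence[float] | None = None,
    rate_noise_sd: float = 0.01,
    fluor_noise_sd: float = 10.0,
    n_replicates: int = 2,
) -> pd.DataFrame:
    """Synthetic growth-rate vs hybridization-fluorescence calibration table.

    Emulates the in vitro arm of the division-rate assay: cultures in
    media supporting different growth rates, each hybridized in
    duplicate.  The true map is rate = intercept + slope * fluorescence;
    observed rates carry Gaussian noise (growth-curve fitting error) and
    each hybridization replicate carries fluorescence noise.
    Columns: sample, rate, replicate, fluorescence.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    if rates is None:
        rates = np.linspace(0.2, 0.9, 8)
    rows = []
    for i, r in enumerate(rates):
        f_true = (r - intercept) / slope
        r_obs = r + rng.normal(0.0, rate_noise_sd)
        for rep in range(1, n_replicates + 1):
            rows.append(
                (f"cond{i + 1}", r_obs, rep, f_true + rng.normal(0.0, fluor_noise_sd))
            )
    return pd.DataFrame(rows, columns=["sample", "rate", "replicate", "fluorescence"])


def simulate_hybridization_table(
    rate_per_hour: float,
    rng: np.random.Generator | int | None = None,
    *,
    slope: float = 0.001,
    intercept: float = 0.1,
    n_mice: int = 6,
    days: Sequence[int] = (1, 3),
    fluor_noise_sd: float = 10.0,
    n_replicates: int = 2,
    mouse_prefix: str = "m",
) -> pd.DataFrame:
    """Synthetic in vivo hybridization fluorescence for mice growing at a
    true rate ``rate_per_hour`` (columns: sample, replicate,
    median_fluorescence)."""
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    f_true = (rate_per_hour - intercept) / slope
    rows = []
    for m in range(1, n_mice + 1):
        for d in days:
            for rep in range(1, n_replicates + 1):
                rows.append(
                    (
                        f"{mouse_prefix}{m}_d{d}",
                        rep,
                        f_true + rng.normal(0.0, fluor_noise_sd),
                    )
                )
    return pd.DataFrame(rows, columns=["sample", "replicate", "median_fluorescence"])


def simulate_growth_curve(
    rate_per_hour: float,
    rng: np.random.Generator | int | None = None,
    *,
    od0: float = 0.02,
    carrying_od: float = 1.2,
    hours: float = 24.0,
    step_h: float = 0.5,
    noise_cv: float = 0.01,
    medium: str = "medium",
) -> pd.DataFrame:
    """Logistic OD curve with multiplicative noise (columns: medium, time_h, od)."""
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    t = np.arange(0.0, hours + step_h / 2, step_h)
    od = carrying_od * od0 * np.exp(rate_per_hour * t) / (
        carrying_od + od0 * (np.exp(rate_per_hour * t) - 1.0)
    )
    od = od * np.exp(rng.normal(0.0, noise_cv, size=t.shape))
    return pd.DataFrame({"medium": medium, "time_h": t, "od": od})
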