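"""Named study-condition presets.

The presets encode the experimental conditions of the mouse colonization
study as generative parameters:

``wt-competition`` / ``rag2-competition``
    1:1 in vivo competition of a single gat mutant against the ancestor.
    Mean advantages per hour are 0.068 (WT hosts) and 0.03 (Rag2-/-);
    generation times 76 and 66 min.  The across-host standard deviations
    (0.008 and 0.016 per hour) set the antagonistic-pleiotropy scale:
    the Rag2-/- value is wide enough for neutral or deleterious draws.

``wt-growth`` / ``rag2-growth``
    True in vivo growth rates implied by 76- and 66-min doubling times
    (rate = 60*ln2/doubling_min per hour), used to generate synthetic
    hybridization fluorescence.

``fzd-wt`` / ``fzd-rag2``
    Furazolidone-resistance locus at mutation-selection balance.  The
    equilibrium resistant fractions 10^-5.65 (WT) and 10^-5.49 (Rag2-/-)
    are decomposed as mu_r = f* x s_d with an assumed cost s_d = 0.1 per
    generation; the IS (transposition) channel fractions follow from the
    measured transposition frequencies (10^-5.99 WT, 10^-5.75 Rag2-/-).

``paper-replica``
    A WT + Rag2-/- pair of full evolution-cohort configurations (marker
    split, gat sweep, secondary adaptive targets with host-specific
    effects such as dcuB/dcuR beneficial only in WT, resistance locus)
    driving the end-to-end pipeline.
"""
from __future__ import annotations

import math

from .simulate import BeneficialLocusSpec, ResistanceLocusSpec, SimConfig

__all__ = ["PRESET_NAMES", "GROWTH_PRESETS", "get_preset", "replica_configs"]

LN2 = math.log(2.0)

#: true per-hour growth rates for the growth presets (doubling 76 / 66 min)
GROWTH_PRESETS = {
    "wt-growth": {"gen_time_min": 76.0, "rate_per_hour": 60.0 * LN2 / 76.0},
    "rag2-growth": {"gen_time_min": 66.0, "rate_per_hour": 60.0 * LN2 / 66.0},
}

# mutation-selection balance decompositions (cost 0.1 per generation)
_FZD_COST = 0.1
_FZD_WT_MU = 10**-5.65 * _FZD_COST          # 2.2387e-7
_FZD_RAG2_MU = 10**-5.49 * _FZD_COST        # 3.2359e-7
_FZD_WT_IS = 10 ** (-5.99 + 5.65)           # 0.457
_FZD_RAG2_IS = 10 ** (-5.75 + 5.49)         # 0.550


def _competition(genotype: str, gen_time: float, s_mean: float, s_sd: float) -> SimConfig:
    return SimConfig(
        n_hosts=10,
        host_genotype=genotype,
        pop_size=10**8,
        gen_time_min=gen_time,
        days=3,
        plate_depth=600,
        beneficial_loci=(
            BeneficialLocusSpec(
                name="gatZ",
                mu_b=0.0,
                s_mean_per_hour=s_mean,
                s_sd_per_hour=s_sd,
                p0=0.5,
                mutation_class="IS insertion",
            ),
        ),
        mutant_marker="YFP",
        mode="stochastic",
    )


def _fzd(genotype: str, gen_time: float, mu_r: float, is_fraction: float) -> SimConfig:
    return SimConfig(
        n_hosts=6,
        host_genotype=genotype,
        pop_size=10**8,
        gen_time_min=gen_time,
        days=15,
        plate_depth=200,
        resistance_plate_depth=10**7,
        resistance_loci=(
            ResistanceLocusSpec(name="FZD", mu_r=mu_r, s_d=_FZD_COST, is_fraction=is_fraction),
        ),
        mode="stochastic",
    )


_FACTORIES = {
    "wt-competition": lambda: _competition("WT", 76.0, 0.068, 0.008),
    "rag2-competition": lambda: _competition("RAG2KO", 66.0, 0.03, 0.016),
    "fzd-wt": lambda: _fzd("WT", 76.0, _FZD_WT_MU, _FZD_WT_IS),
    "fzd-rag2": lambda: _fzd("RAG2KO", 66.0, _FZD_RAG2_MU, _FZD_RAG2_IS),
}

PRESET_NAMES = (
    "wt-competition",
    "rag2-competition",
    "wt-growth",
    "rag2-growth",
    "fzd-wt",
    "fzd-rag2",
    "paper-replica",
)


def get_preset(name: str, **overrides) -> SimConfig:
    """Return the SimConfig for a named preset (growth presets have no
    SimConfig; use :data:`GROWTH_PRESETS`)."""
    if name in GROWTH_PRESETS:
        raise ValueError(
            f"{name!r} is a growth preset; use gutevol.presets.GROWTH_PRESETS"
        )
    if name == "paper-replica":
        raise ValueError("'paper-replica' is a cohort pair; use replica_configs()")
    try:
        cfg = _FACTORIES[name]()
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; known: {PRESET_NAMES}") from None
    return cfg.replace(**overrides) if overrides else cfg


def replica_configs(
    n_hosts: int = 5,
    days: int = 24,
    pop_size: int = 10**7,
    plate_depth: int = 200,
    seed: int = 0,
) -> dict:
    """WT and Rag2-/- evolution-cohort configurations for the pipeline.

    Per-locus mutation rates and secondary-target effects are not
    directly measured quantities; they are chosen so the gat phenotype
    sweeps within the first week in WT hosts (slower in Rag2-/-) and so
    secondary targets generate day-24 clonal interference, as observed.
    dcuB/dcuR is beneficial only in WT (mean 0 in Rag2-/-): the
    host-specific target.
    """

    def _loci(genotype: str):
        wt = genotype == "WT"
        return (
            BeneficialLocusSpec(
                name="gat",
                mu_b=1e-5,
                s_mean_per_hour=0.068 if wt else 0.03,
                s_sd_per_hour=0.008 if wt else 0.016,
                mutation_class="IS insertion",
            ),
            BeneficialLocusSpec(
                name="focA/ycaO",
                mu_b=2e-7,
                s_mean_per_hour=0.040 if wt else 0.035,
                s_sd_per_hour=0.010 if wt else 0.015,
                mutation_class="IS insertion",
            ),
            BeneficialLocusSpec(
                name="dcuB/dcuR",
                mu_b=2e-7,
                s_mean_per_hour=0.045 if wt else 0.0,
                s_sd_per_hour=0.010,
                mutation_class="IS insertion",
            ),
            BeneficialLocusSpec(
                name="srlR",
                mu_b=1e-7,
                s_mean_per_hour=0.040 if wt else 0.030,
                s_sd_per_hour=0.010 if wt else 0.015,
                mutation_class="SNP",
            ),
        )

    out = {}
    for genotype, gen_time, mu_fzd, is_frac, prefix, sub in (
        ("WT", 76.0, _FZD_WT_MU, _FZD_WT_IS, "w", 0),
        ("RAG2KO", 66.0, _FZD_RAG2_MU, _FZD_RAG2_IS, "r", 1),
    ):
        out[genotype] = SimConfig(
            n_hosts=n_hosts,
            host_genotype=genotype,
            pop_size=pop_size,
            gen_time_min=gen_time,
            days=days,
            plate_depth=plate_depth,
            resistance_plate_depth=10**7,
            beneficial_loci=_loci(genotype),
            resistance_loci=(
                ResistanceLocusSpec(name="FZD", mu_r=mu_fzd, s_d=_FZD_COST, is_fraction=is_frac),
            ),
            initial_marker_ratio=0.5,
            mode="stochastic",
            seed=seed * 2 + sub,
            mouse_prefix=prefix,
        )
    return out
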