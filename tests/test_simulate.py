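"""Wright-Fisher engine: conservation, closed forms, drift, balance, sampling."""
import math

import numpy as np
import pytest

from gutevol.simulate import (
    BeneficialLocusSpec,
    ClassTableOverflow,
    ResistanceLocusSpec,
    SimConfig,
    gens_per_day,
    msb_equilibrium,
    run_simulation,
    sample_plate,
)


@pytest.mark.parametrize(
    "gen_min,expected",
    [(72.0, 20.0), (76.0, 1440.0 / 76.0), (66.0, 1440.0 / 66.0)],
)
def test_gens_per_day(gen_min, expected):
    assert gens_per_day(gen_min) == pytest.approx(expected, rel=1e-15)


@pytest.mark.parametrize("bad", [0.0, -10.0])
def test_gens_per_day_rejects_nonpositive(bad):
    with pytest.raises(ValueError):
        gens_per_day(bad)


@pytest.mark.parametrize(
    "mu,s,expected",
    [(0.0, 0.1, 0.0), (1e-8, 0.05, 2e-7), (2.2387e-7, 0.1, 2.2387e-6)],
)
def test_msb_equilibrium(mu, s, expected):
    assert msb_equilibrium(mu, s) == pytest.approx(expected, rel=1e-15)


def test_msb_equilibrium_matches_printed_log10():
    assert math.log10(msb_equilibrium(2.2387e-7, 0.1)) == pytest.approx(-5.65, abs=1e-4)


def test_msb_equilibrium_rejects_nonpositive_cost():
    with pytest.raises(ValueError):
        msb_equilibrium(1e-8, 0.0)


def test_deterministic_neutral_marker_is_conserved_exactly():
    cfg = SimConfig(mode="deterministic", days=5, n_hosts=1, initial_marker_ratio=0.5)
    out = run_simulation(cfg)
    for freqs in out.hosts[0].class_freqs:
        yfp = sum(v for k, v in freqs.items() if k[0] == "YFP")
        assert yfp == 0.5  # exact: no mutation, equal fitness


@pytest.mark.parametrize("s_hour,p0,gen_min", [(0.05, 0.01, 72.0), (0.1, 0.001, 76.0), (-0.03, 0.6, 66.0)])
def test_deterministic_sweep_matches_logistic_closed_form(s_hour, p0, gen_min):
    locus = BeneficialLocusSpec(name="x", s_mean_per_hour=s_hour, p0=p0)
    cfg = SimConfig(
        mode="deterministic",
        days=6,
        gen_time_min=gen_min,
        beneficial_loci=(locus,),
        mutant_marker="YFP",
        n_hosts=1,
    )
    out = run_simulation(cfg)
    h = out.hosts[0]
    sigma = s_hour * gen_min / 60.0
    for t, freqs in zip(h.sample_gens, h.class_freqs):
        fx = sum(v for k, v in freqs.items() if "x" in k[1])
        pred = p0 * math.exp(sigma * t) / (1 - p0 + p0 * math.exp(sigma * t))
        assert fx == pytest.approx(pred, rel=1e-12)


def test_stochastic_neutral_drift_is_unbiased():
    # 200 replicate lines at pop 1e4: mean final marker frequency within
    # 3 Monte-Carlo standard errors of the 1:1 start
    cfg = SimConfig(mode="stochastic", days=3, n_hosts=200, pop_size=10**4, seed=99)
    out = run_simulation(cfg)
    finals = np.array(
        [sum(v for k, v in h.class_freqs[-1].items() if k[0] == "YFP") for h in out.hosts]
    )
    mc_se = finals.std(ddof=1) / math.sqrt(len(finals))
    assert abs(finals.mean() - 0.5) < 3 * mc_se + 1e-12


def test_stochastic_msb_matches_deterministic_equilibrium():
    # time-averaged resistant fraction after burn-in within 10% of mu/s_d
    locus = ResistanceLocusSpec(name="AB", mu_r=1e-6, s_d=0.1)
    cfg = SimConfig(
        mode="stochastic",
        days=30,
        n_hosts=6,
        pop_size=10**7,
        gen_time_min=72.0,
        resistance_loci=(locus,),
        seed=5,
    )
    out = run_simulation(cfg)
    vals = []
    for h in out.hosts:
        for day, freqs in zip(h.sample_days, h.class_freqs):
            if day <= 10:  # burn-in: ~20x the selective time scale 1/s_d
                continue
            vals.append(sum(v for k, v in freqs.items() if k[2]))
    mean = np.mean(vals)
    assert mean == pytest.approx(msb_equilibrium(1e-6, 0.1), rel=0.10)


def test_seed_determinism_byte_identical():
    locus = BeneficialLocusSpec(name="x", mu_b=1e-6, s_mean_per_hour=0.05, s_sd_per_hour=0.01)
    cfg = SimConfig(days=3, n_hosts=3, pop_size=10**5, beneficial_loci=(locus,), seed=7)
    a = run_simulation(cfg).to_json()
    b = run_simulation(cfg).to_json()
    assert a == b
    c = run_simulation(cfg.replace(seed=8)).to_json()
    assert a != c


def test_invalid_mode_rejected():
    with pytest.raises(ValueError, match="mode"):
        SimConfig(mode="hybrid")


def test_class_table_overflow_raises():
    loci = tuple(
        BeneficialLocusSpec(name=f"l{i}", mu_b=1e-2, s_mean_per_hour=0.01) for i in range(6)
    )
    cfg = SimConfig(
        mode="deterministic", days=3, n_hosts=1, beneficial_loci=loci, max_classes=10
    )
    with pytest.raises(ClassTableOverflow):
        run_simulation(cfg)


class TestSamplePlate:
    def test_absent_marker_never_sampled(self):
        state = {("CFP", frozenset(), frozenset()): 1.0}
        p = sample_plate(state, 200, rng=0)
        assert p.marker_counts["CFP"] == 200
        assert p.marker_counts.get("YFP", 0) == 0

    def test_binomial_mean_and_variance(self, rng):
        state = {
            ("YFP", frozenset(), frozenset()): 0.25,
            ("CFP", frozenset(), frozenset()): 0.75,
        }
        draws = np.array(
            [sample_plate(state, 200, rng=rng).marker_counts["YFP"] for _ in range(3000)]
        )
        assert draws.mean() == pytest.approx(50.0, abs=0.6)  # 4 x se of the mean
        assert draws.var(ddof=1) == pytest.approx(37.5, rel=0.15)

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sample_plate({}, 200, rng=0)
        with pytest.raises(ValueError, match="depth"):
            sample_plate({("YFP", frozenset(), frozenset()): 1.0}, 0, rng=0)

    def test_resistant_colonies_on_selective_plate(self, rng):
        res = frozenset([("FZD", "point")])
        state = {
            ("YFP", frozenset(), frozenset()): 1.0 - 1e-5,
            ("YFP", frozenset(), res): 1e-5,
        }
        p = sample_plate(
            state, 200, rng=rng, antibiotics=["FZD"], resistance_plate_depth=10**7
        )
        # expectation 100 on the selective plate; invisible at depth 200
        assert 50 < p.resistant_counts["FZD"] < 200


def test_competition_cohort_starts_at_one_to_one():
    from gutevol.simulate import simulate_competition_cohort

    df = simulate_competition_cohort("wt-competition", n_hosts=6, seed=3)
    day0 = df[df.time_h == 0]
    frac = day0.mutant / (day0.mutant + day0.reference)
    assert np.all(np.abs(frac - 0.5) < 0.09)  # ~4 binomial sd at depth 600
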