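"""Competition-assay selection coefficients and group/variance comparisons."""
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gutevol.fitness import (
    CompetitionSeries,
    cohort_selection_coefficients,
    estimate_selection_coefficient,
    group_anova,
    variance_ratio_test,
)
from gutevol.simulate import simulate_competition_cohort


def _series(times, mutant, reference):
    return CompetitionSeries(
        mouse_id="m1",
        host="WT",
        housing="independent",
        times_h=np.asarray(times, dtype=float),
        mutant=np.asarray(mutant, dtype=float),
        reference=np.asarray(reference, dtype=float),
    )


class TestSelectionCoefficient:
    def test_constant_ratio_gives_zero(self):
        r = estimate_selection_coefficient(
            _series([0, 24, 48, 72], [300] * 4, [300] * 4)
        )
        assert r.s_per_hour == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("s", [0.05, -0.02, 0.0861])
    @pytest.mark.parametrize("p0", [0.5, 0.2])
    def test_exact_on_noiseless_exponential(self, s, p0):
        t = np.array([0.0, 24.0, 48.0, 72.0])
        ref = np.full(4, 1000.0)
        mut = ref * (p0 / (1 - p0)) * np.exp(s * t)
        r = estimate_selection_coefficient(_series(t, mut, ref))
        assert r.s_per_hour == pytest.approx(s, abs=1e-12)
        assert r.intercept == pytest.approx(math.log(p0 / (1 - p0)), abs=1e-10)

    def test_zero_counts_dropped_then_insufficient(self):
        with pytest.warns(UserWarning, match="zero count"):
            r = estimate_selection_coefficient(
                _series([0, 24, 48, 72], [300, 0, 300, 300], [300] * 4)
            )
        assert r.n_points == 3
        with pytest.raises(ValueError, match=">= 3"):
            with pytest.warns(UserWarning):
                estimate_selection_coefficient(
                    _series([0, 24, 48, 72], [300, 0, 0, 300], [300] * 4)
                )

    def test_cohort_mean_recovers_preset(self):
        # small-scale recovery; the full 20-cohort check lives in acceptance
        vals = []
        for c in range(5):
            df = simulate_competition_cohort("wt-competition", seed=300 + c)
            vals.extend(cohort_selection_coefficients(df).s_per_hour)
        assert np.mean(vals) == pytest.approx(0.068, abs=0.01)


class TestVarianceRatio:
    def test_identical_lists(self):
        res = variance_ratio_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_f22(self):
        # F(2,2) cdf is x/(1+x): tail at F=0.25 is 0.2, doubled 0.4
        res = variance_ratio_test([1, 2, 3], [2, 4, 6])
        assert res.statistic == pytest.approx(0.25, rel=1e-12)
        assert res.p_value == pytest.approx(0.4, rel=1e-10)
        rev = variance_ratio_test([2, 4, 6], [1, 2, 3])
        assert rev.statistic == pytest.approx(4.0, rel=1e-12)
        assert rev.p_value == pytest.approx(0.4, rel=1e-10)

    def test_zero_denominator_variance(self):
        with pytest.raises(ValueError, match="variance"):
            variance_ratio_test([1, 2, 3], [5, 5, 5])

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_distribution_oracle(self, seed):
        r = np.random.default_rng(seed)
        a = r.normal(size=int(r.integers(3, 10)))
        b = r.normal(size=int(r.integers(3, 10)))
        res = variance_ratio_test(a, b)
        f = a.var(ddof=1) / b.var(ddof=1)
        dist = sps.f(len(a) - 1, len(b) - 1)
        p = min(1.0, 2 * min(dist.cdf(f), dist.sf(f)))
        assert res.statistic == pytest.approx(f, rel=1e-12)
        assert res.p_value == pytest.approx(p, rel=1e-10)


class TestGroupAnova:
    def test_hand_computed_one_way(self):
        # SSB = 1.5, SSW = 4 -> F = 1.5 on (1, 4) df
        res = group_anova([1, 2, 3, 2, 3, 4], ["a"] * 3 + ["b"] * 3)
        assert res.f == pytest.approx(1.5, rel=1e-10)
        assert res.p_value == pytest.approx(sps.f.sf(1.5, 1, 4), rel=1e-10)
        assert res.tukey is not None and len(res.tukey) == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_one_way_matches_scipy_oracle(self, seed):
        r = np.random.default_rng(seed)
        sizes = r.integers(3, 8, size=3)
        groups = [r.normal(loc=i, size=n) for i, n in enumerate(sizes)]
        labels = np.concatenate([[f"g{i}"] * n for i, n in enumerate(sizes)])
        res = group_anova(np.concatenate(groups), labels, tukey=False)
        f, p = sps.f_oneway(*groups)
        assert res.f == pytest.approx(f, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-8)

    def test_zero_residual_variance_is_error(self):
        with pytest.raises(ValueError, match="residual"):
            group_anova([1, 1, 1, 2, 2, 2], ["a"] * 3 + ["b"] * 3)

    def test_two_way_additive_interaction_is_null(self):
        # 3x2 factorial, additive cell means, 2 exact replicates per cell
        rows = []
        for i, a in enumerate(["x", "y", "z"]):
            for j, b in enumerate(["u", "v"]):
                for _ in range(2):
                    rows.append((1.0 * i + 0.5 * j, a, b))
        y, f1, f2 = zip(*rows)
        res = group_anova(np.array(y), np.array(f1), np.array(f2))
        assert res.table.loc["interaction", "F"] == pytest.approx(0.0, abs=1e-8)
        assert res.table.loc["interaction", "PR(>F)"] == pytest.approx(1.0)

    def test_two_way_missing_cell_named(self):
        y = [1.0, 2.0, 3.0, 4.0, 1.5, 2.5]
        f1 = ["a", "a", "b", "b", "a", "b"]
        f2 = ["u", "u", "u", "u", "v", "u"]  # cell (b, v) empty
        with pytest.raises(ValueError, match=r"\('b', 'v'\)"):
            group_anova(y, f1, f2)


def test_pleiotropy_detection_power_ordering():
    """Cohorts generated with high across-host s variance are rejected by
    the F test against low-variance cohorts more often than null pairs."""
    from gutevol.presets import get_preset
    from gutevol.simulate import BeneficialLocusSpec

    def cohort(s_sd, seed):
        base = get_preset("wt-competition")
        locus = base.beneficial_loci[0]
        cfg = base.replace(
            beneficial_loci=(
                BeneficialLocusSpec(
                    name=locus.name,
                    s_mean_per_hour=locus.s_mean_per_hour,
                    s_sd_per_hour=s_sd,
                    p0=locus.p0,
                ),
            ),
            seed=seed,
        )
        df = simulate_competition_cohort(cfg, seed=seed)
        return cohort_selection_coefficients(df).s_per_hour.to_numpy()

    n_pairs = 20
    rej_alt = sum(
        variance_ratio_test(cohort(0.016, 2 * i), cohort(0.004, 2 * i + 1)).p_value < 0.05
        for i in range(n_pairs)
    )
    rej_null = sum(
        variance_ratio_test(
            cohort(0.004, 1000 + 2 * i), cohort(0.004, 1001 + 2 * i)
        ).p_value
        < 0.05
        for i in range(n_pairs)
    )
    assert rej_alt > rej_null
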