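"""Haplotype calls, clonal interference, variant filtering, prevalence stats."""
import itertools
import math

import numpy as np
import pytest

from gutevol.haplotypes import (
    ADAPTATION_TARGET_COUNTS,
    N_POPULATIONS,
    CloneTyping,
    VariantRecord,
    call_haplotype,
    detect_clonal_interference,
    filter_variants,
    haplotype_frequencies,
    host_specificity_test,
    parallel_targets,
    prevalence_table,
    target_prevalence,
)


def _typing(**states):
    full = {l: "absent" for l in ("gat", "focA/ycaO", "dcuB/dcuR", "srlR")}
    full.update(states)
    return CloneTyping(mouse_id="m1", clone_id="c1", states=full)


class TestCallHaplotype:
    def test_all_absent_is_ancestral(self):
        call = call_haplotype(_typing())
        assert call.label == "ancestral"
        assert call.loci == frozenset()

    def test_double_mutant_label(self):
        call = call_haplotype(_typing(**{"gat": "present", "focA/ycaO": "present"}))
        assert call.label == "gat+focA/ycaO"

    def test_triple_mutant_label_and_panel_order(self):
        call = call_haplotype(
            _typing(**{"srlR": "present", "gat": "present", "focA/ycaO": "present"})
        )
        assert call.label == "gat+focA/ycaO+srlR"  # fixed panel order, not input order

    def test_untyped_excluded_and_flagged(self):
        call = call_haplotype(_typing(**{"gat": "present", "srlR": "untyped"}))
        assert call.loci == frozenset(["gat"])
        assert call.untyped == ("srlR",)

    def test_all_untyped_rejected(self):
        with pytest.raises(ValueError, match="typed"):
            CloneTyping(mouse_id="m", clone_id="c", states={"gat": "untyped"})

    def test_frequencies_from_typed_clones(self):
        clones = [_typing(gat="present")] * 3 + [_typing()] * 1
        freqs = haplotype_frequencies(clones)
        assert freqs[frozenset(["gat"])] == pytest.approx(0.75)


class TestClonalInterference:
    def test_single_fixed_haplotype(self):
        assert detect_clonal_interference({"gat": 1.0}) == (False, [])

    def test_non_nested_pair_detected(self):
        flag, pairs = detect_clonal_interference(
            {"gat+focA/ycaO": 0.5, "gat+srlR": 0.3, "gat": 0.2}
        )
        assert flag
        assert ("gat+focA/ycaO", "gat+srlR") in pairs

    def test_nested_pair_not_interference(self):
        assert detect_clonal_interference({"gat": 0.6, "gat+focA/ycaO": 0.4})[0] is False

    def test_malformed_frequencies_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            detect_clonal_interference({"gat": 0.5, "srlR": 0.3})

    def test_label_and_set_keys_agree_and_order_invariant(self):
        by_label = {"gat+srlR": 0.4, "focA/ycaO": 0.35, "ancestral": 0.25}
        by_set = {
            frozenset(["srlR", "gat"]): 0.4,
            frozenset(["focA/ycaO"]): 0.35,
            frozenset(): 0.25,
        }
        a = detect_clonal_interference(by_label)
        b = detect_clonal_interference(by_set)
        reordered = detect_clonal_interference(dict(reversed(list(by_label.items()))))
        assert a == b == reordered
        assert a[0] is True

    @pytest.mark.parametrize("seed", range(10))
    def test_monotone_in_threshold(self, seed):
        r = np.random.default_rng(seed)
        loci = ["a", "b", "c"]
        haps = [frozenset(s) for n in range(3) for s in itertools.combinations(loci, n)]
        w = r.dirichlet(np.ones(len(haps)))
        freqs = dict(zip(haps, w))
        flags = [detect_clonal_interference(freqs, th)[0] for th in (0.05, 0.10, 0.25)]
        # detected at a higher threshold implies detected at every lower one
        for lo, hi in zip(flags, flags[1:]):
            assert lo or not hi

    def test_multilocus_supply_raises_interference_rate(self):
        """With two co-circulating beneficial targets, non-nested haplotypes
        co-segregate far more often than with a single target."""
        from gutevol.simulate import BeneficialLocusSpec, SimConfig, run_simulation

        def rate(n_loci, seed):
            loci = tuple(
                BeneficialLocusSpec(name=f"l{i}", mu_b=2e-6, s_mean_per_hour=0.04)
                for i in range(n_loci)
            )
            cfg = SimConfig(
                days=10,
                n_hosts=12,
                pop_size=10**7,
                gen_time_min=72.0,
                beneficial_loci=loci,
                seed=seed,
            )
            out = run_simulation(cfg)

            def _hap_freqs(class_freqs):
                agg: dict = {}
                for k, v in class_freqs.items():
                    agg[k[1]] = agg.get(k[1], 0.0) + v
                return agg

            hits = 0
            for h in out.hosts:
                if any(
                    detect_clonal_interference(_hap_freqs(f))[0] for f in h.class_freqs
                ):
                    hits += 1
            return hits / len(out.hosts)

        assert rate(2, 31) > rate(1, 32)


class TestVariantFiltering:
    def _rec(self, freq, pop="p1", host="WT", target="gat"):
        return VariantRecord(pop, host, target, "SNP", freq)

    def test_cutoff_inclusive(self):
        kept = filter_variants([self._rec(0.04), self._rec(0.05)], 0.05)
        assert [r.frequency for r in kept] == [0.05]

    def test_empty_input(self):
        assert filter_variants([], 0.05) == []

    def test_parallel_rule(self):
        recs = [
            self._rec(0.20, pop="p1", target="a"),
            self._rec(0.08, pop="p2", target="a"),  # parallel: 2 pops, peak >= 10%
            self._rec(0.50, pop="p1", target="b"),  # single population
            self._rec(0.06, pop="p1", target="c"),
            self._rec(0.06, pop="p2", target="c"),
            self._rec(0.06, pop="p3", target="c"),  # never reaches 10%
        ]
        assert parallel_targets(recs) == ["a"]

    def test_parallel_pools_hosts(self):
        recs = [
            self._rec(0.2, pop="w1", host="WT", target="a"),
            self._rec(0.2, pop="r1", host="RAG2KO", target="a"),
        ]
        assert parallel_targets(recs) == ["a"]


# frozen printed values: percent (and +- where printed) per target, WT then Rag2
PRINTED_TABLE = {
    "gat operon": ((100, 7), (100, 7)),
    "srlR": ((50, 13), (60, 13)),
    "focA/ycaO": ((29, 12), (40, 13)),
    "yjjP/yjjQ": ((57, 13), (13, 9)),
    "kdgR": ((14, 9), (13, 9)),
    "dcuB/dcuR": ((50, 13), (0, None)),
    "yeaR": ((14, 9), (0, None)),
    "arcB": ((0, None), (13, 9)),
    "frlR": ((0, None), (13, 9)),
    "rimJ": ((0, None), (13, 9)),
}


class TestTargetPrevalence:
    @pytest.mark.parametrize(
        "k,n,pct,sem",
        [(9, 15, 60, 13), (4, 14, 29, 12), (14, 14, 100, 7), (15, 15, 100, 7)],
    )
    def test_examples(self, k, n, pct, sem):
        tp = target_prevalence("t", {"g": k}, {"g": n})
        assert tp.percent["g"] == pct
        assert tp.sem_percent["g"] == sem

    def test_full_published_table_reproduced(self):
        """Every printed percent and +- value follows from the implied hit
        counts under the rounding and boundary rules."""
        df = prevalence_table()
        assert set(df["target"]) == set(PRINTED_TABLE)
        for _, row in df.iterrows():
            (pct_wt, sem_wt), (pct_rag, sem_rag) = PRINTED_TABLE[row["target"]]
            assert row["percent_WT"] == pct_wt
            assert row["percent_RAG2KO"] == pct_rag
            if sem_wt is not None:
                assert row["sem_WT"] == sem_wt
            if sem_rag is not None:
                assert row["sem_RAG2KO"] == sem_rag

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            target_prevalence("t", {"g": 0}, {"g": 0})


def _placement_oracle(k1, n1, k2, n2):
    """Brute force: place K hits on n1+n2 labelled populations, all C(N,K)
    placements equally likely; P(at least k1 land in group 1)."""
    K, N = k1 + k2, n1 + n2
    hits_at_least = sum(
        1
        for combo in itertools.combinations(range(N), K)
        if sum(1 for i in combo if i < n1) >= k1
    )
    return hits_at_least / math.comb(N, K)


class TestHostSpecificity:
    def test_no_hits(self):
        assert host_specificity_test(0, 14, 0, 15).p_value == 1.0

    def test_dcub_exact_value(self):
        res = host_specificity_test(7, 14, 0, 15)
        assert res.extra["p_one_sided"] == pytest.approx(3432 / 1560780, rel=1e-12)

    def test_balanced_hits_near_one(self):
        assert host_specificity_test(1, 14, 1, 15).p_value == 1.0

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_placement_enumeration(self, seed):
        r = np.random.default_rng(seed)
        n1, n2 = int(r.integers(2, 15)), int(r.integers(2, 15))
        k1, k2 = int(r.integers(0, n1 + 1)), int(r.integers(0, n2 + 1))
        res = host_specificity_test(k1, n1, k2, n2)
        assert res.extra["p_one_sided"] == pytest.approx(
            _placement_oracle(k1, n1, k2, n2), rel=1e-10
        )
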