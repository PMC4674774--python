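"""End-to-end in silico replication driver.

Simulates WT and Rag2-/- cohorts for every assay (evolution, competition,
resistance plating, growth/hybridization) and runs all inference stages
on the simulated tables, writing tidy outputs plus a run manifest.
All randomness flows from one root seed via named substreams per stage,
so outputs are reproducible and independent of stage reordering.
"""
from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import fitness as fit
from . import growth as gr
from . import haplotypes as hap
from . import markers as mk
from . import mutrate as mr
from . import sweeps as sw
from .io import config_digest, write_table
from .presets import GROWTH_PRESETS, replica_configs
from .simulate import (
    run_simulation,
    simulate_calibration_table,
    simulate_competition_cohort,
    simulate_hybridization_table,
    simulate_resistance_cohort,
)

__all__ = ["run_pipeline", "StageError"]

STAGES = ("simulate", "markers", "fitness", "mutrate", "growth", "sweep", "haplo")


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"[{stage}] {err}")
        self.stage = stage


def _stage_seed(seed: int, stage: str) -> int:
    # stable per-stage substream below 2^31
    h = np.random.SeedSequence(entropy=seed, spawn_key=(STAGES.index(stage),))
    return int(h.generate_state(1)[0] % (2**31))


def run_pipeline(
    out_dir,
    seed: int = 0,
    n_hosts: int = 5,
    days: int = 24,
    pop_size: int = 10**7,
    plate_depth: int = 200,
    n_competition_hosts: int = 10,
    clones_per_mouse: int = 20,
) -> Path:
    """Run the full in silico study; returns the output directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": "run_pipeline",
        "package_version": __version__,
        "seed": seed,
        "params": {
            "n_hosts": n_hosts,
            "days": days,
            "pop_size": pop_size,
            "plate_depth": plate_depth,
            "n_competition_hosts": n_competition_hosts,
            "clones_per_mouse": clones_per_mouse,
        },
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }
    manifest["config_hash"] = config_digest(
        {k: manifest[k] for k in ("command", "seed", "params")}
    )

    # ---- 1. simulate the evolution cohorts -------------------------------
    stage = "simulate"
    try:
        cfgs = replica_configs(
            n_hosts=n_hosts,
            days=days,
            pop_size=pop_size,
            plate_depth=plate_depth,
            seed=_stage_seed(seed, stage),
        )
        sims = {g: run_simulation(cfg) for g, cfg in cfgs.items()}
        plate = pd.concat([s.to_plate_table() for s in sims.values()], ignore_index=True)
        traj = pd.concat([s.to_trajectory_table() for s in sims.values()], ignore_index=True)
        write_table(plate, out / "simulate" / "plate_counts.tsv", "plate_counts")
        write_table(traj, out / "simulate" / "trajectories.tsv", "trajectories")
        realized = {
            g: {h.mouse_id: h.realized_s_per_hour for h in s.hosts} for g, s in sims.items()
        }
        (out / "simulate" / "run_manifest.json").write_text(
            json.dumps({"seed": seed, "realized_s_per_hour": realized}, indent=2, sort_keys=True)
        )
        manifest["stages"][stage] = "ok"
    except Exception as e:  # noqa: BLE001 - stage-tagged abort
        raise StageError(stage, e) from e

    # ---- 2. markers ------------------------------------------------------
    stage = "markers"
    try:
        marker_df = pd.concat([s.to_marker_table() for s in sims.values()], ignore_index=True)
        write_table(marker_df, out / "markers" / "marker_counts.tsv", "markers")
        div = mk.divergence_table(marker_df)
        div.to_csv(out / "markers" / "divergence.tsv", sep="\t", index=False)
        groups = sorted(div["host"].unique())
        comparison = None
        if len(groups) == 2:
            g1 = div[(div.host == groups[0]) & div.evaluable]
            g2 = div[(div.host == groups[1]) & div.evaluable]
            res = mk.compare_diverged_counts(
                int(g1.diverged.sum()), len(g1), int(g2.diverged.sum()), len(g2)
            )
            comparison = {
                "groups": groups,
                "diverged": [int(g1.diverged.sum()), int(g2.diverged.sum())],
                "n_lines": [len(g1), len(g2)],
                "p_value": res.p_value,
                "test": res.name,
            }
        (out / "markers" / "comparison.json").write_text(
            json.dumps(comparison, indent=2, sort_keys=True)
        )
        manifest["stages"][stage] = "ok"
    except Exception as e:
        raise StageError(stage, e) from e

    # ---- 3. fitness (competition assays) ---------------------------------
    stage = "fitness"
    try:
        sseed = _stage_seed(seed, stage)
        comp = pd.concat(
            [
                simulate_competition_cohort(
                    "wt-competition", n_hosts=n_competition_hosts, seed=sseed
                ),
                simulate_competition_cohort(
                    "rag2-competition", n_hosts=n_competition_hosts, seed=sseed + 1
                ),
            ],
            ignore_index=True,
        )
        write_table(comp, out / "fitness" / "competition.tsv", "competition")
        s_df = fit.cohort_selection_coefficients(comp)
        s_df.to_csv(out / "fitness" / "selection_coefficients.tsv", sep="\t", index=False)
        hosts = sorted(s_df["host"].unique())
        summary = {
            "mean_s_per_hour": {
                h: float(s_df.loc[s_df.host == h, "s_per_hour"].mean()) for h in hosts
            },
            "two_sem": {
                h: float(
                    2
                    * s_df.loc[s_df.host == h, "s_per_hour"].std(ddof=1)
                    / np.sqrt((s_df.host == h).sum())
                )
                for h in hosts
            },
        }
        if len(hosts) == 2:
            a = s_df.loc[s_df.host == hosts[0], "s_per_hour"].to_numpy()
            b = s_df.loc[s_df.host == hosts[1], "s_per_hour"].to_numpy()
            fres = fit.variance_ratio_test(a, b)
            anova = fit.group_anova(s_df["s_per_hour"].to_numpy(), s_df["host"].to_numpy())
            summary["variance_F"] = {"F": fres.statistic, "p": fres.p_value, "df": fres.df}
            summary["anova"] = {"F": anova.f, "p": anova.p_value}
            summary["tukey"] = anova.tukey.to_dict(orient="records")
        (out / "fitness" / "group_tests.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True)
        )
        manifest["stages"][stage] = "ok"
    except Exception as e:
        raise StageError(stage, e) from e

    # ---- 4. mutation rate -------------------------------------------------
    stage = "mutrate"
    try:
        sseed = _stage_seed(seed, stage)
        res_df = pd.concat(
            [
                simulate_resistance_cohort("fzd-wt", seed=sseed),
                simulate_resistance_cohort("fzd-rag2", seed=sseed + 1),
            ],
            ignore_index=True,
        )
        # distinct mouse ids across cohorts
        res_df["mouse_id"] = res_df["host"].str[0].str.lower() + res_df["mouse_id"]
        write_table(res_df, out / "mutrate" / "resistance.tsv", "resistance")
        summary = {}
        per_host = {}
        for host, g in res_df.groupby("host"):
            est = mr.summarize_frequency(mr.records_from_dataframe(g))
            per_host[host] = est
            summary[host] = {
                "mean_log10_frequency": est.mean_log10_frequency,
                "n_mice": est.n_mice,
                "n_censored": est.n_censored,
            }
        if len(per_host) == 2:
            (h1, e1), (h2, e2) = sorted(per_host.items())
            mw = mr.mann_whitney(
                list(e1.per_mouse.values()), list(e2.per_mouse.values())
            )
            summary["mann_whitney"] = {
                "groups": [h1, h2],
                "W": mw.statistic,
                "p": mw.p_value,
                "method": mw.extra["method"],
            }
        (out / "mutrate" / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True)
        )
        manifest["stages"][stage] = "ok"
    except Exception as e:
        raise StageError(stage, e) from e

    # ---- 5. growth (division rate) ----------------------------------------
    stage = "growth"
    try:
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(STAGES.index(stage),))
        )
        calib = simulate_calibration_table(rng)
        write_table(calib, out / "growth" / "calibration.tsv", "calibration")
        cal_means = gr.average_hybridizations(
            calib.rename(columns={"fluorescence": "median_fluorescence"})
        )
        rates = calib.groupby("sample", sort=True)["rate"].first()
        model = gr.fit_calibration(
            rates.loc[cal_means["sample"]].to_numpy(),
            cal_means["median_fluorescence"].to_numpy(),
        )
        summary = {
            "calibration": {
                "slope": model.slope,
                "intercept": model.intercept,
                "residual_sd": model.residual_sd,
                "n": model.n,
            },
            "doubling_min": {},
        }
        hyb_all = []
        for host, preset in (("WT", "wt-growth"), ("RAG2KO", "rag2-growth")):
            hyb = simulate_hybridization_table(
                GROWTH_PRESETS[preset]["rate_per_hour"],
                rng,
                mouse_prefix=host[0].lower(),
            )
            hyb_all.append(hyb)
            means = gr.average_hybridizations(hyb)
            dts = [
                gr.infer_doubling_time(f, model).minutes
                for f in means["median_fluorescence"]
            ]
            summary["doubling_min"][host] = {
                "mean": float(np.mean(dts)),
                "two_sem": float(2 * np.std(dts, ddof=1) / np.sqrt(len(dts))),
                "n_samples": len(dts),
            }
        write_table(
            pd.concat(hyb_all, ignore_index=True),
            out / "growth" / "hybridization.tsv",
            "hybridization",
        )
        (out / "growth" / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True)
        )
        manifest["stages"][stage] = "ok"
    except Exception as e:
        raise StageError(stage, e) from e

    # ---- 6. sweeps ---------------------------------------------------------
    stage = "sweep"
    try:
        pheno = pd.concat(
            [s.to_phenotype_table() for s in sims.values()], ignore_index=True
        )
        pheno = pheno[pheno["day"] <= 9]  # early sweep window
        write_table(pheno, out / "sweep" / "phenotype.tsv", "phenotype")
        sf = sw.fit_sweep(pheno)
        (out / "sweep" / "fit.json").write_text(
            json.dumps(
                {
                    "intercepts": sf.intercepts,
                    "slope_per_day": sf.slope_per_day,
                    "interaction": sf.interaction,
                    "z": sf.z,
                    "p_value": sf.p_value,
                    "reference": sf.reference,
                    "fast": sf.fast,
                    "n_obs": sf.n_obs,
                    "n_mice": sf.n_mice,
                    "separation": sf.separation,
                },
                indent=2,
                sort_keys=True,
            )
        )
        sw.phenotype_variance(pheno).to_csv(
            out / "sweep" / "variance.tsv", sep="\t", index=False
        )
        manifest["stages"][stage] = "ok"
    except Exception as e:
        raise StageError(stage, e) from e

    # ---- 7. haplotypes ------------------------------------------------------
    stage = "haplo"
    try:
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(STAGES.index(stage),))
        )
        typing_rows = []
        variant_rows = []
        interference = {}
        locus_map = {"gat": "gat", "focA/ycaO": "focA/ycaO", "dcuB/dcuR": "dcuB/dcuR", "srlR": "srlR"}
        for g, sim in sims.items():
            for h in sim.hosts:
                final = h.class_freqs[-1]
                keys = sorted(final.keys(), key=repr)
                probs = np.array([final[k] for k in keys])
                probs = probs / probs.sum()
                draw = rng.multinomial(clones_per_mouse, probs)
                hap_freqs: dict = {}
                for k, c in zip(keys, draw):
                    if c == 0:
                        continue
                    loci = frozenset(locus_map.get(l, l) for l in k[1])
                    hap_freqs[loci] = hap_freqs.get(loci, 0) + int(c)
                clone_i = 0
                for loci, c in sorted(hap_freqs.items(), key=lambda kv: hap._label(kv[0])):
                    for _ in range(c):
                        clone_i += 1
                        for locus in hap.LOCUS_PANEL:
                            typing_rows.append(
                                (
                                    h.mouse_id,
                                    f"c{clone_i}",
                                    locus,
                                    "present" if locus in loci else "absent",
                                )
                            )
                total = sum(hap_freqs.values())
                flag, pairs = hap.detect_clonal_interference(
                    {k: v / total for k, v in hap_freqs.items()}
                )
                interference[h.mouse_id] = {"flag": flag, "pairs": pairs}
                # population variant frequencies from the true class freqs
                for b in sim.config.beneficial_loci:
                    f = sum(v for k, v in final.items() if b.name in k[1])
                    if f > 0:
                        variant_rows.append(
                            (h.mouse_id, h.host, b.name, b.mutation_class, min(f, 1.0))
                        )
        typing_df = pd.DataFrame(
            typing_rows, columns=["mouse_id", "clone", "locus", "state"]
        )
        write_table(typing_df, out / "haplo" / "clone_typing.tsv", "clone_typing")
        var_df = pd.DataFrame(
            variant_rows, columns=["population", "host", "target", "class", "frequency"]
        )
        write_table(var_df, out / "haplo" / "variants.tsv", "variants")
        records = [
            hap.VariantRecord(p, h_, t, c, f)
            for p, h_, t, c, f in var_df.itertuples(index=False, name=None)
        ]
        kept = hap.filter_variants(records, 0.05)
        parallel = hap.parallel_targets(kept)
        totals = {g: len(sims[g].hosts) for g in sims}
        prev_rows = []
        for target in parallel:
            hits = {
                g: len(
                    {
                        r.population
                        for r in kept
                        if r.target == target and r.host == g and r.frequency >= 0.10
                    }
                )
                for g in sims
            }
            tp = hap.target_prevalence(target, hits, totals)
            prev_rows.append(
                {
                    "target": target,
                    **{f"percent_{g}": tp.percent[g] for g in sims},
                    **{f"sem_{g}": tp.sem_percent[g] for g in sims},
                    "p_two_sided": tp.specificity.p_value if tp.specificity else None,
                }
            )
        pd.DataFrame(prev_rows).to_csv(out / "haplo" / "prevalence.tsv", sep="\t", index=False)
        (out / "haplo" / "interference.json").write_text(
            json.dumps(interference, indent=2, sort_keys=True)
        )
        manifest["stages"][stage] = "ok"
    except Exception as e:
        raise StageError(stage, e) from e

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
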