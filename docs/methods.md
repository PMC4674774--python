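# Methods

## The system being modeled

`gutevol` implements the quantitative analyses of a within-host
experimental-evolution design: *E. coli* colonizes the gut of
streptomycin-treated mice (immune-competent WT, lymphocyte-deficient
*Rag2*⁻/⁻, and germ-free variants) as a 1:1 mix of YFP- and CFP-tagged
isogenic strains, and adaptation is read out through marker divergence,
the sweep of the galactitol-negative (*gat*) phenotype, in vivo
competition assays, resistant-mutant frequencies at mutation–selection
balance, rRNA-content-based division rates, and end-point haplotype and
population-resequencing data. Every input table the inference modules
consume can be generated by the simulator, so the whole analysis chain
is testable without animal data.

## Simulator (`gutevol.simulate`)

**State.** Populations are tracked as haplotype classes — tuples of
(fluorescent marker, set of beneficial mutations, set of
(antibiotic, channel) resistance mutations) with cell counts. At gut
population sizes (10⁷–10¹⁰ cells) an individual-based model is
infeasible; class-based multinomial resampling has the identical
marginal law.

**Generation update.** Each generation applies (1) deterministic
selection, (2) mutation, (3) multinomial resampling of N cells
(skipped in deterministic mode). Class fitness is Malthusian:
w = exp(Σ s_gen − Σ cost_gen). The exponential parameterization is a
deliberate choice: it makes the deterministic single-mutant sweep follow
the haploid logistic closed form p(t) = p₀e^{σt}/(1−p₀+p₀e^{σt})
exactly, and it makes the log-ratio slope of a competition assay equal
the input selection coefficient by construction — the same definition
the assay itself uses. With w = 1+s instead, every recovered slope
would be ln(1+s), ~4% low at the per-generation effects used here.

**Units.** Selection coefficients are specified per hour (the scale the
competition assays report); conversion is s_gen = s_h · gen_time_min/60.
Generations per day = 1440/gen_time_min.

**Mutation.** Fluxes are Poisson with expectation N·x·μ per
(class, target) pair; double events within one generation are ignored
(rates ≪ 1 per class per generation at the parameters used). Resistance
mutation is split into point and IS (transposition) channels by
`is_fraction`. Back-mutation is ignored.

**Antagonistic pleiotropy.** Host-to-host variation in selective effects
is modeled as one Gaussian draw of s per beneficial locus per host,
constant within the host (the data show sign flips between hosts but no
within-host dynamics, so s is held fixed; this is a documented
simplification). A draw ≤ 0 is allowed and is the model's expression of
antagonistic pleiotropy.

**Observation layer.** Plating is a single multinomial draw of
`plate_depth` colonies over classes (markers, per-locus mutant status
and the gat phenotype are consistent within a plate). Resistant
colonies are drawn on a separate simulated selective plate with
`resistance_plate_depth` = 10⁷ cells equivalent: at equilibrium
frequencies of ~10⁻⁶ they would be invisible among a few hundred
colonies.

**Mutation–selection balance under the exponential convention.** The
closed-form operation `msb_equilibrium` returns μ/s_d. The simulated
deterministic equilibrium is μ/(1−e^{−s_d}), which is ≈5% (0.02 log10)
above μ/s_d at s_d = 0.1; the discrepancy is far inside the stochastic
spread of the assay and is noted here rather than hidden by rescaling.

## Presets (study conditions)

| preset | key parameters |
|---|---|
| `wt-competition` | gen 76 min, s ~ N(0.068, 0.008²) per hour, 1:1 start, pop 10⁸, 3 days, 600 colonies/plate |
| `rag2-competition` | gen 66 min, s ~ N(0.03, 0.016²) per hour (wide enough for s ≤ 0 draws) |
| `wt-growth` / `rag2-growth` | true rates 60·ln2/76 and 60·ln2/66 per hour |
| `fzd-wt` / `fzd-rag2` | μ_r = 10^−5.65·0.1 and 10^−5.49·0.1 per generation, cost s_d = 0.1, IS fractions 0.457 / 0.550, pop 10⁸ |
| `paper-replica` | WT + Rag2 evolution cohorts with four beneficial targets and the furazolidone locus |

The competition/growth means and generation times are the measured study
values; the decompositions behind them are package choices: the across-host
sd values interpret the reported dispersion of per-host s; the cost
s_d = 0.1 per generation ("slightly deleterious" resistance) fixes μ_r
given the measured equilibrium frequencies; the IS fractions follow from
the measured transposition frequencies relative to total furazolidone
resistance. For `paper-replica`, per-locus beneficial mutation rates
(10⁻⁵ for the gat operon — a large loss-of-function target — and
10⁻⁷–2·10⁻⁷ for the secondary targets) and secondary-target effects
(0.03–0.045/h) are not measured quantities; they were chosen once so
that the gat phenotype sweeps within the first week in WT hosts and
secondary targets co-segregate by day 24 (clonal interference), and are
used only for the end-to-end pipeline and qualitative property tests.

## Inference modules

**Markers.** Frequency sem is √(p(1−p)/n), degenerating to 1/n at p ∈
{0, 1} (the binomial formula collapses to zero there; 1/n reproduces
the reported "100% (±7%)" style of uncertainty at n = 14–15).
Divergence is the two-sided t-test on the OLS slope of ln(YFP/CFP) over
days 1–6 (day 0 is the gavage mix, excluded by default); zero-count
days are dropped rather than pseudo-counted (a +0.5 pseudo-count mode
exists for sensitivity analysis). Cross-host comparison of diverged-line
counts is a conditional binomial test — given K total diverged lines,
X₁ ~ Bin(K, n₁/(n₁+n₂)), doubling the smaller tail — with Fisher's
exact test available as an alternative; the published analysis names a
"binomial test" without construction, so the choice is explicit here.

**Fitness.** s is the unweighted OLS slope of ln(mutant/reference) on
hours with a free intercept (the assay definition; no weighting or
intercept constraint is stated for it, and simulation shows the
unweighted fit is unbiased at the depths used). Variance comparison is
the two-sided F test (sample variances, smaller tail doubled). One-way
ANOVA + Tukey HSD (studentized range) and two-way ANOVA with
interaction run through statsmodels behind the module's surface. On
exact-fit two-way data (zero residual variance) terms with zero sum of
squares report F = 0, p = 1 rather than 0/0; the one-way degenerate
case is an error.

**Mutation rate.** The primary quantity is the log10 resistant
*frequency*; days with zero resistant colonies are censored, not
treated as zeros (a log of zero is undefined and the zero is a
detection limit). Averaging is hierarchical — within mouse over days,
then unweighted across mice — so mice with more usable days do not
dominate; pooling all mouse-days is the noted alternative. μ = 10^mean·s_d
is computed only when the caller supplies a cost. Transposition
frequency adds log10(n_IS/n_typed); n_IS = 0 yields a flagged upper
bound. Mann–Whitney reports W as the first sample's midrank sum; p is
exact by tie-aware enumeration when C(n₁+n₂, n₁) ≤ 2·10⁵, by the exact
recursion for tie-free samples up to 12 per group, else the
tie-corrected normal approximation.

**Growth.** Exponential rates come from the maximal-R² sliding window
(default 5 points) of ln(OD) vs time restricted to OD ∈ [0.02, 0.5] —
the exponential window is not defined in the study, so an objective
window rule is used. Calibration regresses rate on fluorescence
(direction chosen for direct inversion by prediction; inverse
regression is the noted alternative), averaging duplicate
hybridizations per sample first. Doubling time is 60·ln2/rate minutes
with a delta-method se from the calibration prediction variance, and an
explicit warning outside the calibrated fluorescence range.

**Sweeps.** The cross-host model is a binomial GLM,
logit(p) = β₀ + (β₁ + β₂·I[fast])·day, with counts as denominators, the
intercept shared across genotypes (both cohorts start from the same
gavage mix), and mouse-level dependence handled by cluster-robust
sandwich standard errors instead of a random-intercept GLMM. This keeps
the estimator light and its fixed effects consistent under cluster
correlation; z = β₂/se(β₂) is therefore not numerically comparable to a
GLMM z from animal data, and only its sign and magnitude ordering are
interpreted. β₂ > 0 means the WT sweep is faster under the default
coding. Complete separation is flagged when coefficients run away
(|β| > 30).

**Haplotypes.** Typing states are present/absent/untyped; untyped loci
are excluded from the call and flagged. Clonal interference requires
two haplotypes with non-nested mutation sets each at ≥ 10% — nested
sets can lie on one genealogical path and are not evidence of
competition. The variant filter keeps frequency ≥ 5% (inclusive
boundary, documented); parallel targets need ≥ 2 populations pooled
across host genotypes and ≥ 10% in at least one. Prevalence percents
and their uncertainties are rounded half-up to integers for reporting;
the degenerate 1/n rule at 0% or 100% matches the published style of
"100% (±7%)" at n = 14–15, and a Wilson-interval mode is available. A
population counts as "hit" for prevalence at the 10% threshold
(configurable; the 5% cutoff is the segregating-variant filter, not the
hit rule). Host specificity is the exact hypergeometric tail
(one-sided primary, doubled for two-sided).

## Numerical and design notes

- All randomness flows from a single root seed through named
  `SeedSequence` substreams (per host, per pipeline stage), so results
  are byte-reproducible and independent of execution order.
- Day sampling maps to the nearest generation; with non-integer
  generations-per-day the day grid is off by at most half a generation.
  Closed-form checks are therefore made at generation resolution.
- The class table is capped (default 20 000 classes) and overflow is an
  explicit error rather than silent memory growth.
- Problem sizes in the test-suite and the acceptance script (20 cohorts
  of 10 hosts for competition; 6 mice × 15 days for the resistance
  assay; 200 lines for the neutrality/type-I checks) are the package's
  chosen desk-scale study sizes: large enough that Monte-Carlo error is
  several-fold below each stated tolerance, small enough to run in
  seconds.

## What the generator does and does not emulate

The synthetic data reproduce the statistical structure the inference
relies on: 1:1 marker starts, host-specific selective effects with
across-host variance, multiple competing adaptive targets, deleterious
resistance alleles at mutation–selection balance, binomial
colony-sampling noise, and a linear rate–fluorescence calibration with
measurement noise. They do not emulate spatial gut structure, migration
between hosts, horizontal transfer, time-varying selection as the
microbiota recovers from antibiotic treatment (s is constant per host),
or any microbiota ecology — host and microbiota effects enter only
through host-genotype-specific s parameters. Passing recovery tests
therefore validates the estimators under the stated generative
assumptions, not the biological completeness of those assumptions.

## Known limitations

- The sweep GLM's z is a different estimator from a random-effects
  GLMM's z; with strong per-mouse heterogeneity its magnitude will be
  smaller at equal data.
- The mutation-rate inversion μ = f*·s_d inherits any error in the
  assumed cost one-for-one.
- The 1/n degenerate-uncertainty rule is an inference from reported
  values, not a derivation; the Wilson option is the statistically
  conventional alternative.
- Linear calibration of rate on fluorescence extrapolates poorly; the
  model warns rather than refuses outside the calibrated range.
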