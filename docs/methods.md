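# Methods

This note documents the models, scaling conventions, numerical choices and
known limitations of mesophylo. It is the reference for anyone asking *what
exactly is computed* and *why a default is what it is*.

## Data model and missing data

Alignments are matrices of A/C/G/T, gap (`-`), missing (`?`/`N`) and IUPAC
ambiguity symbols; `U` is mapped to `T` on input. Ambiguity codes are
treated as missing throughout — resolving them would invent alleles. The
default missing-data policy is **complete deletion** (columns containing any
missing/ambiguous symbol are removed before haplotype collapsing, distances
and diversity), which is the common default for sequence data in this kind
of analysis; a `pairwise-ignore` policy is available where each comparison
uses its own comparable sites. Internal coordinates are 0-based half-open;
user-facing reports are 1-based inclusive. Sequences are used as given —
inputs are curated alignments, so there is no reverse-complement detection.

The number of groups K in the population map is always an *input* (e.g.
from prior phylogenetic or spatial clustering); nothing here infers it.

## Summary statistics

* **Hd** (unbiased haplotype diversity): Hd = n/(n−1)(1 − Σp_i²), with
  Nei's sampling variance
  Var(Hd) = 2/(n(n−1))·{2(n−2)[Σp_i³ − (Σp_i²)²] + Σp_i² − (Σp_i²)²}.
* **k, π**: mean pairwise Hamming distance over all C(n,2) pairs on
  comparable sites; π = k/L_effective. Distances are plain pairwise
  differences — no substitution-model correction — matching the AMOVA
  distance choice below.
* **Tajima's D**: the 1989 statistic from (n, S, k) with the standard
  a1…e2 constants. Undefined (flagged "n. a.", never 0/0) when S = 0 or
  when the variance constants vanish (n ≤ 3).
* **Fu's F_S**: F_S = ln(S′/(1−S′)) with S′ = P(K ≥ K_obs | θ = k, n) under
  the Ewens sampling formula. Unsigned Stirling numbers of the first kind
  are computed once per n by the |s(n+1,k)| = |s(n,k−1)| + n·|s(n,k)|
  recurrence entirely in log space (n capped at 1000 for overflow safety);
  tail sums use log-sum-exp. S′ numerically 0 or 1 yields signed infinity,
  kept distinct from the undefined case (K_obs = 1 or k = 0).
* **Significance** of D and F_S: lower-tail p against a neutral
  constant-size coalescent null with θ set to the observed k (the usual
  plug-in), simulated under infinite sites (exact and fast for a null);
  1000 replicates by default. The conventional significance thresholds are
  stored as constants (0.05 for D, 0.02 for F_S), not baked into logic.
* **π SD** is reported as the square root of Nei's total variance
  ((n+1)/(3(n−1)L)·π + 2(n²+n+3)/(9n(n−1))·π²); it is informational only
  and feeds nothing downstream.

## Φ_ST and AMOVA

Pairwise "F_ST" between sequence populations is the two-level Φ_ST from the
squared pairwise-difference matrix (the sequence-data default of the
standard AMOVA framework); negative estimates are reported as computed, not
clamped. The three-level AMOVA partitions SSD into among-group / among
population-within-group / within-population components with the standard
unequal-sample-size coefficients, giving F_CT = σ²_a/σ²_T,
F_SC = σ²_b/(σ²_b+σ²_c), F_ST = (σ²_a+σ²_b)/σ²_T.

Permutation schemes: F_ST shuffles individuals among populations across the
whole dataset; F_SC shuffles individuals among populations within their
group; F_CT permutes whole populations among groups. p-values use
(hits+1)/(perms+1) with ties counted as ≥ observed (conservative). The
result records the number of *distinct* whole-population reassignments —
with few populations this count is tiny (e.g. 4!/(2!·2!·2) style
multinomials), which is why a large F_CT can be structurally incapable of
reaching significance while F_SC is highly significant.

## Coalescent engine and scaling

The simulator executes an ordered past-ward event list (splits, size
changes, admixture pulses; times in generations) under the continuous-time
coalescent: with j lineages in a population of haploid effective size N the
total coalescence rate is C(j,2)/(2N) per generation, so E[T₂] = 2N. With
per-site per-generation rate u this makes **θ = 4Nu per site**, the scaling
under which E[S] = θ_locus·a1(n), E[k] = θ_locus, and divergence times in
"4·N_AVE generations" units are natural. All rates quoted per year are
converted to per generation via the generation time g (default 2 years)
before entering the simulator, so there is a single internal unit.

Admixture events move each lineage of the target population independently
to one of two sources with probability r; sources may be populations that
only exist past-ward of the event (the target's ancestral continuation).
There is no recombination (mtDNA) and no continuous migration — pulse
admixture covers the gene-flow hypotheses the scenario language expresses.

HKY mutation uses **uniformization**: a Poisson number of candidate events
at the dominating rate Λ = max_i(−Q_ii) per branch, each applying the jump
matrix I + Q/Λ. This reproduces the exact finite-sites process (multiple
hits included) and costs O(mutations), not O(sites·branches). The root
sequence is drawn from the stationary frequencies. Default κ = 4–6
(configurable; the κ prior for inference defaults to Uniform(2, 20)), base
frequencies equal unless estimated from data.

A specialised two-population version of exactly this process is compiled
with numba (`_kernels.py`) for the hierarchical test, which needs millions
of replicates; a distributional test asserts kernel/engine agreement, and
an independent cross-check against msprime validates the neutral S
distribution.

## ABC scenario choice

Reference tables hold (scenario, parameter draw, statistic vector) rows,
balanced across scenarios. The default statistic vector is per-population
(Hd, π, k, S, D) plus per-population-pair (mean between-population
differences, point Φ_ST); D is set to 0 where undefined so that
low-diversity simulations remain usable rows rather than forcing biased
resimulation. Statistics are scaled by their reference-table median
absolute deviation (zero MADs replaced by 1), making the Euclidean
acceptance distance unit-free.

* **Model choice**: rejection PP = scenario frequencies among the closest
  tolerance fraction (default 1%); regression PP from multinomial logistic
  regression of the label on statistic offsets within the accepted set,
  evaluated at the observed point. The 95% CI of the selected PP comes from
  the regression's asymptotic covariance by the delta method; if the fit
  fails (e.g. perfect separation) a binomial CI on the rejection estimate
  is used and labelled as such. Ties select the lowest scenario index with
  a warning.
* **Priors**: uniform (optionally on log/logit regression scale) and
  truncated gamma (mean-parameterised; default shape 2; sampled exactly by
  inverse CDF on the truncated quantile range). Declared order constraints
  (t1 < t2 < …) are enforced by rejection; an apparent satisfaction
  probability below 10⁻⁴ raises with advice to revise the priors.
* **Parameter estimation**: Beaumont-style local-linear regression of each
  transformed parameter (log for sizes/times, logit for proportions) on the
  scaled statistic offsets with Epanechnikov weights; adjusted draws are
  back-transformed and clipped to the prior support. Singular designs fall
  back to the unadjusted rejection sample with a warning. Intervals are
  equal-tailed 2.5–97.5% quantiles; modes by Gaussian KDE.
* **Error rates**: PODs simulated per scenario, pushed through the same
  selector; type I for s is P(not selecting s | s true), type II is
  P(selecting s | another scenario true) averaged over the others.
* **Model check**: PCA fitted on the scaled reference statistics (constant
  columns dropped with notice); the observed point's per-axis percentile
  among posterior-predictive projections flags misfit outside [2.5, 97.5].

Reference-table sizes are configuration, not code: tests and examples use
10³–10⁴ rows per scenario; production analyses simply raise the number.

## Hierarchical co-divergence test

For m population pairs, the hyperprior is: Ψ uniform on 1..m (the maximum
number of divergence events equals the number of pairs tested); Ψ distinct
τ values uniform on (0, τ_max] (τ in units of 4·N_AVE generations); pairs
assigned to the Ψ classes uniformly conditioned on none being empty; and
per-pair nuisance θ (each daughter and the ancestor) uniform on
(0, θ_upper]. Each pair is simulated as a two-population split at its τ
with its own ti/tv ratio, yielding the statistic vector
{π_total, π_within×2, π_net, θ_W, D×2}. Plain acceptance/rejection (no
regression adjustment by default, available behind a flag) on MAD-scaled
concatenated statistics gives the joint hyperposterior.

Ω = Var(τ)/E(τ) (population variance). It is exactly 0 whenever Ψ = 1 —
enforced symbolically, immune to floating-point var() round-off. Modes of Ω
and E(τ) use Gaussian KDE with Silverman bandwidth **with the sample
reflected at 0**: without reflection the kernel pushes half the density of
the boundary atom (all those Ψ = 1 draws) outside the support and the mode
drifts inward. A consequence worth knowing: whenever a sizeable fraction of
accepted draws has Ψ = 1, the Ω mode sits at 0 and the synchrony verdict
(Ω ≤ 0.01) follows the Ψ posterior closely. 95% HPD intervals are the
shortest sample interval containing 95% of the accepted draws.

The ti/tv estimator is ML under a two-parameter (K80-style) model from mean
pairwise transition/transversion proportions (κ̂ = 2s/v, the per-type ratio
the HKY simulator consumes); the raw-count fallback is the pooled
transitions/transversions ratio (half the per-type value when the three
change types are equally frequent). No variable sites → configurable
default (4) with a flag; no transversions → capped, flagged.

**Absolute time**: T_div = E(τ)·(θ_AVE/μ)·g. θ_AVE defaults to the mean of
the uniform θ prior (upper/2) with a switch to use the upper bound itself —
the phrase "mean of the upper θ prior" admits both readings, so both are
exposed. μ's unit (per generation / per year / per Myr) must be declared
and is converted explicitly — note that for μ per year the g factors cancel
algebraically. Defaults: μ = 0.0042 substitutions/site/Myr, g = 2 years.

## Synthetic study designs

The four built-in templates mirror a comparative survey of Mesoamerican
montane birds: group layouts and per-group sample sizes
(5,42,14,2 | 20,8,6,4,10,5 | 8,11,4,1 | 3,7,10,5,2; Σ = 167 — the checksum
is asserted in tests so the parse is auditable), locus lengths 600–1100 bp,
and nested northward-colonisation scenarios with split times from ~0.2 to
~5.9 Myr converted at g = 2. Effective sizes default to N = 25,000 (haploid)
with u = 4×10⁻⁸/site/generation, i.e. θ ≈ 0.004/site, chosen to land the
generated haplotype and nucleotide diversities in the empirically observed
ranges (Hd ~0.4–1.0, π ~0.0004–0.0095); this is an explicit reconstruction,
not an estimate. Truth records (template, seed, parameters, per-pair τ)
regenerate any dataset bit-identically.

What the generator does *not* emulate: base-composition idiosyncrasies,
sequencing error, museum-sample missingness, intralocus recombination.
Passing tests on synthetic data therefore demonstrate correctness of the
inference machinery under the model, not robustness to real-data artefacts.

## Experiment sizes in the test suite

The acceptance tests use problem sizes chosen to make their statistical
checks decisive yet quick: coalescent calibration at 5000 replicates
(3-standard-error bands around Watterson's closed forms); scenario recovery
with 10⁴ reference rows per scenario, 200 PODs and 100 coverage
repetitions (coverage asserted within ~±3 binomial SE of 95%); synchrony
detection at 2×10⁵ simulations with the closest 0.1% accepted, 10 seeded
runs per condition with 8/10 required. The synthetic co-divergence
experiments place pairs at τ = 2.0 (synchronous) and {0.6, 3.0, 3.0}
(five-fold asynchronous) with θ = 0.002 per site — divergence depths at
which a single mtDNA locus with five samples per side carries a clear
signal; much shallower splits are genuinely ambiguous at single-locus scale,
which is a property of the data, not the method.

## Known limitations

* Single-locus (fully linked) data only; the hABC statistic vector is the
  classic single-locus set and multi-locus pairs are out of scope.
* No continuous migration; admixture is pulse-only.
* The regression CI for scenario PPs relies on the multinomial-logit
  asymptotics within the accepted set; with very small accepted sets the
  binomial fallback is wide.
* Ω mode estimation with boundary reflection favours 0 whenever Ψ = 1
  carries noticeable posterior mass (see above); the Ψ posterior is the
  sharper synchrony diagnostic in that regime.
* Hypothesis-style property tests are seeded/derandomised; stochastic
  assertions use 3-SE bands or seed-majority rules and can in principle
  produce rare false alarms under different numerical environments.
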