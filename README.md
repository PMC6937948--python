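# mesophylo

Comparative phylogeography of co-distributed mtDNA datasets: population
summary statistics and AMOVA, coalescent simulation under event-list
demographic scenarios, approximate Bayesian computation (ABC) scenario
choice, and hierarchical ABC (hABC) testing of simultaneous divergence.

## Who this is for

Phylogeographers asking whether several co-distributed taxa — say, montane
birds isolated on the same sky islands — share a common history: Is genetic
variation geographically structured? Which demographic scenario (sequence of
population splits, size changes, admixture pulses) best explains each taxon?
And did the taxa diverge across the same barriers *at the same time*?

The package answers these with four building blocks:

1. **Summary statistics** (`mesophylo.sumstats`): per-population haplotype
   diversity Hd with Nei's sampling SD, nucleotide diversity π, mean pairwise
   differences k, segregating sites S, Tajima's D and Fu's F_S (via the Ewens
   sampling formula with log-space Stirling numbers), with significance from
   neutral coalescent simulation; pairwise Φ_ST and three-level AMOVA
   (F_CT, F_SC, F_ST) with level-appropriate permutation tests.
2. **Coalescent engine** (`mesophylo.coalsim`): continuous-time coalescent
   over populations with splits / size changes / admixture, finite-sites HKY
   mutation by uniformization. Haploid (mtDNA) scaling: a lineage pair in a
   population of haploid size N coalesces after 2N generations on average and
   θ = 4Nu per site.
3. **ABC scenario choice** (`mesophylo.abc_select`): reference tables of
   (scenario, parameters, statistics), rejection + multinomial-logistic
   posterior probabilities with 95% CI, pseudo-observed-dataset (POD) type
   I/II error rates, Beaumont-style local-linear parameter posteriors, and a
   PCA model check.
4. **hABC co-divergence test** (`mesophylo.habc`): hyperprior over the number
   of divergence events Ψ and the τ vector (units of 4·N_AVE generations),
   acceptance/rejection posterior for (Ψ, Ω, E(τ)) with
   Ω = Var(τ)/E(τ) ≤ 0.01 as the synchrony rule, and absolute-time conversion
   T_div = E(τ)·(θ_AVE/μ)·g.

A synthetic-data generator (`mesophylo.synthdata`) emulates a four-taxon
Mesoamerican montane-bird study design (2–6 groups per taxon, 167 sequences
total, ~600–1100 bp loci, Pleistocene–Pliocene split times) so the entire
pipeline is testable with known ground truth and no sequence downloads.

## Worked example

`examples/` contains one short script per capability. For instance, the
co-divergence test (`python examples/04_habc_codivergence.py`) simulates
three population pairs that all split at τ = 2 (in units of 4·N_AVE
generations) and prints:

```
true tau per pair: (2.0, 2.0, 2.0)

P(Psi = k | data): [0.457 0.303 0.24 ]
Psi posterior mode: 1
Omega mode: 0.0000 (95% HPD 0.0000-0.8532)
verdict: synchronous (threshold Omega <= 0.01)

E(tau) mode 1.75 -> T_div ~ 2.08 Myr (mu = 0.0042 subs/site/Myr, g = 2 yr)
```

Ψ mode 1 with Ω at the boundary says a single shared divergence pulse
explains all three pairs; the time conversion places that pulse at ~2 Myr
under the default avian mtDNA rate (0.0042 substitutions/site/Myr) and a
two-year generation time. `examples/01_summary_statistics.py` prints the
per-group diversity table, `02_amova.py` the hierarchical variance
decomposition, `03_abc_scenario_choice.py` a full scenario-choice run with
posterior probabilities, CI and an adjusted split-time posterior.

A thin CLI mirrors the library for shell use:

```bash
mesophylo synth --template aulacorhynchus --seed 1 --out data/
mesophylo stats --fasta data/aulacorhynchus.fasta --popmap data/aulacorhynchus.popmap.tsv
mesophylo amova --fasta ... --popmap ... --perms 1000 --seed 1
mesophylo run --config run.yaml        # stats -> ABC -> hABC end to end
```

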