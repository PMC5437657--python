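# Methods

This note documents the models, defaults and design choices behind
`seqalloc`, and what the synthetic test-bed does and does not establish
about real data.

## Haplotype library and focal-individual selection

**Windows.** Each chromosome is tiled with consecutive, non-overlapping
windows of `window_length` markers (default 250, i.e. a quarter of a
1000-SNP chromosome), anchored at marker 0; a trailing remainder shorter
than the window is dropped so that all haplotype strings within a window
have equal length and exact identity is well defined. Overlapping or
end-anchored tilings would change absolute coverage numbers but not the
orderings the package is used for; non-overlapping tiling was chosen for its
simple copy-count accounting.

**Eligibility.** Individuals with at least `min_phased` (default 90%) of
their alleles called are retained first; markers with at least `min_phased`
called alleles *across the retained individuals* are retained second. The
order matters when missingness is concentrated: filtering individuals first
lets a marker survive that is missing only in discarded individuals. Within
a window, a gamete with *any* missing allele at an eligible marker
contributes nothing for that window — a 100% identity match cannot be
certified from partial data. Haplotype identity is keyed on the allele
string restricted to eligible markers inside the window, so two gametes
differing at a single marker are independent haplotypes (this deliberately
treats phasing errors as new haplotypes rather than merging them).

**Scoring and masking.** An individual's score is the summed population copy
count of the distinct unmasked haplotypes it carries; carrying a haplotype
on both gametes adds its mass once, since masking operates at the haplotype
level and a second copy enables nothing further. The candidate's own copies
are included (copy counting makes the conservation identity Σ counts =
number of contributing gametes exact, and is one of the two readings of
haplotype "frequency"; carrier counting would reweight but rarely reorder).
Masking is global across windows and permanent: once a focal individual is
chosen, its haplotypes are treated as sequenced-and-phased everywhere.
Ties are broken towards the smallest individual id for reproducibility.
Individuals with pre-existing sequence are handled by masking all their
haplotypes before selection starts; individuals without a DNA sample are
excluded as candidates while their copies still count in scores, so their
haplotypes can be captured through other carriers.

The accepted marginal gains are non-increasing (weighted coverage is
monotone submodular); this is asserted on every run, as is copy-count
conservation after every library build.

## Key-ancestors baseline

The expected contribution of an ancestor to a reference set (default: the
youngest generation) is the probability that a gene copy in a reference
individual, traced upward choosing sire or dam with probability 1/2 at each
step, passes through that ancestor. Greedy selection uses *marginal*
contributions: a lineage path is credited to a candidate only if it avoids
all previously selected ancestors everywhere along its length — below the
candidate (the gene is already explained by a younger selected carrier) and
above it (the gene descends from an older selected ancestor). Under this
first-hit capture semantics the cumulative marginals are a capture
probability and cannot exceed 1. The recursion is validated against a
gene-dropping Monte-Carlo oracle and an exhaustive path-enumeration oracle
in the test suite.

## Budget allocation

**Cost model.** Sequencing an individual to target coverage c given prior
coverage c₀ and library flag ℓ costs `(1−ℓ)·library_cost +
per_x_cost·(c−c₀)` when c > c₀ and nothing otherwise. Defaults are £40 per
library and £85 per 1x. Coverages live on physical individuals: an ancestor
shared by several focal families is assigned the maximum coverage requested
for it and paid once, while its coverage feeds the phasing accuracy of every
family containing it.

**Accuracy surrogate.** The expected accuracy φ of phasing a focal
individual's haplotypes at the sequence level, given the family's seven
coverages, is supplied by a pluggable model. The default is the saturating
form

    φ = s(c_focal) · (0.5 + 0.3·s(c_sire + c_dam) + 0.2·s(Σ c_grandparents)),
    s(c) = 1 − e^(−c/5),

clipped to [0, 1]. It encodes the qualitative behaviour of family-based
phasing — φ = 0 without focal data, monotone non-decreasing in every
member's coverage, diminishing returns above ~10x, parents worth more than
grandparents — but its absolute scale is a modelling choice, not a
calibration. Any empirical table (CSV mapping the 7 coverages to φ) can be
substituted, and all tests that depend on exact φ values use explicit
tables. Consequently the package reproduces *orderings* (more budget ⇒ more
phased; heavier families attract more coverage) rather than any particular
phased percentage.

**Objective and search.** The goodness of a combination of scenarios is
G = Σ_f p_f·φ_f − λ·max(0, cost − budget)/budget with λ = 10: the penalty is
strong but finite so the search can traverse infeasible regions. The search
is rand/1/bin differential evolution (population 50, F = 0.8, CR = 0.9,
10,000 rounds by default) over one real-valued logit per (individual,
coverage level). During the search, scenarios are drawn from each member's
softmax probabilities (stochastic decoding keeps the representation smooth);
an elitist best-so-far solution is tracked under deterministic argmax
decoding and never lost, making the reported objective non-decreasing across
rounds (asserted). If the final elite exceeds the budget, a greedy repair
decrements, one step at a time, the member whose decrement loses the least
Σ_f p_f·Δφ (ties resolved towards the larger saving) until the assignment is
feasible; the all-zero assignment is always feasible and triggers a warning
when it is the best available. All families are optimised jointly in one DE
run. With the default 6 coverage levels a single family has 6⁷ = 279,936
possible scenarios (a published figure of 281,728 for the same setting does
not match the combinatorial count; `count_scenarios` reports the latter).

## Population simulator

The simulator emulates a closed livestock nucleus. Base haplotypes are
generated directly from per-marker allele frequencies drawn
Uniform(0.05, 0.95) with i.i.d. Bernoulli alleles, resampling fixed markers
— a deliberately crude neutral stand-in for a coalescent history. The
selection and allocation algorithms consume only phased SNP panels; linkage
structure *within* base haplotypes is destroyed by a few generations of gene
dropping, and none of the package's guarantees depend on it. The frequency
distribution is configurable for users who want site-frequency spectra
closer to sequence data.

Defaults: 10 chromosomes of 1 Morgan, 1000 SNPs each, 1000 base haplotypes,
1000 individuals per generation with an exact 500/500 sex split (alternating
assignment), the 25 highest-TBV males as sires, all 500 females as dams, and
10,000 QTN spread equally across chromosomes with effects ~ N(0, 1/n_qtn);
TBV is the additive dosage sum (no dominance or epistasis). Founders draw
two base haplotypes per chromosome without replacement within an individual
(with replacement across individuals); later generations draw sire and dam
uniformly with replacement from the selected sets — the mating allocation
and litter structure of real programmes are not modelled. Gametes recombine
with crossover counts ~ Poisson(chromosome length in Morgans) and uniform
crossover positions (Haldane, no interference); markers sit at evenly spaced
genetic positions. The panel is fully phased by construction, so
missing-data behaviour is exercised with separately constructed panels in
the tests. An "unrelated" mode draws both chromosomes of each individual
independently from the base pool with all parents unknown.

What the simulator does *not* emulate: coalescent linkage disequilibrium and
realistic site-frequency spectra, mutation, overlapping generations,
non-random mating, genotyping error, and imperfect phasing of real array
data. Tests passing on this test-bed show the algorithms' internal
correctness and the direction of structural effects (relatedness, pedigree
depth, budget size), not the absolute coverage or phasing percentages to
expect on a specific real population.

## Problem sizes and numerics

The test suite runs reduced problem sizes chosen as the smallest that leave
the qualitative effects unambiguous: replicated studies use 200 individuals
per generation on 2 chromosomes (1000 SNPs, 250-SNP windows, 5 replicate
seeds), with the sire count kept at the full-population value of 25 — scaling
sires down proportionally makes a handful of sires dominate transmission,
and the resulting drift collapses deep-pedigree diversity and inverts the
depth ordering that larger populations show. The DE-oracle check uses two
disjoint families over a binary coverage set against exhaustive enumeration
of all 2¹⁴ assignments, with 1,500 DE rounds. Structural bookkeeping (e.g.
the 31,000-record 30-generation pedigree) is verified at full population
size with reduced marker counts.

Floating-point notes: copy counts and greedy scores are integers carried in
float64 (exact far beyond the sizes used); DE objective comparisons use
exact elitist inequalities, and the brute-force equivalence is asserted to
1e-9. All randomness flows from explicit `numpy.random.Generator` seeds;
every stage is bit-reproducible for a fixed seed, which the suite asserts.

## Known limitations

- Algorithm 2 requires a pedigree; panels without parentage can only be
  ranked, not budgeted (the pipeline raises a named error).
- The default accuracy surrogate is uncalibrated; absolute objective values
  are only comparable across runs sharing an accuracy model.
- Greedy selection is near-optimal for the coverage objective but not
  exact; the oracle tests certify per-step optimality of marginals, not
  global optimality of the set.
- The DE search is stochastic; on large instances different seeds can return
  allocations of slightly different quality (the elitist objective bounds
  the regret from below monotonically in rounds).
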