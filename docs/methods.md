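# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `capmap`, and what the simulator does and does not emulate.

## Population and meiosis model

The population is the progeny of a single selfed heterozygous diploid, so
every marker segregates like an F2 intercross locus: genotypes AA : AB : BB
at 1 : 2 : 1. Meioses follow the Haldane (no-interference) model — the
number of crossovers on a chromosome of genetic length *L* cM is Poisson
with mean *L*/100 and breakpoint positions are uniform. Each offspring is
the fusion of two independent gametes. Consequences used throughout:

* the recombination fraction between loci *d* cM apart is
  r = (1 − e^(−2d/100))/2, and d = −50 ln(1 − 2r);
* two gametes are independently recombinant, so the joint genotype table
  at two loci is the two-gamete convolution, and an individual carries
  0, 1 or 2 recombinant gametes per interval;
* the expected number of obligate crossovers per individual over a genome
  of total length L is at most 2L/100, approached from below as marker
  density grows (simultaneous events inside one interval are hidden).

Interference models (e.g. chi-square/gamma) are out of scope; the entire
pipeline, simulator included, is internally consistent under Haldane.

## Simulator

`simulate.SimConfig` defaults are the study conditions of the apple-mint
capture experiment: 12 chromosomes with genetic lengths
(87.65, 89.48, 63.96, 77.20, 66.11, 122.61, 84.09, 58.26, 56.32, 92.64,
57.72, 86.14) cM, n = 415 individuals, mean on-target depth 96X, ~3%
missing cells, sequencing-error rate 0.001.

* **Phase.** Every marker is heterozygous in the parent; which haplotype
  carries the A allele is drawn uniformly per marker. Gametes are
  simulated in haplotype space and converted to genotypes through the
  phase vector, so flipping the phase of any marker subset complements
  exactly those markers' calls — the invariance the mirror-phasing stage
  is tested against.
* **Depth.** Negative binomial with shape k = 48 at mean 96, giving
  variance ≈ 3× the mean — a long right tail qualitatively matching deep
  capture data. The exact tail shape of real capture coverage is not
  modelled.
* **Reads.** Per cell, "other" (non-parental) base calls are
  Binomial(depth, e); the remaining parental reads split with allele-A
  probability 1−e, ½, e for true genotypes AA, AB, BB. The hierarchy
  guarantees count_a + count_b + count_other = depth, the table invariant.
  A `missing_rate` fraction of cells is zeroed.
* **Selection.** Rejection sampling at a locus snapped to the nearest
  marker (allele identity is defined by the recorded phase at markers).
  `zygotic` rejects zygotes carrying a disfavoured genotype with
  probability 1 − strength; `gametic_one_sex` subjects only the first
  gamete of each fusion to the allele test; `gametic_both` subjects both.
  After 10,000 rejections for one individual a `SimulationError` is
  raised (reachable only with contradictory specs).
* **Seeding.** One master seed; independent streams per purpose, and per
  individual, derived via `SeedSequence((seed, stream, index))`, so
  increasing `n_individuals` never reshuffles earlier individuals.
* **Physical coordinates.** Synthetic bp positions come from a monotone
  piecewise-linear cM→bp map in which the central 20% of the genetic
  length occupies 50% of the physical length (a recombination coldspot,
  emulating the sigmoidal Marey shape of heterochromatic chromosome
  cores); slope parameters are configurable. Real assemblies also contain
  inversions, translocations and unplaced contigs, which the simulator
  does not generate — the Marey diagnostics are therefore tested on
  constructed fixtures as well.

What passing simulator-based tests shows: the estimators recover the
truth under the stated generative model. What it does not show: behaviour
under model misspecification (interference, allele-specific capture bias,
contamination, paralogous mis-mapping), which real data may exhibit.

## Genotype calling

Boundary semantics: the depth window [20, 1000] is inclusive; "minor
fraction below 5%" is strict (<); "both alleles at least 30%" is
inclusive (≥). Allele fractions are computed over parental reads only
(count_a + count_b); "other" reads count toward depth for the coverage
test but not toward the fraction rules, which makes homozygote calls
robust to sequencing error. Cells with in-range depth but zero parental
reads are missing. A marker is kept only if ≥ 80% of individuals have
in-range depth (`marker_cov_fraction`, configurable).

## Quality cascade

Order: individuals (≥ 3500 typed markers) → markers (≥ 300 typed
individuals) → duplicate individuals (pairs ≥ 90% similar; the member
with more missing data is removed, ties to the larger id; clusters are
whittled greedily by descending similarity) → excess-heterozygosity
markers (> 90% H strictly) → redundancy collapse. Two markers "match"
when they agree at every individual typed in both and share at least one
typed individual; requiring a shared individual prevents vacuous matches
from merging unrelated markers. The match relation is not transitive, so
redundancy groups are its union–find closure — a stated approximation;
the survivor is the member with the fewest missing calls (ties to the
smallest id). All filters are idempotent and report removals. The fixed
3500 threshold can be replaced by `suggest_individual_threshold`, a Tukey
lower fence (Q1 − 1.5·IQR) on the typed-marker distribution, since outlier
scans are dataset-specific.

Scale caveat: the 90% duplicate-similarity rule assumes thousands of
markers over many chromosomes. On very small simulated genomes (tens of
markers) ordinary sibs can exceed it by chance; small-scale end-to-end
tests therefore raise the threshold rather than exercise that filter.

## Two-point EM

For each pair, the 3×3 joint genotype counts are cross-tabulated over
co-typed individuals. The number of recombinant gametes per individual is
deterministic in every cell except the double heterozygote, where it is 0
or 2 with posterior expectation 2r²/((1−r)² + r²). EM iterates expected
recombinant gametes / (2n) from r₀ = 0.25 until |Δr| < 10⁻¹², capped at
1000 iterations, clamped to [0, ½]. LOD compares log₁₀ likelihood at r̂
with independence. Estimates above ½ (phase-reversed linkage) clamp to ½
with LOD ≈ 0 — by design, since the mirror twin then carries the true
linkage. Pairs with fewer than 20 co-typed individuals are reported as
missing (unstable estimates; threshold configurable). The all-pairs loop
is exact (vectorised over the nine cell-count matrices, no sampling) and
optionally chunks across a thread pool.

## Grouping and mirror-pair resolution

Markers are linked iff rf ≤ max_rf AND LOD ≥ min_lod (the conjunction is
the conservative reading of naming both thresholds, and matches common
tool behaviour); linkage groups are connected components. Mirror pairing
matches each group's marker set against the mirror image of another's; a
group containing a marker and its own mirror raises a phase-inconsistency
error naming the markers. From each pair, the group containing the
lexicographically smallest original marker id is retained — a
deterministic stand-in for an arbitrary choice. Pairs smaller than
`min_group_size` (default 8, from the observation that stray groups had at
most 7 markers) are dropped; with `expected_chromosomes` set, only the
largest that many pairs are kept. Retained mirror ids have their suffix
stripped: the complementary calls *are* the phase assignment.

## Ordering

Obligate crossovers: over ordered gamete-pair states, the transition cost
is the Hamming distance; it is bounded below by |Δg| of the genotype codes
(0/1/2 = number of B alleles), and a state path achieving |Δg| at every
step always exists, so the per-individual minimum is the sum of |Δg| over
consecutive non-missing calls. The implementation uses this closed form;
tests verify it against exhaustive enumeration over gamete configurations
for every call sequence of length 8.

The seriation start chains markers greedily by Haldane-transformed
two-point distances (closest pair first, then cheapest insertion;
deterministic ties). The ripple pass slides a window (default 7, hard cap
8: 7! = 5040 permutations are enumerated exhaustively per position) and
adopts a strictly better arrangement, choosing uniformly among tied
*improvements* with the run's seeded RNG. Adopting equal-cost
permutations at random would never terminate under a repeat-until-no-
improvement loop, so equal-cost rearrangements are left in place; the
repeated-runs protocol restores the intended stochastic exploration: each
of `n_runs` (default 9) runs replays the search with a different
tie-break stream, and the winner is the order with the highest multipoint
log-likelihood. Visual heat-map inspection of rf/LOD matrices is replaced
by this likelihood criterion; the rf/LOD table is still exported for
optional human review. Orientation is normalised so the majority
scaffold's physical positions increase along the map (metadata
available), else so the first marker id is lexicographically smaller than
the last — some orientation convention is needed and none is canonical.

## Multipoint map EM

Hidden states are the true genotypes {AA, AB, BB} with stationary prior
(¼, ½, ¼). Interval transitions derive from one-gamete recombination:
AA→(AA, AB, BB) = ((1−r)², 2r(1−r), r²) and
AB→AB = (1−r)² + r². Observed calls are emitted with probability 1−ε for
the true class and ε/2 for each other class (ε = `error_prob`, default
10⁻⁴); missing calls emit 1 (uninformative), the standard treatment.
Scaled forward–backward recursions yield per-interval expected
recombinant-gamete counts; the M-step divides by 2n. Interval fractions
are initialised from adjacent two-point estimates (clipped to
[10⁻⁶, 0.49]), which typically converges within tens of iterations;
stopping rule max|Δr| < 10⁻⁹, cap 500 iterations, fractions clipped to
[0, ½). A non-positive forward normaliser (possible only with ε = 0 and
contradictory data) raises an error naming the interval. Positions
accumulate from 0 at each group's first marker via the Haldane function.
The per-iteration log₁₀ likelihood trajectory is recorded and asserted
non-decreasing in tests.

## Diagnostics

Distortion is a χ² goodness-of-fit against 1:2:1 on non-missing counts
(df = 2, no continuity correction — the standard three-class test), with
Bonferroni threshold α / n over the final marker count; markers are
flagged, never auto-removed, because distorted regions can span large
genuine segments of the genome. The crossover screen reports per-
individual obligate totals across groups and only flags (never removes)
individuals outside optional bounds. Marey diagnostics report, per group,
the majority scaffold, counts of markers from other scaffolds and
unintegrated contigs, the absolute Spearman correlation of cM with bp on
the majority scaffold, and the longest anti-monotone marker run — a crude
inversion proxy standing in for visual inspection.

## Problem sizes in tests

The library defaults are full scale (12 chromosomes, n = 415, window 7,
9 ordering runs). The test suite uses smaller instances chosen so each
property is still informative: three-chromosome populations (n = 200) for
phasing and diagnostics; single 100 cM chromosomes with 50 markers and
n = 415 for ordering and length recovery (2 ordering runs — on clean data
the runs differ only through tie-breaks and converge to the same order);
the full 12-chromosome, 600-marker configuration for linkage-group
recovery. Monte-Carlo tolerances are set at 3 standard errors of the
statistic under the generative model.

## Known limitations

* No crossover interference; maps from organisms with strong interference
  will show slightly different multilocus probabilities than modelled.
* The HMM error model is symmetric and shared across markers; real
  capture data shows marker-specific error (e.g. allele-specific capture
  bias) that is not modelled.
* Mirror-pair resolution assumes clean complementarity; heavily distorted
  markers can in principle split a chromosome's groups asymmetrically, in
  which case the affected pair is reported as orphans rather than forced.
* The greedy seriation + windowed ripple is a local search; with very
  sparse or noisy data it can settle on locally optimal orders, which is
  why multiple seeded runs and the likelihood comparison exist.
* `read_vcf_allele_depths` matches sites by contig + position only and
  takes allele depths at face value; upstream normalisation (splitting
  multi-allelic records, left-alignment) is the caller's responsibility.
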