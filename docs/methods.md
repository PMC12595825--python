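# Methods

This note documents the statistical models implemented in `ystrpop`, the
conventions and defaults chosen where several were defensible, and the
limits of what the synthetic-data tests demonstrate.

## Marker conventions and preprocessing

All analyses operate on integer repeat counts over the 17-locus Yfiler
panel (or the 27-locus Yfiler Plus superset, intersected down to the 17
shared markers when datasets are merged). Two markers need special
handling:

- **DYS385a/b** is constitutively duplicated: two alleles per man with no
  physical a/b assignment. For distance computations the pair is sorted
  ascending within each individual, removing the arbitrary labelling; for
  networks and rho dating the pair is excluded outright, since an
  unphased two-allele marker has no single-copy mutational interpretation.
- **DYS389II** physically contains DYS389I, so the two reported alleles
  are not independent. Prediction uses DYS389II as reported (the sum
  convention of the allele-frequency tables); networks and rho replace it
  with DYS389II − DYS389I, restoring an independent single-copy unit. A
  reported DYS389II below DYS389I is rejected as an impossible genotype.

Intermediate alleles (e.g. 13.2) are rounded to the nearest integer,
halves away from zero — the convention is explicit because the usual
phrasing "nearest integer" leaves 13.5 ambiguous. Missing alleles (code
`99`, empty cells) propagate through every derived quantity; downstream
statistics use pairwise deletion (a locus is dropped only for the
comparisons in which it is missing), which preserves sample size and
matches common practice for Arlequin-style analyses.

## Haplogroup prediction

The predictor is a naive-Bayes classifier over per-(haplogroup, locus)
allele frequencies: with equal priors by default,

posterior(g) ∝ prior(g) · Π over non-missing loci f(a_l | g, l).

Frequency tables are trained from labelled reference haplotypes with
additive smoothing (pseudocount 5 × 10⁻⁴ per allele, support = observed
range ± 2 repeats) so one unseen allele cannot veto a haplogroup; when
smoothing is disabled the support shrinks to the observed alleles. A call
requires the top posterior to reach the threshold (default 0.85) without
an exact tie. A fitness score — the mean log10 per-locus likelihood — is
reported per haplogroup as a goodness-of-fit diagnostic; the fitness
filter is disabled by default (a floor of 0 is also interpreted as
"disabled", matching the reference predictor's conventional setting,
since a mean log-frequency is never positive). The published predictor's
proprietary training tables are not bundled; tables are trained from
user-supplied references or loaded from TSV.

## Diversity and the distinct-haplogroup test

Nei's haplotype diversity HD = n/(n−1)(1 − Σ p_i²) with haplotypes
compared as full allele vectors; a haplotype containing a missing allele
matches nothing and counts as its own singleton class (the conservative
choice — it can only inflate k, never merge classes). Confidence
intervals are percentile bootstrap over individuals (default 10,000
replicates), chosen over BCa for seed-exact reproducibility.

The distinct-haplogroup permutation test draws |focal| labels without
replacement from the pooled label multiset per permutation — a
rarefaction-style null that respects unequal sample sizes, which dominate
distinct-count statistics. The p-value is two-sided,
2·min(P(≥obs), P(≤obs)) capped at 1, with the (b+1)/(B+1) correction.

## R_ST, AMOVA, and migration rates

Under the stepwise mutation model the molecular distance between
haplotypes is the squared repeat difference summed over loci. AMOVA uses
the distance formulation — SS(set) = Σ pairs d/|set| — and the standard
moment equations with unequal-size coefficients (n₀-style for one level;
n₁, n₂, n₃ for the nested groups/populations design). Negative variance
components are reported as computed and floored at zero only when
percentages are formed, keeping the printed-percentage convention while
preserving the diagnostic sign. Permutation schemes: Φ_ST permutes
individuals among populations, Φ_CT whole populations among groups, Φ_SC
individuals among populations within groups; all p-values carry the +1
correction.

Pairwise R_ST is exactly the two-population Φ_ST and shares the AMOVA
code path (verified to 1e−12 in tests, and against a brute-force
moment-equation oracle to 1e−10). Pair significance permutes individuals
between the two populations only, vectorised so 10⁴ permutations per pair
are cheap.

Migrant numbers use the haploid equilibrium island-model estimator
M = (1 − R_ST)/(2 R_ST). Non-positive R_ST maps to +∞ rather than being
clamped, so near-panmictic regimes (M > 40) stay visible; R_ST = 1 maps
to M = 0. Negative R_ST values are preserved in matrices but treated as 0
for MDS embedding and threshold comparisons.

Nonmetric MDS runs SMACOF (scikit-learn) from 20 seeded restarts
(convergence tolerance 1e−6, 500 iterations); the reported stress is
Kruskal's stress-1 recomputed from the final configuration by isotonic
regression on the dissimilarity order, so it is well-defined regardless
of optimiser internals.

## Median-joining networks

Locus weights are integers 1–10, inverse to allelic variance:
w = round(1 + 9(v⁻¹ − v_max⁻¹)/(v_min⁻¹ − v_max⁻¹)); zero-variance loci
get 10, all-equal variances give the midpoint 5. The network alternates
(1) the ε-relaxed minimum spanning network over the current node set —
an edge is kept iff its weighted length is within ε of the minimax path
weight, which at ε = 0 is exactly the union of all minimum spanning
trees — with (2) addition of component-wise medians of connected
triplets (the middle value of three integers, the natural multistate
generalisation) whenever inclusion strictly lowers the minimum spanning
cost. Since costs are positive integers the iteration terminates. ε
defaults to 0 and is exposed as a flag.

Maximum-parsimony pruning keeps only median nodes appearing in some
inclusion-minimal median subset that achieves the minimum spanning cost
over the observed haplotypes — exact by subset enumeration up to 12
medians, greedy single-removal elimination beyond. Pruning never
increases cost and is idempotent. Samples with a missing allele at a
retained locus are excluded (not imputed) with a warning; a seeded
per-population subsampling option (e.g. cap 20) is available for large
reference panels. Tests verify the constructions against longhand Prim
MST and exhaustive Steiner-point enumeration oracles on small toys; on
larger inputs only the cost bounds (≤ observed-MST cost, ≥ enumerated
optimum) are guaranteed, not global Steiner optimality — the
median-joining heuristic inherits that limitation by design.

## Rho dating

ρ is the mean over individuals of Σ_l |a_il − root_l|; the root defaults
to the per-locus modal haplotype (ties to the smaller allele), and an
explicit root can be supplied. Two conversions to time:

- **median rate**: T = ρ/(L·μ) with μ = 2.5 × 10⁻³
  mutations/locus/generation, the median of pedigree-based Y-STR rates;
- **per-locus (weighted rho)**: each locus's steps are divided by its own
  pedigree rate before averaging, T = mean_i (1/L) Σ_l |Δ_il|/μ_l. With
  uniform rates the two agree to machine precision.

Standard errors use the star-genealogy approximation σ(ρ) = √(ρ/N)
propagated through the same conversion; correlated genealogies make this
an underestimate, a known limitation since the pipeline does not infer
tree structure. Generation time defaults to 30 years (configurable).
Estimates are compared by their separation in pooled-SD units and ±1 SD
interval overlap.

**Saturation correction.** The linear clock assumes E[ρ] = T·L·μ, valid
only while T·μ per locus is small. Under strict single-step mutation the
number of hits per locus is Poisson(Tμ) and the expected net displacement
E|D|(T) = Σ_m P(m) · m·2^(1−m)·C(m−1, ⌊(m−1)/2⌋) falls below Tμ as back
mutations cancel (≈ 20% by Tμ = 0.5). `correct_saturation=True` inverts
E|D| numerically (Brent), with the SE mapped through the local slope.
At Tμ ≲ 0.05 the corrected and linear clocks agree to ~2%; at depth 200
generations with μ = 2.5 × 10⁻³ the linear clock under-recovers truth by
~40 generations while the corrected clock is unbiased — the recovery
tests therefore use the corrected mode, and the linear mode remains the
default for comparability with conventional rho dating.

## The simulator

Forward-time haploid Wright–Fisher reproduction with strict single-step
mutation (probability μ per locus per generation of ±1 repeat, optional
reflecting bounds), chosen over a coalescent engine for direct control of
admixture pulses and per-individual truth labels; msprime remains
available as an external cross-check. Internally all 17 panel markers are
independent mutating units; DYS389II is emitted as DYS389I plus its own
unit so the containment invariant holds and the network/rho view recovers
15 independent rate-μ loci.

Five demographic topologies are provided: panmixia; an east→west chain
with unidirectional stepping-stone migration; divergence from a common
ancestor; divergence with ongoing unidirectional migration; and
divergence with bidirectional migration. Admixture pulses replace a
fraction of a target deme with copies from a HOST deme whose founder is
offset by the exact single-step displacement law at 2,000 generations of
divergence — deep enough that HOST lineage labels are unambiguous,
emulating introgression of host-population lineages (an R1b-like signal)
into a founder population. Realised migrant counts, founder depths and
per-individual lineage labels are recorded as truth.

Preset defaults: five Iberian regional demes (Centre/North/South/West/
East) of N = 250 with splits 20 generations back (~600 years at 30
years/generation, the documented span of Roma presence in Iberia), chain
migration 0.02/individual/generation; a continental Greece → Romania →
Slovakia → Spain chain with 35-generation depth. Ancestral burn-in is 500
generations from a monomorphic founder, which at N·μ ≈ 0.6 per locus
yields realistic Y-STR diversity (HD ≈ 0.9 within demes).

What the simulator does *not* emulate: multi-step mutation tails, rate
heterogeneity across loci (all units share μ unless bounds are set),
population growth, and SNP-defined haplogroup structure — simulated
"haplogroups" are founder-lineage labels. Passing recovery tests
therefore demonstrate estimator correctness under the stepwise model the
statistics themselves assume, not robustness to real-data violations of
it.

## Problem sizes in tests

The bundled tests and the acceptance script run entirely on synthetic
data generated at run time: diversity/AMOVA oracles on ≤ 12-individual
toys; network oracles on 5-haplotype, 3-locus toys (100 random
instances); TMRCA recovery on 50 star replicates of n = 200 at depth 200;
permutation-test calibration on 200 panmictic replicates of n = 100 with
999 permutations; divergence monotonicity on a {20, 50, 200}-generation
grid with 20 seeds per depth. Production defaults (10,000 permutations /
bootstrap replicates) are used when the CLI runs real analyses.
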