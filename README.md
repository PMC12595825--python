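# ystrpop

Population-genetic analysis of paternal lineages from Y-chromosome short
tandem repeats (Y-STRs), built for studies of strongly drifted, substructured
populations — founder effects, regional isolation, and admixture with a host
population — of the kind seen in Roma (and other diaspora) Y-chromosome
datasets.

A Y-STR haplotype is the vector of repeat counts over a forensic marker
panel (the 17-locus Yfiler set, optionally its 27-locus superset). From
tables of such haplotypes the package computes:

- **Haplogroup prediction** — a naive-Bayes classifier over per-haplogroup
  allele frequency tables: posterior(g) ∝ prior(g) · Π_l f(a_l | g, l),
  with a posterior-probability call threshold (default 0.85, equal priors).
- **Diversity** — Nei's haplotype diversity HD = n/(n−1)·(1 − Σ p_i²) with
  a percentile bootstrap CI, and a permutation test for distinct-haplogroup
  counts.
- **Differentiation** — Slatkin's R_ST under the stepwise mutation model
  (Φ statistics on squared repeat differences), pairwise with permutation
  p-values; one- and two-level AMOVA with unequal-size variance
  components; island-model migrant numbers M = (1 − R_ST)/(2 R_ST);
  nonmetric MDS embeddings (Kruskal stress-1).
- **Networks** — weighted median-joining networks with locus weights 1–10
  inverse to STR variance and maximum-parsimony pruning of median nodes.
- **Dating** — rho-based TMRCA: ρ is the mean mutational distance to a
  founder haplotype, converted to time by per-locus pedigree rates or a
  median rate of 2.5 × 10⁻³ mutations/locus/generation, with an optional
  exact back-mutation (saturation) correction.
- **Simulation** — a forward-time Wright–Fisher haploid simulator under
  strict single-step mutation, covering panmixia, east→west chain
  migration, divergence with and without ongoing gene flow, and admixture
  pulses from a deeply diverged host deme; every output carries truth
  labels for estimator validation.

## Worked example

```python
from ystrpop.simdata import scenario_library, simulate
from ystrpop.io import make_view, ViewMode
from ystrpop.distance import pairwise_rst, migration_rate
from ystrpop.amova import amova
from ystrpop.popstats import bootstrap_hd_ci
from ystrpop.rho_tmrca import tmrca

cfg = scenario_library()["iberia_divergence"]   # five regional demes
cfg.seed = 42
ds, truth = simulate(cfg)

view = make_view(ds, ViewMode.DISTANCE)
est = bootstrap_hd_ci(view, "East", replicates=1000, seed=42)
mat = pairwise_rst(view, permutations=999, seed=42)
M = migration_rate(mat)
print(amova(view, permutations=999, seed=42))
```

Output (seed 42):

```
East: n=50 k=22 HD=0.944 CI=(0.890, 0.949)
R_ST(East, West) = 0.0033  (p = 0.2930)
M(East, West) = 149.06 migrants/generation
AMOVA (POPS; 999 permutations, seed 42)
source                                df          SS      sigma2       %
Among populations                      4     86.6960      0.3254    5.68
Within populations                   245   1323.3800      5.4016   94.32
Phi_ST = 0.0568  (p = 0.0010)
East TMRCA: rho=5.020, 134 generations = 4016 +- 253 years
```

Reading this: the five demes diverged 20 generations ago without gene
flow, so a few percent of molecular variance sits among regions
(Φ_ST = 0.057, significant at p ≈ 0.001), while any single pair can still
be weakly differentiated (the East–West pair here is not significant and
converts to a large migrant number). The East TMRCA reaches far beyond
the 20-generation split because lineages coalesce in the ancestral deme —
the rho clock dates the haplotype cluster's common ancestor, not the
split.

## Command line

`ystrpop` exposes `simulate`, `predict`, `diversity`, `rst`, `amova`,
`mds`, `network`, `tmrca`, `export-arp` and `pipeline` (the full chain
plus a run manifest); each subcommand takes `--seed` and `--out`, and
every output file embeds the seed and settings that produced it.

```sh
ystrpop simulate --preset iberia_divergence --seed 1 --out sim.tsv
ystrpop pipeline --input sim.tsv --seed 1 --out runs/demo
```

### Network export schema

GraphML nodes carry `kind` (OBSERVED/MEDIAN), `vector` (comma-separated
alleles), `multiplicity`, and `populations` (`label:count;...`); edges
carry `steps` (`locus:steps;...` over mutated loci) and weighted `length`.

## Input format

Delimited text (TSV/CSV/semicolon, auto-detected) with columns `SampleID`,
`Population`, optional `Region` (Centre/North/South/West/East), then the
panel's locus columns. Missing alleles are coded `99` (or empty);
intermediate alleles like `13.2` are kept until the explicit rounding
step. Arlequin `.arp` export (haploid, DataType=MICROSAT) is provided for
interoperability.

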