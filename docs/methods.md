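# Methods

`tspoly` analyses the persistence of genetic variation across reproductively
isolated plant species — one outcrosser and two independently derived,
severely bottlenecked selfers — and scans for genomic regions where
interspecific allele sharing is too strong to be neutral, the footprint of
long-term balancing selection. This note documents the models, the
numerical choices, and what the synthetic data do and do not emulate.

## The coalescent simulator

The engine (`tspoly.simulate`) is a Hudson-style coalescent with
recombination. Lineages carry their true ancestral material as segment
lists with per-segment descendant counts; material that reaches its local
MRCA is retired, so the event loop and the mutation pass only touch
genealogy that can yield segregating sites. Events — coalescence within a
population, recombination, migration, allelic-class switching — compete as
exponential clocks between scheduled demographic events (population splits,
size-epoch boundaries, migration-epoch boundaries, the balancing time).
Mutations fall on edges as a Poisson process with rate `mu` per bp per
generation under infinite sites; continuous positions are discretised to
integer base pairs, with collisions re-drawn within the edge (and skipped
after 64 failed draws, which matters only at extreme densities).

Self-fertilisation is handled by the classical equilibrium rescaling
`F = sigma / (2 - sigma)`: effective size `N/(1+F)` and effective
recombination `r(1-F)`. Diploid individuals are formed afterwards
(`make_diploids`) by randomly pairing haplotypes within a population and,
with probability `F`, copying the first haplotype over the second
(instant-homozygosity approximation). Random pairing matters: pairing
haplotypes in sample order would correlate pair membership with allelic
class at a balanced locus and suppress Hardy–Weinberg heterozygosity in the
outcrosser.

Migration epochs are specified forward in time (`source -> dest`, fraction
`m` per generation); backward in time a lineage in `dest` jumps to
`source` at rate `m`.

### Balanced loci

An ancient balanced polymorphism is simulated as a structured coalescent
with two allelic classes around a focal site. Lineages coalesce only
within their class until `t_bal` generations ago (far above the deepest
species split), when the classes merge. A fragment created by
recombination re-attaches to a random background chromosome, drawing a new
class from the population's class frequency; fragments whose distance from
the focal site implies more than ~2 expected class switches before `t_bal`
(distance > `2/(r_eff * t_bal)`) are released from the constraint entirely
— the constraint is physically vacuous for them, and releasing them keeps
the ancestral recombination graph small. A class-diagnostic site is placed
at the focal position; sampled class counts are pinned to the configured
class frequency (at least one copy of each class per population).

## The synthetic study

`synthetic_study` builds a multi-window "genome" from independently
simulated 20 kb segments for all three species plus the two selfer-1
subpopulations (E/W). Defaults are chosen once to emulate the study
system at desk scale:

- **Demography** (`default_capsella_model`): outcrosser Ne 694,643 and old
  selfer Ne 14,643 (from four-fold diversity); young selfer founded 170,000
  generations ago through a bottleneck of 7 diploid founders (the top of
  the reported 2–14 effective chromosomes) lasting 10,000 generations;
  E/W subpopulation split 10,000 generations ago; old selfer diverged
  1.8 million generations ago; `mu = 7e-9`; `r = 3.6e-8`/bp/gen.
  Values the source system does not pin down were fixed once: young-selfer
  Ne 1e5 (E) and 5e4 (W), selfing rates 0.97 / 0.99, and bidirectional
  outcrosser–selfer migration `m = 1e-7`/generation from founding until the
  E/W split, then E-selfer → outcrosser only. The migration magnitude
  (~1.6% migrant ancestry) reflects the observed rarity of interspecific
  sharing (many western pairs without any IBD segment, modest D).
- **Scaling** (`scaled_capsella_model`, scale 300): sizes and times /300,
  `mu` ×300 (per-segment theta preserved), `r` kept at its per-bp value so
  the per-segment population recombination rate drops ~300-fold and
  genealogies stay small. Two quantities are deliberately not rescaled
  naively: the founder count stays 7 (it is a census of individuals), and
  the bottleneck duration is floored at 20 coalescent units because the
  full model spends ~1,400 units in the bottleneck — neutral retention of
  ancestral variation through it must remain essentially impossible, which
  is the premise of the analysis.
- **Panel**: 8 diploids per population group — enough for stable
  frequency-based statistics while keeping tens of thousands of simulated
  segments tractable. The pipeline itself has no dependence on this
  choice.
- **Balanced regions** emulate immunity-gene (NLR-like) clusters: a run of
  `balanced_span` windows (default 5, i.e. 100 kb — conservative next to
  the multi-hundred-kb Fst valleys the real candidate regions show), each
  window carrying its own balanced polymorphism with
  `t_bal = 5 x` the deepest split and class frequency 0.5. Linkage
  *between* windows is not modelled; each window is an independent
  segment. A single isolated balanced site structures the outcrosser only
  within ~`1/(r * t_bal)` of the focal position, which is why the cluster
  construction (multiple linked targets, as the source system itself
  suggests for its strongest signals) is the default.

What the generator does **not** emulate: sequencing error, depth and
concordance artefacts (those inputs are consumed if present but are not
synthesised), indels, gene conversion, linkage between windows, selection
other than the balanced-locus constraint, and population growth within
epochs. Passing tests therefore demonstrate the statistical machinery and
the qualitative signatures (diversity footprints, positive Tajima's D,
low interspecific Fst at balanced regions), not robustness to artefacts of
real resequencing data.

## Statistics

- Watterson's theta `S/(a_{n-1} L)`, pairwise diversity with the unbiased
  `n/(n-1)` factor, and Tajima's D with the standard 1989 constants
  (requiring n ≥ 4; NA when S = 0). Diversity statistics use seeded random
  haploidization of heterozygous genotypes, matching the genotype-level
  pipeline rather than genotype likelihoods.
- Fst is the Weir–Cockerham (1984) variance-components estimator on diploid
  genotypes, with heterozygosity terms; windows aggregate as a ratio of
  sums (the "weighted" convention). Monomorphic windows are NA; sites with
  fewer than two non-missing genotypes in any population are NA.
- dxy is the mean between-lineage pairwise difference per
  accessible-in-both site; the divergence-time estimator is net divergence
  `(dxy - pi_ancestral) / (2 mu)` with the contemporary outcrosser
  standing in for the ancestral population.
- LD is genotype-free `r^2` between haploidized alleles; distances are
  between site positions, same-position pairs excluded. The phase sign for
  the high-quality tsSNP filter is `D > 0` under derived-allele coding.

## The outlier scan

The null distribution of window Fst is built by simulating independent
20 kb segments under the neutral demographic model and pushing each through
the same diploid Fst computation as the observed windows. Each
non-overlapping 20 kb window gets a one-sided low-tail rank p-value
`(r+1)/(n+1)` (never exactly zero), Bonferroni-corrected over the tested
windows of its subpopulation comparison. Significant windows are collapsed
into candidate regions with a two-state Bernoulli HMM (Baum–Welch from a
fixed initialisation: stay probabilities 0.99, emissions 0.9/0.01, uniform
start; convergence at log-likelihood improvement < 1e-6 or 500 iterations;
Viterbi decoding with ties toward background; chromosome tracks reset the
state distribution). A region is a connected run of windows that are
Viterbi-balanced or significant and contains at least one significant
window: significant windows always seed a region and the HMM's role is to
bridge gaps between them. (A pure "Viterbi-balanced runs" rule would
discard isolated significant windows outright — under the fixed
initialisation one window's emission odds never outweigh the transition
penalty — which would contradict the purpose of the correction-then-join
procedure.) Regions must be supported in both selfer subpopulations;
overlapping supporters are unioned and merged transitively. The
conditional ("elevated founder diversity") test re-ranks each region's
most extreme member window against only the null segments whose outcrosser
diversity lies in the top 1%; it requires the subset to keep at least 100
segments.

## Other components

- **Classification**: sharing classes over sites accessible in all compared
  species; allele copies counted over non-missing calls. The high-quality
  three-way tsSNP filter iterates its circular in-phase-LD criterion to a
  fixed point; depth and concordance criteria are skipped with a warning
  when those channels are absent.
- **D statistics** use the frequency form (one focal diploid's derived
  dosage vs two population frequencies, outgroup fixed ancestral) with a
  *weighted* delete-one block jackknife (Busing-style): blocks carry very
  unequal ABBA+BABA information, and the unweighted jackknife materially
  underestimates the standard error. Blocks default to 1 Mb; synthetic
  tests aggregate simulated segments into blocks so each block carries
  usable information.
- **Joint SFS fitting** estimates the expected folded joint spectrum by
  simulating unlinked segments (common random numbers make the composite
  likelihood surface deterministic per seed), adds a 0.5 pseudo-count to
  empty polymorphic cells, and maximises the multinomial composite
  log-likelihood with bounded Nelder–Mead on log10 parameters from
  multiple seeded starts. Selfing individuals contribute one allele; sites
  with heterozygous or missing calls in a selfing panel are dropped
  ("complete information"). Folding flips a cell when the total minor
  count exceeds half, with a deterministic tie rule.
- **Haplogroups and trees**: single-linkage collapsing of marker haplotypes
  at Hamming distance ≤ 1 (threshold exposed); canonical neighbour joining
  with lexicographic tie-breaking, negative branch lengths clamped to zero
  with the deficit moved to the sister branch; Jukes–Cantor distances with
  NA at saturation (p ≥ 0.75). Windows with fewer than two informative
  sites yield no tree (we follow this rule rather than emitting a star
  tree, the one place two reasonable conventions conflict).

## Problem sizes

Test and acceptance runs use the scaled model throughout: null
distributions of 10,000 segments, genomes of 25–300 windows, 500–2,000
simulator calibration replicates, 50-replicate D-statistic panels of 200
unlinked 2 kb segments, and 10 two-parameter demographic refits at 10,000
accumulated segregating sites per likelihood evaluation. These sizes give
each check clear statistical resolution (rank p-values to 1e-4, binomial
bounds on calibration fractions) while an entire run stays in the
minutes range on one CPU.

## Known limitations

- The rescaled study preserves per-segment diversity and bottleneck
  completeness but not every dimensionless ratio (notably rho/theta is
  ~300x smaller than in the real system, widening selfer haplotype blocks;
  this is favourable for footprint visibility and is why the defaults are
  not claimed to reproduce the real study's power).
- The class-switch release distance `2/(r_eff t_bal)` is an approximation
  to the structured coalescent's continuous linkage decay.
- Window independence means no LD bleeds across window boundaries, so
  region edges are sharp in a way real data are not.
- `expected_sfs` ignores linkage within segments (composite likelihood);
  bootstrap CIs treat the fitted model as truth.
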