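# Methods

This note documents the models, conventions and numerical choices behind
`galliphylo`, and what the synthetic-data experiments can and cannot say
about real data.

## Topology algebra

Trees are compared through internal bipartitions (splits). A bipartition is
stored in canonical orientation — the side *not* containing the
lexicographically smallest taxon — and hashed on that frozen label set, so
split identity is orientation-free. The Robinson–Foulds distance is the raw
symmetric-difference count over internal splits, which is why all reported
RF values between fully binary trees are even; no normalization is applied.
The same plain symmetric difference is used when one or both trees contain
polytomies (consensus trees): a collapsed edge simply contributes no split.

Majority-rule consensus keeps exactly the splits with frequency strictly
greater than the threshold (default 0.5) and labels them with frequency ×
100; for thresholds ≥ 0.5 the retained splits are automatically mutually
compatible, and the tree is assembled by largest-clade-first refinement of
the star tree. Support values on newick internal labels are interpreted by
magnitude: ≤ 1 is a posterior probability, > 1 a bootstrap percentage.
Support-threshold collapsing contracts edges *strictly below* the threshold
(an edge at exactly 70% survives a 70% filter). Rooted newick input is
silently unrooted by fusing the two root edges.

## The data matrix

The matrix is complete by construction: every locus sampled for every
taxon. Incomplete input is an error, not a warning — completeness is a
design feature of the study system, eliminating missing-data artifacts, and
the code refuses to silently pad.

Site classification treats IUPAC ambiguity codes, `-` and `?` as missing: a
column is variable iff ≥ 2 distinct unambiguous states occur, and
parsimony-informative iff ≥ 2 states each occur in ≥ 2 taxa. An
`ambiguity='expand'` mode instead calls a column variable only when no
single state is compatible with every non-missing symbol. The default is
the simplest defensible convention and matches how sparse heterozygosity
codes should behave (a lone R in an otherwise-A column is not evidence of
variation). Percentages are rounded half-up to whole percent, matching
whole-percent reporting.

Coordinates are 0-based half-open internally; all user-facing partition and
exclusion files are 1-based inclusive (the common partition-file
convention). Exclusion masking preserves each surviving column's original
coordinate (`source_columns`), so provenance survives jackknifing too.

## Base-composition diagnostics

All three diagnostics default to variable sites only, where compositional
signal concentrates. The χ² test is the Pearson statistic on the taxa × 4
count table with df = (T−1)·3; bases with zero pooled count are dropped
with a df adjustment. The p-value is reported together with an explicit
caveat string: taxa are phylogenetically correlated, not independent draws,
which makes the test conservative — the test suite demonstrates this by
showing near-nominal rejection only when branches are long enough to
decorrelate the taxa. RCV is computed on counts with denominator (number of
taxa × mean counted sites per taxon); because the cited formulation is not
restated in most applications, a frequency-based variant is available
behind a flag (`on='frequencies'`), and count-based is the default. RCV
rankings flag the top ⌈k/4⌉ partitions, ties broken by partition name.

## Inference engine

The gene-tree engine is deliberately desk-scale. Full ML heuristic searches
of the kind production programs run are replaced by NJ + NNI hill climbing:
the experiments this package exists for compare trees and measure distances
between them, and do not depend on any particular search engine.

- **Distances.** p, JC and K80, skipping sites where either symbol is
  ambiguous or a gap. Saturated pairs (log arguments ≤ 0) are set to twice
  the largest finite distance in the matrix, with a warning.
- **Neighbor joining.** Classic Q criterion; among tied Q values the pair
  with the lexicographically smallest representative labels is joined,
  making the algorithm fully deterministic. Negative branch lengths are
  clamped to zero with the deficit moved to the sister edge.
- **Likelihood.** Felsenstein pruning over compressed site patterns.
  Transition matrices come from the spectral decomposition of the
  reversible rate matrix (symmetrized with π^½), which is much faster than
  a matrix exponential per call. Discrete-Γ uses 4 categories whose rates
  are the means of equal-probability quantile slices of Γ(α, 1/α).
  Ambiguity codes enter as partial likelihoods over their compatible
  states; gaps and `?` are uninformative (all-ones partials).
- **Model choice.** AIC = 2k − 2lnL on a fixed topology with fixed branch
  lengths (branch lengths are common to all candidates and excluded from
  k); candidates are the reduced set {JC, K80, HKY, GTR} × {+Γ, none}, with
  base frequencies taken as empirical (counted in k for HKY/GTR) and the
  remaining free parameters optimized by Nelder–Mead in log space. Ties go
  to the model with fewer parameters.
- **NNI search.** Steepest-ascent over all internal edges; each candidate
  rearrangement re-optimizes only the edge being rearranged (bounded Brent,
  tolerance 1e-6, lengths capped at 10), and the accepted move is followed
  by one full round of branch-length optimization. The final lnL is never
  below the start's.
- **Bootstrap.** Columns resampled with replacement to the original length;
  each replicate re-inferred by NJ (optionally NJ + NNI); fully determined
  by the seed, with provenance (locus, replicate, seed) on the sample.

## Species trees from gene trees

NJst averages topological internode distances (leaf-to-leaf edge counts)
over every sampled tree of every locus — trees weighted equally within a
locus, loci weighted equally across (a pooling flag weights all trees
equally instead, since published descriptions leave this open). The average
matrix goes through the same NJ implementation; output branch lengths are
internode-distance units, not substitutions, and are flagged as such. The
edge-count vs node-count convention is immaterial: the two differ by a
constant 1 on every pair, and NJ topology is invariant to constant shifts
(tested directly). Bootstrap samples or single best trees per locus are
both accepted; the three mitochondrial regions are always treated as the
single locus they biologically are.

Concordance factors use the naive two-level estimator: within-locus sample
frequency of a clade, then the unweighted mean across loci. This is the
no-pooling limit of hierarchical Bayesian concordance analysis, which is a
large independent method and out of scope here. A CF estimates the
proportion of sampled gene histories containing a clade and is *not* a
support value — the support-vs-concordance report exists precisely to flag
clades with strong support but low concordance (default flags: support ≥ 85
with CF < 0.5). The primary concordance tree adds clades greedily in
descending CF order (ties broken lexicographically on the clade's labels),
keeping each clade iff compatible with all already accepted.

## Jackknife experiments

"Jackknife" means sampling alignment columns *without* replacement to a
fixed size (a with-replacement switch exists for sensitivity checks). Sites
are sampled freely across locus boundaries; each sampled column's partition
identity is recorded. Only nuclear data enter the size series by default —
the mitochondrial genome is one finite, fast-evolving locus, so growing a
dataset in practice means adding nuclear sites — and non-nuclear partitions
are an error unless overridden. The default replicate-inference tag is
`nj-jc` (NJ on JC distances): the series needs hundreds of replicate
inferences and a likelihood-based search per replicate is beyond desk
scale; NJ + NNI is available in the method registry, and because the
experiment records its method tag, results are never compared across tags.
Per-replicate seeds derive from the design seed by the package-wide rule
(below), so any single replicate is reproducible in isolation.

The locus-vs-jackknife report compares a locus tree's RF to the reference
against the jackknife mean ± SD at the nearest size: beyond one SD is
"better/worse than average", and a locus with no jackknife size within a
factor of two of its length is flagged "no comparable size".

## Synthetic data

The generator emulates the study design it was built around: 46 taxa, 15
nuclear loci of the published aligned lengths (417–2007 bp) plus 3
mitochondrial regions (1041, 1143, 951 bp), a species tree with a handful
of very short internal branches, per-locus gene-tree discordance from
lineage sorting, faster and compositionally distinct mitochondrial
evolution, and sparse IUPAC heterozygosity codes.

- **Species trees** are random coalescent-shaped ultrametric trees in
  coalescent units. Radiations are imposed by shortening randomly chosen
  internal branches to a target length (default: 4 branches at 0.05 units),
  sliding the lower node up and compressing its subtree so ultrametricity
  is preserved; root-most chosen branches are processed first so later
  compressions cannot disturb already-set lengths.
- **Gene trees** come from msprime with one haploid lineage per species and
  population size 1 everywhere, so time is in coalescent units and
  discordance obeys coalescent theory — the rooted-triple law
  (2/3)·e^(−t) is a quantitative acceptance check. The three mitochondrial
  regions share one gene-tree draw, taken from the species tree with times
  scaled ×4 (default `mito_ne_factor`): the mitochondrion is haploid and
  maternally inherited, so its effective size is about a quarter of the
  nuclear one and its gene tree tracks the species tree more closely.
- **Sequences** evolve along gene trees under HKY+Γ by default (nuclear:
  κ=3, balanced composition, α=1; mitochondrial: κ=8, AT-rich/G-poor
  composition, α=0.4), via per-branch transition matrices with per-site
  discrete-Γ categories. The coalescent-to-substitution scale is a single
  per-class constant: 0.01 substitutions per coalescent unit for nuclear
  loci, and nuclear × rate-multiplier / ne-factor for mitochondrial
  regions, so the default multiplier of 5 yields five-fold faster
  per-generation mitochondrial evolution.
- **Heterozygosity codes**: `round(rate × cells)` random cells (default
  rate 0.002, hard cap 0.05) are replaced by the two-state code joining the
  current base and its transition partner (A/G → R, C/T → Y), emulating
  heterozygous calls, in nuclear loci only.
- **No indels** are simulated: hard-to-align regions are excluded from real
  analyses before inference, so the generator produces gap-free columns and
  instead emits a random exclusion mask (default 2% of columns) to exercise
  the masking machinery.

What passing tests on this generator do **not** show about real data: there
is no alignment error, no gene flow or recombination within loci, no
heterotachy or composition drift along branches, and locus gene trees are
exactly independent given the species tree. The generator validates the
*machinery* and the statistical behaviour that coalescent theory predicts;
it cannot certify robustness to systematic error.

## Seeds and determinism

Every stochastic component takes an explicit seed derived from one master
seed by `SeedSequence(master, spawn_key=path)` reduced to a uint32, where
`path` is a fixed tuple of small integers naming the stage, locus and
replicate. No component touches a global generator. Two pipeline runs from
the same configuration are byte-identical, which the test suite and the
acceptance script verify by hashing every output file.

## Problem sizes used in the shipped experiments

The test suite and acceptance script run the experiments at sizes chosen to
make their statistical claims testable in minutes on one core: rooted-triple
discordance at 10,000 gene trees per branch length; NJst recovery as 100
seeded runs of 200 gene trees on a 5-taxon species tree with internal
branches ≥ 1 coalescent unit; the jackknife series at sizes
{500, 2000, 8000} with 20 replicates per size on a full 46-taxon synthetic
matrix; and pipeline determinism on an 8-taxon configuration. The library
itself defaults to the study-scale settings (500 bootstrap replicates, the
11-size jackknife ladder at 100 replicates per size).

## Known limitations

- The likelihood stack optimizes branch lengths coordinate-wise (Brent per
  edge); there is no simultaneous Newton optimization, so very flat
  likelihood surfaces converge slowly.
- AIC model fits hold branch lengths fixed at their input values; model
  ranking is therefore conditional on those lengths.
- NJst branch lengths are not in substitution or coalescent units and must
  not be interpreted as divergence estimates.
- The χ² homogeneity p-value inherits the taxon non-independence problem;
  treat it as a ranking index across partitions, not a calibrated test.
- Concordance factors are the naive estimator; with few gene-tree samples
  per locus they are noisy, and no uncertainty interval is attached.
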