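# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of the package. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## The analysis problem

Given whole-genome data for individuals sampled across a recent radiation
of congeneric species — plus one or two focal individuals of uncertain
ancestry — the pipeline asks three coupled questions: do the focal
individuals cluster together in genotype space (PCA)? do they form a
monophyletic pair in a species tree built from many short genomic windows
(quartet consensus of gene trees)? and is their pairwise genetic distance,
once normalized for diversity, within the range seen between individuals
of one species (distance hierarchy)? Agreement across the three lines of
evidence supports a same-lineage assignment.

## Simulation model

The generator states its world explicitly; none of its defaults are
fitted to any analysis outcome.

* **Sequence evolution.** An ancestral sequence is drawn i.i.d. from the
  configured base composition (default uniform) and evolved down the
  rooted species tree under JC69: on a branch of length *t* (expected
  substitutions/site), each site changes with probability
  ¾(1 − e^(−4t/3)) to a uniformly chosen different base. JC69 was chosen
  over richer models deliberately: it keeps every calibration check a
  closed form (the tests verify realized divergence against
  ¾(1 − e^(−4t/3)) on the truth branch lengths).
* **Incomplete lineage sorting.** Each contig is tiled into recombination
  blocks (`ils_block_bp`, default 50 kb — the scale over which linkage
  keeps a single genealogy in a large-Ne radiation). Independently per
  block, with probability `p_ils` the species topology is replaced by one
  random nearest-neighbor interchange at a uniformly chosen internal edge
  before the block is evolved. This is a surrogate for the multispecies
  coalescent: it produces the operative phenomenon (a controllable
  fraction of windows whose gene tree conflicts with the species tree)
  with none of the coalescent's machinery, and the truth record stores
  each block's realized topology so discordance is exactly known.
  Extracted windows that straddle a block boundary see a mixture of two
  genealogies; at the default window (2 kb) and block (50 kb) scales this
  affects a few percent of windows and only adds realistic noise.
* **Heterozygosity.** Within a species, an individual's second haplotype
  differs from the first independently per site with probability θ
  (default 0.001; 0.0015 for the focal species, which the scenario casts
  as unusually diverse). This Bernoulli model reproduces the expectation
  and binomial spread of observed heterozygosity with minimal machinery;
  it does not model linkage between heterozygous sites or shared
  polymorphism between individuals, so within-species gene-tree structure
  is star-like. Consequences: within-species branch lengths are driven by
  θ alone, and the within-species normalized distance concentrates at 1
  (see below) — which is the baseline property the assignment logic needs.
* **Missing data.** Uncallable sites arrive in geometric runs (mean
  `missing_run_mean`, default 300 bp) alternating with geometric gaps
  whose support includes zero, so the stationary missing fraction equals
  `missing_rate` exactly and `run_mean = 1` degenerates to independent
  Bernoulli missingness (the tests verify both by a runs test and an
  independent Monte-Carlo oracle). This stands in for the patchy coverage
  of a degraded museum bone; no attempt is made to model ancient-DNA
  damage (deamination), which the real workflow handles upstream.
* **Genotype metadata.** Per-genotype depth is Poisson(20) and GQ is
  min(99, Poisson(45)), between the coverage levels typical of a museum
  specimen and a fresh blood sample; with these means the DP ≥ 6 and
  GQ ≥ 18 filters are exercised but rarely binding, mirroring a
  well-powered dataset. Masked genotypes are missing with DP = GQ = 0.
* **Pseudo-haploidization.** The real pipeline picks the base with the
  most reads at each site; at a balanced heterozygous site this is a coin
  toss. The simulator implements exactly the degenerate case — a seeded
  fair coin per heterozygous site — because without read-level simulation
  the majority rule has no other signal to follow.

## Windowing

Starts are drawn uniformly on [100000, min(1000000, contig_length − L)]
(integer, inclusive) to avoid starting near a potential telomere, then
segments tile at exactly L + G spacing; a final partial segment is
discarded so every alignment has identical length (the source procedure
continues "through the end of the contig" without defining the remainder;
discarding is our resolution and is flagged here). Contigs shorter than
100000 + L contribute nothing rather than resampling. Coordinates are
0-based half-open everywhere in memory and 1-based only inside VCF files.

## Alignment QC

The three statistics follow the standard alignment-summary definitions:
parsimony-informative columns need at least two distinct non-N states
each carried by at least two rows (N is never a state); missing fraction
is N cells over all cells; GC is computed over non-N cells only, so
missingness cannot leak into composition (an all-N alignment has
undefined GC and auto-fails). All three thresholds — PI > 5,
missing < 0.10, 0.30 < GC < 0.70 — are strict inequalities, read
literally from the protocol they reproduce.

## Gene trees and the quartet species tree

Maximum-likelihood gene-tree inference is deliberately replaced by
neighbor joining on JC69-corrected p-distances: it is deterministic,
desk-scale, and exact on additive matrices, which gives the test suite
hard oracles. Q-matrix ties break to the lowest (row, column) index;
negative branch-length estimates clamp to zero. Alignments with a
zero-overlap pair, a saturated distance (p ≥ 0.75), or no variation are
skipped with a logged reason. Externally computed gene trees can be
supplied as multi-line Newick via `trees.read_gene_trees`.

The species-tree criterion is the quartet score: the number of 4-leaf
subsets whose induced unrooted topology agrees between candidate and
gene tree, summed over gene trees; gene trees missing a leaf simply do
not vote on quartets they do not span. With ≤ 7 leaves all (2n−5)!!
topologies are scored; otherwise a greedy NNI hill climb starts from the
NJ tree of gene-tree-averaged path distances and stops at the first
local optimum (first improving neighbor is taken; candidate order is
deterministic). Branch support is the agreement fraction among quartets
with two leaves on each side of the branch. It is related to, but not
the same thing as, a coalescent local posterior probability: users
should not read it as a probability that the branch is true, only as a
direct measure of gene-tree conflict. A branch of a score-maximizing
tree keeps the plurality of its spanning quartets, so its support cannot
fall below 1/3 (asserted empirically in the tests). Trees are handled
unrooted throughout; any rooting (e.g. on an outgroup) is display only.

## Heterozygosity and the normalized distance

Observed heterozygosity is heterozygous callable genotypes over callable
genotypes, where callable requires DP ≥ 6 and GQ ≥ 18 ("quality above
17", read strictly). Because a variants-only VCF cannot carry invariant
sites, the caller passes `invariant_callable` — in the pipeline, the
callability-mask total minus the individual's callable variant sites —
so the denominator covers variant plus invariant callable sites, as in
the workflow this mirrors (config can set it to 0 for a variant-only
sensitivity check). The same VCF-derived mask underlies both the
heterozygosity denominator and the distance segments, keeping the two
halves of the normalized distance coupled to one callable-site
definition.

The distance averages per-window ratios a_i/S_i with equal weight (the
mean of ratios, not the ratio of sums — a property test pins this down)
and divides by (h₁ + h₂)/2. Windows with S_i = 0 carry no information
for the pair and are dropped from n (including them would divide by
zero); the drop is logged. Distances are computed on pseudo-haploid
sequences, matching the sequence-based pipeline, not on genotypes.

Why normalize: under the simulator's within-species model, two
conspecific pseudo-haploid sequences mismatch at rate ≈ θ (each is
heterozygous at ≈ θ of sites and the coin picks the minor allele half
the time, twice), and each individual's ĥ ≈ θ, so the normalized value
concentrates at 1 for any θ. Between species the numerator gains the
fixed divergence while the denominator stays at the diversity level, so
values separate by the divergence/diversity ratio.

### Assignment rule

The qualitative criterion "the focal distance is similar to
intraspecific differences" is formalized as: nearest lineage = argmin of
per-lineage mean focal distance; **same-lineage** when the focal's
minimum distance ≤ the q-quantile (default q = 0.95) of the
within-species reference distribution; **novel** when it exceeds every
within-species value and the margin to the second-nearest lineage is
positive; **ambiguous** otherwise. All criterion values are recorded in
the Assignment so the decision is reproducible from its own fields. A
caveat follows from exchangeability: when the focal individual truly is
conspecific, its distance is a draw from (approximately) the same
distribution as the reference values, so with a small reference panel
the q-quantile rule has an intrinsic ≈ (1−q)-scale chance of returning
"ambiguous" rather than "same-lineage". The packaged configuration
therefore carries 11 reference species × 3 individuals (33 within-species
pairs), and q is exposed in the config.

## Site filtering, LD pruning, PCA

Site filters: minor-allele count ≥ 1 (drops invariant/monomorphic
rows), zero missing genotypes, and mean depth within ±1 SD of the
across-site mean (computed over all input sites before any other
criterion). LD pruning slides a 50 kb (bp-span) window in steps of 5
kept variants; within a window, offending pairs (r² > 0.5, squared
Pearson correlation of dosages; a constant vector has r² ≡ 0) are
resolved by removing the lower-minor-allele-frequency member, ties to
the higher position. Pairs are examined in position order; since r²
between two fixed vectors never changes, compliant pairs are never
re-examined — provably equivalent to restarting the scan after each
removal, and orders of magnitude faster. Sweeps repeat until no window
removes anything, so the result is a fixed point and independent of
sample order. Exact parity with any external pruner's removal order is a
non-goal; the rule here is fully specified and deterministic.

PCA mean-centers each variant and scales by √(2p̂(1−p̂)) (the standard
genotype-PCA variance standardization; a flag switches to unit
variance), eigendecomposes via SVD of the sample × variant matrix,
orders axes by decreasing eigenvalue, and fixes each axis' sign so its
largest-magnitude variant loading is positive. Variance explained is
reported over all nonzero axes and sums to 100%. Missing dosages are
mean-imputed per variant for r² and PCA only — moot on the default path,
where the site filter has already removed them.

## Numerical and degenerate-input conventions

* JC69 correction raises a saturation error at p ≥ 0.75 rather than
  returning infinity.
* An all-N alignment raises for GC and fails QC; an alignment of
  identical rows is skipped before tree building (a star tree carries no
  topology).
* `pca` truncates k beyond the matrix rank with a warning; `site_filter`
  returns an empty matrix with a warning rather than raising.
* Zero callable sites, an empty within-species reference, or
  h₁ = h₂ = 0 are errors, not NaNs.
* Every stochastic step takes an explicit seed; identical config + seed
  reproduces every output file byte for byte (tested).

## Scaled-down defaults

The packaged configuration (12 species × 2–3 individuals, two 1.5 Mb
contigs, 2 kb windows with 8 kb gaps) is a desk-scale replica of a
genome-wide design whose real shape — 10/100 kb windows with 100 kb/1 Mb
gaps over a 2.2 Gb assembly — is a single-line config switch away but
would not run in test time. Sample counts per species (3, with 2 for the
focal species) mirror the motivating study's sampling design. The tests
that loop over 20 seeds use 1–2 Mb single-contig worlds for the same
reason; tolerances in those tests are 3-binomial-SD bands or majority
counts stated up front, not fitted.

## Known limitations

* No read-level simulation, indels, sequencing error, recombination
  within blocks, gene flow/hybridization, or aDNA damage; the generator
  emulates the statistical structure the analysis consumes, not the
  upstream bioinformatics.
* The NNI-block ILS surrogate cannot produce the full quartet-frequency
  spectrum of the multispecies coalescent (e.g. it never produces
  anomalous-zone geometries), so a green species-tree test shows the
  quartet machinery works under controlled discordance, not that the
  pipeline would resolve any empirical radiation.
* Quartet support is not a posterior probability (see above).
* Within-species genealogical structure is absent by construction, so
  the within-species distance distribution is tighter than real data,
  where demography adds spread; the assignment quantile q is exposed
  partly for this reason.
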