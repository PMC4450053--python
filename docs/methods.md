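# Methods

`gbgcscan` tests whether homologous recombination leaves a GC-enrichment
footprint — the signature of GC-biased gene conversion (gBGC) — in groups of
closely related bacterial genomes, and provides the population-genetic
machinery and a synthetic-data generator to interpret and validate that
analysis. This note records the model, the estimators, the default
parameters and the design choices that were genuinely open.

## Analysis model

A *genome group* is a set of at least six genomes whose pairwise distance
`1 - s` (one minus the mean best-hit identity) is below 0.15; groups are the
connected components (single linkage) of the thresholded distance graph.
The clustering rule is a package choice: single linkage is the simplest
reproducible rule consistent with "all members closer than the cutoff to at
least one other member"; complete linkage would give smaller, denser groups.

Within a group, the analysis uses *single-copy core families*: gene families
with exactly one member in every genome. Families are consumed as in-frame
nucleotide alignments and trimmed to their 900 central columns (families
shorter than 900 bp are set aside), so every recombination test sees the
same amount of alignment. With an odd surplus the extra discarded column
falls on the right; all internal coordinates are 0-based half-open.

## Recombination detection

Three site-pattern statistics share one site-permutation null. All of them
start from the *parsimony-informative* columns (>= 2 states, each carried by
>= 2 sequences; gaps, `N` and other ambiguity codes are missing data, and a
taxon missing at either site of a pair is dropped from that pair).

**Refined incompatibility.** For a pair of sites, the minimum number of
extra state changes (homoplasies) that the pair forces on *any* tree equals
the cycle rank `e - v + c` of their partition intersection graph (vertices:
observed states at either site; edges: observed joint states). For two
binary sites this is the four-gamete test. The implementation has a
vectorised binary fast path and a general multi-state path; both are checked
in the test suite against a brute-force oracle that enumerates every
unrooted topology and scores it by Fitch parsimony.

**PHI** is the mean refined incompatibility over informative-site pairs
whose distance in original alignment coordinates is at most the window
(default 100 bp; a rank-distance window over informative sites is available
as `window_unit='sites'`). Recombination makes nearby sites more congruent
than random pairs, so *low* observed values are significant.

**NSS** is the neighbour similarity score of the site-compatibility matrix:
for each adjacent pair of informative sites, the fraction of sites with
which the two members have the same compatibility status, averaged along the
sequence. This row-agreement form follows the original compatibility-matrix
formulation and has a much finer-grained permutation null than the plain
fraction of compatible adjacent pairs, which is retained as
`formulation='adjacent'`. High observed values are significant.

**MaxChi2** scans, for every sequence pair, candidate breakpoints along the
pair's variable sites and contrasts match/mismatch counts in windows of
`h = max(10, v/4)` variable sites either side of the breakpoint (capped at
`v/2`) with a 2x2 chi-squared without continuity correction; the statistic
is the maximum over pairs and breakpoints. The windowed scan is the default
because gene conversion transfers tracts much shorter than a gene, so the
contrast lives at tract scale; `half_window='full'` gives the classic
whole-sequence split. High observed values are significant.

**Permutation null.** Permuting the assignment of site patterns to positions
destroys spatial signal while preserving the patterns themselves, so the
null is exact for clonal (exchangeable-site) alignments. The p-value is
`(1 + k) / (1 + n_perm)` where `k` counts permutations at least as extreme
as the observation; ties count as extreme. This estimator never returns 0
and is conservative when the null distribution is discrete. On low-diversity
alignments the PHI null can be coarse (few attainable values), making PHI
mildly conservative — a safe direction, but worth knowing when comparing
rejection rates with the nominal level. All three tests of a family draw
from a single seeded stream, and each family's stream is derived from the
run seed and the family's rank in sorted-id order, so results are
independent of file-system ordering.

**Classification.** Single-method mode (default, PHI): recombinant iff
p < 0.05. Consensus mode: recombinant (non-recombinant) only when all three
tests agree; disagreements are discarded. A family on which a requested test
cannot be computed — too little phylogenetic signal to accept or reject
recombination — is *unclassified* and excluded from all downstream
contrasts.

## Composition statistics

GC is `(#G + #C) / (#A + #C + #G + #T)`; gaps and ambiguity codes are
excluded from numerator and denominator (ambiguity codes other than `N` are
treated the same way — fractional attribution is not attempted). GC1/GC2/GC3
apply the same count to each codon position of the alignment frame.
Family values average member sequences with equal weight; all-gap rows are
skipped with a warning.

Intergenic GC is gene-centred: for each core gene, up to 400 bp of
non-coding sequence on each side (truncated at the nearest neighbouring gene
boundary), averaging the GC of flanks longer than 50 bp — the length floor
avoids noisy estimates from tiny flank samples; a gene with no qualifying
flank is missing. The per-family value is the mean over genomes with
non-missing values. A flank shared by two core genes counts once per gene
(the analysis is gene-centred), and the focal gene's strand is irrelevant
because GC is strand-symmetric.

## Optimal codons and Fop/Fnop

The **RP method** pools codon counts over ribosomal-protein genes and over
all other genes. For each codon of an amino acid with >= 2 synonyms, a 2x2
table (focal codon vs its synonyms, RP vs other genes) is tested by
chi-squared without continuity correction (counts are large in practice; a
Yates option exists); the codon is *optimal* when p < 0.001 and its relative
frequency among synonyms is higher in RP genes. Codons unobserved in a class
margin are excluded as untestable; Met and Trp have no synonymous choice and
are always excluded. The six-fold amino acids (Leu, Ser, Arg) are treated as
single synonym families.

The **HCB method** ingests per-strain preferred-codon tables: an amino
acid's optimal codon is accepted only when a strict majority above 60% of
documented strains agree on it and every dissenting strain prefers a codon
with the same third-base composition; otherwise the amino acid is excluded.

**Fop/Fnop** are the fractions of a gene's sense codons that are optimal and
non-optimal, split by AU- vs GC-ending third base. The denominator is the
gene's total sense-codon count, so the four fractions plus the excluded
fraction sum to one.

## Association analyses

Recombinant vs non-recombinant contrasts use a two-sided Student's t-test
with pooled variance (a Welch option exists), reported as recombinant minus
non-recombinant so positive means GC enrichment of recombinants. Across
datasets, the sign of the differences is tested by a 1-df chi-squared
goodness of fit of the positive/non-positive split against equal
expectation, without continuity correction; exact zeros are dropped with a
warning. No multiple-testing correction is applied across datasets or
metrics — each contrast is reported with its own p-value.

For the binned analysis, classified families (unclassified and discarded
families are removed first) are stably sorted by GC3 with ties broken by
family id, and split into 20 classes: with `n = 20*q + r` the first `r` bins
take `q + 1` genes. Each bin reports its mean GC3, the proportion of
recombinant families P_REC — the proxy for the bin's average recombination
rate — and, when a per-family external rate table is supplied, the bin's
mean rate. The response is regressed on mean GC3 by ordinary least squares;
constant inputs yield NaN (undefined) rather than an error.

## Population-genetic model

In a haploid population the strength of gBGC relative to drift is
`B = 2*Ne*r*L*b0` with `b0 = 2*pGC - 1`. gBGC acts like genic selection:
the fixation probability of a GC allele is scaled by
`kappa(B) = B/(1 - exp(-B))` (`kappa(0) = 1` by continuity; a series
expansion is used for |B| < 1e-5 to avoid cancellation) and that of an AT
allele by `kappa(-B)`. With mutational bias `lambda` (GC->AT over AT->GC),
detailed balance of the resulting two-state substitution process gives the
equilibrium GC content `GC* = 1/(1 + lambda*exp(-B))`, using
`kappa(B)/kappa(-B) = exp(B)`.

## Synthetic genome groups

The generator produces the statistical structure the analysis assumes, with
known ground truth:

* One neutral-coalescent clonal genealogy per group (msprime, haploid), in
  coalescent time units, shared by all families.
* Per-site two-state GC/AT substitution on a four-letter emission: each site
  is assigned one AT letter and one GC letter, AT->GC proceeds at rate
  `theta*kappa(B)/(1+lambda)` and GC->AT at
  `theta*lambda*kappa(-B)/(1+lambda)`, so the stationary GC equals `GC*`
  above. Roots are drawn from the stationary distribution, or from a
  codon-sampled sequence for coding families.
* Codon structure: positions 1-2 evolve at a reduced rate and with a damped
  bias (both scaled by `pos12_factor`), modelling purifying selection on
  amino acids; GC3 therefore responds to gBGC more than GC1/GC2.
* Gene conversion as unidirectional tract transfer between extant lineages:
  each event picks a donor and recipient, a uniform tract start, replaces
  recipient sites with donor sites, except that at GC/AT-heterozygous sites
  the GC allele is retained with probability `p_gc` whichever lineage
  carries it.
* Two conversion-rate classes; a gene's long-term composition feels its
  conversion rate through an effective bias
  `B_gene = b_scale * b0 * conv_rate * tract_length / gene_length`, the
  per-generation conversion coverage of a site times the repair bias, scaled
  into drift units.
* Ribosomal-protein families are rooted with codon usage enriched toward a
  fixed planted optimal-codon set (a synthetic profile mixing GC- and
  AU-ending choices), giving the RP method a known truth to recover.
* Intergenes (one per family, concatenated with the genes into genome
  sequences with a coordinate table) evolve without codon structure under
  the family's bias.

Default study conditions: 10 genomes; 900-bp genes; `theta = 0.05` per site
per coalescent time unit, i.e. pairwise diversity near 10%, within the
<0.15 group-distance criterion; `lambda = 2` (AT-biased mutation, the rule
in bacteria); conversion classes of 1 and 4 expected events per family
(4-fold heterogeneity); 200-bp tracts; `p_gc = 0.5` (null) with 0.8 as the
strong-bias condition; `pos12_factor = 0.25`; `b_scale = 2`; 10% RP
families; 200-bp intergenes. All randomness flows from one seed through
named per-family streams, so identical configurations are byte-identical.

What the generator does **not** emulate: four-letter substitution models
(each site toggles between two letters, which maximises the visibility of
recurrent mutation but caps pairwise incompatibility at 1), indels and
alignment error, stop-codon avoidance during evolution, ongoing selection on
codon usage (the RP signal is planted at the root and decays with
divergence), demography, donors outside the group, and recombination
embedded in an ancestral recombination graph (tracts are exchanged between
extant lineages, which is sufficient to create the homoplasy signal the
tests detect). Passing tests therefore demonstrate correct statistical
behaviour under the assumed structure, not performance on every real
dataset.

## Validation problem sizes

The acceptance-level suites use: 500 independent clonal families (and 500
with five conversion tracts) for type-I error and power of each test at 200
permutations; 20 seeded replicates of 600-family groups per bias condition
for end-to-end parameter recovery; 1,000 random site pairs against the
brute-force parsimony oracle; and 20-kb sequences across a
`(lambda, B)` grid for stationarity, judged within three binomial standard
errors. These sizes give stable operating-characteristic estimates while
keeping the default suite desk-scale.

## Known limitations

* PHI's permutation null is discrete on low-homoplasy alignments; with ties
  counted as extreme its rejection rate can fall somewhat below the nominal
  level (conservative, never anticonservative).
* P_REC is a detection-rate proxy: it compresses rate variation above the
  detection ceiling and below the detection floor.
* The intergene of a family shares the genealogy and bias of its gene, so
  the intergenic analysis on synthetic data is easier than on real genomes,
  where flank assignment and alignment add noise.
* Group selection by single linkage can chain distant genomes through
  intermediates; inspect the group manifest when the distance distribution
  is not clearly bimodal.
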