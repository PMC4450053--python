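# gbgcscan

Does homologous recombination drive bacterial genomes toward G+C? GC-biased
gene conversion (gBGC) — a repair bias that favours G/C alleles when a
conversion tract covers a GC/AT heterozygous site — predicts that, within a
genome, the genes that recombine most should be the most GC-rich, especially
at synonymous (third codon) positions. `gbgcscan` is a pipeline for testing
that prediction in groups of closely related bacterial genomes, aimed at
comparative genomicists working with core-genome alignments.

## What it does

Given per-family in-frame nucleotide alignments of single-copy core genes
(plus optional gene coordinates, a ribosomal-protein gene list, and a
per-gene external recombination-rate table), the pipeline:

1. **Selects analysis groups** — >= 6 genomes at pairwise distance
   `1 - s < 0.15` from a mean-identity matrix — and the single-copy core
   families of each group; alignments are trimmed to their 900 central
   positions (shorter families are set aside).
2. **Detects recombination** per family with three site-pattern statistics
   sharing one site-permutation null (p = (1+k)/(1+n), default 1,000
   permutations): **PHI** (mean pairwise homoplasy of informative sites
   within a 100-bp window; low tail), **NSS** (neighbour similarity of the
   site-compatibility matrix; high tail) and **MaxChi2** (maximum windowed
   match/mismatch chi-squared over sequence pairs and breakpoints; high
   tail). Families are classified recombinant / non-recombinant by PHI
   alone or by the strict consensus of all three (disagreements discarded;
   families without enough signal are unclassified).
3. **Computes composition**: GC, GC1-3 per family, and a gene-centred
   intergenic GC (flanks up to 400 bp, counted only when longer than 50 bp).
4. **Defines optimal codons** by ribosomal-protein enrichment (2x2
   chi-squared, p < 0.001) or from per-strain preferred-codon tables (>60%
   consensus with matching third-base composition), and splits Fop/Fnop by
   AU- vs GC-ending third base.
5. **Runs the statistics**: Student's t contrasts of every metric between
   recombinant and non-recombinant families; a cross-dataset chi-squared
   sign test; and the binned correlation — families sorted by GC3 into 20
   equal classes, per-bin proportion of recombinant families (P_REC, a
   proxy for the bin's mean recombination rate) regressed on mean GC3.

The population-genetic backbone is the haploid gBGC coefficient

    B = 2 Ne r L b0,        b0 = 2 pGC - 1,

with fixation-bias factor kappa(B) = B/(1 - e^(-B)) and equilibrium GC
content GC* = 1/(1 + lambda e^(-B)) under a mutational AT bias lambda.
A coalescent-based simulator (`gbgcscan.simulate`) generates genome groups
with a shared clonal genealogy, AT-biased mutation, per-gene conversion
tracts and tunable transmission bias pGC, with full ground truth — every
pipeline stage is testable without downloads.

## Worked example

Generate a biased (pGC = 0.8) and an unbiased (pGC = 0.5) synthetic group of
10 genomes x 400 core families and run the full pipeline:

```sh
python analysis/01_simulate.py
python analysis/02_run_pipeline.py
```

which prints (PHI test, 200 permutations; `*` marks p < 0.05):

```
biased: tested 400, recombinant 61, non-recombinant 339, unclassified 0
            gc: diff +0.0169 (t=+3.62, p=0.000331)*
           gc3: diff +0.0472 (t=+3.67, p=0.000279)*
  intergenic_gc: diff +0.0280 (t=+2.73, p=0.00664)*
        fop_gc: diff +0.0289 (t=+3.54, p=0.00045)*
       fnop_gc: diff +0.0208 (t=+2.77, p=0.00593)*
       fnop_au: diff -0.0371 (t=-3.31, p=0.00101)*
  GC3 vs P_REC over 20 bins: slope +0.70, R2 0.557, p 0.000158
unbiased: tested 400, recombinant 36, non-recombinant 364, unclassified 0
            gc: diff +0.0042 (t=+1.40, p=0.163)
           gc3: diff +0.0015 (t=+0.25, p=0.8)
  GC3 vs P_REC over 20 bins: slope +0.10, R2 0.002, p 0.854
```

Under biased conversion, recombinant families are significantly GC-enriched
— more strongly at third codon positions (+4.7 GC3 points vs +1.7 GC
points), extending to intergenic flanks and to GC-ending codon classes —
and the 20-bin P_REC regression recovers the recombination-composition
gradient (R² = 0.56). The unbiased control is flat throughout. The remaining
drivers (`03`-`06`) tabulate the contrasts, check that the RP method
recovers all 18 planted optimal codons, refit the bin regressions, and print
the gBGC theory table, including the comparison of measured transmission
biases: human pGC = 0.70 vs yeast pGC = 0.507 gives a ~30-fold b0 ratio,
which, against 4x longer yeast tracts, leaves gBGC ~7-fold stronger in
humans at equal Ne·r.

The same steps are scriptable from the shell:

```sh
gbgc-scan simulate --seed 4 --out group1
gbgc-scan report group1 --out group1_results --methods phi --n-perm 1000
gbgc-scan bcalc --ne 1e8 --r 1e-9 --tract-length 100 --p-gc 0.53 --lambda-mut 2
```

## Layout

```
src/gbgcscan/      library: genome_io, composition, recombination,
                   codon_usage, association, popgen, simulate, pipeline, cli
analysis/          numbered narrative drivers writing tables to results/
scripts/           acceptance.py
tests/             pytest suite (unit, property, acceptance)
docs/methods.md    model, estimators, defaults, limitations
```
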