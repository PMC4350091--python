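# rvassoc

A rare-variant case–control association pipeline, built as a reusable
Python package with a synthetic cohort generator so that every stage is
testable end to end without any external data.

Stages:

1. **Synthetic cohorts** (`rvassoc.simulate`) — rare-skewed minor-allele
   frequency spectrum (truncated Beta; ≥85 % of sites below 1 % MAF,
   ≥90 % below 5 % by default), Hardy–Weinberg genotypes, a logistic
   disease model on carriage of rare non-silent alleles in a designated
   risk gene set, Poisson read depth with base-quality-consistent
   sequencing errors, and full truth tables.
2. **Variant calling** (`rvassoc.calling`) — per-sample genotype
   likelihoods from base qualities, EM maximum-likelihood population
   allele frequency under HWE, likelihood-ratio SNP calling
   (2·ΔlogL > 24), Bayesian genotype calls with the HWE prior
   (per-sample depth < 8 set missing), and a QC filter bank
   (base-quality rank-sum, strand-bias Fisher, depth/MAPQ bounds, each
   at p < 1e-5).
3. **Single-marker tests** (`rvassoc.single_marker`) — differential
   call-rate/depth QC between groups, logistic regression of phenotype
   on dosage with age as covariate, label-permutation p-values.
4. **Gene-based burden tests** (`rvassoc.burden`) — BURDEN, FRQWGT
   (control-frequency weights), VT (variable MAF threshold) and UNIQ
   (case-unique alleles) statistics with adaptive permutation
   (stop at 10 exceedances, p = (r+1)/(b+1)), over rare (< 1 %) and
   rare+low-frequency (< 5 %) MAF strata and non-silent/UTR variant
   classes, plus per-gene carrier-frequency Fisher statistics.
5. **Gene-set aggregation** (`rvassoc.aggregate`) — per-gene and total
   allele counts of all/group-exclusive qualifying variants and
   distinctive loci, two-sided Fisher's exact burden tests against
   total chromosomes, carrier-level tests, and the normalized
   per-capita distinctive-loci ratio R.
6. **Pathway enrichment** (`rvassoc.enrichment`) — nominal-gene
   flagging (any test p < 0.05), upper-tail hypergeometric
   over-representation tests, Benjamini–Hochberg FDR.

## Command line

Every stage is a subcommand of `rvassoc` (see `rvassoc --help`):

```sh
# generate a synthetic cohort with truth tables and read summaries
rvassoc simulate --out-dir sim/ --seed 1

# call variants from read summaries -> VCF with GT/DP + filter columns
rvassoc call --reads sim/reads.tsv --pheno sim/phenotypes.tsv --out called.vcf

# single-marker association (MAF >= 1%)
rvassoc assoc --vcf sim/cohort.vcf --pheno sim/phenotypes.tsv \
    --out markers.tsv --permutations 10000 --seed 1

# gene-based burden tests
rvassoc burden --vcf sim/cohort.vcf --anno sim/annotation.tsv \
    --pheno sim/phenotypes.tsv --out genes.tsv --stratum rare --seed 1

# gene-set aggregation (allele/exclusive/loci bookkeeping + Fisher tests)
rvassoc aggregate --vcf sim/cohort.vcf --anno sim/annotation.tsv \
    --pheno sim/phenotypes.tsv --gene-set sim/gene_sets.tsv --out agg.tsv

# pathway enrichment from gene-level results
rvassoc enrich --gene-results genes.tsv --pathways pathways.tsv \
    --universe universe.txt --out enrichment.tsv

# full pipeline from a YAML config
rvassoc run --config config.yaml --out-dir out/
```

Interchange formats are plain text: VCF 4.2 (GT/DP), TSV sidecars for
phenotypes (`sample`, `status`, `age`), annotation (`chrom`, `pos`,
`ref`, `alt`, `gene`, `class`), gene sets (one set per line,
tab-separated), and read summaries.

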