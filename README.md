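# isohap

Comparative analysis of long- versus short-read RNA-seq, built around the
question a sequencing-core user actually faces: *what does a longer read buy
you* — in mapping confidence, in isoform resolution, and in the power to
detect allele-specific transcription — *and is it worth the price per base?*

The package implements the full analysis chain as a library with a thin CLI:

- **Read-pair overlap merging** (`isohap.read_merge`). When a cDNA fragment is
  shorter than the read length, each mate sequences through the fragment into
  the ligated adapter; locating the 13-bp adapter in both mates gives the
  fragment length exactly. Pairs are merged into single-end reads
  (disagreements resolved by base quality), fragments < 20 bp and pairs with
  > 10 disagreements are discarded, and the library is bipartitioned into a
  merged single-end part and a paired-end part.
- **RNA/DNA genotype concordance** (`isohap.concordance`). At every genotyped
  SNP with depth n ≥ 10, the number x of reads carrying an allele the DNA
  genotype does not support is modelled as x ~ Binomial(n, ε) under a
  sequencing-error-only null, with ε estimated as total mismatches over total
  aligned bases. The upper-tail probability P(X ≥ x) is the site's
  *discordance p-value*; libraries are compared per depth bin
  (10–99, 100–499, 500–999, ≥ 1000) with a one-sided Wilcoxon rank-sum test.
- **Consistent-feature assignment** (`isohap.feature_assignment`). Each
  aligned fragment is assigned the intersection of the non-empty per-base
  feature sets (genes or isoforms) over the bases it covers, further
  restricted to isoforms whose intron chain contains every splice junction
  the alignment asserts. Transcript abundance is quantified from unambiguous
  reads normalized by each transcript's *unique bases* (exonic bases
  belonging to no sibling isoform, minimum 10).
- **Allele-specific expression and splicing** (`isohap.allele_specific`).
  Fragments covering phased heterozygous sites whose alleles all match one
  parental haplotype are haplotype-assigned. Gene-level ASE is an exact
  two-sided binomial test against a balanced null (≥ 20 assigned reads);
  ASAS tests each *exon block* (atomic exonic interval with no internal
  isoform boundary) with a 1-df chi-square on the 2×2 haplotype ×
  block-overlap table (≥ 40 reads); discoveries at 10% FDR
  (Benjamini–Hochberg). Reference-allele mapping bias is controlled with the
  *mapping retention rate*: het-site bases are flipped to the other haplotype
  and realigned; genes retaining < 90% are untestable. The
  haplotype-assignable fraction follows p(L) = 1 − exp(−λL) in the covered
  length L when het sites form a Poisson process of rate λ; fitting λ
  extrapolates assignability to arbitrary read lengths.
- **Cost model and subsampling** (`isohap.cost_subsampling`). Cost per
  megabase, per-read cost ratios and cost-matched fractions from library
  price/yield specs; deterministic subsampling by reads, bases or cost, and
  read truncation for simulated short-read libraries.
- **Synthetic data** (`isohap.synthetic_data`). A seeded generator for a toy
  diploid transcriptome: genome with diverged duplicate (pseudogene-like)
  loci, multi-isoform gene models, Poisson-placed phased SNPs,
  strand-specific paired reads with adapter read-through and substitution
  errors, full per-read truth tables, and an exhaustive spliced toy aligner —
  so every stage above is testable without any download.

## Worked example

```python
import isohap as ih

cfg = ih.SimulationConfig(n_fragments=2000, seed=7)
genome, annotation, sites, library = ih.simulate(cfg)

part = ih.partition_library(library.pairs, cfg.adapter)
print(f"merged {part.stats.n_merged} of {part.stats.n_input} pairs "
      f"(disagreement rate {part.stats.disagreement_rate:.4f})")

index = ih.build_base_index(annotation, "isoform")
assignments = ih.assign_fragments(library.fragments, index, annotation)
print(f"unambiguous isoform rate: {ih.unambiguous_rate(assignments):.3f}")

site_index = ih.SiteIndex(sites)
calls = [ih.assign_haplotype(f, site_index) for f in library.fragments]
model = ih.fit_poisson_model(
    [f.effective_length for f in library.fragments],
    [c.assigned for c in calls])
print(f"fitted het rate lambda = {model.lambda_:.2e}; "
      f"extrapolated p(1000 bp) = {float(model.predict(1000)):.3f}")
```

prints

```
merged 1180 of 2000 pairs (disagreement rate 0.0097)
unambiguous isoform rate: 0.387
fitted het rate lambda = 3.46e-04; extrapolated p(1000 bp) = 0.293
```

59% of the pairs came from fragments shorter than the 262-bp reads and were
merged; mates disagreed at ~1% of overlapping bases, the two-draw rate
implied by the 0.5% per-base error setting. 38.7% of assigned fragments were
consistent with exactly one isoform, and the fitted per-base heterozygosity
(3.5 × 10⁻⁴, truth 3 × 10⁻⁴) extrapolates to ~29% of 1-kb alignments covering
at least one het site.

The same stages are available from the shell:

```sh
isohap simulate --out sim --seed 7
isohap merge sim/reads_1.fastq sim/reads_2.fastq --out merged
isohap ase --sam sim/true.sam --gtf sim/annotation.gtf --vcf sim/phased.vcf --out ase.tsv
isohap cost --price 880 --pairs 9524186 --bases-per-pair 524
```

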