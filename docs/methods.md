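# Methods

This note documents the models, defaults and design choices behind each
stage of the pipeline, and what the synthetic benchmark does and does not
establish about real data.

## Read-pair overlap merging

A poly-A RNA library whose fragment-size distribution sits below the read
length produces pairs in which both mates sequence through the insert into
the adapter. The merge stage searches each mate, in its own orientation, for
the leftmost occurrence of the adapter (default `AGATCGGAAGAGC`, the 13-base
TruSeq read-through prefix; any ≥ 13-base sequence can be supplied). A
full-length match must be exact (configurable); a *truncated* match at the
read end must show at least 5 adapter bases and tolerates one substitution
once ≥ 8 bases are visible — without a minimum, 1–2-base "prefixes" would
match a quarter of all random tails and corrupt the bipartition. If both
mates report the same position, that position is the fragment length;
mismatched or one-sided adapter hits leave the pair untouched (`kept_pair`).

Merging reverse-complements mate 2 onto mate 1 over the fragment.
Disagreements are resolved in favour of the higher base quality (ties keep
mate 1, the transcript-sense mate); merged quality is the per-position
maximum. Fragments shorter than 20 bases are discarded, as are pairs
disagreeing at more than ten overlapping positions. With per-base error
rate e, two independent reads of the same base disagree at rate
2e(1 − e) + (2/3)e², which the reported disagreement rate estimates; at the
default e = 5 × 10⁻³ this is ≈ 1.0%. Note that a pair is only recognized
when the adapter 13-mer is error-free in both mates, i.e. a fraction
(1 − e)²⁶ of read-through pairs (≈ 0.88 at the default e); the remainder
safely fall into the paired-end partition.

## Genotype concordance

Given genotyped SNPs (indels and incomplete genotypes removed upstream), a
read is *mismatched* at a site when its base equals neither genotype allele
— allelic imbalance at a het site is deliberately not penalized. Sites need
depth ≥ 10; each fragment contributes one base per site (overlapping mates
are collapsed first). The error rate ε is estimated per dataset as total
mismatches over total aligned bases *at the analyzed sites*; the numerator
and denominator therefore refer to the same base population. The
discordance p-value is the exact binomial upper tail P(X ≥ x),
X ~ Binomial(n, ε), computed by `scipy.stats.binom.sf`; x = 0 gives 1.
Libraries are compared per depth bin (boundaries exactly 10/100/500/1000)
with `scipy.stats.mannwhitneyu(alternative="greater")`, which uses the
exact null distribution for small samples and midrank ties otherwise. Bins
with fewer than two sites on either side are reported as NaN. The modal
indel-size diagnostic reports the plurality indel size per genotyped indel
site; ties go to the smaller magnitude and are flagged.

## Feature assignment and quantification

The per-base index maps every genomic position to the features containing
it: at gene level the gene's full genomic footprint (so intronic bases vote
for their gene), at isoform level exactly the annotated exonic bases. A
fragment's consistent set is the intersection of its non-empty per-base
sets — empty sets are skipped so bases outside the annotation cannot veto
an otherwise informative fragment — followed, at isoform level, by the
junction filter: only isoforms whose intron chain contains every junction
of the alignment survive, and a junction unknown to all base-consistent
isoforms leaves the fragment unassigned. Both mates of a pair are pooled
before intersection; the read pair is the unit throughout. Strand is
ignored during assignment (a strict-strand mode is not needed for the
synthetic layouts, where genes do not overlap on opposite strands).

Transcript abundance divides a transcript's unambiguous fragment count by
its *unique bases*, scoped within the gene: exonic bases belonging to no
sibling isoform. Cross-gene ambiguity is handled upstream by unambiguous
gene assignment, so genome-wide uniqueness would double-count the same
evidence. Transcripts with < 10 unique bases are excluded, and the default
analysis set is multi-isoform protein-coding genes. Mappability is
summarized per gene as the length-weighted mean of the interval track over
the gene's footprint; genes without track coverage score 0 and are logged.
The estimator-comparison utility reports Spearman correlations against the
unambiguous-read abundances across an ambiguity-rate threshold sweep, and a
bootstrap-over-genes test (default 10⁴ seeded resamples; genes, not
transcripts, are the exchangeable unit) for the difference between two
external estimators.

## Allele-specific analysis

Haplotype assignment requires every covered phased het site to show the
same haplotype's allele; one discordant or non-allelic base makes the
fragment `conflicting`. ASE is a two-sided exact binomial test at p = 0.5
on a gene's maternal/paternal fragment counts — two-sided because
imbalance in either direction is of interest — with a 20-read minimum.
Fragments are counted once per gene (per-fragment, not per-mate).

Exon blocks are the atomic intervals of the partition induced by all
isoform exon boundaries; they tile the exonic union and never contain an
internal boundary. Each block of each eligible gene (≥ 40 assigned
fragments) is tested with the 1-df Pearson chi-square, no continuity
correction, on the 2×2 haplotype × block-overlap table; a fragment
overlaps the block if either mate covers any of its bases. Tables with a
zero margin are skipped; tables with a minimum expected count below 5 are
flagged but still tested. All blocks of all genes enter a single
Benjamini–Hochberg pool at q = 0.10; the step-up is implemented directly
(largest k with p₍ₖ₎ ≤ kq/m) and cross-checked against
statsmodels in the test suite.

The retention filter flips every covered het-site base to the other
haplotype's allele (an involution wherever bases were allelic; a
sequencing error at the site is replaced by the allele opposite the
fragment's assigned haplotype and flagged) and realigns each sequenced
segment — consecutive blocks joined across splice gaps, split at
inner-mate gaps. A fragment is retained only if every segment maps
uniquely with its original block structure; genes retaining < 0.9 are
untestable. Gene-name exclusion (default prefix `HLA-`) guards against
loci with unreliable genotypes.

The assignability model p(L) = 1 − exp(−λL) is fitted by maximizing the
Bernoulli likelihood over log λ with bounded scalar minimization
(tolerance 1e−8 on log λ); all-assigned or none-assigned inputs are
boundary-flagged. The eQTL-overlap enrichment is the hypergeometric upper
tail on (tested genes, het-eQTL genes, significant genes, overlap).

## Cost model and subsampling

Costs are unit-agnostic ratios of a library's price to its yield; library
preparation is excluded by default and can be added as a constant.
Cost per megabase is reported at 3 decimals. Subsampling draws without
replacement with replicate seeds spawned deterministically from one master
seed (default 3 replicates); `by_bases` accumulates a random permutation
until the base target and includes the fragment that crosses it (documented
overshoot ≤ 1 fragment), counting raw pre-merge bases. Read truncation
keeps each mate's first bases, emulating a shorter-read run of the same
flow cell.

## Synthetic data generator

The generator is the package's study design. One seeded configuration
produces a genome of equal-width gene slots, a fraction of which
(`duplicate_locus_fraction`) is copied to fresh slots with independent
per-base divergence d — the pseudogene-like, low-mappability regime.
Coding genes get a random exon chain (2–8 exons of 80–260 bp, introns
60–200 bp) and 1–k isoforms formed by skipping distinct internal exons, so
isoforms always share the first exon and differ by exactly one exon;
duplicated loci carry the source chain as single-isoform `pseudogene`
genes. Phased het SNPs are laid down as a Poisson process of rate
`het_density` per base; phase is random and recorded.

Fragments are drawn per gene-expression weight (default: log-normal across
coding genes, with a configurable total pseudogene share), haplotype
(per-gene maternal fraction) and per-haplotype isoform usage; lengths are
normal, truncated below at `fragment_min` and above at the transcript
length. Mate 1 is transcript-sense (the strand-specific protocol); when
the fragment is shorter than the read length both mates read through into
the adapter and are padded with random bases. Substitution errors are
applied per base; qualities are constant Q37 (or a linear-decay option) —
qualities only matter at merge disagreements. Indel errors are not
simulated (the indel diagnostic consumes genotyped indels, not error
indels); PCR duplicates, GC bias, positional bias and quality-dependent
errors are likewise out of scope. The truth tables record, per fragment,
its transcript, haplotype, mRNA interval, reference blocks and covered het
sites, and the true alignments can be emitted as SAM.

The toy aligner is exhaustive within a mismatch budget (default 4): it
scans both genome strands and every multi-exon isoform's spliced sequence
using exact pigeonhole seeding (m + 1 chunks, one must match exactly), so
its hits equal a brute-force Hamming scan. A unique best hit maps the
read; ties multimap. The 75-mer uniqueness track mirrors alignability
tracks: score = 1 / occurrences, counting both strands.

Defaults describe a desk-scale deeply sequenced human lymphoblastoid
library: het density 3 × 10⁻⁴/bp (the regime in which roughly a quarter of
1-kb alignments cover a het site), 262-bp reads over fragments of mean
220 ± 80 bp (short-fragment-heavy, so most pairs overlap), error rate
5 × 10⁻³, and a few percent of reads from pseudogene-like loci.

## What the benchmark shows — and does not

Passing tests establish that the statistics are implemented exactly (oracle
equivalence against brute-force enumeration), that the null calibration and
power behave as designed on data satisfying the generator's assumptions,
and that the directional read-length effects — higher isoform unambiguity,
higher haplotype assignability, low-mappability genes better captured by
long reads, and at least as many base-matched ASE discoveries after the
retention filter — emerge from the mechanisms the analysis posits. They do
not certify performance on real libraries, where fragment-size selection,
alignment artifacts beyond substitution errors, annotation incompleteness
and genotype error all intrude. Problem sizes in the suite (genomes of
35–400 kb, 8–60 genes, 10³–10⁴ fragments, 50–100 replicates for
calibration) were chosen as the smallest at which the binomial/Poisson
tolerances derived in each test are meaningful; every stochastic assertion
states its tolerance as a multiple of the standard deviation implied by the
generative model itself, never as a fitted constant.

## Numerical and degenerate-input conventions

Exact tail probabilities come from scipy's survival functions rather than
summation. The chi-square statistic uses the closed form
n(ad − bc)²/((a+b)(c+d)(a+c)(b+d)). Zero-depth sites, genes with no reads,
empty strata and empty p-value vectors return empty/None results rather
than raising. The Wilcoxon comparison switches between exact and midrank
asymptotic forms via scipy's defaults. All randomness flows through
`numpy.random.Generator` streams spawned from a single `SeedSequence`, so
identical configurations are byte-reproducible and sub-studies (genome,
annotation, diplotype, library) are independently perturbable.
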