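# Methods

This note documents the models, conventions and numerical choices behind
`sdrmap`, and what the synthetic studies do and do not establish about
real data.

## Setting and assumptions

The pipeline targets a species in which a single sex-determining region
(SDR) segregates in full-sib families but adults show no dimorphism and
larvae cannot be phenotyped. The working model is single-locus genetic
sex determination with male heterogamety (XY) as the primary hypothesis
and female heterogamety (ZW) as the alternative; both are evaluated, and
a randomized grouping serves as the negative control. Marker and gene
coordinates live on an orthologous reference linkage map (positions in
Mbp, 1-based, closed intervals), because the focal species is assumed to
lack its own assembly. Strand is ignored throughout.

## Parentage (exclusion principle)

A candidate parent is excluded at a marker when no allele it carries can
explain the offspring genotype. In the trio case (the other parent
known), exclusion requires that no pairing of one candidate allele with
one known-parent allele reproduces the offspring call; when the known
parent's call is missing at a marker, the duo rule is applied there.
Missing calls never contribute, and a pair with zero co-genotyped
markers is reported `untestable`, never `compatible`. The default
verdict threshold is a single mismatching marker (the strict exclusion
principle); `threshold >= 2` is exposed because one genotyping error can
otherwise exclude a true parent. Offspring are assigned only when
exactly one candidate remains compatible. On error-free data the true
parent's exclusion count is exactly zero — a Mendelian identity the
tests assert. Likelihood-based assignment (LOD scores, mutation models)
is out of scope.

## Haplotype phasing and sex-group assignment

A marker is informative for a parent when that parent is heterozygous
and transmission is resolvable for every possible offspring call (other
parent homozygous, or carrying no allele in common). Phasing is greedy:
it seeds at the informative marker resolving the most offspring and
extends outward, at each marker orienting the parent's allele pair so
that the majority of offspring stay on the haplotype they carried at the
previous informative marker; orientation ties fall back to the smaller
allele. Mendelian-inconsistent calls are treated as missing and counted.
A family with no paternally informative marker is rejected as
unphaseable. An offspring is flagged a candidate recombinant when at
least `min_run` (default 3) consecutive informative markers support the
alternative haplotype, the shortest discordant run the detection stage
accepts as real.

Sex-groups are the paternal haplotype carried across the SDR interval
(XY scenario), the maternal haplotype (ZW), or a random permutation of
the paternal labels that preserves group sizes — a permutation null
keeping DE power comparable across scenarios. The SDR allele, not the
chromosome-wide majority, defines the group: an offspring whose resolved
transmissions disagree inside the interval (a crossover within it), or
with no resolvable marker there, is `unassignable` and excluded
downstream with a logged count.

## Recombinant detection and interval refinement

Within each family, every marker gets a modal genotype per sex; a marker
is sex-informative when the two modes are defined (no tie) and differ.
An individual matching the opposite sex's mode over `min_run` or more
adjacent sex-informative markers defines a recombination event. Missing
calls and uninformative markers neither extend nor break a run; a
non-missing call matching neither mode breaks the run without being
opposite-pattern evidence. Detection was verified against an exhaustive
(individual × window) scan on small families.

The refined SDR is the intersection, over all events and families, of
the region still consistent with each individual's sex. Endpoints sit at
the **margin markers** of the discordant runs (the innermost run
marker): the true crossover lies in the gap just beyond the margin, so
the closed interval keeps that gap and, on error-free data, can never
exclude the causal locus — a coverage property checked over simulated
families (≥ 95% observed ≈ 99%). Consensus is per family and events are
never pooled before the intersection, since families may segregate
different linked variants. An empty intersection signals inconsistent
events (phenotype or genotype error).

The modal-consensus rule presumes a marker panel associated with sex, as
fine-mapping panels are in practice. On panels containing non-sex-linked
markers the rule flags spurious "sex-informative" markers at an
appreciable rate; `build_consensus(min_concordance=0.8)` reproduces the
panel-selection step by dropping markers whose modal genotype has less
than 80% within-sex support. Pipeline-level runs enable this filter;
the default (0) keeps the bare modal rule.

## Differential expression

The per-gene test is an exact conditional count test: conditioning on a
gene's pooled count `n`, it asks whether the group-A sum deviates from
group A's share of the total library size, with a two-sided
minimum-likelihood (double-tail) rejection region. Overdispersion is
handled by a single common dispersion estimated from the matrix by
Pearson-residual matching under group-wise fitted means with
library-size offsets (group-wise fitting keeps truly DE genes from
inflating the estimate); each group sum is then treated as negative
binomial with an effective size `(S^2 / sum s_j^2) / phi`, exact for
equal library sizes and a close approximation within the ±20% spread
simulated. With `phi = 0` the conditional law is exactly binomial, so
the test degenerates to a conditional binomial for Poisson-like data.
On 2300-gene null matrices at the default dispersion the observed
type-I error at raw p < 0.01 is ≈ 0.008–0.010, and recall of planted
|log2FC| = 2 genes at 8 samples per group is ≈ 1.0. Genes with pooled
count below `min_total` (default 10) are excluded from testing and
reported as filtered. Benjamini–Hochberg FDR is reported alongside, but
the significance rule used throughout is the raw p < 0.01 convention of
sex-biased-expression studies. Normalization is by total library size; a
trimmed-mean factor is a possible extension, as is gene-wise dispersion
shrinkage.

Sex-specific genes are tagged by the strict all-or-nothing rule: count
at least `min_expr` (default 1) in **every** sample of one group and
exactly zero in every sample of the other. The simulator plants such
genes with expectation exactly zero in the silent group (rather than
thresholded low expression) so the rule is exactly recoverable; a
planted gene can still legitimately escape tagging when sampling noise
puts a zero in its expressed group. Transcript-level results collapse to
genes by minimum p-value, ties broken by lexicographic transcript id for
determinism; unmapped ids pass through flagged unannotated.

## Enrichment and scenario comparison

`RA_i = DE_i G_t / (DE_t G_i)` is computed per linkage group; DE genes
not placed by the orthology map are reported and excluded from `DE_t`,
which makes `sum_i RA_i (G_i / G_t) = 1` an exact identity, asserted on
every summary to 1e-12. Percentages are rounded half-away-from-zero to
integers and ratios to one decimal, the conventions of the tabulated
study designs this layout mirrors. The scenario table carries one row
per grouping (paternal / maternal / random) with the SD-LG count, other
count, total and SD-LG percentage, plus the paternal/maternal total
ratio; the random row's seed is recorded for reproducibility. Pooling
assignments across families is supported but group labels have no
cross-family meaning, so scenario comparisons should use one family's
larvae (as the simulated study does).

## Synthetic-data generator: what it emulates

Defaults mirror the emulated study design: two full-sib mapping families
(24 offspring each) on a 15-marker panel spanning 0.10–3.39 Mbp of the
orthologous SD linkage group with the SDR at 0.96–1.85 Mbp; a spawning
group of 45 larvae from one dam and three candidate sires on 6
microsatellites with 4 alleles (Dirichlet population frequencies); and a
23-LG transcriptome of 2300 genes in which 100 genes are truly
sex-biased, 48% of them on the SD linkage group, 20 of them sex-specific
with 96% on the SD LG. Sixteen larvae (8 per putative group) form the
expression subset. Crossovers occur at most once per meiosis per parent
(single recombinants being what terminal-run margin logic interprets),
placed uniformly over inter-marker gaps with the switch point at the gap
midpoint; the causal locus is the SDR-interval midpoint. The observed
per-meiosis crossover frequency is not documented for the emulated
design, so the default rate (0.1) is a placeholder, not an estimate.
Counts are negative binomial with log-normal gene weights (σ = 1),
common dispersion 0.1, and library sizes of 200 000 ± 20% — standard
bulk RNA-seq emulation at a desk-scale depth; recovery-rate replicates
use a scaled set-up (1150 genes, 50 per LG, 50 DE genes, 60 000 reads)
chosen so 200 replicates run in about a minute. With `effect_log2fc =
0` all group differences, including sex-specific zeroing, are
suppressed, giving an exact null matrix for calibration.

What the generator does **not** emulate: genotyping error (beyond
optional missingness), linkage disequilibrium in the wild population,
double crossovers and interference, multi-mapping or length bias in
counts, sample-quality failures, and transcript-level assembly
artifacts. Passing tests therefore establish the correctness and
calibration of the inference machinery under the stated model, not
robustness to those real-data pathologies.

## Degenerate inputs and tie rules

Configuration validation rejects an SDR interval containing no marker
(true sex transmission would be undefined), non-increasing marker
positions, and a sex-specific count exceeding the DE count. Consensus
ties make a marker uninformative; orientation ties in phasing and
collapse ties in DE resolve deterministically (smaller allele,
lexicographic id). A disconnected refined region keeps the widest
component with a warning; an empty one raises. All generators are
bit-reproducible given (config, seed).
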