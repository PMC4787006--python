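# Methods

`phyllopipe` re-implements, as a tested library, the computational chain of
a two-morph insect transcriptome analysis: leaf-galling (GA) and
root-feeding (RA) forms of the grapevine phylloxera compared through a de
novo transcriptome. Every stage is exercised end-to-end on synthetic data
with planted ground truth, so the statistical behaviour of each component
can be verified without the original sequencing data. This note records
the models, the parameter choices, and the points where the design was
genuinely open.

## Redundancy clustering

De novo assemblies emit many near-identical contigs per gene — alternative
transcripts that are locally identical but differ by large facultative-exon
indels. The reduction rule is the published one: two contigs are redundant
if they share a local match with identity ≥ 0.99 over ≥ 200 bp that spans
≥ 50% of *both* sequences; redundant contigs are linked single-linkage
(connected components — the retained-longest rule implies transitive
grouping), and each cluster keeps its longest member (ties broken by
lexicographically smallest id, for determinism).

The pairwise aligner is exact-k-mer-seeded (k = 31) and **ungapped**: for
every diagonal carrying a shared 31-mer, the maximum-scoring ungapped
segment is found by a prefix-sum (Kadane) scan with match +1 / mismatch −2;
`N` never counts as an identity. Ungapped segments are the deliberate
choice rather than gapped extension: identity here is defined as
matches/alignment-columns with gap columns counting as mismatches, so an
aligner that bridged a 50–300 bp deletion would dilute identity far below
0.99 and *no* alternative-transcript pair would ever pass the filter.
Stopping at the indel — the behaviour of X-drop HSP extension in
megablast-style tools — is what makes the published rule workable, and it
gives the aligner an exact oracle: the best ungapped local segment equals
the Smith–Waterman optimum with gaps prohibited, computable by full
quadratic dynamic programming.

Seeding is provably sufficient at the default filter: any passing segment
(≥ 200 columns, ≥ 99% identity ⇒ ≤ 2 mismatches per 200 columns) contains
an exact run of ≥ 66 bp by pigeonhole, so it always carries a 31-mer seed;
a `None` return therefore certifies that no passing match exists. The
all-vs-all pre-screen indexes one side of each candidate pair every 32
positions (guaranteeing detection of shared exact runs ≥ 62 bp) and scans
the other side at every position. Known limitation: the aligner returns
the best-*scoring* segment; in pathological inputs a lower-scoring
sub-segment could pass the identity filter while the best segment does not.
The synthetic data (and any data with roughly uniform divergence along the
match) cannot trigger this.

Assembly statistics follow the integer conventions of published assembly
tables: N50 is the observed length at which the cumulative sum (longest
first) reaches half the total; the mean is rounded to the nearest bp; the
median is the lower-middle element for even n; size-class counts use
strict `>`.

## Expression shares and differential expression

Shares are 100 × count / library total, averaged over replicates per
condition; they sum to 100 per library by construction.

Normalization uses median-of-ratios size factors: for contigs with nonzero
counts in every library, factor_j = median over contigs of
count_ij / (geometric mean of the contig across libraries). This statistic
is invariant to globally rescaling all counts (both numerator and
denominator scale together) and to contig order; tests cross-check it
against an independent implementation.

The DE test is an explicit negative-binomial Wald test, documented rather
than delegated: per contig, the dispersion α is estimated by the method of
moments on normalized counts, α̂ = max((s² − μ)/μ², 10⁻⁸) with s² the
pooled within-condition variance, then shrunk 50/50 toward a parametric
trend α(μ) = a₀ + a₁/μ fitted by least squares across contigs. The fold
change is log2((m_RA + 0.5)/(m_GA + 0.5)) with a 0.5 pseudo-count to avoid
infinities; its standard error uses the NB variance μ + αμ² of each
condition mean; the Wald z gives a two-sided normal p; Benjamini–Hochberg
adjustment runs over tested contigs only. Contigs with all-zero counts in
the compared libraries are excluded from testing but reported (bias
`ambiguous`, padj empty), never dropped silently.

Orientation follows positive log2fc = higher in RA
(radicicoles/gallicoles); it is configurable via the
`numerator`/`denominator` arguments because the source material phrases
the ratio both ways.

Bias classes apply the published thresholds with strict inequalities, so
boundary values fall to `ambiguous`:

* `RA_biased`: padj < 0.01 and log2fc > 1
* `GA_biased`: padj < 0.01 and log2fc < −1
* `unbiased`: padj > 0.05 and |log2fc| < 1
* `ambiguous`: everything else (including untested contigs)

Simulations at the study conditions (2 + 2 replicates, dispersion 0.05,
depth 5 × 10⁵) show the test controls the padj < 0.01 call rate on null
data well below 2% and detects planted 4-fold changes at base mean ≥ 100
with power above 0.8, with estimated fold-change signs matching the
planted signs for > 99% of detections. What this does *not* show: the
moment/trend dispersion estimator is cruder than modern shrinkage
estimators, multi-factor designs are unsupported, and no outlier
(Cook's-distance-style) filtering is applied.

## GO enrichment

Enrichment between two disjoint contig lists (e.g. RA-biased vs unbiased)
builds one 2×2 table per GO term observed in either list; the universe is
annotated contigs only (in de novo transcriptomes only a minority of
contigs carries GO terms), with the number of dropped unannotated contigs
logged. The Fisher exact p is computed by direct hypergeometric
enumeration: the two-sided p sums the probabilities of all tables with the
same margins whose probability does not exceed the observed one, with a
relative slack of 10⁻⁷ on the comparison (the convention of the standard
implementations); one-sided alternatives are available by flag. BH-FDR
runs across all tested terms with the published cutoff 0.05. No
ancestor propagation up the GO graph is performed — terms are tested as
annotated; propagation is a documented possible extension, not a default.

A table in which every annotated contig carries the term (zero "lacks
term" margin) is degenerate and raises an error rather than returning an
arbitrary p.

## Gene families, ORFs, codon composition

Family categories are a pure function of per-species gene counts (nA, nB):
many-to-many (≥2, ≥2), many-to-one (≥2, 1)/(1, ≥2), one-to-one (1, 1),
species-specific families (≥2, 0)/(0, ≥2), and singletons. Bookkeeping
conserves genes and families by construction; singletons are counted as
their own trivial families in the totals.

The ORF finder is a deliberate simplification of HMM-based CDS predictors:
a six-frame scan for complete ATG..stop ORFs of at least `min_codons`
(default 100) codons, longest CDS wins, ties broken forward strand → lowest
frame → leftmost start. 5′-partial ORFs are excluded — a known difference
from tools that allow them.

Codon-position GC is pooled over the CDS set: gc_k = 100 × (G+C at codon
position k) / total codons, complete codons only.

## NG86 dN/dS

Maximum-likelihood codon models are replaced by Nei–Gojobori (1986)
counting, a defensible stand-in here because at the phylogenetic distance
involved dS is saturated (dS ≫ 1) and only the *ordinal* behaviour of dN
is interpreted. Sites: per codon and position, the fraction of the three
single-nucleotide changes that are synonymous under the standard genetic
code (NCBI table 1; the code table is the configurable hook); changes to
stop codons count as non-synonymous, so S + N = 3 × codons exactly.
Differences: codons differing at k sites average the per-step
classifications over all k! minimal pathways with equal weights, excluding
pathways that pass through a stop codon (if every pathway is blocked, all
are used as a fallback). Proportions pS = Sd/S and pN = Nd/N receive the
Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3); a non-positive logarithm
argument sets the estimate to NaN with an `undefined` flag, and dS > 3 is
flagged `saturated`. The implementation agrees exactly with an independent
pathway-enumeration oracle over all 61 × 61 sense-codon pairs.

Rates across bias classes are compared by per-group median/quartiles and
two-sided Mann–Whitney U tests on each pair of groups, BH-adjusted across
pairs. The rank-sum choice is this package's own declaration — a
distribution-free test matching the ordinal use of dN — not an inference
about what the original analysis used.

## qPCR arithmetic

The standard-curve method: OLS of Cq on log10(quantity) over a serial
dilution series (≥ 3 distinct points), amplification efficiency
10^(−1/slope) − 1 (1.0 at slope −1/log10 2 ≈ −3.3219), quantification by
10^((Cq − intercept)/slope). Relative expression divides each target
quantity by the geometric mean of the two invariant reference genes.

Two conventions the procedure itself does not fix are chosen and
configurable: technical replicates are collapsed by the arithmetic mean of
*quantities* (not Cq) before normalization, and condition-level fold
changes are computed from biological-replicate means with the log taken
last. Method agreement is summarized by the Pearson r (and regression
line) between RNAseq and qPCR log2 fold changes over shared genes.

## The synthetic-data generator

All generators draw from named substreams of one integer seed (substream
key = hash of the generator name), so identical seeds give byte-identical
outputs and adding a generator never perturbs the others.

What is emulated, and the default conditions:

* **Transcriptome** — coding-frame base transcripts (ATG + sense codons +
  stop, short UTRs) of 1.2–3 kb with per-position GC targets (45/38/24.8%),
  matching the extreme AT-richness of the organism at third positions.
  A fraction `redundancy_rate` (0.3) of bases receives 1–3 near-identical
  variants: point mutations at rate 1 − `variant_identity` (0.995) and,
  with probability 0.5, one internal deletion of 50–300 bp mimicking a
  facultative exon. Two recoverability constraints are built in: mutations
  sit on an evenly spaced jittered grid (spacing 1/rate, jitter ±¼ step),
  so no aligned block dips below the identity cutoff; and the deletion
  starts within [0.05L, 0.20L], so the downstream colinear block always
  spans ≥ 50% of both sequences. Without these constraints a centrally
  deleted variant is *provably* unclusterable under the published filter,
  and the planted partition could not serve as ground truth. Stop-codon
  rejection during codon sampling biases realized GC3 upward by a little
  under one percentage point relative to the 24.8% target.
* **Counts** — NB counts (dispersion 0.05) for GA and RA (2 replicates
  each, expected depth 5 × 10⁵ mapped reads per library) plus one egg
  library. DE contigs (fraction 0.15, |log2fc| = 2) split their fold
  change symmetrically (×2^(±lfc/2)) so library composition stays balanced
  and size factors remain near 1 — the planted fold change survives
  normalization exactly in expectation. A six-member high-share family
  carries 10% of expected reads in GA and RA (member weights following the
  observed strongly skewed within-family profile) but only 0.04% in eggs,
  emulating the oviparity-associated family.
* **Annotations** — background GO terms assigned uniformly at probability
  0.05; each planted enriched term is assigned to true-DE contigs at the
  probability that yields exactly the requested odds ratio against the
  baseline.
* **Codon pairs** — per-site substitutions at probability 0.03 on 100-codon
  sequences; proposals creating stops are rejected; synonymous proposals
  always accepted, non-synonymous ones at the intensity ω (0.2). At most
  one substitution is accepted per codon: this keeps every differing codon
  a single-step difference, so the recorded truth counts coincide exactly
  with NG86's pathway counts, and ω = 0 guarantees dN = 0 (unrestricted
  multi-hit evolution can create same-amino-acid codon pairs, e.g. AGA vs
  CGC, whose pathway average has dN > 0). The cost is a ceiling on
  per-codon divergence, acceptable at these substitution rates.
* **qPCR** — per-gene standard curves with slope −1/log10(2) × (1 + 2%
  noise) and intercepts in 28–34 cycles; ten-fold dilution series in
  duplicate; 3 biological × 3 technical replicates per condition and gene;
  Cq = intercept + slope·log10(q) + N(0, 0.15) with biological log-normal
  spread of 0.10 log2 units; four targets with planted fold changes
  (+2.5, +1.5, −2.0, −3.0) and two invariant references.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: read-level errors and mapping ambiguity (counts
are drawn, not mapped), multi-gene families with partial homology between
clusters, GC-content and length biases in expression, annotation errors,
batch effects between sequencing runs, or qPCR amplification inhibition.

## Numerical choices

* Alignment scoring match +1 / mismatch −2; segment ties break to the
  smallest diagonal offset, then the rightmost minimal prefix (the
  densest segment, which never starts on a mismatch column).
* Dispersion floor 10⁻⁸; log2fc pseudo-count 0.5; p-values capped at 1.
* Fisher two-sided comparison slack 1 + 10⁻⁷ (relative).
* Representative and ORF ties break deterministically (documented above).
* Degenerate inputs raise typed errors (`errors` module) rather than
  returning sentinel values: zero-total libraries, zero-margin tables,
  all-zero normalization, non-positive reference quantities, <3 dilution
  points, <3 shared genes.

## Problem sizes

The shipped tests and the acceptance script run the study-condition
simulations at: ~2,100 contigs (1,250 base transcripts) for cluster
recovery; 5,000 contigs × 10 seeds for null error control and 3,000 for
power; 1,500 contigs for enrichment recovery; all 3,721 sense-codon pairs
for the NG86 oracle; every 2×2 table with margins ≤ 30 for the Fisher
oracle. These sizes give the concentration the assertions need while
keeping a full run in tens of seconds; all scale linearly if enlarged.
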