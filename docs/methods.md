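# Methods

## The burden model

The analysis treats a public reference panel as a pseudo-control cohort.
For each gene, qualifying rare variants (missense + loss-of-function by
default; synonymous as a negative-control track) are collapsed by summing
alt-allele counts over variants and individuals. The case margin is fixed
at A = 2N alleles regardless of per-variant missingness: a genotype failing
QC removes that variant's contribution but does not shrink the denominator,
which matches how aggregate case MAFs are conventionally reported and keeps
gene-to-gene comparisons on one scale. The control side sums the panel's
per-variant allele counts over the same contributing variants; the control
allele number B is the median per-variant AN (panels report slightly
different AN per site; in synthetic panels it is constant). Per-variant 2×2
tables are never formed — frequencies are aggregated before testing.

Conditioning on the margins of the resulting 2×2 table, the case alt count
follows Fisher's noncentral hypergeometric distribution with odds parameter
ψ. All exact quantities are computed by direct enumeration of the
conditional support in log space:

- **Two-sided p** (`fisher_exact_p`): the point-probability rule — sum of
  P(k) over all k with P(k) ≤ P(a)·(1 + 1e-7). The relative slack is the
  de-facto convention (R `fisher.test`, scipy) protecting ties against
  floating-point noise. A tail-doubling variant is available by flag.
  Degenerate margins (no alt or no ref alleles anywhere) return p = 1 with
  a warning.
- **Odds ratio** (`odds_ratio`): sample cross-product ad/cb by default —
  reconstructed published ORs match the cross-product to 4–5 significant
  figures — with the conditional MLE (solving E<sub>ψ</sub>[X] = a) as an
  option. Zero-cell conventions: b = 0, a > 0 → +∞; a = 0, b > 0 → 0;
  a = b = 0 → NaN with no direction defined.
- **Exact CI** (`exact_ci`): central interval inverting
  P<sub>ψ</sub>(X ≥ a) = α/2 (lower) and P<sub>ψ</sub>(X ≤ a) = α/2
  (upper) by bisection on log ψ over ψ ∈ [e⁻⁶⁰, e⁶⁰] to relative tolerance
  1e-8. When a sits at the top of its support the upper limit is +∞; at the
  bottom the lower limit is 0. Because the distribution is discrete, this
  construction is conservative: realised coverage exceeds the nominal 95%,
  substantially so when expected counts are small (~98% in the regimes the
  test suite measures). That is a property of exact central intervals, not
  a defect; a mid-P interval would be less conservative but loses the
  guaranteed-coverage property and is not implemented.
- **Multiple testing** (`adjust_multiple`): Bonferroni and
  Benjamini–Hochberg step-up (via statsmodels), applied per panel × variant
  class over the declared gene family (the full curated list, 63 genes by
  default, padding untested members with p = 1 so the family size is
  honest).
- **Prioritisation**: FDR < 0.05 and OR > 5 in the primary panel, after
  excluding variants with rarity-panel (CSVS) AF strictly greater
  than 0.05. Enrichment direction is OR > 1.

Panel **absence** is distinct from AF = 0 at a known AN: both contribute
b = 0 to the table, but absence from every queried panel flags the variant
as novel, which the workflow carries for filtering and reporting.

## Genotype-level QC

Thresholds follow standard short-read germline practice: heterozygous
allele balance (alt depth / total depth) within [0.2, 0.8], genotype
quality ≥ 20, depth ≥ 10 (≥ 5 haploid), all boundaries inclusive as the
conventions are printed; allele balance is only defined — and only
checked — for heterozygous calls. Tranche membership ("first tranche", 90%
truth sensitivity) is a site property: sites whose FILTER differs from the
configured pass label are dropped whole. A missing required FORMAT field is
an explicit failure (MISSING_FIELD), never a silent pass. Every genotype
set to missing is recorded in an audit log with its reason, and the
pipeline accumulates per-stage filter counts (variants read, off-tranche
sites, QC failures by reason, gene-restriction and rarity drops, class
composition of survivors) so a run can report its own workflow numbers.

## Synthetic data: what it emulates, and what it does not

`simulate` generates the study design the statistics assume:

- **Cohort**: N diploid cases (default 371, the reference cohort's analysed
  size) genotyped at per-gene sets of rare variants. Each genotype is the
  sum of two independent Bernoulli(min(λq, 0.5)) draws, where q is the
  variant's panel frequency (log-uniform on [1e-6, 5e-2] by default) and λ
  the gene's enrichment factor — the synthetic stand-in for a true odds
  ratio. λq > 0.5 is clamped with a warning.
- **Panels**: per-population rows with AC = round-half-even(q·AN),
  AF = AC/AN; AN defaults NFE 68,058, Global 152,312, CSVS 4,208 (genome-
  panel and Spanish-cohort scale). Non-primary populations jitter q by a
  lognormal factor (σ = 0.3). A variant can be drawn absent from a
  population (novelty) only when its panel count would round to ≤ 2
  alleles — a panel does not miss a common variant — at rate 5% by default.
- **Planting**: forced multi-variant carriers (two qualifying variants, or
  a synonymous + missense pair, set heterozygous in one individual), QC
  failures injected into 2% of genotype cells with one field moved just
  outside its threshold (AB into [0.05, 0.19] ∪ [0.81, 0.95], GQ ≤ 19,
  DP ≤ 9), and 1% of sites marked below the passing tranche. Everything
  planted is recorded in a truth JSON keyed so it can be recovered from
  the emitted files.
- **Splice regions**: `generate_splice_region` searches (greedy single-base
  moves, random restarts, bounded) for a k-mer scoring inside a requested
  band, plants it in random flanks, and derives the ref sequence by the
  single-base change with the largest score drop; an unreachable band
  raises rather than returning an off-band site.

Deliberately **not** emulated: linkage disequilibrium (allele-count
aggregation is insensitive to LD at these frequencies, so independent
per-variant draws suffice); read-level noise and variant calling;
multi-allelic sites (the reader decomposes them, the generator emits
biallelic sites only); population stratification between cases and panel;
per-site AN variation within a panel. Consequently, passing tests
demonstrate the statistics and bookkeeping are correct under the stated
sampling model — they say nothing about ancestry mismatch or batch effects
between a real cohort and a real panel, which remain the dominant risks of
pseudo-control designs.

Same seed ⇒ byte-identical output files; the writer fixes float formatting
(AB at 3 decimals, matched by the generator's quantisation) to make this
hold through write→read round trips.

### Null calibration

Exact conditional tests on discrete ultra-rare counts are super-uniform
(conservative) under the null, with a large point mass at p = 1; their
p-values are valid but not uniform. The calibration check therefore
asserts one-sided correctness — the empirical CDF of null p-values never
exceeds the uniform CDF beyond the one-sided Kolmogorov–Smirnov band at
α = 0.01 over 500 null genes — plus FDR control (fraction of null genes
with q < 0.05 is ≤ 0.05). A two-sided uniformity test would reject a
correct implementation here.

### Power at the tested design point

At the synthetic design point used for recovery checks (400 cases, 60
genes × 5 variants, q log-uniform on [1e-5, 1e-3], λ = 8 in 3 genes), a
planted gene whose five q draws land low has an expected enriched allele
count of only 1–3 and cannot outrank 57 null genes; joint top-3 recovery
is ≈ 50–60% per run (an independent scipy/statsmodels Monte Carlo gives
the same figure). Larger per-gene frequency mass or λ raises this
steeply. The acceptance suite reports the measured rate.

## Constraint density

Missense density along a CDS is computed per population from that
population's panel variants only — study variants are overlaid, never
counted into their own background. Windows are half-open, default 90 bp
(30 codons) with 30 bp step; the trailing window is truncated and
normalised by its true length; a window longer than the CDS collapses to
one whole-CDS window. Constrained regions are maximal runs of windows with
density ≤ a profile quantile (default 0.25), merged across the step grid;
a flat profile is flagged degenerate rather than producing an arbitrary
threshold. Coordinates are 0-based half-open CDS positions; the
genomic→CDS mapping comes from the annotation table. This is a descriptive
density profile: it involves no mutational expectation model, so it is not
a substitute for formal constraint metrics (missense Z, o/e).

## Splice-site scoring

Donor sites are 9-mers (exon −3..−1, intron +1..+6), acceptors 14-mers
(eight pyrimidine-tract positions, a weakly constrained −4, the −3 C, the
AG, two exon bases). A site's score is the per-position weight sum rescaled
so the consensus k-mer scores 100 and the per-position-minimal k-mer 0.
The shipped matrices use splice-consensus base frequencies with the
invariant GT/AG dinucleotide doubly weighted so core-dinucleotide presence
dominates the consensus value; any matrix in the same TSV layout can be
substituted, and absolute scores are meaningful only relative to the matrix
used. Percent variation is 100·(mut − wt)/wt, reported to 2 decimals.
`scan_pair` scores every k-mer frame overlapping a single substitution on
both sequences (reverse-complementing first for − strand) and calls a new
site at mutant score ≥ 65 with variation ≥ +10%, a broken site in the
mirrored case — the published motif-tool convention; both thresholds are
configurable. ESE/ESS/ISE/ISS scanning is exact k-mer counting over
pluggable motif sets; the shipped sets are small exemplars, so motif-ratio
deltas are comparable only under a fixed motif database.

## Numerical and interface choices

- Support enumeration is exact and cheap because qualifying rare-variant
  counts keep the conditional support tiny even at AN ≈ 10⁵.
- Round-half-even is used wherever a frequency is converted to an integer
  allele count, making AF→AC reconstruction the exact inverse of AC→AF
  emission.
- Gene symbols match exactly and case-sensitively; alias resolution belongs
  in the annotation table.
- Multi-allelic VCF records are decomposed into biallelic rows, each ALT
  treated independently.
- "Haplotype" language is avoided in outputs: with unphased short-read
  calls the package reports *co-occurrence* of variants in one individual;
  a homozygous call counts as one distinct carried variant.
- Every output TSV carries the run's configuration hash; the manifest
  records tool version and input checksums. CLI exit codes separate
  configuration/path errors (2) from runtime failures (1).

## Limitations

- Pseudo-control inference inherits the panel's ancestry and platform
  biases; no covariate adjustment or stratification correction is offered
  (regression-based burden frameworks are out of scope).
- The exact CI overcovers at small expected counts (see above).
- The CDS density profile depends on window/step/quantile choices; defaults
  are documented, not canonical.
- Splice scores are matrix-relative; cross-tool absolute comparisons are
  not meaningful.
- The default 63-gene list is a curated convenience file; treat the gene
  list as study input.
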