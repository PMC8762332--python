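# Methods

## Scope and model

`ribostruct` operates downstream of read processing: its inputs are
per-gene count matrices for paired Ribo-seq and RNA-seq libraries in a
2 strain × 2 condition factorial design, per-nucleotide 5′UTR/CDS
structure-score tracks, gene→term maps, and gradient absorbance traces.
The statistical core is deliberately simple and transparent:
point-estimate fold-changes on normalized replicate means with a hard
threshold, exact combinatorial tests for set relationships, and Student
*t* comparisons of structure features between gene sets. It does not fit
per-gene dispersion models; shrinkage-based differential testing (e.g. a
negative-binomial GLM per gene) is intentionally out of scope, and the
measurable-gene filter below takes its place in keeping noise genes out
of the classified sets.

## Normalization and TE contrasts

Size factors use the median-of-ratios estimator: for sample *j*,
sf*ⱼ* = median over genes *i* (with all-nonzero counts) of
*c**ᵢⱼ*/(∏*ₖ* *c**ᵢₖ*)^(1/m). CPM scaling is available as a fallback for
matrices with no gene expressed everywhere. Per cell (strain ×
condition × assay), replicate normalized counts are combined by
arithmetic mean. A contrast of cell B over cell A reports

log₂FC(RNA), log₂FC(Ribo), and log₂FC(TE) ≔ log₂FC(Ribo) − log₂FC(RNA),

so the TE identity holds exactly by construction. The pseudocount
(default 0.5 normalized counts) is added to both numerator and
denominator of a ratio *only* for genes where either mean is zero. This
zero-guard placement matters: an unconditional additive constant makes
fold-changes depend on the arbitrary overall scale of the normalized
matrix, whereas the guarded form is exactly invariant to uniform
rescaling of any library.

**Measurable filter.** A gene enters a contrast only if its raw counts
summed across replicates reach `min_count` (default 10) in each of the
four assay × cell combinations. The filter is deliberately explicit and
configurable, since any threshold choice changes the classified sets and
the enrichment universe.

**Classification.** Up/down sets use fold-change ≥ τ and ≤ 1/τ with
τ = 1.5, boundaries inclusive; a 1e-12 slack on the log₂ scale absorbs
float round-trip at the exact boundary. The universe for overlap and
enrichment statistics defaults to the contrast's measurable genes.

## Structure windows

Transcript coordinates are 1-based and signed: −1 is the last 5′UTR
nucleotide, +1 the first CDS nucleotide; there is no position 0. Named
windows: `total5utr` (−L..−1), `first30` (first 30 nt from the cap),
`start30` (−15..−1 and +1..+15), and the CDS windows `plus15` (+1..+30),
`plus30` (+16..+45), `plus45` (+31..+60), `plus60` (+46..+75), `plus75`
(+61..+90). A window that does not fully fit the available sequence is
*missing*, not truncated — a truncated cumulative score is not comparable
across transcripts — and missing genes never enter group means or their
*n*. `start30` is defined symmetrically (15 nt each side of the start)
since "surrounding the start codon" does not fix the split; the
alternative reading (30 UTR-only or 30 CDS-only nt) is covered by
`first30`/`plus15`.

Group comparisons use the pooled-variance (Student) two-sided *t* test,
with Welch's form behind a flag; significance is flagged at p < 0.05.
Degenerate inputs are explicit: two constant, equal groups return t = 0,
p = 1 with a `degenerate` flag; constant unequal groups raise rather than
report an infinite statistic. Cumulative scores accumulate 5′→3′ so the
sum is reproducible position by position.

## Set statistics

`overlap_fisher` builds the 2×2 table (both, A-only, B-only, neither) and
computes the hypergeometric weights with exact integer arithmetic
(`math.comb`); the two-sided p sums all tables with probability ≤ the
observed table's (minimum-likelihood convention) with exact tie
resolution, and the one-sided upper tail is reported alongside because
overlap questions are usually enrichment questions. The odds ratio is
ad/bc with the Haldane 0.5 correction when any cell is zero. Term
enrichment is the upper-tail hypergeometric test per term (terms
intersected with the universe first) with Benjamini–Hochberg q-values
across tested terms. Rank stratification selects ⌊fraction·n⌋ genes
(default fraction 0.30) with ties broken by ascending gene id.

## Polysome quantification

P:M ratios integrate the baseline-subtracted A254 signal by the
trapezoidal rule over user-supplied, non-overlapping monosome and
polysome intervals, with interval endpoints interpolated onto the trace.
Peak intervals are configuration, not auto-detected — peak boundaries in
practice are operator judgments tied to the gradient program. The
baseline is a constant, or `"linear"` for a per-interval straight line
through the trace values at the interval endpoints. Negative
baseline-subtracted values are clipped to zero before integration.
Fraction distributions are percent-of-total per collected fraction;
condition comparisons pool the mass at or after a 1-based split fraction
(the mRNP vs ribosome-containing boundary, which depends on the gradient
type and is therefore configuration) and apply the Student *t* test.

## Synthetic experiment design

The generator emulates a 16-library factorial study: strains WT and
`ntd-del`, conditions SD (rich synthetic medium) and urea (stress),
assays RNA and Ribo, two biological replicates per cell. Genes belong to
one of two classes. Defaults, chosen once as the study conditions:

| parameter | default | rationale |
|---|---|---|
| `n_genes` | 4000 | a typical measurable yeast transcriptome at desk scale |
| `replicates` | 2 | two independent cultures per condition |
| `library_size` | 1e6 | desk-scale depth; mean ≈ 250 counts/gene |
| `nb_dispersion` | 0.1 | typical bulk RNA-seq biological dispersion |
| `frac_membrane_like` | 0.3 | membrane-associated genes ≈ ⅓ of a transcriptome |
| 5′UTR length | log-normal, exp(μ) = 90 / 50 nt, σ(log) = 0.6 | membrane-like transcripts carry longer 5′UTRs |
| 5′UTR score means | +0.35 / −0.35 | membrane-like 5′UTRs more structured; ribosomal/cytoplasmic 5′UTRs largely single-stranded |
| CDS score means | 0.0 / +0.25 | the structure asymmetry reverses in the ORF |
| `pars_sd` | 1.0 | per-nucleotide score noise |
| `te_log2_sd` | 0.35 | baseline TE spread across genes |
| `beta_structure_te` | 0.4 | log₂-TE penalty per SD of 5′UTR cumulative score in the mutant |
| `urea_te_boost_membrane_wt` | 1.0 | log₂-TE gain of membrane-like genes in WT urea |

RNA counts are NB(μ = relative abundance × library size, variance
μ + disp·μ²); Ribo counts are NB around the RNA mean times the cell's
true TE, so Ribo column sums equal library_size × mean(TE) rather than
library_size exactly. Score tracks cover the 5′UTR plus the first 90 CDS
nt — everything the windows need — to bound file sizes; the CDS length is
fixed at 300 nt. Random streams are seeded per stage
(`default_rng([seed, stage])`), so annotation and counts are individually
reproducible and byte-identical TSVs follow from identical config + seed.

What the generator does **not** emulate: positional read-count structure
within transcripts (counts are per-gene draws), uORFs and alternative
TSSs, GC/length bias, correlated gene modules, batch or lane effects, and
RNA-level responses to the stress (planted effects act on TE only).
Passing recovery tests therefore shows that the statistics detect a
structure–TE coupling of realistic magnitude under NB noise — not that
they are robust to every artifact of real libraries.

## Pipeline and reproducibility

The pipeline stages run in analysis order: contrasts → fold-change sets →
cross-strain correlations and overlaps → window-score group summaries →
term enrichment → rank-stratification term overlaps. The manifest records
seed, package versions, and a SHA-256 of the canonical configuration
(excluding the output directory, which is a run location, not analysis
configuration); no timestamps are written, so identical config + seed
reproduces the bundle byte for byte.

Validation problem sizes: the exhaustive Fisher check enumerates every
2×2 table with universe ≤ 60 in tests (≈ 636k tables) and ≤ 40 in the
reproduction script; recovery of the planted structure coupling uses 20
seeds at 4000 genes for each of β = 0.4 and β = 0; enrichment ranking
uses 10 default-config seeds; null overlap calibration uses 2000 draws in
an 800-gene universe.

## Known limitations

- Point-estimate classification has no per-gene error control; borderline
  genes flip sets under resampling. Set sizes are therefore not
  comparable across depths without matching the measurable filter.
- The two-class generator makes class enrichment strong by construction;
  it probes ranking direction, not power at subtle effect sizes.
- `compare_groups` against the full transcriptome compares a set with a
  superset containing it; with small sets the overlap's effect on the
  test is negligible and this mirrors common practice, but it is not an
  independent two-sample design.
- The Fisher exact integer path is exact but O(support) per table with
  big-integer cost growing with the universe; for universes ≫ 10⁵ a
  normal approximation would be preferable.
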