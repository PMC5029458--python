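# Methods

This note documents the models, parameter choices and numerical
conventions behind `raex`, and what the synthetic-data calibration
does and does not demonstrate about real data.

## Allelic β and Δβ

Two-channel SNP-array intensities are quantile normalized per material
type (gDNA and cDNA separately), pooling **all** (sample, channel)
columns of that material into one reference distribution of mean order
statistics.  Pooling the X and Y channels jointly is what makes the
two allele channels comparable, so that β = X/(X+Y) is an allele
fraction rather than an arbitrary ratio of differently scaled
channels.  Rank order within each column is preserved; tied values
receive the mean of their reference values via average ranks (with
ties, quantile normalization is therefore not exactly idempotent — a
generic property of tie-averaged QN, irrelevant for continuous
intensities).  Columns with missing cells are placed on the pooled
reference by quantile interpolation; missing cells stay missing
through every downstream stage, and no imputation is performed.

The background filter is strict: a probe cell enters the analysis only
when X + Y > 750 (a total exactly at the cutoff is background).  The
count of passing cells is monotone non-increasing in the cutoff.
Intronic SNPs are retained: gene membership comes from a probe→
(gene, transcript) membership table, and transcript-level analysis is
isoform-specific.

Δβ = β_cDNA − β_gDNA is computed only at SNPs heterozygous in the
paired gDNA sample (β_gDNA ∈ [0.3, 0.7] and filter passed; the
heterozygote band and the homozygote bands β > 0.8 / β < 0.2 are
configurable operating points, not biology).  Using the measured gDNA
β rather than the ideal 0.5 cancels probe-specific affinity bias
common to both hybridizations — this is the reason the method is a
difference of βs, and the synthetic generator models that bias as
shared between materials accordingly.

## Gene scores and classes

The per-gene score is the weighted mean of |Δβ| over informative SNPs
(unit weights by default).  A penalty hook for large transcripts is
exposed as `PenaltyConfig`; the one built-in scheme shrinks the score
by n/(n+k) with k = 0 (off) by default, since the historical weighting
scheme it stands in for is not fully specified anywhere usable.
Direction is the common sign among SNPs with |Δβ| ≥ 0.1; mixed signs
give DISCORDANT.

Class thresholds act on the score: BA < 0.1 ≤ SK < 0.2 ≤ MA, with
lower-closed intervals (the boundary values 0.1 and 0.2 land in the
higher class; a measure-zero convention, configurable).  Under the
symmetric fold-ratio mapping r = (0.5+Δβ)/(0.5−Δβ) the BA/SK boundary
is exactly 1.5-fold, and the MA boundary Δβ = 0.2 corresponds to
2.33-fold.  (A 2.85-fold anchor is sometimes quoted for the MA
boundary in this assay family; it corresponds to Δβ ≈ 0.24 under the
symmetric mapping.  The Δβ thresholds are authoritative here because
classification is defined on Δβ; ratios are reported informationally.)
ND means no informative SNP with passing cDNA intensity — "expression
not reliably detected" — and a gene is *detected* in a clone iff it
has ≥ 1 such SNP (`min_informative`, default 1).

Known imprinted genes and the α/γ protocadherin clusters are excluded
from autosomal summaries (their monoallelic expression is not random
AEI: parent-of-origin imprinting, and overlapping gene annotations,
respectively).  Chromosome X genes are auto-flagged from the probe
manifest and kept out of autosomal summaries; their near-bimodal |Δβ|
distribution (X inactivation) is the natural calibration for the MA
threshold.

## Random AEI across sister clones

Within a group of ≥ 2 sister clones of one developmental state, each
gene expressed somewhere receives one category: RANDOM_MA (monoallelic
for opposite alleles in different clones), RANDOM_AEI (MA in ≥ 1 clone
with a biallelic sister), CONSTANT_MA (consistent direction wherever
detected, ≥ 2 clones detected, no biallelic sister — the cis-genetic
signature), INDETERMINATE_MA (MA in a single clone, nothing detected
elsewhere; kept distinct because non-detection blocks the random-AEI
call), NOT_MA otherwise.  The categories partition the expressed MA
genes.  State-level transition analysis collapses clones to a
consensus class (MA ≻ SK ≻ BA ≻ ND) and maps (before, after) pairs to
RESET / RETAINED / TO_SKEWED / LOST / DE_NOVO / STABLE_BA / OTHER.

The gene universe for frequencies is genes expressed (non-ND) in ≥ 1
clone of the group after exclusions.  Reported percentages follow the
reporting convention of the field's summary tables: two-decimal
frequencies are truncated (126/7334 → 1.71%), whole-number
percentages are rounded half-up (42/48 → 88%); both modes are
explicit in `raex.percentage`.  Transition reset rates are reported
against two denominators — all MA-before genes, and MA-before genes
still detected after — because both appear in practice.

## Statistics

Fisher's exact test (gene-set overlap) uses the two-sided convention
of summing point probabilities ≤ the observed table's, with fold
enrichment observed / (|A||B|/N).  The Wilcoxon signed-rank
(paired MA-vs-BA methylation, pairing per probe after averaging
within each clone group — pairing per probe rather than per gene
maximizes n) and rank-sum (promoter chromatin signal) tests enumerate
their full permutation null for small samples (2^n sign vectors up to
n = 12; C(n+m, n) labelings up to n+m = 16), which stays valid under
ties, where closed-form exact distributions do not apply; two-sided
p-values use the symmetric-tail convention.  Larger samples use the
normal approximation with continuity and tie corrections.  Zero
paired differences are dropped; an all-zero difference vector yields
p = 1.  A "paired rank-sum test" is a contradiction in terms; the
paired comparison here is deliberately the signed-rank test on
per-probe MA-minus-BA differences.

Methylation β matrices are consumed as-is (array preprocessing is
upstream); cross-hybridizing probes are removed by blocklist.
Hierarchical clustering of samples uses 1 − Pearson correlation and
average linkage with samples pre-sorted by id for deterministic ties;
a constant sample vector is a named fatal error.  Promoter windows
are TSS −1000/+500 bp, strand-aware, 1-based inclusive.

## Synthetic data

The generator emulates one genetic background profiled as several
single-cell-derived clones.  Gene truth classes and key defaults:

| parameter | default | why |
|---|---|---|
| class proportions | BA 92.5%, EQTL_SK 2%, IMPRINTED 1%, RANDOM_MA 3%, X_INACTIVATED 1.5% | random-MA rates reported for neural progenitors span ~0.5–3%; 3% gives usable truth-positive counts at 1000 genes while staying in the observed range; ~1% imprinted ≈ 100 genes genome-wide |
| allelic ratio, RANDOM_MA | 5.0 (Δβ = 1/3) | conventional "clear monoallelic" cutoff; also the operating point at which 100-founder polyclonal mixing keeps the true |Δβ| under 0.1 for >99% of genes |
| allelic ratio, IMPRINTED / X | 10 / 19 | imprints are strong; X inactivation near-complete (|Δβ| ≈ 0.45, the bimodal chrX signature) |
| EQTL_SK true Δβ | uniform [0.11, 0.19] | inside the skewed band, clear of both boundaries |
| random_ma_commitment | 1.0 | pure fair-coin model: every clone monoallelic, allele i.i.d. Bernoulli(½) per clone and per lineage commitment, giving the closed-form detection rate 1 − 2·0.5^c for c clones; values < 1 emulate panels where a random-AEI locus stays biallelic in some sisters |
| snps per gene | 1 + Poisson(4), het fraction 0.75 | ~3.5 informative SNPs/gene after genotyping and filtering |
| β noise s.d. (cDNA) | 0.03 | canonical array allele-fraction noise used throughout calibration |
| gDNA het bias s.d. | 0.02 | probe affinity bias, **shared** between gDNA and cDNA of a probe, so Δβ cancels it — modelling it as independent noise would contradict the Δβ design |
| totals | log-normal(ln 4000, 0.5), 5% forced low | exercises the 750 filter; unexpressed genes (10%) get low cDNA totals |
| reset states | iPSC_early, iPSC_late | pluripotency erases random-MA choices; imprints persist |
| methylation | promoter/island +0.2 and body −0.1 in MA clones; β-distributed noise s.d. 0.05; non-CpG 0.02 → 0.15 in pluripotent samples | the coupled epigenetic signature of monoallelic commitment |

Everything is a deterministic function of the seed (child streams per
stage), and two runs with one config produce byte-identical report
bundles.

Polyclonal mixtures re-draw the founder allele choice independently
`founders_per_polyclonal` (default 100) times per stochastic gene and
average; the mixture deviation is (2p̂−1)(f−½) with p̂ ~ Bin(F,½)/F.
At F = 100 and Δβ = 1/3 this leaves the true |Δβ| < 0.1 for ~99.7% of
random-MA genes; measurement noise erodes the *called*-biallelic rate
to ≈ 99.1% (dominated by genes with 1–2 informative SNPs), which is
why the polyclonal calibration check sits close to its 99% margin.

What passing the synthetic calibration shows — and does not.  The
generator reproduces the statistical skeleton the analysis relies on
(fair-coin clone choices, ratio-separated classes, intensity dropout,
probe-shared bias, promoter-coupled methylation).  It does not model
cross-hybridization, genotyping errors, GC- or intensity-dependent β
bias, correlated SNPs within a transcript, culture-passage drift,
partial X-inactivation skewing, or cell-cycle/bursting noise, so
recovery rates on synthetic panels are upper bounds on real-data
performance, and the classification thresholds should be re-examined
against the chrX Δβ distribution of any real panel.

## Pipeline and problem sizes

`run_pipeline` executes normalize → call → compare → methylation →
report from a YAML/dict config, on either simulated or file inputs,
and emits a `ReportBundle` (JSON + TSV) whose percentages are all
re-derivable from counts in the same bundle, with a config hash and
seed in the metadata.  The package is a library: the importable API
plus the narrative scripts in `examples/` are its interface, and the
orchestration layer is `raex.pipeline` rather than a shell command.
Plot generation is intentionally out of scope.

Calibration problem sizes used by the test suite: 1000 genes × 5
clones for parameter recovery, a 20 000-gene panel (~500 truth
random-MA genes) for the polyclonal averaging rate, 100 replicates of
50 probe pairs for methylation detection power.  These sizes give the
binomial resolution the asserted margins need while keeping the whole
suite fast.

## Known limitations

- Quantile normalization couples samples: columns whose underlying
  intensity-fraction distribution differs from the pool (e.g. a
  polyclonal sample next to heavily skew-enriched clonal columns in a
  stress simulation) acquire a small systematic β distortion.  At
  realistic class proportions the effect is ≤ 0.003 β s.d.
- The polyclonal estimator attributes MA/SK-in-polyclonal genes to
  cis-genetic control without genotype evidence; it is a candidate
  label, not an eQTL mapping.
- Exact printed-percentage reproduction depends on the truncation
  convention described above; half-up rounding of two-decimal
  frequencies would print 1.72/0.85 instead of 1.71/0.84.
- The generator's gDNA replicate-to-replicate noise is folded into
  the shared probe bias; per-sample gDNA measurement noise beyond it
  is not modelled separately.
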