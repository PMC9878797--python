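# Methods

`promark` implements an integrative analysis of bulk RNA-seq and promoter
H3K4me3 ChIP-seq in patient-matched tumor/normal tissue pairs (uterine
leiomyoma, UL, versus adjacent myometrium, MM). This note documents the
models, the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical conventions.

## Consensus differential expression

Each cohort's raw count matrix is tested with three re-implemented
differential-expression statistics, and a gene is called a DEG only when
all of them agree (FDR < 0.01 and |log2FC| > 1 with a consistent sign; a
2-of-3 majority rule is available via `consensus_rule="majority"`):

1. **NB exact test** (`nb_exact_test`). Counts are equalized to a common
   library size by the median-of-ratios size factors; per gene the UL and
   MM totals are tested with a conditional exact test: given the total
   T, the split follows the convolution of NB(nₐ·μ, α/nₐ) and
   NB(n_b·μ, α/n_b) restricted to 0..T, and the two-sided p-value sums
   the probability of splits as or less likely than the observed one.
   At α = 0 this reduces to a conditional Binomial(T, nₐ/(nₐ+n_b)) split.
2. **NB Wald test** (`nb_wald_test`). Per-group NB maximum-likelihood
   means at fixed dispersion (Newton iteration on the score equation,
   100 iterations max; non-converged genes get a missing p), Wald
   statistic on log(μ_UL/μ_MM) with the Fisher-information standard
   error.
3. **Moderated log-CPM test** (`logcpm_moderated_test`). log2 CPM on
   size-factor-normalized libraries, then the empirical-Bayes moderated
   t-statistic (below). `paired=True` adds patient blocks to the design.

Dispersion is a method-of-moments estimate from normalized counts,
α = max(0, (var − mean)/mean²) with the variance pooled within tissue
groups; per-gene values are shrunk toward a 20%-trimmed-mean common value
with weight df/(df+10). These are deliberate simplifications of the
edgeR/DESeq2/limma machinery (no TMM, no dispersion-trend or Cox-Reid
fitting, no voom weights): the fidelity target is statistical behavior —
type-I error control and recovery of planted effects — not numerical
identity with any one package. A pseudo-count of 0.5 is used everywhere a
log of counts is taken.

Shared DEGs are the direction-consistent intersection of the two cohorts'
consensus sets; genes significant in opposite directions are reported as
between-dataset discordant and excluded.

DE tests run unpaired by default even though tissues are patient-matched;
pairing is never silently assumed and can be enabled for the moderated
test (`paired_de=True`).

## Moderated linear model

For feature g with residual variance s²_g on d degrees of freedom, the
prior (d₀, s₀²) is estimated by moment matching on log variances: with
z_g = log s²_g − ψ(d/2) + log(d/2), solve
ψ′(d₀/2) = Var(z) − ψ′(d/2) by Newton inversion of the trigamma function
(tolerance 1e−8, 50 iterations max) and
s₀² = exp(mean(z) + ψ(d₀/2) − log(d₀/2)). The posterior variance is

    s̃²_g = (d₀ s₀² + d s²_g) / (d₀ + d),

the moderated t is the OLS contrast divided by its unscaled SE times s̃_g,
with d₀ + d degrees of freedom. d₀ is capped at 1e6 to represent
"infinite"; d₀ = 0 recovers the ordinary t-statistic exactly, and the cap
pools every feature's variance to s₀² (both limits are tested).

## Promoter H3K4me3 quantification

The TSS is the interval start on the + strand and the last base
(end − 1, 0-based) on the − strand; the promoter window is the closed
interval TSS ± 2 kb (configurable flank). A peak belongs to a promoter
when its **summit** lies in the window (midpoint when the caller reports
no summit; `anchor="midpoint"` and `"any-overlap"` are available). The
summit is the sharpest single-point anchor and is the default because the
source convention ("peaks up to 2 kb from the TSS") does not define the
peak anchor. One TSS per gene: input is gene-level; transcript models are
out of scope.

The enrichment matrix matches peaks across samples by identical
(chrom, start, end) on a master list (union over samples by default). A
sample missing a master peak contributes raw fold-enrichment 0 — absent
mark, imposed **before** standardization. Each sample column is then
standardized as (value − median)/sd (sample sd, n−1); samples with no
peaks or zero variance are excluded with a warning, mirroring the QC
removal of low-depth libraries in real studies.

**Global comparison.** All standardized peak values are pooled per tissue
and compared with the Wilcoxon rank-sum test (signed-rank on per-patient
differences with `paired=True`). Because per-sample median-centering
forces every column's median to zero — and hence the pooled median of
each tissue to ~zero — the *median difference is structurally
uninformative here*; the reported direction is the difference in pooled
means, which is consistent with the rank statistic, and the per-tissue
medians/quartiles are reported alongside for boxplot-style summaries.
Note the pooled test treats peak-sample values as exchangeable; shared
per-peak baselines make it conservative under the null in this usage.

**Differential trimethylation.** The moderated linear model runs on the
standardized values of the promoter peaks of the candidate (shared DEG)
genes only, with a tissue effect and, by default, patient blocks (the
ChIP cohort is explicitly matched; `paired_chip=False` is available).
BH correction runs across exactly the tested peaks. The significance
default is FDR < 0.05; the stricter 0.01 that some descriptions of this
analysis use is a config value (`peak_fdr`).

## Concordance classification

Per shared DEG, the best owned promoter peak is the one with the smallest
q (ties by smaller p, then lexicographic peak id). The gene is
differentially trimethylated iff that q < FDR; its direction (hyper/hypo)
combined with the expression direction gives hyper_up, hypo_down,
discordant, or no_differential_mark. q is computed once at peak level —
no second gene-level correction. Discordant genes are retained and
counted so the "hyper_up + hypo_down = all differential" structure of
concordant-only datasets is checkable rather than assumed. The Venn
summary enforces n_differential = n_hyper_up + n_hypo_down + n_discordant
and n_differential ≤ n_with_promoter_mark ≤ n_deg_shared at construction.

## Over-representation analysis

Database-agnostic hypergeometric ORA over user-supplied GMT sets. Each
set is intersected with the testable universe — by default all genes that
entered the expression analysis, not the whole annotation — then sets of
size 2..2000 are scored with the upper-tail hypergeometric probability
and BH-corrected across tested sets. GO hierarchy and redundancy
trimming are out of scope.

## ΔΔCt

Replicate Ct wells are averaged arithmetically; ΔCt = Ct_target −
Ct_housekeeping per (patient, tissue); ΔΔCt = ΔCt_UL − ΔCt_MM; fold
change = 2^(−mean ΔΔCt). Significance is a paired t-test on the ΔCt pairs
by default, Wilcoxon signed-rank by flag; the choice is explicit, never a
hidden normality gate. Fewer than 3 complete patients yields a missing
p-value; patients missing any of the four measurements are dropped with a
warning. No amplification-efficiency correction (Pfaffl) is attempted.

## Synthetic data: the planted world

Defaults describe a world in which every acceptance property is
measurable: 2000 genes on 2 chromosomes (one gene per 50 kb, so promoter
windows are non-overlapping by construction), 8 UL/MM pairs per cohort in
two RNA cohorts plus one matched ChIP cohort.

RNA-seq: gene means are log-normal (ln-mean 4, ln-sd 1, i.e. a median of
~55 counts), counts are NB with dispersion 0.05, per-sample library
factors log-normal (ln-sd 0.3), and a per-(gene, patient) log-normal
random effect (sd 0.1) induces the pairing structure a paired model can
exploit. 15% of genes are DE at |log2FC| = 2, the half-effect applied
symmetrically to both tissues; all DE genes are planted identically in
both cohorts by default (`frac_de_shared`).

ChIP: 75% of genes carry a promoter peak (a marked fraction typical of
what integrative UL/MM studies report), with the summit uniform in
TSS ± 1 kb and 400 bp width, plus 20% background peaks placed
mid-intergenic. log2 fold-enrichment = base (mean 3, sd 1) + per-(peak,
patient) effect (sd 0.2) + tissue shifts + noise (sd 0.35). "SD units"
for shifts mean the cross-peak sd of log2 fold-enrichment (= 1.0 by
default). 60% of shared DE genes get a concordant ±1 SD promoter shift
(up → hyper, down → hypo); concordant genes are forced to carry a peak.

**The global deficit is dynamic-range compression**, not a uniform shift:
UL log2 signal = mean + γ·(base − mean) with γ = 1 + 0.6·shift, so the
strongest promoter domains lose the most mark. This choice is forced by
the standardization math: per-sample (value−median)/sd cancels any
uniform additive or multiplicative shift exactly, and empirically a
heterogeneous multiplicative shift (exponential susceptibility) flips the
standardized direction *positive* because shrinking the high tail
compresses the column sd. Compression is the simplest mechanism that
survives standardization with the correct sign, and it matches the
biology of genome-wide erosion of H3K4me3 breadth/amplitude. With
shift = −0.5 at 5000 genes the pooled rank-sum test yields p ≤ 1e−13
with a negative direction in every tested seed.

What the generator does **not** emulate: chromatin-domain correlation,
overlapping promoters (a stress mode exists via config geometry),
GC/length biases, dispersion-mean trends, batch effects, hormonal
covariates, read-level artifacts. A green recovery test therefore
establishes correctness of the pipeline logic under the stated
generative model, not robustness to real-data confounding.

## Numerical conventions and edge cases

- All internal coordinates 0-based half-open; GTF converted at the parse
  boundary; BED round-trips byte-identically.
- Wilcoxon: exact enumeration of midrank assignments for n+m ≤ 10 (a
  rank permutation test, so tied inputs are handled exactly as well);
  otherwise normal approximation with tie-corrected variance and
  continuity correction.
- BH: step-up with cumulative minimum from the largest p; NaN p-values
  propagate as NaN q.
- PCA: feature-centered SVD; each component's sign fixed by making its
  largest-|loading| entry positive; constant matrices give zero scores
  and zero variance fractions rather than an error.
- Rank-deficient designs raise an error naming the collinear columns
  (pivoted QR); zero residual df raises.
- QC thresholds (library < 0.25 × median, PCA score > 4 sd from the
  centroid on PC1/PC2) are invented defaults for behavior the motivating
  study performed by inspection; QC is report-only unless `apply_qc`.

## Known limitations

- The NB exact test enumerates all splits of the (rounded, equalized)
  total; genes with extreme totals dominate runtime, though chunked flat
  vectorization keeps 5000 genes × 16 samples in ~1 s.
- The pooled global rank-sum test ignores the peak-level dependence
  between tissues (conservative under the null; direction unaffected).
- Consensus intersection is stringent by construction; sensitivity is
  bounded by the least sensitive member (the NB exact test at small n).
- Gene identifiers are opaque; no Ensembl/symbol mapping is attempted —
  all inputs must share one identifier namespace.
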