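# promark

Integrative analysis of promoter H3K4me3 ChIP-seq and bulk RNA-seq in
patient-matched tumor/normal cohorts — built around the question of how a
genome-wide trimethylation deficit in uterine leiomyoma (UL) versus
adjacent myometrium (MM) rewires gene expression.

The pipeline:

1. **Consensus differential expression** per cohort: three re-implemented
   statistics (conditional NB exact test, NB Wald test, empirical-Bayes
   moderated t on log2 CPM) must all agree at FDR < 0.01 and
   |log2FC| > 1; the two cohorts' DEG sets are then intersected with
   direction consistency.
2. **Promoter H3K4me3 quantification**: narrowPeak fold-enrichment values
   over a master peak list, per-sample standardization
   (value − median)/sd, peaks assigned to genes when their summit lies in
   the closed window TSS ± 2 kb.
3. **Global trimethylation shift**: pooled standardized enrichment, UL vs
   MM, Wilcoxon rank-sum.
4. **Differential trimethylation** of the shared DEGs' promoter peaks:
   moderated linear model with patient blocks, BH FDR < 0.05.
5. **Concordance classification**: each shared DEG becomes hyper_up
   (mark gained & mRNA up), hypo_down (mark lost & mRNA down),
   discordant, or no_differential_mark, with nested Venn counts.
6. **ORA** (hypergeometric, GMT input) and **ΔΔCt qPCR** fold-change math
   for validation cohorts.

The statistical core — BH step-up, exact/approximate Wilcoxon tests,
hypergeometric tail, the moderated t-statistic with digamma/trigamma
moment-matched priors

    s̃²_g = (d₀·s₀² + d·s²_g)/(d₀ + d),   t̃_g = β̂_g / (SE_g · s̃_g)

— is implemented from first principles and verified against independent
oracles (enumeration, scipy reference distributions) in the test suite.

A synthetic-data module generates the whole study — two NB count cohorts
with matched UL/MM pairs, promoter peak signals, a tunable global UL
trimethylation deficit, and a planted concordant gene subset — with known
ground truth, so every stage is testable without any data download.
See `docs/methods.md` for the models and defaults.

## Worked example

Simulate a planted study and run it end to end:

```sh
promark simulate --out demo --seed 1 --n-genes 2000 --n-pairs 8
```

then analyze it in Python:

```python
from promark.pipeline import run_bundle
from promark.synthetic_data import SimConfig, simulate_dataset

bundle = simulate_dataset(SimConfig(seed=1))
res = run_bundle(bundle.genes, bundle.cohorts, bundle.chip_sample_peaks,
                 bundle.chip_sheet, master_peaks=bundle.master_peaks)
print(res["venn"].to_dict())
```

With seed 1 this prints:

```
{'n_deg_shared': 298, 'n_with_promoter_mark': 270, 'n_differential': 173,
 'n_hyper_up': 89, 'n_hypo_down': 79, 'n_discordant': 5}
```

Reading: of 300 planted shared DEGs, 298 were recovered by the consensus;
270 carry a promoter peak; 173 of those show differential trimethylation
at FDR < 0.05, split into 89 hypertrimethylated/upregulated and 79
hypotrimethylated/downregulated genes (the planted truth is 90 + 90
concordant genes), with 5 discordant calls. The nested counts follow the
shared-DEGs ⊇ marked ⊇ differentially-marked structure such integrative
studies report.

The same run on a bundle with a −0.5 SD global deficit
(`SimConfig(global_ul_shift=-0.5, n_genes=5000)`) gives

```
global deficit bundle: rank-sum p = 1.92e-13, direction (mean UL - MM) = -0.0320
```

i.e. a highly significant global suppression of promoter H3K4me3 in the
tumor tissue.

The full file-based pipeline (`promark run-all --config config.yaml`)
writes per-stage TSVs, a Venn summary JSON, QC reports, a log and a
reproducibility manifest; individual stages are available as the
subcommands `simulate | qc | de | chip | integrate | ora | qpcr`.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the headline analysis from scratch at the given seed: it
simulates the default planted world, runs consensus DE, the promoter
ChIP stages and the concordance classification, prints the recovered
Venn counts against the planted truth, runs the global-deficit bundle
through the pooled rank-sum comparison, and writes the results JSON to
`--out`.
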