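# chromage

Cell-type-resolved detection of age-dependent chromatin-accessibility
changes — and what they do to genes and heterochromatin — from
single-nucleus ATAC-seq-style pseudo-bulk data.

Aging reshapes the regulatory genome unevenly across cell types: a
minority of candidate cis-regulatory elements (cCREs) gain or lose
accessibility between young and old, some of those changes drive
concordant transcription changes in nearby genes, and in excitatory
neurons age-up elements pile into megabase-scale clusters inside
constitutive heterochromatin (H3K9me3) domains that lose the mark with
age. `chromage` implements the statistical pipeline for all four
observations and ships a synthetic-data generator with planted effects
and truth tables, so the whole chain is testable without external data.

## What's inside

| stage | statistic |
|---|---|
| QC | TSS enrichment (Tn5 +4/−5 cut sites, ±2 kb profile, flank-normalised, 11-bp smoothed, max), ≥500-fragment / TSS≥10 nucleus filter, exact 1M-read down-sampling (multivariate hypergeometric) |
| Differential | per-feature NB LRT, `log μ_is = β_{i,g(s)} + log L_s`, Cox–Reid-adjusted common + tagwise dispersions, χ²₁ p-values, age-up/down at p < 0.01 |
| Linking | weighted Pearson correlation of gene CPM vs cCRE CPM within 500 kb over (cell type × age) data points, cell counts as weights, t/Kish-n_eff p, BH over all pairs at 0.05, positive-r filter; Wilcoxon concordance of linked-gene fold changes |
| Clusters | 100-kb binning of p<0.001 differential cCREs, window-20 Gaussian density score, permutation-null threshold, ≥5-member calls |
| Domains | SICER-style broad-domain scan (5-kb windows, 10-kb gaps, >100 kb), tri-modal per-domain old-vs-young tests with robust normalisation, per-cell fraction-of-reads-in-domain, top-1% Fisher overlap enrichment, domain–cluster shuffle enrichment, TE meta-profiles |
| Synthetic data | NB counts over cell types × ages × replicates with planted folds, clustered age-up cCREs inside decaying domains, latent-coupled RNA, per-cell H3K9me3 reads, barcoded fragments with a TSS pile-up — plus truth tables |

The model details, parameter defaults and the generator's scope are in
[docs/methods.md](docs/methods.md).

## Worked example

Run the whole synthetic study (deterministic for a given seed; two runs
are byte-identical):

```
chromage all --seed 1 --out study_out
```

which prints:

```
simulated 4000 cCREs, 600 genes, 10 domains, 521324 fragments
QC: kept 183/200 barcodes; pooled TSS enrichment 14.55
differential[ExN]: 137 age-up, 96 age-down cCREs (p<0.01)
differential[Micro]: 52 age-up, 59 age-down cCREs (p<0.01)
differential[Oligo]: 55 age-up, 48 age-down cCREs (p<0.01)
clusters: 3 calls (3 up)
domain caller: 10 broad domains (true: 10)
FRiP (ExN, decaying domains): rank-sum p = 5.86e-165
top-1% Fisher: OR=5.26 p=3.21e-07; domain-cluster overlap: observed=0.300 fold=1.68 p=0.227
linking: 626/59365 significant pairs; concordance p = 3.04e-08 (45 concordant pairs)
```

Reading the output: the generator planted age effects in ~12% of cCREs
(5% up and 5% down scattered across cell types, plus three 1-Mb
clusters of 100 age-up elements in the ExN-like cell type), and the
pipeline recovers the structure — the 17 rejected barcodes are the
degraded ones plus a small TSS-score tail; the excess of ExN
differential calls reflects the planted clusters; all 3 clusters are
called in the up direction only; the broad-domain scan recovers all 10
H3K9me3 domains from the aggregated signal; the per-cell fraction of
H3K9me3 reads in decaying domains drops uniformly in 18-month ExN cells
(rank-sum p ≈ 1e-165 over 500 cells per age); and the most
age-associated ExN cCREs are ~5-fold enriched inside H3K9me3 domains.
The domain–cluster fold (1.69) is modest *by construction* at this
40-Mb genome scale, where three 1-Mb clusters cover ~7% of the genome
— on a real 2.5-Gb genome the same statistic can yield folds of tens
(see docs/methods.md).

The `analysis/` directory holds the same pipeline as numbered
narrative scripts (`01_simulate.py` … `06_linking.py`), each writing
its tables under `results/`. The linking stage runs on 36 merged data
points (12 cell types × 3 ages) and reports, at seed 1, recovery of
84% of planted gene–cCRE links at BH < 0.05 with 3.3% decoy retention,
and a concordance p of 3.1e-06 between genes linked to age-up versus
age-down elements.

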