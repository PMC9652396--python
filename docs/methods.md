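# Methods

`chromage` implements, at desk scale, the computational core of a
cell-type-resolved chromatin-accessibility aging study: pseudo-bulk
differential testing of candidate cis-regulatory elements (cCREs),
gene–cCRE linking, density-based detection of megabase clusters of
age-differential elements, and heterochromatin (H3K9me3) domain calling
with decay statistics. Every stage is exercised end to end on a
synthetic study with planted effects and truth tables, so recovery can
be quantified exactly.

## Differential accessibility model

Counts for feature *i* in pseudo-bulk sample *s* (one column per cell
type × age group × biological replicate) are modelled as negative
binomial,

    y_is ~ NB(mu_is, phi_i),   log mu_is = beta_{i,g(s)} + log L_s,

with library size L_s a fixed offset and dispersion phi_i
(Var = mu + phi·mu²). The age contrast (18- vs 3-month) compares a
full model with one mean per age group to a null with a shared mean;
the likelihood-ratio statistic is referred to chi² with 1 df. Group
means are profiled out with a damped Newton solver on the score
equation, which is strictly monotone in the log rate, so convergence
is guaranteed; an adaptive grid-search maximiser serves as the
independent oracle in the tests (agreement to 1e-4).

Dispersion estimation is deliberately compact. A **common** dispersion
maximises the Cox–Reid adjusted profile log-likelihood summed over
features, on a log-spaced grid (61 points, 1e-4–5). The adjustment
(−½ Σ_g log I_g with I_g the expected information of the group means)
matters at pseudo-bulk sample sizes: with 2+2 samples the unadjusted
profile MLE is biased low by roughly a factor of two. **Tagwise**
dispersions maximise each feature's adjusted profile likelihood plus a
prior-weighted shared curve (the grid-mean over features), the weight
chosen so the shared signal carries `prior_df` (default 10)
pseudo-degrees of freedom against the feature's residual df; as
`prior_df → ∞` every tagwise value equals the common one. Empirical
Bayes mean–dispersion trends and quasi-likelihood F-tests are out of
scope, and exact numerical agreement with edgeR is not a goal. Under a
null simulation (2 vs 2, phi = 0.1, 5,000 features) the rejection rate
at p < 0.01 is ~0.011 and the Kolmogorov–Smirnov distance of the
p-values from uniform is ~0.03.

Classification: accessibility features are called age-up/age-down at
raw p < 0.01 by the sign of the offset-adjusted log2 fold change
(group totals with a half-count continuity adjustment); RNA features
are classified on BH-adjusted p < 0.1. A power note: with a fold of
2.25, mean 100, dispersion 0.1 and two replicates per group, the
Fisher information of the design caps two-sided power at alpha = 0.01
near 45–50% for *any* test (per-observation information
mu/(1+phi·mu) ≈ 9.1, noncentrality ≈ 6); the recovery rates reported
by the tests and the acceptance script sit at that bound.

## TSS enrichment and nucleus filtering

Each fragment contributes two Tn5 cut sites — the start shifted +4 bp
(plus-strand cut) and end−1 shifted −5 bp (minus-strand cut).
Insertion events are aggregated at strand-corrected offsets within
±2,000 bp of every TSS; the profile is normalised by the mean over the
distal flanks (±1,900–2,000 bp, 202 positions) and smoothed with a
centred 11-bp moving average (shrinking windows at the edges; no
padding). The score is the maximum of the smoothed profile; a flat
landscape scores ≈ 1. When the flank signal is exactly zero the flank
mean is floored at (total events)/(4001·50) with a warning rather than
dividing by zero. Nuclei are kept when they have ≥ 500 fragments and a
TSS enrichment ≥ 10 (a relaxed cutoff of 7 is appropriate for
low-complexity tissues such as heart and leg muscle).

The score is a maximum of a smoothed noisy profile, so on *sparse*
profiles it is biased upward: per nucleus (~2,500 fragments, ~6% of
events in TSS windows on the default 40-Mb genome) a truly flat
profile scores ~4–15, not 1, and an enriched nucleus scores above its
true fold. Consequences: the uniform-limit checks are run at ≥ 1e5
in-window events (where the bias is < 0.2), and a small fraction of
"background-only" low-quality barcodes can pass the TSS ≥ 10 filter.
This mirrors real per-cell QC, where the same estimator is applied to
equally sparse data.

Down-sampling for fair cross-cell-type comparisons draws exactly
1,000,000 reads without replacement (multivariate hypergeometric over
features); samples with fewer reads are removed.

## Gene–cCRE linking

Replicates are merged into one data point per (cell type, age group).
For every gene and every cCRE whose midpoint lies within 500 kb of the
gene's TSS, the weighted Pearson correlation (WPCC) between gene CPM
and cCRE CPM is computed across data points with per-point cell counts
as weights. P-values use a t approximation with the Kish effective
sample size n_eff = (Σw)²/Σw²; the choice of p-value for a weighted
correlation is not canonical, and this is the package's documented
convention. BH correction runs across **all** tested pairs (stricter
than per-gene correction); a significant link additionally requires a
positive correlation. The concordance check collects the RNA log2 fold
changes of genes linked to age-up and to age-down cCREs in the same
cell type and compares the two groups with a two-sided Wilcoxon
rank-sum test (normal approximation, tie-corrected). Note that the
number of data points governs power directly: with 36 points
(12 cell types × 3 ages) a planted correlation of 0.8 survives the
genome-wide BH threshold with high probability; with 9 points it does
not, so linking analyses are run on the 12-cell-type configuration.

## cCRE clusters

Age-differential cCREs at p < 0.001 are counted into non-overlapping
100-kb bins by midpoint (one track per cell type and direction; last
partial bin kept), and smoothed with a truncated Gaussian kernel of
window length 20 bins. The kernel's sigma is not part of the published
recipe; the package uses sigma = window/4 = 5 bins, truncated at
±window/2 and renormalised per source bin so mass is conserved exactly
and nothing bleeds across chromosome ends. Clusters are contiguous
runs of bins whose density score reaches the (1 − 0.001) quantile of a
permutation null that relabels which of the tested cCREs are
differential (their number preserved, 1,000 permutations), re-bins and
re-smooths; calls with fewer than five member differential cCREs are
discarded. The permutation respects the real cCRE landscape, so
regions dense in cCREs are not spuriously called.

## Heterochromatin domains

The broad-domain caller is a compact scanner in the SICER tradition,
run without an input library: 5-kb windows are "eligible" when their
read count clears the Poisson upper tail (p < 0.01) against the
genome-wide mean; eligible windows separated by ≤ 10 kb are chained
(intervening sub-threshold windows included); candidates longer than
100 kb are kept. SICER's island-score machinery is intentionally not
reproduced.

Per-domain differential statistics reuse the NB LRT per cell type and
modality (H3K9me3 domain counts; ATAC and RNA aggregated over the same
intervals), with BH within each (cell type, modality) stratum. Library
normalisation is the delicate point: when a large minority of domains
genuinely loses signal, raw library offsets — and even a median ratio
over ten features — convert that loss into spurious gains elsewhere.
The package therefore uses within-group median-ratio factors plus a
between-group offset estimated by the shortest-half (least-median-of-
squares) location of the per-domain group-mean log-ratios, which stays
anchored on the unchanged majority up to 50% coherent contamination.
Residual borderline false positives (|log2FC| ≈ 0.2 at dispersion
0.005) still occur at roughly the nominal BH rate.

The per-cell fraction of reads in a domain subset (FRiP) excludes
cells with zero reads and contrasts ages with the rank-sum test. The
top-1% overlap enrichment ranks elements by p-value (ties by |log2FC|
descending, then id) and tests the 2×2 overlap table with Fisher's
exact test (sample odds ratio, Haldane correction on zero cells). The
domain–cluster enrichment reports the observed fraction of domains
hitting ≥ 1 cluster against both an analytic baseline (genome fraction
covered by clusters) and, as the headline, a shuffle null that
replaces the domain set uniformly at random (sizes preserved, same
chromosome, non-overlapping), with p = (1 + #{null ≥ obs})/(n + 1).
Because the observed fraction is discrete over ~10 domains, this p is
valid but lumpy rather than exactly uniform under the null. At the
synthetic genome's scale (3 × ~1-Mb clusters on 40 Mb ≈ 7% coverage)
the attainable fold enrichment is ~2 by construction — orders of
magnitude less genome sparsity than a real mammalian genome, where
clusters cover < 1% and folds of tens are possible.

Aggregate profiles over element instances (e.g. one TE subfamily) use
a fixed grid: `flank` bp each side at 1-bp resolution, the body
rescaled to 100 points, minus-strand instances mirrored, the mean over
instances block-averaged by 10, optionally normalised to the flank
level.

## The synthetic study

Defaults are the study conditions; one seed drives all draws through
fixed sub-streams.

* Genome: 2 chromosomes × 20 Mb. 4,000 disjoint cCREs of 200–1,000 bp;
  600 genes with one stranded TSS each.
* Samples: 3 cell types (one excitatory-neuron-like, "ExN") × ages
  {3, 10, 18} months × 2 replicates; 500 cells and ~2×10⁶ ATAC reads
  per pseudo-bulk. Linking analyses use 12 cell types (36 merged data
  points).
* Accessibility: per-cCRE lognormal baseline (sigma = 1) times a
  per-(cCRE, cell type) lognormal factor (sigma = 0.5) — cell-type
  specificity is what makes correlation-based linking identifiable.
  NB dispersion 0.1.
* Age effects: 5% of non-cluster cCREs age-up and 5% age-down in one
  random cell type, multiplicative fold 1.5 per age step (10-month
  samples intermediate, so trends are monotone; 18/3-month ratio
  2.25).
* Domains: 10 disjoint domains of 0.5–1.5 Mb placed with ≥ 2 Mb
  separation; 40% decay with age in ExN only (factor 1 − 0.3·step/2,
  i.e. 0.7 at 18 months). Domain-level NB dispersion 0.005 —
  megabase-scale aggregates over hundreds of nuclei vary far less
  across replicates than individual 200–1,000-bp elements. Sample
  H3K9me3 library sizes are full depth (60% in domains at baseline,
  40% genomic background), so decay removes reads instead of
  redistributing them.
* Clusters: 3 planted 1-Mb clusters of 100 cCREs, each inside a
  distinct decaying domain (hosts sized to fit the full span), all
  age-up in ExN. With per-element detection power ~0.15–0.2 at the
  stringent p < 0.001 binning threshold, a planted cluster yields
  ~15–20 detectable members — a detectable-by-design effect.
* RNA: 200 linked genes follow the summed expected CPM of their linked
  cCREs (15% carry a second linked element) through a shared latent
  activity with lognormal noise; the noise is calibrated by inverting
  the lognormal level-correlation formula so the *measured* WPCC on
  CPM levels targets 0.8. Multi-link genes realise a lower per-pair
  correlation (the RNA follows the sum), which is intrinsic to the
  shared-latent design.
* Per-cell H3K9me3: ~2,000 reads per cell assigned multinomially to
  domains and background, with the decay factor applied in ExN, giving
  the substrate for the FRiP statistic.
* Fragments: short stylised tags whose two shift-corrected cut sites
  coincide at a position drawn from a uniform background plus a flat
  ±100-bp plateau at each TSS weighted to the configured fold (15×).
  10% of barcodes are degraded (half sparse, half background-only) for
  filter testing.

What the generator does **not** emulate: genomic sequence, GC or
mappability structure, doublets, batch effects, fragment-length
periodicity, TSS-profile shape beyond a flat plateau, within-cell-type
substructure, and mean–dispersion trends. Passing tests therefore
demonstrate the statistical machinery under its stated model, not
robustness to those real-data complications.

## Numerical conventions and degenerate inputs

Coordinates are 0-based half-open everywhere; 1-based inputs are
rejected, not shifted. Fragment–interval overlap counts whole
fragments at ≥ 1 bp (featureCounts-on-pairs semantics); insertion-site
semantics are used only for TSS enrichment. Fragments with insert size
≥ 2,000 bp are rejected at parse time. Barcodes missing from the
sample mapping are skipped and tallied, not errors. Zero-variance
correlation pairs are flagged with p = 1; all-zero features get p = 1
and log2FC = 0; empty cluster or domain inputs return empty calls; an
empty concordance group flags the result. All shuffle and permutation
operations take explicit seeds, and gzip output is written with a
fixed timestamp so identical runs are byte-identical.

## Problem sizes

The default test and acceptance workloads use 4,000 cCREs, 600 genes,
5,000-feature calibration simulations, 1,000 permutations/shuffles for
cluster and overlap nulls, 50-seed cluster-null replication and
200-seed overlap-null replication — sizes chosen so the full suite and
the acceptance script each complete in minutes on a single CPU while
keeping Monte-Carlo error well below the tolerances being checked.
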