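# Methods

## The assay and the statistical model

mSTARR-seq couples a massively parallel reporter assay to CpG methylation:
a fragment library is cloned into a self-transcribing reporter plasmid,
split into a mock-treated (unmethylated) and an M.SssI-treated (fully
CpG-methylated) pool, and transfected into cells. Fragments with regulatory
activity drive transcription of their own sequence, so the mRNA/DNA read
ratio over a genomic window measures enhancer activity, and the contrast of
that ratio between pools measures methylation dependence.

The genome is tiled into fixed non-overlapping windows (200 bp default).
For each window, with normalized abundance `y_i` for sample `i`, sample
type `t_i` (DNA input = 0, mRNA = 1) and condition `c_i` (unmethylated = 0,
methylated = 1), two weighted linear models are fitted:

* nested:      `y = mu + t*b1*I[c=0] + t*b2*I[c=1] + e`
* interaction: `y = mu + t*bt + c*bc + t*c*btxc + e`

`b1`/`b2` are the mRNA-over-DNA excess within each condition; `btxc` is the
methylation dependence (negative = more active when unmethylated). A window
is an *enhancer* if `b1` or `b2` is positive with q-value below the FDR
threshold (0.10); among enhancers, a window is a *methylation-dependent
(MD) enhancer* if the interaction q-value — computed over the enhancer set
only — passes the same threshold.

## Analysis-set filters

Two filters define the analyzable windows. Detection: nonzero mRNA and DNA
counts in at least half the replicates of every condition (threshold
exposed as `min_fraction`). DNA stability: all pairwise signed differences
in normalized DNA abundance between replicates are pooled genome-wide; a
window is removed if more than 25% of its pairs fall outside the pooled
central 90% interval. Pooling is genome-wide; differences are signed and
taken in a fixed replicate order (the symmetric central interval makes the
result order-invariant).

## Normalization

Counts become `log2((count + 0.5) / (lib + 1) * 1e6)` with the library size
taken as the column sum before filtering. Precision weights follow the
standard mean–variance-trend construction: a locally weighted regression
(span 0.5, 4 robustness iterations) of the square-root residual SD on
average log2-CPM, with each observation weighted by the inverse fourth
power of the trend value at its fitted abundance. Optional per-sample
quality weights are estimated by at most two alternations between
window-wise weighted fits and per-sample residual variance factors,
normalized to geometric mean 1. RNA and DNA samples are normalized jointly
(both enter the same per-window models), with the interaction design as the
normalization design.

## Multiple testing

Storey q-values: `pi0(lambda) = #{p > lambda} / (m (1 - lambda))` on a grid
0.05..0.95, smoothed by a cubic least-squares fit evaluated at the largest
lambda; if the smooth leaves (0, 1], a bootstrap estimator (minimum
estimated MSE over the grid) takes over. q-values are the `pi0`-scaled
cumulative minimum of `m p_(j) / j` from the largest p downward.
Benjamini–Hochberg adjustment is provided as a cross-check and equals the
Storey q-values when `pi0` is fixed at 1.

## Directional q-values and the empirical-null offset

Two properties of reporter count data required numerical care:

* **Composition shift.** Active windows absorb a disproportionate share of
  each mRNA library, so after counts-per-million scaling the typical
  *inactive* window sits slightly below zero on the `b1`/`b2` scale. Under
  a two-sided test, those windows reject "beta = 0" in the negative
  direction, the estimated null proportion collapses, and q-values lose
  their meaning for the directional call ("beta > 0 at FDR < 0.1"). The
  enhancer q-values are therefore computed from upper-tail (one-sided)
  p-values by default, which matches the directional call exactly; the
  reported p-values remain two-sided, and `alternative="two-sided"`
  restores the symmetric behavior.
* **Interaction offset.** Because more MD enhancers lose than gain activity
  under methylation, the two mRNA pools differ slightly in composition,
  giving every null window a small positive interaction offset. Since well
  under 2% of windows carry a true interaction, the genome-wide median of
  `btxc` estimates this null offset; it is subtracted before the
  interaction test (`center_interaction_null=True`, applied only when at
  least 50 windows are available). This is an empirical-null location
  correction in the spirit of genomic control.

Both corrections act on the calling layer; the single-window fitting
functions are exact weighted least squares without any adjustment.

## MD classifier

The classifier contrasts methylation-suppressed MD enhancers against
enhancers with interaction q-value above 0.5 (strong evidence against
methylation dependence), after dropping rows with any missing feature
(pre/post counts are reported). The forest is explicit bagging over
decision trees (1000 trees by default, mtry = floor(sqrt(F)), node size 1,
no class weights) so that each tree's out-of-bag rows are known. OOB votes
give the accuracy estimate; a region is assigned a class only when more
than 50% of its OOB votes agree (exact ties are left unclassified).
Feature significance combines randomForest-style scaled mean decrease in
accuracy (per-tree OOB permutation, normalized by the SD of the per-tree
differences over sqrt(n_trees)) and mean Gini decrease; empirical p-values
come from whole-forest label permutations via the `+1/(n+1)` estimator, and
a feature is significant only when both measures pass the 10% empirical
FDR. Rows and columns are canonicalized (content/name sorted) before any
random draw, so results are invariant to input ordering. Note that the
permutation count bounds the attainable p-value at `1/(n_perm + 1)`; with
m features, `n_perm` must exceed `m / fdr` for any feature to pass.

## Synthetic-data generator

The generator emulates the study's statistical structure with known truth:

* Counts: negative binomial with a single shared size parameter
  (default 10; variance = mu + mu^2/size; Poisson in the infinite-size
  limit), window propensities Dirichlet(5), target depth 1e6 reads/sample,
  6 + 6 replicates with droppable replicates. DNA means are
  `depth * propensity`; mRNA means are additionally scaled by the
  condition's activity multiplier — methylation acts only on the mRNA
  rate, since the plasmid DNA pool is methylation-independent.
* Truth: enhancers are Bernoulli(0.08) per window with baseline activity
  log2 fold changes uniform on (1, 4); 15% of enhancers are MD with
  interaction log2 effects uniform on (1, 3), direction Bernoulli(0.86)
  toward more-active-when-unmethylated; MD propensity scales with
  `1 - exp(-0.5 * CpG count)` (CpG counts Poisson(4)), and CpG-free
  windows are never MD.
* Features: standard-normal columns, with informative columns shifted by a
  configurable effect size (in SDs) in MD windows; optional missingness.
* Methylation: pre-transfection levels 0/1 by condition; post-transfection
  levels drift toward a bimodal endogenous landscape (Beta(0.4, 0.4)) at
  TFBS-specific rates; observed counts are binomial given level, coverage
  and a bisulfite error rate (0.003); an unmethylated spike-in contig
  supports conversion-efficiency estimation.
* In vivo pairs: per-pair methylation M-values and expression across
  individuals, with a causal fraction correlated at `rho_causal` and the
  rest independent.
* Luciferase: `log2 activity = a + b * assay estimate + c * length + batch
  + noise` with 18 constructs, 8 replicates per condition (1–2 droppable),
  4 batches.

Every operation draws from its own labelled random stream derived from the
master seed (SHA-256 of the label into the seed sequence), so adding one
simulation never perturbs another's draws and identical seeds give
byte-identical outputs.

What the generator does *not* emulate: fragment-length structure and
alignment artifacts, GC/mappability bias, correlated windows (linkage of
overlapping fragments), per-window dispersion heterogeneity, and batch
structure in the sequencing counts. Passing calibration tests on these
simulations therefore demonstrates correctness of the statistical
machinery under the stated generative model, not robustness to every
artifact of real sequencing data.

## Problem sizes used in the checks

The full-scale calibration runs use 20,000 windows at 1e6 reads/sample
(the per-window depth then matches a genome-scale experiment); null
uniformity uses 20 runs of 5,000 windows; classifier calibration uses
n = 2000 rows with 600 label permutations and 20 trees per forest (the
defaults remain 1000/1000 for analysis use; 600 is the smallest
permutation count whose p-value floor clears a 10% FDR over 51
features); luciferase recovery averages
50 simulated experiments. These sizes give Monte-Carlo error comfortably
below the asserted tolerances.

## Numerical choices and degenerate inputs

* Windows whose weighted normal equations are singular (e.g. an empty
  design cell after replicate loss) yield NA results with a
  `rank_deficient` reason code; exact fits (zero residual variance) yield
  NA p-values with `exact_fit` rather than p = 0.
* Fisher odds ratios use the Haldane–Anscombe 0.5 correction when a cell
  is zero (flagged), with Woolf 95% intervals on the corrected table; a
  zero margin returns an undefined-result marker.
* Spearman correlations use average ranks for ties throughout; ranking
  ties in the TF methylation-delta ordering are broken by TF name.
* The demethylation logistic model reports McFadden pseudo-R^2; complete
  separation falls back to an L2-penalized fit, flagged.
* The luciferase mixed model is fitted by REML; a singular random effect
  falls back to batch-as-fixed-effect, flagged. "Variance explained" is
  reported both as the squared correlation of the fixed-effect prediction
  with the response and for the assay-estimate term alone, so either
  reading of a variance-explained claim can be checked.

## Known limitations

* The stability filter pools differences genome-wide; per-chromosome
  pooling is not implemented.
* The motif-enrichment p-value is a Fisher exact test of hit counts
  against the background set; external scanners' binomial approximations
  are not replicated (a deliberate methodological substitution — the
  module consumes scanner hit tables, it does not scan).
* Empirical-Bayes variance moderation is deliberately absent: the calling
  models are plain weighted least squares with t-tests on the normalized
  values.
* The end-to-end direction-split check is evaluated on correctly
  recovered MD windows: those are the draws from the direction
  distribution, while contamination from false calls is bounded
  separately by the false-discovery-proportion check.
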