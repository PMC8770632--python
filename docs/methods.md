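# Methods

`kerndep` implements a network-guided variable-selection and modeling
workflow for predicting how strongly cancer cell lines depend on a focal
gene (the default focal gene throughout is KRAS) from whole-transcriptome
expression. The premise is that useful predictors of dependency are genes
close to the focal gene in the protein-protein interaction network, where
"close" is measured by heat diffusion rather than hop count.

## Network construction

Protein-protein interactions arrive as a STRING-dialect edge list with a
confidence score per pair (0–1000 or 0–1; the scale is auto-detected and
weights are normalized to [0, 1]). Proteins are mapped to gene symbols
(uppercased, first-listed alias per protein; unmapped proteins are dropped
with a count), duplicate scores between the same unordered gene pair are
replaced by their arithmetic mean, and self-loops are removed — the
Laplacian construction below assumes a simple graph. Edges scoring below a
percentile of the gene-level score distribution (default: 90th) are
discarded; the percentile uses linear interpolation between order
statistics (the "type 7" rule, the default of mainstream statistical
environments) and ties at the threshold survive, since only strictly lower
scores are dropped. The threshold is computed after duplicate averaging —
on gene-level edges — and is recorded in the network's provenance so the
alternative convention is auditable. Finally the graph is restricted to
the focal gene, its direct partners (shell 1) and their partners
(shell 2), by breadth-first search on the filtered edges; shell labels and
all filter counts are stored with the network.

## Diffusion kernel and centrality

For the retained graph with adjacency A (binary by default: surviving an
edge filter is treated as presence; a weighted mode is available) and
degree matrix D, the kernel is

    K = exp(beta * H),    H = -(D - A)

computed by symmetric eigendecomposition, which is exact to machine
precision; the defining power series I + beta H + (beta^2/2!) H^2 + … is
retained only as an independent test oracle. Because H is symmetric with
zero row sums, K is a symmetric stochastic matrix — each row sums to 1, and
K[i, j] is the share of heat flowing from node i to node j in "time" beta.
beta controls diffusion extent: as beta → 0, K → I; on a connected graph,
as beta grows every row approaches the uniform distribution. The default
beta schedule is 0.75^n for n ∈ {1, 5, 10, 20, 30}.

Centrality (closeness) of gene i defaults to the focal row of the kernel,
K[focal, i] — the heat the focal gene sends to i — because the network is
explicitly focal-centered and because row sums of K are constant (a
row-sum "closeness" would be degenerate). An alternative
`kernel_distance_closeness` method, 1 / Σ_j d(i, j) with
d(i, j) = sqrt(K_ii + K_jj − 2 K_ij), is provided and labeled in
provenance.

## Predictor selection

Selection is strictly unsupervised — no stage sees the dependency
variable. Candidate genes (the network's genes) are reduced by:

1. dropping genes with any missing expression value across the cohort;
2. dropping genes whose mean log2(TPM+1) expression does not strictly
   exceed the configured percentile (default grid: P25, P50, P75, P95) of
   the candidates' mean expression — the reference distribution is the
   candidate pool itself, not the whole transcriptome, since the filter
   sits inside the network selection workflow;
3. keeping the k highest-closeness genes (grid: 100, 500, 1000), ties
   broken lexicographically.

The mean (rather than median or minimum) is the recorded choice of
expression summary, computed over the full modeling cohort; filtering
before splitting shares information between train and test folds, which is
inherent to the published workflow and is deliberately reproduced. The
default grid of 4 expression percentiles × 5 betas × 3 gene counts gives
60 predictor sets per dependency dataset; with 100 resamples and two
dependency screens that schedules 12,000 models. (Elsewhere a count of 105
predictor sets appears for this workflow; the grids here are config-driven
and default to the 4×5×3 protocol grid that the model counts are built
from.) Non-kernel predictor sets — all RNA genes, all network genes,
published signature lists, RAE markers, mutation indicators — are plain
named gene lists fed to the same modeling engine.

## Cohort classification

* **wt/mut**: a line is mutant in a gene iff it carries ≥ 1 non-silent,
  non-deleterious mutation there (the pattern of an activating hotspot).
  Silent variants are excluded from the mutant call for consistency with
  the predictor encoding below.
* **dependent/independent**: dependency probability strictly > 0.5.
* **amplified**: gene copy number divided by the sample's mean copy number
  (NaNs excluded from the mean) strictly > 3.
* **RAE matrix**: binary dependent-calls on a configured marker gene list
  plus the amplification flag (with the reference 42-gene marker list this
  is 43 markers). The marker list is a plain text input; a synthetic
  default ships with the generator.
* **mutation predictors**: three binary indicators — deleterious (any
  deleterious record), hotspot and other (non-silent, non-deleterious,
  with/without hotspot annotation).
* **group comparison**: two-sided Wilcoxon–Mann–Whitney rank-sum test,
  exact for combined n ≤ 20 without ties, tie-corrected normal
  approximation otherwise; the path taken is deterministic in the data.

## Ensemble modeling and evaluation

The lasso objective is RSS + λ Σ|β_j|; the elastic net adds the ridge term
with the same λ on both penalties (RSS + λ Σβ_j² + λ Σ|β_j|). Fits are
delegated to scikit-learn with the penalty re-parameterized exactly
(lasso: alpha = λ/2n; elastic net: l1_ratio = 1/3, alpha = 3λ/2n, because
scikit-learn halves its L2 term). λ defaults to the 10-fold
cross-validation minimum inside each training split; a fixed λ can be
given in the objective's own units. Predictors are standardized on
training statistics and coefficients are reported on the original scale.
Random-forest regression uses 500 trees and ⌊p/3⌋ features per split, the
classical regression defaults, and shares the split schedule with the
linear models at the same seed.

Each ensemble draws `n_models` (default 100) independent uniform 80/20
splits from counter-derived child streams of one master seed
(`SeedSequence(seed, spawn_key=(model_index,))`), so results are
reproducible and independent of execution order. Per cell line, test-set
predictions are averaged over the models in which that line was held out;
the ensemble score is the Pearson correlation between these averages and
the observed dependency over covered lines. Lines never held out (possible
at very small `n_models`) are reported and excluded, never silently
dropped. When the averaged predictions are constant — e.g. every model
shrank to its intercept — the correlation is reported as 0 with a warning
rather than NaN.

The frequency analysis counts, per gene, how many models gave it a
negative or positive coefficient (negative = higher predicted dependency
under the gene-effect sign convention). The exclusion analysis removes a
gene list from the network predictor superset and refits; a drop in r that
the remaining network cannot compensate indicates the excluded genes carry
non-substitutable signal.

### A caveat on repeated-holdout averaging

Averaged held-out predictions are not independent of the observed values
under the null. A line's own y is excluded from the training set — and
hence from the training mean — of every model that predicts it, so when
models shrink toward their intercepts, E[ŷ_i] acquires a slope of
−1/n_train in y_i, and the null correlation converges to
−1/sqrt(1 + (n_test − 1)/coverage) — about −0.58 at 200 lines with 100
splits — instead of 0. The effect is negligible whenever predictions carry
genuine variance (it scales with σ/n_train relative to the prediction SD),
but it dominates for intercept-collapsed models: a permutation null of
this protocol therefore shows a systematic negative correlation rather
than |r| ≈ 0. This is a property of the evaluation design itself; the
package reproduces it faithfully and reports it (see the
`null_mean_abs_r` output of the acceptance script).

## Synthetic data generator

The generator emulates the shapes of the real inputs — STRING-style edge
list and alias map, DepMap-style expression, gene-effect,
dependency-probability, mutation and copy-number tables — with planted,
recoverable structure. Defaults define the study conditions: 500 genes,
200 cell lines, 5 planted predictor genes, designed R² = 0.5.

* **Network** (`two_shell_planted`): a spanning backbone (focal → 50
  shell-1 genes → 449 shell-2 genes) whose edges score in the top decile
  (≥ 900/1000), plus nine filler edges per backbone edge scoring below
  890, so the 90th-percentile filter retains exactly the backbone.
  Planted genes are dedicated focal partners: they sit in shell 1 and
  host no shell-2 children, which keeps them kernel-central across the
  beta schedule (heat sent to a low-degree partner is not dissipated
  onward). A preferential-attachment topology is available for
  heavy-tailed degree structure.
* **Expression**: per-gene right-skewed baselines (gamma) on the
  log2(TPM+1) scale, clipped at 0; adjacent genes share latent variation
  through a parent-latent construction (child signal =
  sqrt(1−ρ)·own + sqrt(ρ)·parent latent, ρ = 0.1, giving adjacent
  correlation ≈ sqrt(ρ(1−ρ)) ≈ 0.3); a 15% low-expression gene fraction
  exercises the expression filter and optional NaN injection exercises the
  missing-value filter. Planted genes are kept expressed so their signal
  is observable.
* **Dependency**: the focal gene's effect is Σ w_g · z(expr_g) over the
  planted genes plus a mutation shift and Gaussian noise; default weights
  (−1.0, −0.8, 0.6, −0.5, 0.4) mix signs so the frequency analysis has
  both directions to find. More-negative effect = more dependent (the
  gene-effect convention). Noise SD is derived from the target R² (0.5) so
  recoverable signal is scale-free: the attainable correlation is about
  sqrt(R²) ≈ 0.71, and the 100-gene lasso ensemble reaches r ≈ 0.55–0.65.
  Dependency probability is a steep logistic of the negated, centered
  effect, calibrated so roughly the most-dependent quarter of lines
  crosses the 0.5 call.
* **Mutations / copy number**: activating focal mutations in a seeded 15%
  of lines (80% flagged hotspot), with silent and deleterious decoys on
  wild-type lines; copy numbers center at 2 with 10 lines set to a focal
  copy number whose relative value exceeds 3.

What passing on this generator does **not** show: the generator has no
tissue/entity structure, batch effects, realistic transcriptome marginals,
or correlated measurement error between expression and dependency screens;
recovery here demonstrates that the machinery is correct, not that the
biological signal in any particular DepMap/STRING release is of comparable
strength. Results published on real 21Q1-era data (network size, headline
correlations, RAE fractions) are snapshot-dependent and are not asserted
by this package.

## Numerical and degenerate-input choices

* Kernel: eigendecomposition, symmetrized and clipped at 0 (round-off
  never exceeds 1e-10); kernel invariants (symmetry, row sums,
  nonnegativity) are validated at construction.
* Percentiles: linear interpolation everywhere, strict `>` for expression
  and classification thresholds, `>=` for edge-score retention.
* Top-k ties: lexicographic by gene symbol; all-equal expression
  summaries empty the filter with a warning rather than erroring.
* Ensembles: train size = round(0.8 n) clamped to [1, n−1]; < 10 training
  rows or a constant training response is an error; constant-column
  predictors get unit scale (their coefficient is exactly 0).
* Problem sizes: unit tests run on 40–80-line bundles; the study-scale
  checks use 200 lines × 500 genes × 100 splits, at which the full
  acceptance run completes in a few minutes on one core.

## Known limitations

* Closeness from the focal row is one of several defensible readings of
  kernel centrality; the alternative kernel-distance closeness is included
  but the two are not interchangeable and the choice is recorded.
* The five-value beta schedule is the protocol default; the workflow it
  reproduces mentions seven closeness estimates without listing the extra
  two, so the schedule is exposed as configuration.
* The permutation-null bias of holdout averaging (above) means ensemble r
  values near zero should be interpreted against a slightly negative, not
  zero, null expectation when models are heavily shrunken.
* Hotspot/deleterious annotations are taken as given; no variant-level
  re-annotation is performed.
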