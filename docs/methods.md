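# Methods

## Problem setting

A single-point mutation in an antibody's CDRs changes the binding free energy
of the antibody–antigen complex. The quantity of interest is
ΔΔG_binding = ΔG_binding(mutant) − ΔG_binding(wild-type), in kcal/mol, with
positive values meaning weakened binding. Constituent predictors estimate
this quantity (or the related fold-stability change ΔΔG_folding) from the
complex structure; `ddgstack` never runs those programs — it consumes their
numeric outputs as feature columns and learns a meta-model on top.

## The stacked models

Let x_i ∈ R^p be the vector of p predictor scores for mutant i and y_i its
experimental ΔΔG.

**GPR.** Features are standardized per column (mean/sd learned on the
training rows only) and the target is centered; the GP uses the kernel

    k(x, x') = s_f^2 * exp(-||x - x'||^2 / (2 l^2)) + s_n^2 * 1[x = x']

with a single shared length-scale, which is why column standardization
matters. Hyperparameters maximize the log marginal likelihood on the
training set alone — no validation data — so plain (non-nested) CV is a fair
evaluation. Search bounds: amplitude [1e-3, 1e3], length-scale [1e-2, 1e3],
noise [1e-6, 1e1] on the centered-target scale (the noise floor prevents
degenerate noise-free fits of noisy calorimetry/SPR-derived targets).

*Initialization.* The marginal-likelihood surface has a spurious basin in
which the length-scale collapses to its lower bound: the kernel matrix
becomes diagonal, the GP explains everything as noise plus per-point spikes,
and predictions degenerate to a constant. Starting the optimizer at noise
level 1.0 (the scale of the centered-target variance) and length-scale
sqrt(p) (the typical inter-point distance of standardized features) avoids
the basin reliably; two additional seeded random restarts are kept as
insurance, and the restart count is configurable (`StackSpec.gpr_n_restarts`).
On standardized stacked features all restart counts from 0 to 10 reach the
same optimum with this initialization, so more restarts buy runtime, not
accuracy.

**RFR.** Squared-error splits, bootstrap resampling, unlimited depth, all
features considered at every split. The tree count is the one tuned
hyperparameter; the default candidate grid {16, 64, 128, 256, 512} is
log-spaced to bracket the performance plateau at a few hundred training
rows. Feature importance is Gini / mean decrease in impurity, averaged over
trees and normalized to sum to one.

**Determinism.** Both fits are bitwise deterministic given
(features, targets, spec, seed).

## Evaluation protocol

* `make_folds(n, k, seed)`: uniformly random balanced partition; fold sizes
  differ by at most one.
* Repeated CV: repeat r uses fold seed `master_seed + r`; default 100
  repeats of 4 folds. The repeat-level score is the unweighted mean over
  test folds of the Pearson correlation between predictions and experimental
  ΔΔG (not a pooled-prediction correlation). Reported per method:
  mean over repeats ± SEM (sample sd / sqrt(n_repeats)).
* Nested CV (RFR only): inside each outer training set, an inner 4-fold CV
  scores every candidate tree count by mean validation Pearson R; ties go to
  the smallest count; the forest is refit on the full outer training set.
  The audit trail records every fold label, every inner split and every
  selected tree count, and `verify_cv_hygiene` proves that outer test
  indices never reach an inner loop.
* Method comparison: the per-repeat scores of two methods evaluated under an
  equal scheme share fold assignments (common random numbers), so the
  two-sided Wilcoxon signed-rank test over the paired per-repeat differences
  is the comparison statistic. Zero differences are dropped (Wilcoxon's
  original treatment), tied absolute differences get midranks; the null
  distribution is computed exactly by rank-sum convolution for effective
  n <= 25 and by normal approximation with continuity and tie corrections
  above that (the branches agree to |dp| <= 0.01 in the overlap region).
* Fold scoring convention: a constant *target* in a test fold is an error
  (the fold cannot be scored); constant *predictions* against a non-constant
  target score R = 0, because a constant predictor carries no linear
  association — this keeps null evaluations (pure-noise ensembles, where the
  GP honestly collapses to its noise-only optimum) well defined.
* Fold splitting is by mutant, uniformly at random, not grouped by antibody
  complex; a grouped option is deliberately not offered (see Limitations).

## Leakage firewall

A constituent predictor that is itself a trained machine-learning model
(here: mCSM-AB) may have seen some benchmark mutants during its own
training; its raw scores for those mutants would leak the answer into any
evaluation. The feature table therefore carries `firewall_flags` — the set
of (record, predictor) cells with such overlap — and
`firewall_substitutes` — leakage-safe replacement values, typically the
constituent's published cross-validated predictions.
`apply_leakage_firewall` substitutes exactly the flagged cells and errors,
listing the offending cells, if any flagged cell lacks a substitute. The
substitutes travel inside the table rather than being fetched from any
server, generalizing the published-predictions mechanism to arbitrary
user-supplied leakage-safe values.

## Consensus baseline

`consensus_score` is the row-mean of per-predictor Z scores computed over
the whole supplied table (sample sd, ddof = 1 by default; configurable).
The transform touches no target values, so computing it on the full table
introduces no label leakage. Named subsets `cons3`
(SIE-Scwrl_mut, Ros_mut, FoldX-S) and `cons4` (cons3 + FoldX-B) reproduce
the historical consensus panels. Standardization is global, not
per-complex.

## Synthetic generator

The generator emulates the statistical structure of a curated antibody
single-point-mutant benchmark:

* **Truth.** ΔΔG_exp ~ shift + Gamma(shape, scale); defaults
  shape 2, scale 1.2, shift -0.65 kcal/mol give a right-skewed distribution
  supported on [-0.65, ∞) with mean 1.75 — mostly mildly destabilizing
  mutations, a few strongly destabilizing, matching the range of curated
  antibody mutant panels.
* **Predictors.** With the truth standardized internally (t) and f a vector
  of m shared standard-normal latent factors, predictor j's standardized
  score is s_j = alpha_j t + gamma_j . f + eps_j with eps_j ~ N(0, sigma_j^2),
  then rescaled by a positive affine map to a kcal/mol-like spread.
  Closed forms follow:

      corr(s_j, t)   = alpha_j / n_j,         n_j = sqrt(alpha_j^2 + |gamma_j|^2 + sigma_j^2)
      corr(s_j, s_k) = (alpha_j alpha_k + gamma_j . gamma_k) / (n_j n_k)

  `calibrate_noise` inverts these exactly for an exchangeable block
  (alpha = r_truth, gamma = sqrt(r_pair - r_truth^2),
  sigma = sqrt(1 - r_pair)), feasible iff r_pair >= r_truth^2.
* **Outliers.** With probability `outlier_rate` a cell's noise term is
  multiplied by `outlier_scale`, emulating the occasional wild predictions
  of loop-remodelling protocols. Where contamination is on, sigma is shrunk
  by sqrt(1 + rate*(scale^2 - 1)) so the calibrated correlations still hold.
* **Benchmark-scale config** (`sipmab_like_config`): 212 records, the 12
  registry predictors, one shared factor. Truth correlations: four
  informative predictors (Ros_mut 0.60, SIE-Scwrl_mut 0.58, mCSM-AB 0.56,
  DS-B 0.55) and eight weaker ones (0.45–0.52); pairwise targets 0.66
  (informative block) and 0.58 (weak block) put all pairwise correlations in
  the 0.5–0.8 band; Ros_iface-sc and Ros_CDR-loop carry small contamination
  (rate 0.02, scale 5). At n = 212 a single draw's empirical correlation
  wanders ~±0.06 (and co-fluctuates with the shared factor draw), so
  individual tables can stray slightly outside the calibrated bands; the
  across-seed means sit on target.
* **Reduction benchmark** (`informative_plus_noise_config`): the same four
  informative predictors plus eight near-noise ones (truth correlation 0.10,
  pairwise 0.20) — a setting where importance-based predictor reduction has
  a well-defined right answer.
* Mutation labels (complex, chain, position, residues) are random and
  biologically unvalidated; no method reads them. The generator does not
  emulate structure-derived feature distributions or per-complex batch
  effects, so passing tests demonstrate correctness of the statistical
  machinery on realistically correlated ensembles, not accuracy on any real
  antibody system.

## Problem sizes in the shipped analyses

GPR-based quantities use the full protocol (100 repeats of 4-fold CV,
n = 212). The nested-CV random-forest evaluation runs at 10 repeats and the
averaged-importance analyses at 2 repeats x 4 outer folds with 256 trees;
the importance-recovery rate is estimated over 20 generated tables in the
acceptance script (100 in the test suite) and the independent-data benchmark
over 30 train/test pairs. These sizes keep a full reproduction run to a few
CPU-minutes while leaving the Monte-Carlo error of each reported rate well
below the effects being measured.

## Known limitations

* **MDI masking.** Gini importance of deep, all-features-per-split forests
  concentrates on the locally strongest of a correlated group of informative
  features and gives every feature a nonzero deep-split baseline. At
  n = 212 with four informative predictors inter-correlated at ~0.66, the
  weakest informative predictor's importance occasionally (roughly 1 draw in
  12) falls below a near-noise feature's baseline, so top-4 recovery by
  importance ranking is reliable but not certain. Permutation importance
  would mitigate this but is outside the scope of the Gini-based protocol
  implemented here.
* The oracle-free single-predictor baseline for independent-data comparisons
  is selected on the training table; selecting it on a 34-record test set
  would inflate the baseline by the maximum of twelve noisy correlations.
* Global (not per-complex) Z-standardization; random (not complex-grouped)
  CV folds; point predictions only (no GP posterior intervals); no
  imputation — missing feature values are hard errors.
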