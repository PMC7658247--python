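# ddgstack

Stacked meta-prediction of antibody binding affinity changes upon mutation
(ΔΔG<sub>binding</sub>), for computational antibody engineers who already run a
battery of structure-based ΔΔG predictors and want a principled way to combine
them.

## The problem and the method

Single-point mutations in an antibody's complementarity-determining regions
change its binding free energy to the antigen; predicting that change,
ΔΔG<sub>binding</sub> = ΔG<sup>mut</sup><sub>binding</sub> −
ΔG<sup>wt</sup><sub>binding</sub> (kcal/mol, positive = weakened binding),
guides affinity maturation. Many predictors exist — molecular-mechanics
protocols combining a scoring function (SIE, Talaris2013, Talaris-interface,
CHARMm Polar H, FOLDEF) with mutant/unbound structure-regeneration schemes, and
machine-learning models such as mCSM-AB — but no single one is accurate enough
on its own.

`ddgstack` treats each predictor's score as a feature and learns a *stacked*
regression from the feature vector **x** = (s₁, …, s_p) to the experimental
ΔΔG:

* **GPR stack** — Gaussian-process regression with kernel
  k(x, x′) = σ²_f · exp(−‖x − x′‖² / 2ℓ²) + σ²_n δ(x, x′); hyperparameters
  (σ_f, ℓ, σ_n) maximize the log marginal likelihood on training data only.
* **RFR stack** — random-forest regression with squared-error splits; the
  tree count is the one tuned hyperparameter, selected by nested
  cross-validation strictly inside each outer training fold. The forest also
  yields Gini (mean-decrease-in-impurity) feature importances, used to prune
  the predictor panel.
* **Consensus baseline** — the historical alternative: the unweighted mean of
  per-predictor Z scores, z_j = (s_j − mean(s_j)) / sd(s_j), over a named
  subset (`cons3`, `cons4`).

Evaluation follows a repeated cross-validation protocol: 100 repeats of
4-fold CV; the repeat-level score is the mean over test folds of the Pearson
correlation between predicted and experimental ΔΔG; methods are compared by a
paired two-sided Wilcoxon signed-rank test over the 100 per-repeat scores,
which share fold assignments across methods. Scores of a machine-learning
constituent predictor that overlap its own training data pass through a
*leakage firewall* that substitutes leakage-safe (cross-validated) values.

A calibrated synthetic generator produces feature tables with the statistical
structure of a real antibody mutant benchmark (right-skewed ΔΔG from a shifted
gamma; predictor columns from a latent loading model with closed-form truth
and inter-predictor correlations), so the entire pipeline is testable without
any external download.

## Worked example

Generate a benchmark-scale synthetic table (212 mutants × 12 predictors) and
compare the best single predictor, the 4-predictor consensus and the GPR
stack under shared repeated-CV folds:

```sh
ddgstack simulate --out sipmab_like.csv --seed 7 --n-records 212
ddgstack evaluate --table sipmab_like.csv \
    --method single:Ros_mut --method cons4 --method gpr \
    --repeats 20 --seed 0 --out report.json
```

which prints (and writes to `report.json` / `report.txt`):

```
Repeated 4-fold CV, 20 repeats (master seed 0)

  single:Ros_mut                 R = 0.616 +/- 0.001 (SEM)
  cons4                          R = 0.642 +/- 0.002 (SEM)
  gpr                            R = 0.669 +/- 0.003 (SEM)

  single:Ros_mut vs cons4: dR = -0.026, p = 1.91e-06
  single:Ros_mut vs gpr: dR = -0.052, p = 1.91e-06
  cons4 vs gpr: dR = -0.027, p = 1.91e-06
```

Each `R` is the mean (± standard error over the 20 repeats) of the per-repeat
Pearson correlation with experimental ΔΔG; each `p` is the paired Wilcoxon
signed-rank p-value. The stack beats the consensus, which beats the best
single predictor — the ordering the stacking approach is designed to produce.
`dR` is the difference of mean correlations between the two methods of a row.

The same analyses are available as library functions:

```python
from ddgstack import (CVScheme, cv_evaluate_gpr, generate_feature_table,
                      sipmab_like_config)

table = generate_feature_table(sipmab_like_config(seed=7))
result = cv_evaluate_gpr(table, scheme=CVScheme(n_repeats=20, master_seed=0))
print(result.mean_r, result.sem_r)   # 0.669 0.003
```

Other subcommands: `ddgstack consensus` (append the consensus Z-score column
for a predictor subset), `ddgstack importance` (averaged Gini importance and
threshold/top-k predictor reduction), `ddgstack correlate` (inter-predictor
Pearson matrix), `ddgstack predict` (train on one table, predict an
independent one).

## Using your own feature table

Input is a CSV/TSV with one row per mutant: identity columns (`record_id`,
`complex_id`, `chain`, `position`, `wt_residue`, `mut_residue`), the
experimental target (`ddg_exp`, kcal/mol) and one numeric column per
predictor. Column names are remappable via a YAML/JSON config
(`column_map:`), so tables with different layouts need no editing. All
predictor scores are assumed positively oriented with ΔΔG (higher = more
destabilizing); `validate_table` warns about suspicious orientations but
never flips signs.

See `docs/methods.md` for the model details, generator calibration, numerical
conventions and known limitations.
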