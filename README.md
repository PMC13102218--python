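# grmsim

Monte Carlo parameter-recovery studies for the unidimensional **graded
response model** (GRM), aimed at psychometricians and applied researchers
planning sample sizes for ordinal rating scales: how do sample size *n*,
item count *J* and response-category count *K* jointly determine how well
the model's discriminations and latent traits are recovered?

## The model and the study design

Respondents carry a latent trait θ ~ N(0, 1). Item *j* has discrimination
a_j ~ U(0.5, 2.5) and K−1 ascending category locations b_jk ~ U(−2, 2)
(sorted), combined into intercepts

    d_jk = −D · a_j · b_jk,   D = 1.701.

The probability of answering in category k or above is logistic in θ
(Samejima's boundary curves); category probabilities are adjacent
differences. For each design cell (n, J, K) a finite population of
N_pop = ⌈n / 0.001⌉ traits plus one item bank is fixed; each of R
replications draws n respondents without replacement, generates responses,
fits the GRM by **marginal-maximum-likelihood EM** (fixed N(0,1) prior,
61-node quadrature), scores respondents by **EAP**, and records

* RMSE_a = √(Σ_j (â_j − a_j)² / J), optionally multiplied by the
  finite-population correction √(J/(J−1)) and/or standardized by the range
  of â;
* RMSE_θ = √(Σ_i (θ̂_i − θ_i)² / n), with FPC √(1 − n/N_pop);
* the Pearson correlation r(θ, θ̂), averaged across replications on the
  Fisher-z scale: r̄ = tanh(mean artanh r).

See `docs/methods.md` for estimation details, conventions and limitations.

## Worked example

```python
from grmsim import Condition, run_condition

cond = Condition(n=500, J=10, K=5, R=5, base_seed=123)
agg, rep = run_condition(cond)
print(rep[["rep", "rmse_a", "rmse_theta", "r"]].round(4).to_string(index=False))
print(f"mean rmse_a={agg['rmse_a']:.4f}  r_fisher={agg['r_fisher']:.4f}")
```

prints

```
 rep  rmse_a  rmse_theta      r
   0  0.1580      0.3725 0.9265
   1  0.1798      0.4101 0.9115
   2  0.1620      0.4023 0.9221
   3  0.1787      0.4065 0.9067
   4  0.2461      0.4219 0.9009
mean rmse_a=0.1849  r_fisher=0.9141
```

Each row is one replication of the (n=500, J=10, K=5) cell: the RMSE of
the ten estimated discriminations against the generating values, the RMSE
of the 500 EAP trait estimates against the true traits, and their Pearson
correlation. The aggregate row averages the RMSEs arithmetically and the
correlations on the Fisher-z scale — here a mean slope error of about 0.18
and ordinal agreement of about 0.91 ("high" on the Cohen bands used in the
reports).

A full grid run, from the shell:

```bash
grmsim run-study --preset desk --out-dir results/desk      # corner grid, R=20
grmsim run-study --subset n=500,1500 --subset J=10 --subset K=5 \
       --reps 20 --out-dir results/slice
grmsim summarize --results results/slice
```

`run-study` writes `per_replication.csv`, `per_condition.csv` and a
`manifest.json`, checkpointing each condition so interrupted runs resume.
`generate`, `fit` and `score` expose the individual pipeline stages for
externally supplied response matrices (respondent × item integer CSV).

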