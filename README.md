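# aretree

Data-adaptive discovery of **threshold regions** in multivariate exposure
data, with valid inference on the effect of restricting a population to
the discovered region.

## The problem

Environmental-health studies routinely measure several correlated
exposures (chemical mixtures, metals, pollutants) together with
covariates and an outcome. Policy questions are rarely about one
chemical at a time: they ask for joint *cut points* — "what would happen
to the population mean outcome if everyone's exposures were kept inside
`A1 ≤ τ1 and A2 > τ2`?" Answering this requires (i) finding a good
region in exposure space and (ii) estimating its effect without the
overfitting bias that comes from using the same data for both.

`aretree` addresses both with a combination of:

- a **significance- and positivity-filtered decision tree** that
  searches axis-aligned regions `𝒜 = {A_j ≤ τ_j} ∩ {A_k > τ_k} ∩ …`,
  splitting only where the targeted child mean differs from the parent
  mean (Wald p < α) and the estimated split propensity
  `π̂(w) = P(A_j ≤ s | W = w)` stays inside `[ε, 1−ε]`;
- **targeted maximum likelihood estimation (TMLE)** of the
  *attributable regional effect* `ψ_𝒜 = E[Q(1, W)] − E[Y]`, where
  `Q(1, w) = E[Y | A ∈ 𝒜, W = w]` — the change in mean outcome if the
  population were restricted to 𝒜 while preserving relative
  self-selection within it;
- **K-fold cross-estimation (CV-TMLE)**: regions and nuisance fits come
  from each fold's training sample and are evaluated on the held-out
  sample, so the data-adaptively chosen parameter still gets valid
  efficient-influence-function inference. Out-of-fold predictions are
  stacked and one pooled fluctuation yields

  `Ψ̂_CV = (1/K) Σ_k (1/n_k) Σ_{i∈fold k} [Q*_{−k}(1, W_i) − Y_i]`.

A region is only declared when **every** fold discovers one; otherwise
the result is "no consistent region found", which keeps the spurious
discovery rate near `α^K` under a null.

## Worked example

```python
import numpy as np
from aretree import CVRegionTMLE, ContinuousDGPSpec, generate

data = generate(ContinuousDGPSpec(), n=5000, seed=7)   # W1..W3, A1, A2, Y
est = CVRegionTMLE(exposures=["A1", "A2"], n_folds=2,
                   objective="max", random_state=11)
est.fit_dataset(data)            # or est.fit(X_dataframe, y)
print(est.pooled_table().to_string(index=False))
```

Output:

```
 Solution      ARE       SE  Lower CI  Upper CI  p-value                                       Region  Prop. folds
(1) A1-A2 3.316553 0.021656  3.274107  3.358998      0.0 A1 > 0.5 (0.5, 0.5) & A2 ≤ -0.3 (-0.3, -0.3)          1.0
```

Both folds discovered the region `A1 > 0.5 & A2 ≤ -0.3` (the cutpoint
mean and fold range are shown in parentheses). The pooled ARE of 3.32
(SE 0.022) says: restricting everyone to that region would raise the
mean outcome by about 3.3 units. The generating process used here gives
the region a true effect of 3.32, so the estimate and its 95% interval
are on target. `est.fold_table()` lists the per-fold regions and
estimates behind the pooled row.

The same workflow runs from the shell:

```bash
aretree simulate continuous --n 5000 --seed 7 --out mix.csv
aretree discover mix.csv --outcome Y --exposures A1,A2 \
        --covariates W1,W2,W3 --folds 2 --objective max --seed 11 --out run/
```

`discover` writes the fold table, the pooled table, the echoed config
and a per-split trace log; its exit status distinguishes a found region
from "no consistent region found".

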