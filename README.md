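# ingarch-dpd

Robust estimation and change-point testing for integer-valued time series
(INGARCH-type count models) via **minimum density power divergence**.

## The problem

Count series — disease case counts, numbers of transactions, return times of
extreme events — are commonly modelled with INGARCH feedback recursions: the
conditional distribution of `Y_t` given the past is a one-parameter
exponential family (Poisson, negative binomial with known size `r`, or a
trials-counting geometric) with conditional mean

```
X_t = d + a·X_{t-1} + b·Y_{t-1}            (linear INGARCH(1,1))
X_t = d + a·X_{t-1} + b1·max(Y_{t-1}-l,0) + b2·min(Y_{t-1},l)   (threshold)
```

A central practical question is whether the parameter
`θ = (d, a, b)` stayed constant over the sample. The classical score-based
CUSUM test answers this, but both the conditional MLE and the test built on
it are badly distorted by additive outliers: isolated large counts masquerade
as parameter changes and the test's false-alarm rate can explode several-fold.

## The method

For tuning constant `α ≥ 0` the per-observation density-power-divergence loss
is

```
l_t(θ) = Σ_y p^{1+α}(y|η̃_t(θ)) − (1 + 1/α)·p^α(Y_t|η̃_t(θ)),   α > 0
l_t(θ) = −log p(Y_t|η̃_t(θ)),                                    α = 0
```

where `η̃_t = B⁻¹(X̃_t(θ))` is the natural parameter of the filtered
intensity. Minimising the average loss gives the MDPDE `θ̂_α`; `α = 0` is the
CMLE, larger `α` down-weights observations that are improbable under the
model, buying robustness at a small efficiency cost. The change-point
statistic is the CUSUM of per-observation loss gradients
`g_t = ∂l_t(θ̂_α)/∂θ`,

```
T̂ = max_k (1/n) · S_k' K̂_α⁻¹ S_k,      S_k = Σ_{t≤k} g_t,
```

with `K̂_α` the average score outer product. Under a constant parameter `T̂`
converges to `sup_s ‖B°_d(s)‖²` for a d-dimensional Brownian bridge, whose
level-0.05 critical value for three parameters is 3.004. The location of a
detected change is estimated by the maximising `k`. Standard errors come from
the sandwich `(ΣH_t)⁻¹(Σg_t g_t')(ΣH_t)⁻¹`, and `α` can be chosen by
minimising an estimated asymptotic MSE against the `α = 1` pilot fit.

## Worked example

```python
import numpy as np
from ingarch_dpd import (ModelSpec, POISSON, ContaminationSpec,
                         simulate_ingarch, contaminate, fit_mdpde,
                         dpd_test, score_cusum_test)

model = ModelSpec(POISSON)
y, _ = simulate_ingarch(model, (1.0, 0.2, 0.2), 1000, seed=42)   # no change
yc = contaminate(y, ContaminationSpec(p=0.03, gamma=10.0), seed=1)

fit = fit_mdpde(yc, alpha=0.25, model=model)
print(np.round(fit.theta_hat, 3), np.round(fit.se, 3))
# [1.095 0.166 0.144] [0.206 0.133 0.034]

print(score_cusum_test(yc, model).statistic, score_cusum_test(yc, model).reject)
# 3.8227... True   <- outliers fool the classical test (no change exists)
print(dpd_test(yc, 0.25, model).statistic, dpd_test(yc, 0.25, model).reject)
# 0.6805... False  <- the robust test is not fooled (critical value 3.004)
```

The series has *no* parameter change, only 3% additive outliers — the score
CUSUM statistic (3.82) exceeds 3.004 and falsely signals a change, while the
DPD test statistic (0.68) correctly does not.

The same workflow is available from the shell:

```
ingarch-dpd simulate --theta 1,0.2,0.2 --n 1000 --contaminate-p 0.03 --out y
ingarch-dpd fit y.csv --alpha 0.25
ingarch-dpd test y.csv --alpha 0.25        # DPD + score comparator
ingarch-dpd experiment --theta 1,0.2,0.2 --n 500 --reps 200  # size study
```

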