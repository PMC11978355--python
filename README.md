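# locpois

Local linear multi-predictor **Poisson regression** by locally kernel-weighted
maximum likelihood, with Newton–Raphson fitting, leave-one-out **MLCV**
bandwidth selection, and a global Poisson-GLM baseline.

## The problem

Small-area count data — disease cases per district, stunting counts per
health-office catchment — are classically modelled with a Poisson GLM,
`E[Y | x] = exp(β₀ + Σⱼ βⱼ xⱼ)`. When the true log-mean surface `m(x)` is not
log-linear, that global fit smooths away exactly the local structure an
analyst cares about. `locpois` instead estimates `m(x)` nonparametrically:
at every evaluation point `x₀` it fits a first-order expansion

```
m(xᵢ) ≈ β₀(x₀) + Σⱼ β₁ⱼ(x₀) (xᵢⱼ − x₀ⱼ)
```

by maximizing the kernel-weighted Poisson log-likelihood

```
ℓ(β; x₀) = Σᵢ wᵢ [ yᵢ ηᵢ − exp(ηᵢ) − ln(yᵢ!) ],   wᵢ = Πⱼ K_hⱼ(xᵢⱼ − x₀ⱼ)
```

with a product kernel (one bandwidth `hⱼ` per predictor) and Newton–Raphson
on the analytic score `g = Xcᵀ W (y − μ)` and Hessian `H = −Xcᵀ diag(w μ) Xc`.
`exp(β₀(x₀))` is the fitted mean at `x₀`; `β₁ⱼ(x₀)` estimates `∂m/∂xⱼ` there.
Bandwidths are chosen by maximizing the leave-one-out likelihood criterion

```
MLCV(h) = Σᵢ [ m̂₋ᵢ(xᵢ) yᵢ − exp(m̂₋ᵢ(xᵢ)) − ln(yᵢ!) ]
```

over a grid. The intended users are biostatisticians and epidemiologists
modelling counts over a small number of areal units with a few continuous
covariates.

## Worked example

The package ships a synthetic 39-district dataset (`stunting_fixture()`)
emulating a stunting-count study: counts with mean ≈ 115 and large spread,
two right-skewed percentage predictors.

```python
import locpois as lp

data = lp.stunting_fixture()
print(lp.describe(data).round(2))
#             mean   min     max      sd
# y         115.23  14.0  829.00  157.19
# x1          4.03   0.0   11.66    3.51
# x2          7.69   0.8   21.42    5.62

res = lp.select_bandwidth(data, [[2.0, 3.0, 4.0], [2.0, 3.0, 4.0]],
                          lp.FitOptions(), mode="per_predictor")
print(res.best, round(res.best_mlcv, 3))        # [3. 4.] -141.066

reg = lp.LocalLinearPoissonRegressor(bandwidths=res.best).fit(data.X, data.y)
print(reg.fits_[0].beta.beta.round(4))          # [3.3931 0.1135 0.1631]
print(reg.comparison_loglik())
# {'local': -129.93..., 'global': -133.26...}
print(reg.predict(data.X[:1]).round(2))         # [29.76]  (observed count: 24)
```

The per-predictor MLCV scan picks `h = (3, 4)`; each of the 39 local fits
returns `(β₀, β₁, β₂)` at its own anchor — the first district's local
intercept 3.3931 means a fitted mean of `exp(3.3931) ≈ 29.8` cases there,
and the local slopes are the log-mean gradients at that district. The local
model's in-sample Poisson log-likelihood (−129.9) exceeds the global GLM's
(−133.3), the expected gain when the surface is not exactly log-linear.

The same pipeline is available from the shell:

```sh
locpois simulate --scenario stunting_like --n 39 --seed 3 -o d.csv
locpois select-bandwidth -i d.csv --response y --predictors x1,x2 \
        --grid "2,3,4;2,3,4" --mode per_predictor
locpois fit -i d.csv --response y --predictors x1,x2 \
        --bandwidths 3,4 -o coefs.csv --model-json model.json
locpois predict --model-json model.json -i query.csv --strategy refit
```

Estimators follow the scikit-learn contract (`get_params`, `clone`,
`GridSearchCV` over `bandwidths` all work); `score` returns D², the fraction
of Poisson deviance explained.

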