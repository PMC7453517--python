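# cidecomp

Decomposition of wealth-related inequality in binary health outcomes from
household-survey microdata: asset-based wealth ranking, weighted
concentration indices with the Erreygers normalization, regression-based
(Wagstaff-style) decomposition of the concentration index into determinant
contributions, and Blinder–Oaxaca decomposition of the change in that
inequality between two survey waves.

It is written for health-equity analysts working with DHS-style data — one
row per recent birth, a binary service-use outcome (the motivating case is
regular antenatal care, four or more visits), determinant covariates,
household asset indicators and sampling weights.

## The method

Economic status is the first principal component of the standardized asset
indicators; its **weighted fractional rank** $r_i$ (midpoint convention,
weighted mean exactly 0.5) is the equity stratifier. Inequality in a
variable $x$ is the **concentration index**

$$\mathrm{CI} = \frac{2}{\mu}\,\mathrm{cov}_w(x, r),$$

negative when $x$ is concentrated among the poor. Because a binary
outcome's CI is bounded by $1-\mu$, the **Erreygers normalization**
$E = 4\mu\,\mathrm{CI}$ is reported alongside.

Given a linear-additive outcome model $h = \alpha + \sum_k \beta_k x_k + \varepsilon$,

$$\mathrm{CI} = \sum_k \eta_k C_k + \frac{GC_\varepsilon}{\mu},
\qquad \eta_k = \frac{\beta_k \bar{x}_k}{\mu},$$

so each determinant contributes its elasticity $\eta_k$ times its own
concentration index $C_k$; percent contributions are shares of the
explained part $\widehat{\mathrm{CI}}=\sum_k \eta_k C_k$. For a binary
outcome the logit is linearized through average marginal effects
(discrete-change form for dummy regressors); the linear probability model
is available when exact additivity is wanted.

Between an early wave $A$ and a late wave $B$, each determinant's change in
contribution splits as

$$\Delta(\eta_k C_k) = C_k^{(\cdot)}\,\Delta\eta_k + \eta_k^{(\cdot)}\,\Delta C_k$$

under either of two reference weightings (`table4`, the default, uses
$C_{k,B}\,\Delta\eta_k + \eta_{k,A}\,\Delta C_k$; `paper` uses
$C_{k,A}\,\Delta\eta_k + \eta_{k,B}\,\Delta C_k$); both satisfy the exact
row identity.

A synthetic two-wave generator ties every covariate and asset to a latent
wealth factor through a Gaussian copula, with defaults calibrated to the
benchmark setting (early-wave prevalence ≈ 0.30 with strong pro-rich
inequality, late wave ≈ 0.83 with weak inequality), so the whole pipeline
is testable with known ground truth and no restricted microdata.

## Worked example

```python
from cidecomp import (SyntheticConfig, generate_wave, recode_determinants,
                      rank_households, CIDecomposition, decompose_change)

cfg = SyntheticConfig(seed=1)          # two waves at the study sample sizes
tables = {}
for wave in ("1995", "2014"):
    ds = generate_wave(cfg, wave)
    rm = recode_determinants(ds)
    ranking = rank_households(ds.assets, rm.weights)
    dec = CIDecomposition(model="logit").fit(rm.X, rm.y, rank=ranking.rank,
                                             sample_weight=rm.weights)
    tables[wave] = dec.table_
    print(f"{wave}: prevalence={dec.mu_:.3f}  CI={dec.ci_:.3f} "
          f"Erreygers={dec.erreygers_:.3f}  explained={dec.explained_ci_:.3f}")

print(tables["1995"]["pct_share"].sort_values(ascending=False).head(3).round(1))
change = decompose_change(tables["1995"], tables["2014"], scheme="table4")
print(f"explained change = {change.attrs['delta_ci_explained']:.3f}")
```

prints

```
1995: prevalence=0.303  CI=0.268 Erreygers=0.324  explained=0.254
2014: prevalence=0.829  CI=0.043 Erreygers=0.143  explained=0.042
region_rural_upper    24.1
toilet_modern         21.0
edu_secondary         14.1
explained change = -0.211
```

Reading: in the early wave three in ten births get regular care and use is
strongly concentrated among the rich (CI 0.268); residence in rural Upper
Egypt, lacking a modern toilet (the living-standard proxy) and secondary
education carry the largest shares of that inequality. By the late wave
coverage is 83% and the concentration index has collapsed to 0.043; the
explained inequality fell by 0.211.

The same analysis runs from the shell:

```sh
cidecomp simulate --seed 1 --out data/
cidecomp decompose --data data/wave_1995.csv --label 1995 --out out95/
cidecomp change --a out95/decomposition_1995.json --b out14/decomposition_2014.json
```

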