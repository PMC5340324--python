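# epiwalsh

High-order epistasis in combinatorially complete genotype-phenotype maps:
Walsh-Hadamard decomposition into interaction coefficients of every order,
estimation and removal of a monotone nonlinear phenotypic scale by a power
transform, and bootstrap propagation of measurement uncertainty into
coefficient significance. Includes a simulator of nonlinear epistatic maps
for validation.

**Who it is for.** Anyone analyzing a complete set of combinatorial
mutants — 2^L genotypes over L binary sites (or mixed two-/four-state
sites) with replicate phenotype measurements — who wants to know which
mutations interact, at what order, and with what confidence, without
mistaking a curved measurement scale for genuine epistasis.

## The model

Genotypes are coded ±1 per site (wild type −1, mutant +1). With X the
2^L × 2^L design whose columns are all products of site codes, a phenotype
vector decomposes exactly as

    P = X β,    β = Xᵀ P / 2^L        (X is Hadamard: XᵀX = 2^L·I)

where β₀ is the map's center, first-order β_j are average mutational
effects, and higher orders are interactions measured from the map's
geometric center. Four-state sites use the WYK tetrahedral code (wild type
(1,1,1); other states at tetrahedron corners), which keeps the design
orthogonal.

Before decomposing, the pipeline removes the map's *scale*: it estimates
additive phenotypes P̂_add (average effect of each mutation summed per
genotype), fits the power transform

    P_obs ≈ τ(P̂_add; λ, A, B) = ((P̂_add + A)^λ − 1) / (λ·GM^(λ−1)) + B

by nonlinear least squares (GM is the geometric mean of P̂_add + A), and
back-transforms the observations onto the linear scale with the exact
inverse of τ. The fit is iterated to self-consistency — P̂_add is
re-estimated on the linearized scale — so that curvature is fully absorbed
by τ rather than leaking into interaction coefficients. Measurement
uncertainty is propagated by parametric bootstrap: pseudoreplicate
phenotype vectors drawn per genotype from Normal(mean, sd), rescaled,
decomposed; each coefficient gets a z-score and a Bonferroni-corrected
two-sided P-value.

See `docs/methods.md` for assumptions, numerical choices and limitations.

## Worked example

Simulate a 5-site map with known coefficients through a saturating scale
((1+K)p/(1+Kp), K=2), then analyze it with and without scale removal:

```python
import numpy as np
from scipy.stats import pearsonr
import epiwalsh as ew

coefs = ew.random_coefficients(L=5, order=5, seed=0)      # ground truth
sim = ew.build_map(coefs, scale_spec=("saturating", 2.0)) # observable map

res = ew.run_pipeline(sim.map, scale="power", bootstrap="off")
raw = ew.run_pipeline(sim.map, scale="none", bootstrap="off")

truth = sim.true_coefs.values[sim.true_coefs.orders > 0]
for name, r in [("with linearization", res), ("without", raw)]:
    out = r.coefficients.values[r.coefficients.orders > 0]
    print(name, round(pearsonr(truth, out)[0] ** 2, 3))
print(res.partition.to_frame().round(3))
```

prints

```
with linearization 0.981
without 0.448
   order  contribution  cumulative_fit
0      1         0.186           0.186
1      2         0.494           0.681
2      3         0.214           0.894
3      4         0.068           0.962
4      5         0.038           1.000
```

The generating coefficients are recovered almost perfectly after the
fitted scale is removed (R² = 0.981) but are badly scrambled if the
saturating map is analyzed as if linear (R² = 0.448); the partition table
shows how much phenotypic variation each interaction order explains on the
linearized scale (this seed happens to draw small first-order effects, so
pairwise terms dominate).

The same analyses are available from the shell:

```bash
epiwalsh simulate --sites 5 --scale-k 2 --seed 1 --out sim/
epiwalsh fit --input sim/map.json --scale power --bootstrap auto --seed 1 --out fit/
epiwalsh partition --input sim/map.json --scale power --out part/
```

`fit` writes `coefficients.csv` (beta, bootstrap sd, z, raw and
Bonferroni-corrected P-values, significance stars), `scale.json` (fitted
λ, A, B, GM and fit quality), `partition.csv`, and `metadata.json`
(input hash, configuration, seed) sufficient to reproduce the run.

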