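# driftfa

Factor analysis of serially sampled genotypes with correction for
allele-frequency drift.

## The problem

Ancient-DNA studies routinely ordinate genotype matrices that mix
individuals sampled thousands of years apart.  Standard PCA ignores the
sample dates, and genetic drift along the time axis produces two
well-known artifacts:

* **horseshoes / arches** — serial samples trace sinusoidal arcs in PC
  space even when there is no population structure at all, because the
  eigenfunctions of a Brownian (drift) covariance are sines;
* **projection shrinkage** — projecting ancient samples onto axes built
  from present-day samples pulls them toward the origin, biasing any
  ancestry proportion read off the plot.

`driftfa` implements a latent factor model whose scores are corrected for
temporal drift, together with ancestry-coefficient estimation from factor
geometry, a coverage-adjustment step, simulators for serial-sampling
scenarios, and the metrics used to compare methods.  It is aimed at
population geneticists doing descriptive analyses of temporal samples
(ancient DNA, experimental evolution, museum series).

## The model

Let **Y** be the row-centered *n* × *p* genotype matrix and *t*ᵢ ∈ [min v,
max v] the sample ages mapped forward onto the scale of the per-sample
variances.  Drift is modeled by the Brownian covariance *C* with entries
*c*ᵢⱼ = min(*t*ᵢ, *t*ⱼ), whose spectral decomposition *C* = *P*Λ*P*ᵀ
yields correction factors **Z** = *P*√Λ.  The data decompose as

    Y = W + Z Bᵀ + ε,      B ~ N(0, α),  ε ~ N(0, σ²),

with **W** the rank-*K* latent matrix carrying population structure.
Maximum-a-posteriori estimation minimizes the ridge-penalized loss

    L(W, B) = ½ ‖Y − W − Z Bᵀ‖²_F + ½ λ ‖B‖²,    λ = σ²/α,

which has the exact solution
**W** = *P* D_λ^(−1/2) svd_K(√D_λ *P*ᵀ **Y**) with D_λ(i,i) = λ/(λ+λᵢ);
factors **U** and loadings **V** come from the SVD of **W**.  Large λ
recovers ordinary PCA; small λ enforces strong drift correction.  The
cost is two SVDs, O(*npK*) for *p* ≫ *n*.  The drift parameter is chosen
as the largest value on a descending grid at which no factor shows a
significant linear effect of time (F-test).

Two-way ancestry coefficients are read from factor-1 positions relative
to the source cluster centers, *q* = (c_b − u)/(c_b − c_a), truncated to
[0, 1]; with three or more sources the coefficients are barycentric
coordinates in the frame of the source centers.

## Worked example

Serial samples from a single panmictic population (41 individuals, ages
0–4000 generations, *N*ₑ = 10,000, 9,000 SNPs) carry no population
structure, yet PC1 is essentially a clock.  The corrected factors are
not:

```python
import numpy as np
import driftfa as dfa

ds = dfa.simulate_wf_serial(dfa.wf_single_population(seed=42))
g = dfa.center_rows(ds.genotypes)
ts = dfa.transform_ages(ds.ages, g)

U, s, _ = np.linalg.svd(g.values, full_matrices=False)
r2_pc1 = dfa.factor_time_association(U[:, 0] * s[0], ts.times)[0]
print(f"PC1 vs time: r^2 = {r2_pc1:.3f}")

lam, res, diag = dfa.select_lambda(g, ts, K=2)
r2 = [dfa.factor_time_association(res.U[:, k], ts.times)[0] for k in range(2)]
print(f"selected lambda = {lam:.3g}")
print(f"factor 1 vs time: r^2 = {r2[0]:.4f}")
print(f"factor 2 vs time: r^2 = {r2[1]:.4f}")
print(f"variance explained by drift term: {res.varexp_drift:.1%}")
```

Output:

```
PC1 vs time: r^2 = 0.928
selected lambda = 0.1
factor 1 vs time: r^2 = 0.0017
factor 2 vs time: r^2 = 0.0000
variance explained by drift term: 49.0%
```

Uncorrected, 93% of the variance of the leading axis is explained by
sampling time — the horseshoe.  After correction at the selected drift
parameter, neither factor retains any association with time, and the
drift term accounts for about half of the total variance in this
strongly drifting scenario.

The same workflow is available from the shell:

```sh
driftfa simulate --scenario single --seed 42 --out sim
driftfa fa --geno sim.geno.tsv --meta sim.meta.tsv --k 2 --lambda auto --out fit
driftfa bench --scenario wf-admixture --replicates 20 --seed 1 --out bench.tsv
```

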