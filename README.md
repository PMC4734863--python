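# rrtdm — random-regression test-day models for dairy milk yield

Quantitative geneticists evaluating dairy cattle do not observe "lactation
yield"; they observe **test-day records** — one milk weight per cow per
monthly recording visit. The random regression test-day model (RR-TDM)
treats the whole lactation as a curve: each animal carries its own
regression coefficients on Legendre polynomials of days in milk (DIM), so
genetic and permanent-environment (co)variances become smooth functions of
the lactation stage. This package implements that analysis end to end for
the setting of a milking-frequency contrast (3× vs 4× daily milking) in
first- and second-lactation Holsteins:

* pedigree handling — numerator relationship matrix **A**, inbreeding, and
  Henderson's sparse **A⁻¹**;
* the model, for cow *p* measured in herd-test-date *i* at days in milk *t*:

  y = HTD_i + Σₙ bₙ·ageⁿ + Σₙ cₙ·tⁿ + Σₙ αₚₙ φₙ(t) + Σₙ γₚₙ φₙ(t) + e,

  with α ~ N(0, A ⊗ K_a), γ ~ N(0, I ⊗ K_pe), and residual variances
  heterogeneous over ten 30-day DIM classes; φₙ are orthonormal Legendre
  polynomials on DIM 5–305 mapped to [−1, 1];
* REML estimation of (K_a, K_pe, σ²ₑ₁…σ²ₑ₁₀) by average-information
  updates with guaranteed-monotone EM fallback, all through a sparse
  mixed-model-equation factorization;
* model-order choice by Schwarz's criterion, BIC = −2l + K·log n, over the
  (ka, kpe) grid of polynomial orders;
* derived quantities: variance trajectories, heritability
  h²(t) = σ²ₐ(t)/(σ²ₐ(t)+σ²ₚₑ(t)+σ²ₑ(t)), repeatability, and genetic /
  phenotypic correlation surfaces between any two test days;
* a synthetic herd-book generator, because the motivating study's Iranian
  Holstein records were never deposited — every stage of the pipeline is
  exercised on simulated data with the published structure, and the
  published tables themselves are reproduced at the arithmetic level.

## Worked example

```python
import numpy as np
from rrtdm import (SimConfig, simulate_tddata, apply_edits, build_design,
                   ModelSpec, fit_reml, trajectory_table, BasisSpec)

sim = simulate_tddata(SimConfig(n_herds=5, cows_per_herd=100, n_sires=25,
                                parities=(1,), freq_split=0.0, seed=12345))
records, report = apply_edits(sim.records)
design = build_design(records, ModelSpec(ka=2, kpe=2), sim.pedigree)
fit = fit_reml(design)
print(fit.converged, fit.n_iter)
tab = trajectory_table(fit.vc, BasisSpec(2))
print(tab[["dim", "sigma2_a", "sigma2_pe", "sigma2_e", "h2"]].round(2).head(3))
```

prints (seed 12345):

```
True 11
   dim  sigma2_a  sigma2_pe  sigma2_e    h2
0   20     10.66      15.61     13.81  0.27
1   50      9.94      12.57     11.54  0.29
2   80      9.55       9.94     11.62  0.31
```

— at DIM 20 the additive variance 10.66 kg² is the quadratic form
φ(20)'K̂ₐφ(20), the residual 13.81 kg² is the first 30-day class estimate,
and h² = 10.66/(10.66+15.61+13.81) ≈ 0.27: early-lactation daily milk
yield is ~27 % heritable in this simulated herd-book (truth ≈ 0.2–0.3).

The same pipeline is available from the shell (`rrtdm simulate / edit /
select / fit / trajectories / report`), and the numbered drivers under
`analysis/` run it as a narrative: simulate the herd-book, edit and
describe it, select (ka, kpe) by BIC per parity × frequency group, derive
the trajectory tables, check the published-table arithmetic, and run the
replicated recovery study.

## Layout

```
src/rrtdm/        pedigree, basis, tdm_data, mme, reml, model_selection,
                  trajectories, synthetic_data, study, reference, cli
analysis/         numbered narrative drivers writing results/
scripts/          acceptance.py
tests/            pytest suite (unit, property and end-to-end checks)
docs/methods.md   model, algorithms, defaults and limitations
```
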