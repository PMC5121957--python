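# dosegam

Penalized-spline Poisson dose–response modelling for grouped person-years
cohort data, built for low-dose radiation epidemiology: cancer incidence in
the A-bomb survivor cohort and cohorts with the same tabulated structure.

The package is for biostatisticians and radiation epidemiologists who want
to move beyond the linear excess-relative-risk model `ERR = β·D` when the
exposure distribution is heavily skewed: it fits generalized additive
Poisson/quasipoisson models to grouped cells, transforms dose through its
empirical cumulative distribution, quantifies risk at low doses with
counterfactual relative-risk inference, and validates its confidence
intervals by simulation.

## The model

Each cell *j* of a grouped cohort table carries person-years `py_j`, a case
count `obs_j`, and py-weighted mean covariates (organ dose in mGy, attained
age, age at exposure, calendar year). Cells are modelled as independent
Poisson counts with a log link and offset:

    obs_j ~ Pois(mu_j),      log mu_j = log py_j + Σ_i β_i f_i(x_j)

where the `f_i` are factors (city, urban/rural/NIC residence and their
interaction), cubic regression splines with basis dimension 10, and
interaction-only tensor-product smooths. Coefficients minimize the
penalized deviance `Dev + βᵀS(λ)β`, with one curvature penalty (and
smoothing parameter λ_b) per spline block and per tensor margin; λ is
chosen by Laplace-approximate marginal likelihood (ML; REML and GCV are
also available). As λ→∞ a smooth degenerates to its linear null space.
Inference uses the Bayesian posterior covariance `V_β = (XᵀWX + S)⁻¹φ`;
the quasipoisson scale φ is the fixed point of Pearson χ²/dfres.

Because the dose distribution is skewed and multimodal (most person-years
sit below 20 mGy), dose can be replaced by **ecdos**, its within-subcohort
empirical CDF — a monotone transform with a near-uniform distribution that
gives the spline resolution where the data are. A model catalogue
(P0…P5 / Q0…Q5, with `e`/`d` dose-covariate and `a`/`s` timescale variants)
augments the baseline

    P0: offset(log py) + (city+distcat)^2 + ti(logage) + ti(birth) + ti(logage,birth)

with dose terms and interactions, fitted as nested chains and compared by
ML score, AIC-type score, or deviance tests.

Relative risk is counterfactual: `RR_j = mu_j / mu_{j,0}` with the dose
covariate reset to its zero-dose value and everything else held fixed;
`ERR = RR − 1`. The package also computes attributable fractions, internal
standardized incidence ratios, cellwise significance-region summaries, and
a simulation framework (known true ERR curves embedded in synthetic
cohorts; CI coverage; bootstrap-t and coverage-calibrated "stretched"
intervals; lognormal dosimetry-error perturbation; cross-validation).

A seeded synthetic-cohort generator reproduces the structural hallmarks of
the public grouped data — stratified cells, dose-category cutpoints with
clumped within-category doses, a zero-dose Not-In-City stratum, >70% of
person-years below 20 mGy — so the entire pipeline runs and is tested
without any restricted-access download.

## Worked example

```python
import numpy as np
from dosegam import (SyntheticCohortConfig, SubcohortSpec, generate,
                     subcohort, ecdos_transform, build_spec, fit_model,
                     rr_curve)

cohort = generate(SyntheticCohortConfig(seed=0))          # ~2000 cells
bminus = ecdos_transform(subcohort(cohort, SubcohortSpec.from_name("B-")))
fit = fit_model(bminus, build_spec("P2e"))                # ecdf-dose smooth
for e in rr_curve(fit, [2.5, 10, 40], {"age": 70, "since": 35}):
    print(f"RR|{e.dose:g} mGy = {e.rr:.3f} ({e.lcl:.3f}, {e.ucl:.3f})")
```

On the default synthetic cohort (whose embedded true excess risk is null)
this prints, to three decimals:

```
RR|2.5 mGy = 1.005 (0.989, 1.021)
RR|10 mGy = 1.011 (0.976, 1.047)
RR|40 mGy = 1.020 (0.964, 1.080)
```

i.e. a relative risk indistinguishable from 1 at every dose, with 90%
intervals (the bounds are the lower/upper 95% confidence limits), exactly
as it should be for a null cohort. Fitting the same model to a cohort
generated with an embedded two-phase curve recovers the rise (see
`tests/test_acceptance.py`).

The same workflow is scriptable from the shell:

```sh
dosegam synth --seed 0 --out out/synth
dosegam ladder --input out/synth/cohort.csv --subcohort B- \
        --models P0,P2e,P2d --method 1 --out out/ladder
dosegam risk --input out/synth/cohort.csv --subcohort B- --model P2e \
        --doses 2.5,10,40 --out out/risk
dosegam simulate --input out/synth/cohort.csv --subcohort B- \
        --curve C2 --reps 200 --out out/sim
```

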