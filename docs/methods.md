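# Methods

This note documents the statistical model, the numerical choices, and the
design decisions behind `dosegam`, in the spirit of a model-documentation
page: what is computed, under what assumptions, and what the tests do and
do not establish.

## Grouped-cell Poisson model

The unit of analysis is a *cell* of a grouped cohort table: a stratum with
person-years `py`, an incident case count `obs`, py-weighted mean
covariates (organ dose in mGy; attained age; age at exposure `agex`;
calendar year, giving time since exposure `since = year − 1945.6` and birth
cohort `birth = year − age`), and factors for city, residence
(urban/rural/NIC) and sex. Cells are treated as independent Poisson
observations with a log link and `log py` offset (coefficient fixed at 1),
so the modelled quantity is the incidence rate. The Poisson deviance is
evaluated exactly as

    Dev = −2 Σ_j [ obs_j log μ_j − μ_j − I(obs_j>0)(obs_j log obs_j − obs_j) ].

Assumptions worth stating: cells are conditionally independent given
covariates (no shared frailty), py-weighted mean covariates stand in for
the within-cell covariate distribution, and the NIC stratum is a zero-dose
comparison group distinguished only through the residence factor.

## Spline machinery

Smooths are *cardinal* natural cubic regression splines: `k` knots at
equally spaced quantiles of the unique covariate values (explicit knots may
be supplied), basis function *i* interpolating the indicator of knot *i*.
Coefficients are then function values at the knots, and `∫f″²` has the
exact band-matrix form `DᵀB⁻¹D` of the natural-spline construction, whose
null space is the constant-plus-linear span. Evaluation outside the knot
range extrapolates linearly, as a natural spline does.

Each main-effect smooth carries a sum-to-zero constraint over the
construction data, absorbed through a Householder null-space basis
(`k−1` columns; the constant lives in the model intercept). Tensor-product
interaction blocks are row-wise products of two constrained margins —
`(k_a−1)(k_b−1)` columns — with two penalties, `S_a⊗I` and `I⊗S_b`, each
taking its own smoothing parameter, so `ti(x) + ti(x,z)` decomposes a main
effect and an interaction. The joint tensor penalty's null space is the
single bilinear direction.

## Fitting and smoothing-parameter selection

For fixed λ the coefficients minimize `Dev + βᵀS(λ)β` by penalized IRLS
with step-halving, converged when the relative penalized-deviance change
falls below 1e−9; a short plain-Newton "polish" then drives the penalized
score equation `Xᵀ(y−μ) = Sβ` below 1e−7·Σobs in sup norm, which is what
makes the canonical-link identity `Σμ = Σobs` hold to 1e−6 relative.
Numerical guards: means clamped away from 0, a 1e−12 relative ridge on the
Cholesky factorization, λ clamped to [1e−8, 1e9] and the quasipoisson scale
to ≥1e−4.

Smoothing parameters minimize, over log λ, the negative Laplace-approximate
log marginal likelihood

    V(λ) = [Dev + βᵀSβ]/(2φ) + ½ log|XᵀWX + S| − ½ log|S|_+ + const(φ),

with a flat prior over the penalty null space (`|·|_+` is the pseudo-
determinant, accumulated per diagonal block from precomputed spectra; for a
tensor's pair of kron-structured penalties the eigenvalues of
`λ₁S_a⊗I + λ₂I⊗S_b` are the pairwise sums `λ₁α_i + λ₂β_j`, so no dense
eigendecomposition is needed). REML is the same construction and GCV
(`n·Dev/(n−edf)²`) is available; ML is the default throughout.

The outer optimization is L-BFGS-B with the *exact* gradient of V,
obtained by differentiating through the penalized score equation
(`dβ̂/dρ_j = −λ_j A⁻¹S_jβ̂`, `A = XᵀWX+S`), including the weight-dependence
of `log|A|` via the diagonal of `XA⁻¹Xᵀ`; the gradient was validated
against central differences. A generalized Fellner–Schall multiplicative
update (one inner fit per iteration) serves as a warm-up, since its fixed
point is the REML stationary point. Two degenerate situations are handled
deliberately: a flat criterion leaves λ at its bound with a warning, and
simulation loops *cold-start* the λ search per replicate — warm-starting
from another replicate's optimum can strand a smoothing parameter on the
flat λ=1e9 boundary and silently force linear fits.

Effective degrees of freedom are `edf = tr(A⁻¹XᵀWX)`; `dfres = n − edf`.
The quasipoisson scale iterates `φ ← Pearson χ²/dfres` under refitting to a
1e−3 fixed point. Wald inference uses `V_β = A⁻¹φ`; relative-risk contrasts
use the variance of the linear-predictor *difference* (covariances
included), intervals default to 90% with bounds labelled LCL95%/UCL95%, and
"borderline" means 0.98 ≤ LCL95% ≤ 1. Leverage is the diagonal of the
influence matrix (summing to edf); Cook's distance combines standardized
Pearson residuals with leverage, and a helper drops the top q% (default 5).
Nested penalized fits are compared by deviance-difference tests on
edf-difference degrees of freedom (χ² for Poisson; F at the fuller model's
Pearson scale for quasipoisson).

## The ecdf dose transform

`ecdos` is the empirical CDF of dose evaluated at each cell's dose — the
unweighted proportion of cells with dose ≤ that cell's (ties share a value,
max = 1, min > 0 when zero-dose cells exist). It is computed *within the
modelling subcohort, after all filters*, because it is a property of the
analysed table; it must be recomputed after any further filtering. The
inverse map is the empirical quantile (smallest observed dose with
ecdf ≥ q). Prediction grids in mGy are pushed through the stored
subcohort ecdf, and the zero-dose counterfactual for ecdos models resets
the covariate to ecdf(0), so RR(0) = 1 exactly. The unweighted (cell-level)
convention is deliberate; a py-weighted variant would change the transform
and is left to sensitivity analysis.

## Model catalogue and selection

`build_spec` materializes the catalogue: P0/Q0 as baseline, P1 adds the
dose covariate log-linearly, P2 adds `ti(dcov)`, P3 adds `ti(dcov,logage)`,
P4a/P4s swap in an `agex`/`since` interaction, and P5a/P5s carry both plus
the timescale main effect; `e`/`d` selects ecdos or raw dose, Q* the
quasipoisson family. Basis dimension is 10 per margin by default (a
configurable choice also for tensor margins), with optional per-term
minimum smoothing parameters. Selection method 1 is the minimum ML score
with ties broken toward fewer effective degrees of freedom — the only
method whose definition is fully pinned down; methods 2 (AIC with edf) and
3 (forward walk along nested chains by deviance tests at α = 0.05) are
clearly-labelled configurable stand-ins, as is method 4 (minimum ML at the
model's own Pearson-optimized scale) for quasipoisson fits. The
quasipoisson e/d pair rule refits each twin at the scale optimized for the
other and declares a preference only when the same member wins at both
common scales, otherwise "ambiguous".

## Risk inference

Counterfactual RR per cell divides the fitted mean by the mean with the
dose covariate reset, all coefficients and other covariates held fixed.
Dose-response curves and surfaces are evaluated on synthetic single cells
(py = 1, reference factor levels — factor choice cancels in the ratio)
at a fixed attained age plus one timescale, the others derived
consistently from the exposure date. Attributable fraction `1 − Σμ₀/Σμ`
and internal SIR `Σμ/Σμ₀` satisfy `SIR = 1/(1−AF)` identically.
Significance regions summarize the proportions of cases and person-years
with LCL95% > 1 (indicator I) or UCL95% < 1 (indicator J) over the regions
D₀ (dose>0), D₀.₅ (dose>0.5 mGy), S₀.₅ (since<35 ∧ dose>0.5),
T₀.₅ (agex>35 ∧ dose>0.5) and S∩T; no multiplicity correction is applied
to these cellwise maps (raw proportions are reported by design). The
linear-extrapolation comparison multiplies an external ERR-per-Gy slope by
the target dose in Gy and reports the model/extrapolation ratio.

## Simulation framework

True ERR curves come in three families — `f(d)=βd+σ(1−e^{−τd})`,
`g(d)=βd+σd·e^{−τd}`, `h(d)=0` below a threshold γ then
`(1/5)((d−γ)/(100−γ))³` — with a named catalogue (N1 null; L1 linear;
H1 hormesis; P1 plateau; C1, C2, R1, R2 two-phase; T1, T2 threshold).
Coverage studies fit the no-dose baseline model to the supplied cohort,
simulate `obs ~ Pois(μ₀·(1+ERR(dose)))` per replicate, refit the
no-interaction ecdos and dose models, and score containment of the true RR
by their CIs at 10…100 mGy; 95% intervals by default with a level switch
(90% is the reporting convention elsewhere — both conventions appear in
the source material, so the level is explicit). Bootstrap-t intervals use
a parametric bootstrap from the fitted model with a studentized pivot on
the link scale (≥20 resamples enforced); "stretched" intervals scale the
Wald half-width by the smallest s ≥ 1 whose simulated coverage reaches the
target within 1%, found by bisection against a calibration batch that
treats the fitted model as truth. The dosimetry-error study multiplies
doses by median-1 lognormal errors (σ_log default 0.3 — a configuration
choice, the magnitude of the true errors being unknown), recomputes the
ecdf transform, resimulates counts, refits, and reports geometric means.
Cross-validation splits cells into k folds (case-free folds merged with a
warning), scoring held-out deviance explained against the training mean
rate plus the training fit's RR at the evaluation dose.

## Synthetic cohort generator

The generator emulates the structure the analysis depends on, not the real
survivors' dosimetry. Cells are strata of city (2) × residence
(urban/rural, plus a zero-dose NIC stratum) × dose category (cutpoints
0, 5, 20, 40, 60, 80, 100, 150, 250, 500 mGy) × six age-at-exposure bands ×
eight calendar periods (1960–1995; time since exposure ≥ 12.4 years, the
cohort's minimum follow-up delay) — about 2,000 cells, sized so every
ladder fit completes in seconds. Person-years (2.5M total) are allocated so
the dose skew matches the public data's hallmarks: NIC holds 25% of py and
the in-city category shares put >70% of py below 20 mGy including NIC
(>60% excluding) and >84%/>79% below 100 mGy. Within a category, doses
*clump*: one right-skewed clump position per (city × residence × category)
stratum with tight jitter (3% of the category width), reproducing the
multimodal, stratification-clumped dose marginal of grouped public data.
Baseline incidence is log-linear in log attained age (slope 5 — incidence
roughly ∝ age⁵, a standard epidemiological magnitude) with a 1%/year birth-
cohort trend and city/residence effects including an interaction; the
intercept is calibrated so the expected case total hits a configured value
(default 5,000). A true ERR curve can be embedded multiplicatively.

What passing tests on this cohort do **not** show: fidelity to the real
spatial dose reconstruction, to the real stratum layout, or to the real
data's exact information geometry. One documented consequence: the
dramatic coverage collapse of the raw-dose model under the two-phase curve
C2 that motivates the ecdf transform on the real data does *not* reproduce
at this generator's geometry — here the ML-chosen dose spline places knots
at the dose clumps and captures the curve, so both models stay near
nominal and only the direction of the linear-curve asymmetry (ecdos
under-covers under L1 while the dose model stays nominal) is recovered.
The corresponding acceptance check is left failing rather than tuning the
generator toward the published coverage numbers.

## Problem sizes used by the test suite and acceptance script

The suite fits reduced bases (k = 3–6) on toy tables and a smaller
(~300-cell) cohort for most checks; the acceptance-grade coverage studies
run 50 replicates in the test suite and 200 in `scripts/acceptance.py`,
both over the ~1,300-cell 0–100 mGy NIC-excluded subcohort of the default
generator. Scale estimation and φ-recovery checks use 2,000 simulated
cells. All random draws flow from explicit seeds; rerunning any entry
point with the same seed reproduces its outputs bit-for-bit.

## Known limitations

* Selection methods 2–4 are stand-ins with documented, configurable
  definitions; only method 1 (minimum ML) is canonical.
* The ML criterion integrates all coefficients with a flat prior on the
  penalty null space; it is a behavioural implementation (model ranking,
  degeneracy to the linear model, edf behaviour are what the tests pin
  down), not a formula-level clone of any other package.
* Thin-plate bases, a smooth approximation to the ecdf transform, fully
  Bayesian MCMC inference, and negative-binomial families are out of
  scope; neutron RBE enters only as a pluggable constant or function.
* Cellwise significance maps are reported without multiplicity
  correction, matching the reporting convention of the field.
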