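# Methods

## Scope and model

`blipta` estimates the probability of target attainment (PTA) for β-lactam /
β-lactamase-inhibitor (BL/BLI) combinations at the site of infection. The
chain is: population-PK model → virtual population → steady-state plasma
profile → unbound site exposure → PK/PD index → attainment → PTA.

Each compound is a linear mamillary compartmental model (1–3 compartments,
central elimination) dosed by repeated constant-rate infusions. Individual
parameters are `typical × covariate multiplier × exp(η)` with η multivariate
normal on the log scale. The only simulated covariate dimension is creatinine
clearance: a typical renal clearance population (CrCL 80 mL/min) and an
augmented one (CrCL 200 mL/min); any other covariate a source model declares
is frozen at its reference value, so its multiplier is exactly 1. Covariate
relations support power, linear and proportional forms plus an optional
covariate ceiling (some source models cap the CrCL effect); all forms evaluate
to exactly 1 at the reference value by construction.

Unbound site concentration is `C_plasma,total · fu · TPR(site)` with a
constant tissue penetration ratio. This inherits the assumption that the
tissue profile mirrors the plasma profile's shape — no distributional delay or
tissue accumulation — which is why the sensitivity sweep can re-evaluate PTA
by pure rescaling of already-simulated profiles without re-drawing the
population. Residual (assay) variability is excluded: attainment is evaluated
on model-predicted individual profiles, the standard convention for PTA work.
When a BLI lacks a measured TPR, it inherits the partner BL's value (flagged
`extrapolated`); a site with no value for either compound is *unresolvable*
and its grid cells are omitted, never imputed.

## Simulation engine

Profiles are computed analytically, not by ODE integration. The amount-space
rate matrix of a mamillary model is similar to a symmetric matrix via the
diagonal transform `D = diag(1, sqrt(k21/k12), sqrt(k31/k13))`, so a batched
symmetric eigendecomposition gives real eigenvalues λ and orthonormal modes
for the whole population at once; the central amount after one dose is a sum
of `(e^{λs}−1)/λ`-type mode terms, and multi-dose profiles are exact
superpositions of time-shifted single-dose responses. An independent
numerical oracle (piecewise `solve_ivp` between infusion on/off events,
rtol 1e-11) agrees with the engine to ≤ 1e-6 relative (measured ~1e-11) on
random 1–3 compartment fixtures.

The evaluation window is the dosing interval starting at the first dose time
at or after `max(7 × terminal half-life, 48 h)`; the population engine extends
the run-in by 24 h so that the *preceding* 24 h window used for fAUC0–24 is
itself past seven half-lives. For every shipped drug (t½ ≤ ~3 h) both rules
give the same 48 h start. A required run-in beyond 30 days raises a
configuration error. The output grid is uniform at 0.05 h, augmented with the
exact dose and end-of-infusion event times and the window endpoints.

## Indices and attainment

* `%fT>MIC` and `%fT>C_T` (C_T = 1 mg/L): percent of the dosing interval with
  unbound site concentration strictly above the threshold, with crossing times
  solved exactly on the piecewise-linear grid profile. Against a brute-force
  dense-grid (1e-4 h) oracle the deviation is far below 0.1 percentage points.
* `fAUC0–24`: trapezoidal integration over the steady-state 24 h window. At
  steady state it satisfies the identity `fu · TPR · (daily dose)/CL` to
  better than 0.1%.
* Attainment is inclusive (≥), chosen because the published fAUC/MIC targets
  are printed as "≥" and extended to the time metrics for consistency. Tier
  magnitudes are strictly increasing EUCAST < Severe < Aggressive. `%fT>C_T`
  attainment is MIC-invariant by construction.
* Time metrics use the dosing interval as denominator (not a fixed 24 h), the
  convention adopted where the source is silent.

## PTA and common random numbers

PTA is the attained fraction among n virtual patients, with a Clopper–Pearson
95% CI (statsmodels `proportion_confint(method="beta")`). The default n = 5000
gives a binomial standard error ≤ 0.71 percentage points at PTA = 50%. The
random-effect stream is keyed by (seed, compound entry) only — not by renal
scenario, regimen, tier, MIC or site — so every cell of a scenario grid reuses
the same virtual patients. Consequences that then hold exactly rather than in
expectation: combination PTA ≤ min(component PTAs) (a patient must meet both
targets), PTA non-increasing across tiers and along the MIC grid, and
ARC ≤ TRC for renally cleared compounds. The BL and BLI of a combination share
covariates per patient index but draw independent random effects; their
random-effect correlation is set to zero because no joint estimate is
available for these pairs.

## Configuration layer

One YAML file per compound (model, penetration, target) and per combination
(component keys, per-indication regimens, shared MIC grid), units fixed to mg,
L, h, mg/L, mL/min. Tazobactam ships as two entries — one as dosed with
ceftolozane, one with piperacillin — because its source model, TPR values and
target tier magnitudes all depend on the partner; a loader option
(`swap_tpr_between`) exchanges the ELF/peritoneal TPRs between the two entries
for the swap sensitivity analysis. Where a published value is a range
(ceftolozane fu 0.79–0.84; ceftazidime peritoneal 0.33–0.35; piperacillin and
tazobactam prostate), the base case uses the midpoint and the sensitivity
sweep uses the bounds. Prostatitis has no approved regimen and reuses the cUTI
regimen by default (configurable per combination). The fixed indication→site
map is cIAI→peritoneal fluid, HAP/VAP→epithelial lining fluid, cUTI and
bacteraemia→unbound plasma, prostatitis→prostate.

The shipped population-PK parameter sets are provisional transcriptions from
the cited source publications (each file says so); fu/TPR, targets, MIC grids
and regimens follow the published tables and SmPCs. The synthetic library
(`data/synthetic/`) is fully self-contained — two fictitious combinations
covering all three index types, correlated IIV and a covariate cap — and is
what the test suite and the oracle/property checks run on, so the framework is
verifiable with no transcription at all.

## What the synthetic layer does and does not show

The synthetic fixtures have closed-form steady-state concentrations, AUCs and
crossing times, and a two-point clearance mixture with analytically known PTA;
passing tests demonstrate the correctness of the sampling, simulation, metric
and orchestration code, and the exactness of the structural orderings under
common random numbers. They do not validate the transcribed drug parameters,
and absolute PTA percentages for the real combinations are only as good as
that transcription (see the README note). Real-data features deliberately not
emulated: residual variability, covariate distributions (all patients share
one CrCL value per scenario), nonlinear elimination, time-varying renal
function, and tissue distribution kinetics.

## Numerical choices and degenerate inputs

* Zero IIV reproduces covariate-adjusted typical values exactly; a zero
  covariance matrix is valid (positive semi-definite is required, not
  definite; sampling uses the SVD method).
* Strict `>` in time-above-threshold means a profile exactly at the threshold
  over an interval counts as not above; threshold 0 on a positive profile
  gives 100%.
* Eigendecomposition assumes distinct eigenvalues in exact arithmetic;
  mamillary matrices with positive rates have simple real negative spectra,
  and random log-normal parameters never produce exact degeneracy.
* Problem sizes: tests run the synthetic grids at n = 400 and the
  transcribed-library cardinality check at n = 300; the analysis drivers and
  the acceptance script use the full n = 5000. These sizes were chosen so the
  binomial error is negligible relative to each check's tolerance.

## Known limitations

Sequential (rather than simultaneous) BL/BLI target logic, β-lactamase
binding kinetics and enzyme turnover, renal replacement therapy/ECMO,
physiologically based tissue models, and MIC-distribution summaries (CFR) are
out of scope. The combination rule "both targets attained by the same
patient" is a deliberate simplification of the mechanistically sequential
action of inhibitor and antibiotic.
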