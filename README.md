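# blipta — target-site PTA analysis for β-lactam / β-lactamase-inhibitor combinations

Therapeutic drug monitoring of β-lactam (BL) antibiotics is increasingly
routine, but the β-lactamase inhibitor (BLI) co-administered with them is
usually not monitored. That leaves a blind spot: a patient's BL exposure can
look adequate while the BLI — which must also reach its own pharmacodynamic
target for the combination to kill β-lactamase-producing bacteria — falls
short at the site of infection. `blipta` is a Monte-Carlo simulation framework
for quantifying that risk. It computes the probability of target attainment
(PTA) for the BL alone, the BLI alone, and the combination (both targets met
by the same virtual patient) across infection sites, renal-function scenarios,
MIC grids and target stringency tiers, for five marketed combinations:
piperacillin-tazobactam, ceftolozane-tazobactam, ceftazidime-avibactam,
meropenem-vaborbactam and imipenem-relebactam.

## Model

For each compound a population-pharmacokinetic model (1–3 compartment linear
mamillary, intermittent intravenous infusion) generates individual parameters

```
θ_i = θ_typical · f(CrCL) · exp(η_i),   η_i ~ MVN(0, Ω)
```

where `f(CrCL)` is the model's renal covariate relation evaluated at 80 mL/min
(typical renal clearance, TRC) or 200 mL/min (augmented, ARC), and Ω is the
log-scale interindividual covariance. Steady-state concentration–time profiles
are the exact analytic superposition of infusion responses (verified against a
numerical ODE oracle to ≤ 1e-6 relative). Unbound site exposure is a constant
rescaling of total plasma concentration,

```
C_site(t) = C_plasma(t) · fu · TPR(site)
```

with fu the unbound fraction and TPR the tissue penetration ratio (epithelial
lining fluid for pneumonia, peritoneal fluid for intra-abdominal infection,
prostate for prostatitis, unbound plasma for bacteraemia/cUTI). A BLI missing
a TPR inherits its partner BL's value. Three PK/PD indices are supported, each
with EUCAST < Severe < Aggressive tier magnitudes:

* `%fT>MIC` — percent of the dosing interval with unbound site concentration
  above the MIC (BLs),
* `%fT>C_T` — same against a fixed 1 mg/L threshold (time-dependent BLIs:
  avibactam, tazobactam),
* `fAUC0–24/MIC` — unbound 24 h AUC over MIC (relebactam, vaborbactam).

PTA is the attained fraction of n = 5000 virtual patients with a
Clopper–Pearson 95% CI; attainment comparisons are inclusive (≥). Within a
combination the BL and BLI share covariates per patient but draw independent
random effects, and the same virtual population is reused across tiers, MICs
and sites (common random numbers), so the structural orderings — combination
PTA ≤ min(component PTAs), tier and MIC monotonicity — hold exactly.

## Worked example

```python
from blipta import load_model_library, default_library_path
from blipta.pta import PTAEngine, ScenarioKey

lib = load_model_library(default_library_path())
engine = PTAEngine(lib, n=5000, seed=1)
for component in ("BL", "BLI", "combined"):
    key = ScenarioKey(combination="CAZ-AVI", component=component,
                      indication="HAP/VAP", scenario="TRC",
                      tier="EUCAST", mic=4.0)
    res = engine.compute_pta(key)
    print(f"{component:8s} PTA {res.pta:5.1f}%  CI [{res.ci_low:.1f}, {res.ci_high:.1f}]")
```

prints

```
BL       PTA  99.8%  CI [99.7, 99.9]
BLI      PTA  77.1%  CI [75.9, 78.3]
combined PTA  77.0%  CI [75.8, 78.1]
```

— for pneumonia at MIC 4 mg/L the ceftazidime target is met by essentially
every simulated patient, but avibactam's lung exposure (fu 0.92 × ELF
penetration 0.30) leaves roughly a quarter of patients below its 50% fT>C_T
target, and the combination inherits that shortfall. Monitoring ceftazidime
alone would not see it.

The numbered drivers under `analysis/` run the complete study: input overview,
typical-patient exposures, the full stratified PTA grid with plots
(`03_pta_grid.py`, ~1 min), headline scenarios and the fu/TPR sensitivity
sweep.

## A note on the shipped model parameters

fu, TPR, PK/PD targets, MIC grids and dose regimens are transcribed from
published tables and SmPCs. The population-PK parameter sets under
`src/blipta/data/library/` are provisional transcriptions from the cited
source models (see each file's header) and should be confirmed against the
original publications before absolute PTA values are relied on; the synthetic
library under `src/blipta/data/synthetic/` is fully self-contained and backs
the test suite. Structural conclusions (which component limits the
combination, orderings across tiers/MIC/renal function) are robust to these
values; absolute percentages are not.

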