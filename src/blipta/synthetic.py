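"""Self-contained fixtures and independent oracles.

Everything here exists so that the whole pipeline is testable without any
transcribed drug model: reference compartmental models whose key quantities
have closed forms, a two-point mixture population with analytically known PTA,
a general-purpose ODE integration oracle for the analytic engine, and a
dense-grid brute-force oracle for the exact-crossing time-above-threshold
computation. Fixture parameter values are arbitrary but frozen; they are test
scaffolding, not estimates of any real drug.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .library import (
    DoseRegimen,
    IIVSpec,
    ModelLibrary,
    PatientScenario,
    PKPDTarget,
    PopPKModel,
    SitePenetration,
    TPREntry,
    load_model_library,
    synthetic_library_path,
)
from .simulate import PopulationSample, rate_matrix


@dataclass
class ReferenceFixture:
    """A fully specified model + regimen + penetration + target with frozen
    closed-form expected values stored alongside."""

    name: str
    model: PopPKModel
    regimen: DoseRegimen
    penetration: SitePenetration
    target: PKPDTarget
    scenario: PatientScenario
    expected: dict[str, float] = field(default_factory=dict)


def make_onecpt_fixture() -> ReferenceFixture:
    """1-compartment reference: CL=10 L/h, V=20 L, 1000 mg over 1 h q8h,
    fu=0.5, TPR=0.5 at a generic 'ELF' site.

    Closed forms (k = CL/V = 0.5 /h, rate R = 1000 mg/h):
      single-dose end-of-infusion   C = (D/CL)(1 - e^{-k T_inf})
      steady-state end-of-infusion  C_ss = C / (1 - e^{-k tau})
      unbound plasma fAUC0-24       fu * (daily dose) / CL
    """
    cl, v, dose, t_inf, tau, fu, tpr = 10.0, 20.0, 1000.0, 1.0, 8.0, 0.5, 0.5
    k = cl / v
    c_eoi = (dose / cl) * (1.0 - math.exp(-k * t_inf))
    c_eoi_ss = c_eoi / (1.0 - math.exp(-k * tau))
    fauc24_unbound = fu * (dose * 24.0 / tau) / cl
    model = PopPKModel(
        compound_name="refdrug1",
        n_compartments=1,
        typical_params={"CL": cl, "V1": v},
        iiv=IIVSpec(parameters=[], matrix=[]),
    )
    return ReferenceFixture(
        name="onecpt",
        model=model,
        regimen=DoseRegimen(dose_mg=dose, infusion_duration_h=t_inf, interval_h=tau),
        penetration=SitePenetration(
            compound_name="refdrug1",
            fu=fu,
            tpr={"ELF": TPREntry(value=tpr, provenance="measured")},
        ),
        target=PKPDTarget(
            metric="ft_above_mic",
            tier_magnitudes={"EUCAST": 40.0, "Severe": 60.0, "Aggressive": 90.0},
            mic_grid_mg_per_L=[1.0, 2.0, 4.0, 8.0],
        ),
        scenario=PatientScenario(label="TRC", crcl_mL_per_min=80.0),
        expected={
            "single_dose_c_at_1h": c_eoi,  # ~39.347 mg/L
            "ss_end_of_infusion": c_eoi_ss,  # ~40.081 mg/L
            "fauc24_unbound_plasma": fauc24_unbound,  # 150 mg.h/L
            "fauc24_site": fauc24_unbound * tpr,  # 75 mg.h/L
            "terminal_half_life": math.log(2.0) / k,
        },
    )


def make_twocpt_fixture() -> ReferenceFixture:
    """2-compartment reference with an fAUC-type target; the steady-state
    unbound fAUC0-24 identity fu*TPR*(daily dose)/CL still holds exactly."""
    cl, v1, q2, v2 = 8.0, 15.0, 6.0, 25.0
    dose, t_inf, tau, fu = 500.0, 0.5, 12.0, 0.8
    model = PopPKModel(
        compound_name="refdrug2",
        n_compartments=2,
        typical_params={"CL": cl, "V1": v1, "Q2": q2, "V2": v2},
    )
    return ReferenceFixture(
        name="twocpt",
        model=model,
        regimen=DoseRegimen(dose_mg=dose, infusion_duration_h=t_inf, interval_h=tau),
        penetration=SitePenetration(
            compound_name="refdrug2",
            fu=fu,
            tpr={"peritoneal": TPREntry(value=0.6, provenance="measured")},
        ),
        target=PKPDTarget(
            metric="fauc_over_mic",
            tier_magnitudes={"EUCAST": 10.0, "Severe": 20.0, "Aggressive": 30.0},
            mic_grid_mg_per_L=[1.0, 2.0, 4.0],
        ),
        scenario=PatientScenario(label="TRC", crcl_mL_per_min=80.0),
        expected={
            "fauc24_unbound_plasma": fu * (dose * 24.0 / tau) / cl,  # 100 mg.h/L
            "fauc24_site": fu * 0.6 * (dose * 24.0 / tau) / cl,
        },
    )


def make_random_model(
    rng: np.random.Generator, n_compartments: int | None = None
) -> tuple[PopPKModel, dict[str, float]]:
    """Random positive 1-3 compartment model with physiologically plausible
    ranges (CL 2-30 L/h, volumes 5-60 L, inter-compartmental clearances
    1-20 L/h). Returns the model and a realized parameter dict."""
    m = int(n_compartments or rng.integers(1, 4))
    values = {
        "CL": float(rng.uniform(2.0, 30.0)),
        "V1": float(rng.uniform(5.0, 40.0)),
    }
    for j in range(2, m + 1):
        values[f"Q{j}"] = float(rng.uniform(1.0, 20.0))
        values[f"V{j}"] = float(rng.uniform(5.0, 60.0))
    model = PopPKModel(
        compound_name=f"random{m}cpt",
        n_compartments=m,
        typical_params=dict(values),
    )
    return model, values


def make_random_regimen(rng: np.random.Generator) -> DoseRegimen:
    tau = float(rng.choice([6.0, 8.0, 12.0, 24.0]))
    t_inf = float(rng.uniform(0.25, min(4.0, tau)))
    return DoseRegimen(
        dose_mg=float(rng.uniform(250.0, 4000.0)),
        infusion_duration_h=t_inf,
        interval_h=tau,
    )


def oracle_ode_profile(
    model: PopPKModel,
    values: dict[str, float],
    regimen: DoseRegimen,
    times: np.ndarray,
    n_doses: int = 1,
    rtol: float = 1e-11,
    atol: float = 1e-12,
) -> np.ndarray:
    """Central concentration via general-purpose numerical ODE integration.

    Integrates segment by segment between infusion on/off events so the
    discontinuous input never crosses a solver step. Independent of the
    analytic superposition engine; intentionally slow.
    """
    times = np.asarray(times, dtype=float)
    A = rate_matrix(values, model.n_compartments)
    rate = regimen.dose_mg / regimen.infusion_duration_h
    breaks = set()
    for k in range(n_doses):
        breaks.add(k * regimen.interval_h)
        breaks.add(k * regimen.interval_h + regimen.infusion_duration_h)
    t_end = float(times.max())
    breaks = sorted(b for b in breaks if b < t_end) + [t_end]

    def infusing(t: float) -> bool:
        for k in range(n_doses):
            if k * regimen.interval_h <= t < k * regimen.interval_h + regimen.infusion_duration_h:
                return True
        return False

    x = np.zeros(model.n_compartments)
    out = np.zeros_like(times)
    out[times <= 0] = 0.0
    t_prev = 0.0
    for t_next in breaks:
        if t_next <= t_prev + 1e-15:
            t_prev = max(t_prev, t_next)
            continue
        mid = 0.5 * (t_prev + t_next)
        b = np.zeros(model.n_compartments)
        if infusing(mid):
            b[0] = rate

        def rhs(t, y):
            return A @ y + b

        t_eval = times[(times > t_prev + 1e-12) & (times <= t_next + 1e-12)]
        t_all = np.unique(np.append(t_eval, t_next))
        sol = solve_ivp(
            rhs, (t_prev, t_next), x, method="LSODA", t_eval=t_all,
            rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"ODE oracle failed: {sol.message}")
        if t_eval.size:
            pos = np.searchsorted(t_all, t_eval)
            out[np.searchsorted(times, t_eval)] = sol.y[0, pos]
        x = sol.y[:, -1]
        t_prev = t_next
    return out / values["V1"]


def oracle_ft_above(
    time: np.ndarray,
    conc: np.ndarray,
    threshold: float,
    window: tuple[float, float],
    dt: float = 1e-4,
) -> float:
    """Brute-force %fT>threshold by counting on a dense uniform grid (linear
    interpolation of the stored profile). Intentionally slow; bin midpoints so
    the count converges to the exact crossing answer as dt -> 0."""
    t0, t1 = window
    dense = np.arange(t0 + 0.5 * dt, t1, dt)
    c = np.interp(dense, time, conc)
    return 100.0 * float(np.mean(c > threshold))


def make_mixture_population(
    p_attain: float, n: int, seed: int
) -> tuple[PopulationSample, ReferenceFixture, float, np.ndarray]:
    """Two-point clearance mixture over the 1-compartment fixture, engineered so
    exactly the low-CL patients attain the EUCAST %fT>MIC target at MIC 2 mg/L
    (site = ELF, scale fu*TPR = 0.25); true PTA = p_attain.

    Returns (population, fixture, true_pta_percent, attain_mask).
    Construction is validated at run time: the low-CL patient must attain and
    the high-CL patient must not, by the closed-form time-above solution.
    """
    if not (0.0 <= p_attain <= 1.0):
        raise ValueError("p_attain must lie in [0, 1]")
    fx = make_onecpt_fixture()
    cl_low, cl_high, v = 5.0, 40.0, fx.model.typical_params["V1"]
    mic, scale = 2.0, 0.25
    magnitude = fx.target.tier_magnitudes["EUCAST"]  # 40% of the interval

    def ft_closed(cl: float) -> float:
        # steady-state 1-cpt: rises during infusion, single down-crossing per interval
        k = cl / v
        reg = fx.regimen
        acc = 1.0 / (1.0 - math.exp(-k * reg.interval_h))
        thr_total = mic / scale

        def conc(t: float) -> float:  # t in [0, tau) at steady state
            r = reg.dose_mg / reg.infusion_duration_h
            if t <= reg.infusion_duration_h:
                c = (r / cl) * (1.0 - math.exp(-k * t))
                # accumulated tails of all previous doses, summed geometrically:
                # each dose j back decays for (t + j*tau - T_inf) hours
                c += (
                    (r / cl)
                    * (1.0 - math.exp(-k * reg.infusion_duration_h))
                    * (acc - 1.0)
                    * math.exp(-k * (t - reg.infusion_duration_h))
                )
                return c
            c_eoi = (r / cl) * (1.0 - math.exp(-k * reg.infusion_duration_h)) * acc
            return c_eoi * math.exp(-k * (t - reg.infusion_duration_h))

        ts = np.linspace(0.0, reg.interval_h, 20001)
        above = np.array([conc(t) > thr_total for t in ts])
        return 100.0 * above.mean()

    ft_low, ft_high = ft_closed(cl_low), ft_closed(cl_high)
    if not (ft_low >= magnitude > ft_high):
        raise RuntimeError(
            f"mixture engineering broken: ft(low)={ft_low:.1f}, ft(high)={ft_high:.1f}"
        )
    rng = np.random.default_rng(seed)
    attain_mask = rng.random(n) < p_attain
    cl = np.where(attain_mask, cl_low, cl_high)
    pop = PopulationSample(
        compound_key=fx.model.compound_name,
        scenario=fx.scenario,
        params=pd.DataFrame({"CL": cl, "V1": np.full(n, v)}),
        seed_info=f"mixture:{seed}",
    )
    return pop, fx, 100.0 * p_attain, attain_mask


def make_synthetic_library() -> ModelLibrary:
    """Load the shipped self-contained synthetic config library (same schema as
    the transcribed one; doubles as schema documentation)."""
    return load_model_library(synthetic_library_path())
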