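"""Target-site scaling and PK/PD index computation.

Plasma-to-site translation is a constant-ratio scaling by ``fu x TPR`` (the
site profile mirrors the shape of the plasma profile; distributional delay and
tissue accumulation are out of scope). The three indices are

* ``%fT>MIC``   -- percent of the dosing interval with unbound site
  concentration above the MIC (exact linear-interpolated crossing times);
* ``%fT>C_T``   -- the same against a fixed threshold concentration
  (1 mg/L by default), used for time-dependent beta-lactamase inhibitors;
* ``fAUC0-24/MIC`` -- trapezoidal unbound AUC over the steady-state 24 h
  window, divided by the MIC.

Attainment comparisons are inclusive (>=).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UnknownPenetrationError
from .library import PKPDTarget, SitePenetration
from .simulate import ConcentrationProfile, PopulationProfiles


@dataclass
class SiteProfile:
    """A plasma profile rescaled to unbound site concentration.

    ``conc`` is ``total plasma x fu x TPR``; the applied scale is recorded for
    audit. Works for a single patient (1-d conc) or a population (2-d).
    """

    time_h: np.ndarray
    conc_mg_per_L: np.ndarray
    site: str
    scale: float
    interval_window: tuple[float, float]
    fauc_window: tuple[float, float]
    compound_name: str = ""


@dataclass
class MetricValue:
    """One computed PK/PD index value."""

    kind: str  # ft_above_mic | ft_above_ct | fauc_over_mic
    value: float  # % of interval for time metrics; mg.h/L for fAUC0-24
    threshold_mg_per_L: float | None
    window: tuple[float, float]


def site_scale(
    pen: SitePenetration,
    site: str,
    *,
    fu_sel: str = "base",
    tpr_sel: str = "base",
    tpr_override: float | None = None,
) -> float:
    """Resolve the ``fu x TPR`` scaling factor for a compound at a site.

    ``fu_sel``/``tpr_sel`` pick ``low``/``base``/``high`` bounds for the
    sensitivity sweep; ``tpr_override`` substitutes an explicit TPR value
    (used by the tazobactam combination-swap variants).
    Raises :class:`UnknownPenetrationError` when the site has no usable TPR.
    """
    fu = pen.pick_fu(fu_sel) if (fu_sel == "base" or pen.fu_bounded) else pen.fu
    if tpr_override is not None:
        tpr = tpr_override
    else:
        entry = pen.resolve(site)
        tpr = entry.pick(tpr_sel) if (tpr_sel == "base" or entry.bounded) else entry.value
    return fu * tpr


def to_site(
    profile: ConcentrationProfile | PopulationProfiles,
    pen: SitePenetration,
    site: str,
    *,
    fu_sel: str = "base",
    tpr_sel: str = "base",
    tpr_override: float | None = None,
) -> SiteProfile:
    """Rescale a total-plasma profile to unbound concentration at ``site``."""
    scale = site_scale(
        pen, site, fu_sel=fu_sel, tpr_sel=tpr_sel, tpr_override=tpr_override
    )
    return SiteProfile(
        time_h=profile.time_h,
        conc_mg_per_L=profile.conc_mg_per_L * scale,
        site=site,
        scale=scale,
        interval_window=profile.interval_window,
        fauc_window=profile.fauc_window,
        compound_name=pen.compound_name,
    )


def _window_slice(time: np.ndarray, conc: np.ndarray, window: tuple[float, float]):
    """Restrict (time, conc) to ``window`` with linear interpolation at the
    endpoints; conc may be (T,) or (n, T) on a shared grid."""
    t0, t1 = window
    if not (t1 > t0):
        raise ValueError("empty evaluation window")
    if t0 < time[0] - 1e-9 or t1 > time[-1] + 1e-9:
        raise ValueError("window outside the simulated profile span")
    conc2 = np.atleast_2d(conc)

    def interp_at(t: float) -> np.ndarray:
        i = np.searchsorted(time, t, side="right") - 1
        i = min(max(i, 0), time.size - 2)
        f = (t - time[i]) / (time[i + 1] - time[i])
        return conc2[:, i] * (1.0 - f) + conc2[:, i + 1] * f

    inner = (time > t0 + 1e-12) & (time < t1 - 1e-12)
    sub_t = np.concatenate(([t0], time[inner], [t1]))
    sub_c = np.concatenate(
        (interp_at(t0)[:, None], conc2[:, inner], interp_at(t1)[:, None]), axis=1
    )
    return sub_t, sub_c


def fraction_above(
    time: np.ndarray,
    conc: np.ndarray,
    threshold: float,
    window: tuple[float, float],
) -> np.ndarray | float:
    """Percent of ``window`` during which ``conc`` exceeds ``threshold``.

    The profile is treated as piecewise linear on its grid; crossing times
    inside each segment are solved exactly. Returns a scalar for a 1-d profile,
    an array over patients for a 2-d one; values lie in [0, 100].
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    sub_t, sub_c = _window_slice(time, conc, window)
    dt = np.diff(sub_t)[None, :]
    c0, c1 = sub_c[:, :-1], sub_c[:, 1:]
    above0, above1 = c0 > threshold, c1 > threshold
    frac = np.zeros_like(c0)
    frac[above0 & above1] = 1.0
    cross = above0 ^ above1
    if cross.any():
        hi = np.where(above0, c0, c1)
        lo = np.where(above0, c1, c0)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (hi - threshold) / (hi - lo)
        frac[cross] = f[cross]
    t_above = (frac * dt).sum(axis=1)
    out = 100.0 * t_above / (window[1] - window[0])
    out = np.clip(out, 0.0, 100.0)
    return float(out[0]) if np.ndim(conc) == 1 else out


def ft_above(
    profile: SiteProfile,
    threshold_mg_per_L: float,
    window: tuple[float, float] | None = None,
) -> np.ndarray | float:
    """%fT>threshold over the steady-state dosing interval (or a given window)."""
    window = window or profile.interval_window
    return fraction_above(profile.time_h, profile.conc_mg_per_L, threshold_mg_per_L, window)


def fauc24(
    profile: SiteProfile, window: tuple[float, float] | None = None
) -> np.ndarray | float:
    """Unbound site AUC (mg.h/L) over the steady-state 24 h window, by the
    trapezoidal rule on the event-aware grid."""
    window = window or profile.fauc_window
    if window[1] - window[0] < 24.0 - 1e-9:
        raise ValueError("fAUC window must span 24 h")
    sub_t, sub_c = _window_slice(profile.time_h, profile.conc_mg_per_L, window)
    auc = np.trapezoid(sub_c, sub_t, axis=1)
    return float(auc[0]) if np.ndim(profile.conc_mg_per_L) == 1 else auc


def metric_for_target(
    profile: SiteProfile, target: PKPDTarget, mic: float | None = None
) -> MetricValue:
    """Compute the index a target prescribes, on a single-patient site profile."""
    if target.metric == "ft_above_mic":
        if mic is None:
            raise ValueError("ft_above_mic requires a MIC")
        value = ft_above(profile, mic)
        thr = mic
    elif target.metric == "ft_above_ct":
        value = ft_above(profile, target.c_t_mg_per_L)
        thr = target.c_t_mg_per_L
        # identical across the MIC grid by construction
    else:
        value = fauc24(profile)
        thr = None
    window = profile.fauc_window if target.metric == "fauc_over_mic" else profile.interval_window
    return MetricValue(kind=target.metric, value=float(np.atleast_1d(value)[0]) if np.ndim(value) == 0 else value, threshold_mg_per_L=thr, window=window)


def evaluate_attainment(
    metric: MetricValue, target: PKPDTarget, tier: str, mic: float | None = None
) -> bool:
    """Inclusive (>=) attainment of a tier magnitude.

    Time metrics attain when the percent value reaches the magnitude;
    fAUC-based targets attain when ``fAUC0-24 / MIC`` reaches it. The MIC is
    ignored for %fT>C_T targets.
    """
    if metric.kind != target.metric:
        raise ValueError(
            f"metric kind {metric.kind!r} does not match target {target.metric!r}"
        )
    magnitude = target.magnitude(tier)
    if target.metric == "fauc_over_mic":
        if mic is None:
            raise ValueError("fauc_over_mic requires a MIC")
        return bool(metric.value / mic >= magnitude)
    return bool(metric.value >= magnitude)


def attainment_vector(
    values: np.ndarray, target: PKPDTarget, tier: str, mic: float | None = None
) -> np.ndarray:
    """Vectorized attainment over a population of metric values."""
    values = np.asarray(values, dtype=float)
    magnitude = target.magnitude(tier)
    if target.metric == "fauc_over_mic":
        if mic is None:
            raise ValueError("fauc_over_mic requires a MIC")
        return values / mic >= magnitude
    return values >= magnitude
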