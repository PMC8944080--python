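"""Michaelis–Menten kinetics from the coupled tryptophanase–LDH/NADH assay.

The tryptophanase (TNA) reaction releases pyruvate, which an excess of lactate
dehydrogenase immediately reduces to lactate at the expense of NADH.  Under
this quasi-steady coupling the rate of NADH oxidation — read photometrically
at 340 nm — equals the TNA turnover rate, so:

    v(S) = -dA340/dt / (epsilon * l)

with epsilon the molar absorptivity of NADH and l the path length.  Initial
rates measured over a substrate series are fitted to v = v_max*S/(K_M+S) by
nonlinear least squares; v_max is converted to the turnover number k_cat via
the molar enzyme concentration, and the catalytic efficiency is k_cat/K_M.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

#: NADH molar absorptivity at 340 nm, AU mM^-1 cm^-1, and cuvette path, cm.
EPSILON_NADH = 6.22
PATH_LENGTH_CM = 1.0


@dataclass
class KineticTrace:
    """An absorbance-vs-time record of one coupled-assay reaction."""

    time_s: np.ndarray
    absorbance: np.ndarray
    substrate_mm: float
    conditions: dict = field(default_factory=dict)
    exhausted_at_s: Optional[float] = None  # NADH (or substrate) ran out here

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.time_s.shape != self.absorbance.shape:
            raise ValueError("time and absorbance must have equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance must be finite")

    @property
    def epsilon(self) -> float:
        return float(self.conditions.get("epsilon_nadh", EPSILON_NADH))

    @property
    def path_length(self) -> float:
        return float(self.conditions.get("path_length_cm", PATH_LENGTH_CM))


@dataclass(frozen=True)
class RateEstimate:
    """Initial rate extracted from the linear region of a trace."""

    initial_rate_mm_per_min: float
    fit_window_s: tuple[float, float]
    r_squared: float
    substrate_mm: float
    low_r2_warning: bool = False


@dataclass(frozen=True)
class MMFitResult:
    """Michaelis–Menten parameters with curvature-based standard errors."""

    km_mm: float
    vmax_mm_per_min: float
    kcat_per_s: float
    km_se: float
    vmax_se: float
    kcat_se: float
    residual_ss: float
    n_points: int
    extrapolation_warning: bool = False

    def rate_at(self, substrate_mm: float) -> float:
        """Fitted v(S) in mM/min."""
        return self.vmax_mm_per_min * substrate_mm / (self.km_mm + substrate_mm)


@dataclass(frozen=True)
class EfficiencyResult:
    """Catalytic efficiency k_cat/K_M with its uncertainty."""

    kcat_over_km: float  # mM^-1 s^-1
    uncertainty: float
    method: str  # "per-replicate" | "propagation"

    @property
    def rounded(self) -> float:
        from .bioconversion import round_half_away
        return round_half_away(self.kcat_over_km, 1)


def linear_window(trace: KineticTrace) -> tuple[float, float]:
    """The trace's initial linear region: start to exhaustion (or the end).

    Under quasi-steady coupling the NADH signal falls linearly until either
    NADH or substrate runs out, so the widest unbiased rate window stretches
    to ``exhausted_at_s`` when set and the whole trace otherwise.
    """
    t = trace.time_s
    hi = trace.exhausted_at_s if trace.exhausted_at_s is not None else float(t[-1])
    return float(t[0]), min(float(t[-1]), hi)


def trace_to_rate(trace: KineticTrace, window: Optional[tuple[float, float]] = None,
                  *, min_r_squared: float = 0.2) -> RateEstimate:
    """Least-squares initial rate of NADH consumption from one trace.

    The slope of absorbance vs time over ``window`` (default: the first 10% of
    the trace span, at least 3 points) is converted to a rate in mM/min via
    -slope / (epsilon*l).  A window reaching into the region where the coupled
    readout is exhausted is rejected; a noise-dominated fit only triggers a
    low-R^2 warning flag.
    """
    t, a = trace.time_s, trace.absorbance
    if window is None:
        span = t[-1] - t[0]
        window = (t[0], t[0] + 0.10 * span)
    lo, hi = window
    if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
        raise ValueError("fit window outside trace span")
    mask = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    if mask.sum() < 3:
        # widen to the first 3 points rather than fail on coarse sampling
        mask = np.zeros_like(mask)
        mask[:3] = True
        hi = t[2]
    if trace.exhausted_at_s is not None and hi > trace.exhausted_at_s + 1e-9:
        raise ValueError(
            f"fit window extends past NADH/substrate exhaustion at "
            f"{trace.exhausted_at_s:.1f} s")

    tw, aw = t[mask], a[mask]
    slope, intercept = np.polyfit(tw, aw, 1)
    pred = slope * tw + intercept
    ss_res = float(np.sum((aw - pred) ** 2))
    ss_tot = float(np.sum((aw - aw.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    rate = -slope * 60.0 / (trace.epsilon * trace.path_length)  # AU/s -> mM/min
    return RateEstimate(
        initial_rate_mm_per_min=max(0.0, rate),
        fit_window_s=(float(tw[0]), float(tw[-1])),
        r_squared=r2,
        substrate_mm=trace.substrate_mm,
        low_r2_warning=r2 < min_r_squared,
    )


def _mm(s, vmax, km):
    return vmax * s / (km + s)


def fit_mm(rates: Sequence[tuple[float, float]], enzyme_molar_mm: float) -> MMFitResult:
    """Nonlinear least-squares Michaelis–Menten fit of (substrate, rate) pairs.

    Initialization: v_max0 = max observed rate; K_M0 = substrate at half-max,
    linearly interpolated.  k_cat = v_max / (60 * [E]) with [E] in mM and
    v_max in mM/min.  Standard errors come from the Jacobian-based covariance
    at the optimum.

    Raises if fewer than 4 substrate levels are given or the design is
    degenerate (a single substrate level cannot identify both parameters).
    """
    if enzyme_molar_mm <= 0:
        raise ValueError("enzyme_molar_mm must be positive")
    data = sorted((float(s), float(v)) for s, v in rates)
    s_arr = np.array([d[0] for d in data])
    v_arr = np.array([d[1] for d in data])
    if len(set(s_arr.tolist())) < 4:
        raise ValueError("need rates at >= 4 distinct substrate levels "
                         "spanning below and above K_M")

    vmax0 = float(v_arr.max())
    half = vmax0 / 2.0
    km0 = float(np.interp(half, v_arr, s_arr))  # v sorted ~increasing with s
    km0 = max(km0, 1e-9)

    try:
        popt, pcov = curve_fit(_mm, s_arr, v_arr, p0=[vmax0, km0],
                               bounds=([0.0, 0.0], [np.inf, np.inf]),
                               maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - pathological data
        raise RuntimeError(
            f"Michaelis–Menten fit failed to converge "
            f"(init vmax0={vmax0:.4g}, km0={km0:.4g}): {exc}") from exc
    vmax, km = float(popt[0]), float(popt[1])
    if km <= 0 or vmax <= 0:
        raise RuntimeError("fit collapsed to a non-positive parameter")
    ses = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    vmax_se, km_se = float(ses[0]), float(ses[1])

    kcat = vmax / 60.0 / enzyme_molar_mm
    kcat_se = vmax_se / 60.0 / enzyme_molar_mm
    resid = v_arr - _mm(s_arr, vmax, km)
    return MMFitResult(
        km_mm=km, vmax_mm_per_min=vmax, kcat_per_s=kcat,
        km_se=km_se, vmax_se=vmax_se, kcat_se=kcat_se,
        residual_ss=float(np.sum(resid ** 2)), n_points=len(s_arr),
        extrapolation_warning=not (s_arr.min() <= km <= s_arr.max()),
    )


def catalytic_efficiency(kcat_per_s: float, km_mm: float) -> float:
    """k_cat/K_M in mM^-1 s^-1 (raw)."""
    if km_mm <= 0:
        raise ValueError("km must be positive")
    return kcat_per_s / km_mm


def efficiency(fit: MMFitResult,
               replicates: Optional[Sequence[tuple[float, float]]] = None) -> EfficiencyResult:
    """Catalytic efficiency of a fit, with an uncertainty estimate.

    With ``replicates`` — a list of per-replicate (kcat, km) pairs — the
    uncertainty is the sample SD of the per-replicate ratios; otherwise
    first-order propagation of the fit's standard errors is used.
    """
    central = catalytic_efficiency(fit.kcat_per_s, fit.km_mm)
    if replicates:
        ratios = [catalytic_efficiency(k, m) for k, m in replicates]
        n = len(ratios)
        mean = sum(ratios) / n
        sd = math.sqrt(sum((r - mean) ** 2 for r in ratios) / (n - 1)) if n > 1 else 0.0
        return EfficiencyResult(central, sd, "per-replicate")
    rel = math.sqrt((fit.kcat_se / fit.kcat_per_s) ** 2
                    + (fit.km_se / fit.km_mm) ** 2)
    return EfficiencyResult(central, central * rel, "propagation")


def specific_activity(rate_umol_per_min: float, protein_mg: float) -> float:
    """Specific activity in mU per mg protein.

    One unit (U) converts 1 umol substrate per minute, so U = umol/min and
    the result is 1000 * rate / protein.
    """
    if protein_mg <= 0:
        raise ValueError("protein_mg must be positive")
    if rate_umol_per_min < 0:
        raise ValueError("rate must be non-negative")
    return 1000.0 * rate_umol_per_min / protein_mg
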