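"""ATP turnover from coupled-enzyme (NADH-depletion) progress curves.

In the regenerating assay each hydrolysed ATP oxidises one NADH, so the
340 nm absorbance falls linearly at steady state.  The turnover number is

    k = -slope_corrected / (epsilon * path * [enzyme])    [min^-1]

with the slope in AU/min, epsilon the NADH extinction coefficient
(default 6220 M^-1 cm^-1 at 340 nm) and the enzyme concentration per
protomer (per-dimer reporting available via a flag).  The
Hsp90-independent background slope, measured after adding a
NTD-competitive inhibitor (radicicol) at the end of the run, is
subtracted.  ATP and co-chaperone dependences are fitted with the
Michaelis–Menten and hyperbolic activation/inhibition models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from lmfit import Parameters, minimize
from scipy.stats import linregress

EPSILON_NADH_340 = 6220.0  # M^-1 cm^-1


@dataclass
class ProgressCurve:
    """A340 vs. time for one ATPase reaction."""

    times: np.ndarray  # min
    absorbance: np.ndarray  # AU at 340 nm
    enzyme_conc: float  # µM protomer
    path_length: float = 1.0  # cm
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.times.shape != self.absorbance.shape:
            raise ValueError("times and absorbance must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.enzyme_conc <= 0:
            raise ValueError("enzyme concentration must be positive")


@dataclass
class TurnoverResult:
    """Background-corrected ATP turnover and the underlying slopes."""

    k_turnover: float  # min^-1 per protomer (or per dimer, see per_dimer)
    raw_slope: float  # AU/min
    background_slope: float  # AU/min
    stderr: float  # min^-1
    per_dimer: bool = False
    flags: list[str] = field(default_factory=list)


@dataclass
class MMFit:
    """Michaelis–Menten parameters for the ATP dependence."""

    K_M: float  # µM ATP
    v_max: float  # min^-1
    stderr: dict[str, Optional[float]] = field(default_factory=dict)
    rss: float = 0.0
    flags: list[str] = field(default_factory=list)


@dataclass
class ActivationFit:
    """Hyperbolic co-chaperone response (activation or inhibition)."""

    v0: float  # min^-1 at zero co-chaperone
    v_max: float  # min^-1 plateau
    K_half: float  # µM co-chaperone
    direction: Optional[str]  # "activation" | "inhibition" | None if flat
    stderr: dict[str, Optional[float]] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


def _window_slope(curve: ProgressCurve, window: tuple[float, float]) -> tuple[float, float]:
    lo, hi = window
    mask = (curve.times >= lo) & (curve.times <= hi)
    if mask.sum() < 5:
        raise ValueError(f"window {window} contains fewer than 5 points")
    reg = linregress(curve.times[mask], curve.absorbance[mask])
    return float(reg.slope), float(reg.stderr)


def slope_to_turnover(
    curve: ProgressCurve,
    rate_window: tuple[float, float],
    background_window: Optional[tuple[float, float]] = None,
    epsilon: float = EPSILON_NADH_340,
    per_dimer: bool = False,
) -> TurnoverResult:
    """ATP turnover from the linear-regression slope in ``rate_window``.

    ``background_window`` (after inhibitor addition) gives the
    Hsp90-independent slope to subtract.  A positive corrected slope
    (apparent negative rate) is floored at zero with a warning flag.
    """
    raw_slope, raw_se = _window_slope(curve, rate_window)
    if background_window is not None:
        bg_slope, bg_se = _window_slope(curve, background_window)
    else:
        bg_slope, bg_se = 0.0, 0.0
    corrected = raw_slope - bg_slope
    enzyme = curve.enzyme_conc / (2.0 if per_dimer else 1.0)
    # AU/min -> M/min via Beer-Lambert, -> µM/min, -> min^-1 per enzyme.
    scale = 1e6 / (epsilon * curve.path_length * enzyme)
    k = -corrected * scale
    stderr = float(np.hypot(raw_se, bg_se) * scale)
    flags: list[str] = []
    if k < 0:
        warnings.warn("corrected slope is positive; turnover floored at 0", stacklevel=2)
        flags.append("rate_floored_at_zero")
        k = 0.0
    return TurnoverResult(
        k_turnover=float(k),
        raw_slope=raw_slope,
        background_slope=bg_slope,
        stderr=stderr,
        per_dimer=per_dimer,
        flags=flags,
    )


def michaelis_menten(atp: np.ndarray, v_max: float, k_m: float) -> np.ndarray:
    atp = np.asarray(atp, dtype=float)
    return v_max * atp / (k_m + atp)


def fit_michaelis_menten(atp_uM: np.ndarray, rates: np.ndarray) -> MMFit:
    """Least-squares fit of ``v = v_max [ATP] / (K_M + [ATP])``.

    Requires at least 5 concentrations; data with no visible curvature
    (all points in the linear regime) are flagged rather than rejected.
    """
    atp = np.asarray(atp_uM, dtype=float)
    v = np.asarray(rates, dtype=float)
    if len(atp) < 5:
        raise ValueError("at least 5 ATP concentrations are required")
    params = Parameters()
    params.add("v_max", value=float(v.max()) or 1.0, min=np.finfo(float).tiny)
    params.add("K_M", value=float(np.median(atp)), min=np.finfo(float).tiny)

    def residual(pars):
        return michaelis_menten(atp, pars["v_max"].value, pars["K_M"].value) - v

    out = minimize(residual, params, method="leastsq", xtol=1e-12, ftol=1e-12)
    if not out.success:
        raise RuntimeError(f"Michaelis-Menten fit failed: {out.message}")
    fit = MMFit(
        K_M=float(out.params["K_M"].value),
        v_max=float(out.params["v_max"].value),
        stderr={
            name: (float(out.params[name].stderr) if out.params[name].stderr is not None else None)
            for name in out.params
        },
        rss=float(np.sum(out.residual**2)),
    )
    if fit.K_M > 2.0 * atp.max():
        fit.flags.append("no_curvature_in_range")
    return fit


def fit_cochaperone_response(conc_uM: np.ndarray, rates: np.ndarray) -> ActivationFit:
    """Hyperbolic fit ``v = v0 + (v_max - v0) [C] / (K_half + [C])``.

    Requires at least 5 concentrations including 0.  ``direction`` follows
    the sign of (v_max - v0); a flat response leaves it None with an
    unidentifiable-K_half flag (the phenotype of a stimulation-dead
    variant).
    """
    c = np.asarray(conc_uM, dtype=float)
    v = np.asarray(rates, dtype=float)
    if len(c) < 5:
        raise ValueError("at least 5 co-chaperone concentrations are required")
    if not np.any(c == 0):
        raise ValueError("the series must include a zero-concentration point")
    nonzero = c[c > 0]
    params = Parameters()
    params.add("v0", value=float(v[np.argmin(c)]))
    params.add("v_max", value=float(v[np.argmax(c)]))
    params.add("K_half", value=float(np.median(nonzero)), min=np.finfo(float).tiny)

    def residual(pars):
        return (
            pars["v0"].value
            + (pars["v_max"].value - pars["v0"].value) * c / (pars["K_half"].value + c)
            - v
        )

    out = minimize(residual, params, method="leastsq", xtol=1e-12, ftol=1e-12)
    if not out.success:
        raise RuntimeError(f"co-chaperone response fit failed: {out.message}")
    v0 = float(out.params["v0"].value)
    v_max = float(out.params["v_max"].value)
    fit = ActivationFit(
        v0=v0,
        v_max=v_max,
        K_half=float(out.params["K_half"].value),
        direction=None,
        stderr={
            name: (float(out.params[name].stderr) if out.params[name].stderr is not None else None)
            for name in out.params
        },
    )
    span = abs(v_max - v0)
    data_scale = max(float(np.ptp(v)), abs(v0), np.finfo(float).tiny)
    se = fit.stderr.get("v_max")
    flat = span < 1e-3 * data_scale or (se is not None and span < 2.0 * se)
    if flat:
        fit.flags.append("flat_response_K_half_unidentifiable")
    else:
        fit.direction = "activation" if v_max > v0 else "inhibition"
    return fit
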