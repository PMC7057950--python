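"""Exponential fits for FRET closing and chase (subunit-exchange) kinetics.

The acceptor-channel signal after nucleotide addition reports N-terminal
dimer closure; it is fitted with ``y = A1 exp(-x/t1) + y0``.  For a
partially modified protein the population is a fixed-weight mixture of
unmodified and modified dimers and the model becomes

    y = w1 * A1 * exp(-x/t1_fixed) + w2 * A1 * exp(-x/t2) + y0

with the weights taken from the binomial species distribution and the
fast time constant fixed to the unmodified protein's value, leaving
(A1, t2, y0) free.  Rising (closing) traces are handled by a negative
amplitude; chase traces (dissociation after unlabelled-protein excess)
use the same mono-exponential form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from lmfit import Parameters, minimize

MAX_ITERATIONS = 500
XTOL = 1e-10


class FitConvergenceError(RuntimeError):
    """Raised when the optimizer fails; the message reports initial values."""


@dataclass
class FluorescenceTrace:
    """A fluorescence time course (s, arbitrary units)."""

    times: np.ndarray
    signal: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.shape != self.signal.shape:
            raise ValueError("times and signal must have equal length")
        if len(self.times) < 8:
            raise ValueError("at least 8 points are required for fitting")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class ExpFitResult:
    """Parameters, uncertainties and residual summary of an exponential fit."""

    params: dict[str, float]
    stderr: dict[str, Optional[float]]
    rss: float
    n_points: int
    fixed: frozenset[str] = frozenset()
    flags: list[str] = field(default_factory=list)
    model: str = "monoexponential"

    def predict(self, times: np.ndarray) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        p = self.params
        if self.model == "species_weighted_biexponential":
            w1, w2 = p["w1"], p["w2"]
            return (
                w1 * p["A1"] * np.exp(-t / p["t1"])
                + w2 * p["A1"] * np.exp(-t / p["t2"])
                + p["y0"]
            )
        return p["A1"] * np.exp(-t / p["t1"]) + p["y0"]


def _initial_guess(trace: FluorescenceTrace) -> tuple[float, float, float]:
    """Deterministic initialisation: offset from the last decile, amplitude
    from the first point, time constant from the (1 - 1/e) span crossing."""
    n = len(trace.times)
    y0 = float(np.mean(trace.signal[max(n - max(n // 10, 1), 1):]))
    a1 = float(trace.signal[0] - y0)
    span_target = trace.signal[0] - (1.0 - 1.0 / np.e) * a1
    if a1 >= 0:
        crossed = np.nonzero(trace.signal <= span_target)[0]
    else:
        crossed = np.nonzero(trace.signal >= span_target)[0]
    if len(crossed) and crossed[0] > 0:
        t_guess = float(trace.times[crossed[0]] - trace.times[0])
    else:
        t_guess = float((trace.times[-1] - trace.times[0]) / 3.0)
    return a1, max(t_guess, np.finfo(float).tiny), y0


def _run_fit(trace, params, model_fn, model_name, fixed=frozenset()) -> ExpFitResult:
    def residual(pars):
        return model_fn(pars, trace.times) - trace.signal

    out = minimize(
        residual, params, method="leastsq", xtol=XTOL, ftol=XTOL, max_nfev=MAX_ITERATIONS * 10
    )
    if not out.success:
        init = {name: params[name].value for name in params}
        raise FitConvergenceError(
            f"{model_name} fit failed ({out.message}); initial values {init}"
        )
    values = {name: float(out.params[name].value) for name in out.params}
    stderr = {
        name: (float(out.params[name].stderr) if out.params[name].stderr is not None else None)
        for name in out.params
    }
    result = ExpFitResult(
        params=values,
        stderr=stderr,
        rss=float(np.sum(out.residual**2)),
        n_points=len(trace.times),
        fixed=fixed,
        model=model_name,
    )
    # Degeneracy diagnostics: a vanishing amplitude leaves the time constant
    # unconstrained; an unreported stderr signals a flat direction.
    if abs(values.get("A1", 0.0)) < 1e-6 * max(np.ptp(trace.signal), abs(values["y0"]), 1e-30):
        result.flags.append("amplitude_negligible")
        result.flags.append("time_constant_unidentifiable")
    for tname in ("t1", "t2"):
        if tname in values and tname not in fixed:
            se = stderr.get(tname)
            if se is None or not np.isfinite(se) or se > 10 * abs(values[tname]):
                if "time_constant_unidentifiable" not in result.flags:
                    result.flags.append("time_constant_unidentifiable")
    return result


def fit_monoexponential(trace: FluorescenceTrace) -> ExpFitResult:
    """Least-squares fit of ``y = A1 exp(-x/t1) + y0``."""
    a1, t_guess, y0 = _initial_guess(trace)
    params = Parameters()
    params.add("A1", value=a1 if a1 != 0 else 1e-12)
    params.add("t1", value=t_guess, min=np.finfo(float).tiny)
    params.add("y0", value=y0)

    def model(pars, t):
        return pars["A1"].value * np.exp(-t / pars["t1"].value) + pars["y0"].value

    return _run_fit(trace, params, model, "monoexponential")


def fit_species_weighted_biexponential(
    trace: FluorescenceTrace,
    weights: tuple[float, float],
    t1_fixed: float,
) -> ExpFitResult:
    """Fixed-weight bi-exponential fit with the fast time constant held fixed.

    ``weights`` are the (unmodified, modified) dimer fractions and must sum
    to 1; ``t1_fixed`` is the unmodified protein's time constant (s).  Free
    parameters are the shared amplitude A1, the modified-species time
    constant t2 and the offset y0.
    """
    w1, w2 = weights
    if not np.isclose(w1 + w2, 1.0):
        raise ValueError(f"weights must sum to 1, got {w1 + w2}")
    if w2 == 0:
        raise ValueError("modified-species weight is 0; use fit_monoexponential instead")
    if t1_fixed <= 0:
        raise ValueError("t1_fixed must be positive")

    a1, t_guess, y0 = _initial_guess(trace)
    params = Parameters()
    params.add("A1", value=a1 if a1 != 0 else 1e-12)
    params.add("t1", value=t1_fixed, vary=False)
    params.add("t2", value=max(t_guess, 2.0 * t1_fixed), min=np.finfo(float).tiny)
    params.add("y0", value=y0)
    params.add("w1", value=w1, vary=False)
    params.add("w2", value=w2, vary=False)

    def model(pars, t):
        return (
            pars["w1"].value * pars["A1"].value * np.exp(-t / pars["t1"].value)
            + pars["w2"].value * pars["A1"].value * np.exp(-t / pars["t2"].value)
            + pars["y0"].value
        )

    return _run_fit(
        trace, params, model, "species_weighted_biexponential",
        fixed=frozenset({"t1", "w1", "w2"}),
    )


def fit_chase_dissociation(trace: FluorescenceTrace) -> ExpFitResult:
    """Fit a chase (subunit-exchange) trace: mono-exponential decay toward
    the exchanged-complex baseline.  A flat trace (no dissociation, as for
    the unmodified protein under a non-hydrolyzable nucleotide) yields a
    negligible amplitude flag."""
    result = fit_monoexponential(trace)
    result.model = "chase_dissociation"
    return result
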