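"""Time-derivative (dc/dt) analysis of sedimentation-velocity data.

Closely spaced radial scans from a sedimentation-velocity run are
differenced pairwise; each radius is mapped to an apparent sedimentation
coefficient

    s* = ln(r / r_meniscus) / (omega^2 * t)

with t the mean time of the scan pair, giving a dc/dt profile on the s*
scale (Svedberg, 1 S = 1e-13 s).  Boundary positions appear as peaks;
complex formation shifts the dominant peak to larger s*.  Peaks are
quantified by a sum-of-Gaussians least-squares fit.

Per-scan baselines are estimated from the outermost radii (default 5 %)
and subtracted before differencing; profiles from multiple scan pairs are
averaged on a common linearly interpolated s* grid.  Radial dilution is
not corrected (fluorescence data, comparative use).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from lmfit import Parameters, minimize
from scipy.signal import find_peaks

SVEDBERG = 1e-13  # s


class AmbiguousPeakError(ValueError):
    """No dominant peak could be identified by the amplitude criterion."""


@dataclass
class RotorParams:
    """Rotor speed and meniscus position; omega derives from rpm."""

    rpm: float
    meniscus_radius: float  # cm

    @property
    def omega(self) -> float:
        """Angular velocity in rad/s."""
        return 2.0 * np.pi * self.rpm / 60.0


@dataclass
class RadialScan:
    """One radial concentration scan at a given time since speed was reached."""

    time: float  # s
    radii: np.ndarray  # cm, strictly increasing
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.radii.shape != self.signal.shape:
            raise ValueError("radii and signal must have equal length")
        if np.any(np.diff(self.radii) <= 0):
            raise ValueError("radii must be strictly increasing")


@dataclass
class DcdtProfile:
    """dc/dt (signal per second) on the apparent-s scale (Svedberg)."""

    s_star: np.ndarray  # S
    dcdt: np.ndarray

    def __post_init__(self) -> None:
        self.s_star = np.asarray(self.s_star, dtype=float)
        self.dcdt = np.asarray(self.dcdt, dtype=float)
        if np.any(np.diff(self.s_star) <= 0):
            raise ValueError("s_star must be strictly increasing")


@dataclass
class GaussianPeak:
    """One fitted Gaussian component, sorted by center."""

    center_s: float  # S
    width_s: float  # S (Gaussian sigma)
    amplitude: float  # peak height
    center_stderr: Optional[float] = None


def _baseline(scan: RadialScan, fraction: float) -> float:
    n = max(int(round(fraction * len(scan.radii))), 1)
    return float(np.mean(scan.signal[-n:]))


def compute_dcdt(
    scans: Sequence[RadialScan],
    rotor: RotorParams,
    baseline_fraction: float = 0.05,
    n_grid: int = 200,
) -> DcdtProfile:
    """dc/dt profile from consecutive scan pairs on a common s* grid.

    Every pair of consecutive scans must share a radial grid and have
    distinct times; the meniscus must lie inside all radii.  The per-pair
    profiles are averaged after linear interpolation onto ``n_grid``
    points spanning their common s* range.
    """
    if len(scans) < 2:
        raise ValueError("at least two scans are required")
    omega2 = rotor.omega**2
    pair_profiles: list[tuple[np.ndarray, np.ndarray]] = []
    for first, second in zip(scans, scans[1:]):
        if not np.array_equal(first.radii, second.radii):
            raise ValueError(
                f"scans at t={first.time} s and t={second.time} s have mismatched radial grids"
            )
        dt = second.time - first.time
        if dt == 0:
            raise ValueError(f"zero time difference between scans at t={first.time} s")
        if rotor.meniscus_radius >= first.radii[0]:
            raise ValueError("meniscus must lie below the smallest scan radius")
        # Sign convention: the solvent region behind the moving boundary is
        # depleted, so c falls with time at a fixed radius; -dc/dt makes the
        # boundary appear as a positive peak, the standard presentation.
        dcdt = -(
            (second.signal - _baseline(second, baseline_fraction))
            - (first.signal - _baseline(first, baseline_fraction))
        ) / dt
        t_mean = 0.5 * (first.time + second.time)
        s_star = np.log(first.radii / rotor.meniscus_radius) / (omega2 * t_mean) / SVEDBERG
        pair_profiles.append((s_star, dcdt))

    lo = max(p[0][0] for p in pair_profiles)
    hi = min(p[0][-1] for p in pair_profiles)
    grid = np.linspace(lo, hi, n_grid)
    stacked = np.array([np.interp(grid, s, v) for s, v in pair_profiles])
    return DcdtProfile(s_star=grid, dcdt=stacked.mean(axis=0))


def _sum_of_gaussians(pars: Parameters, s: np.ndarray, n_peaks: int) -> np.ndarray:
    out = np.zeros_like(s)
    for i in range(n_peaks):
        a = pars[f"a{i}"].value
        c = pars[f"c{i}"].value
        w = pars[f"w{i}"].value
        out += a * np.exp(-0.5 * ((s - c) / w) ** 2)
    return out


def fit_gaussian_peaks(profile: DcdtProfile, n_peaks: int = 1) -> list[GaussianPeak]:
    """Sum-of-Gaussians least-squares fit; peaks returned sorted by center.

    Initial centers come from the ``n_peaks`` most prominent local maxima
    (falling back to evenly spaced positions when the profile has fewer).
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    s = profile.s_star
    y = profile.dcdt
    span = s[-1] - s[0]
    if span <= 0 or np.allclose(y, y[0]):
        raise ValueError("degenerate profile: no structure to fit")

    idx, props = find_peaks(y, prominence=0.05 * np.ptp(y))
    order = np.argsort(props["prominences"])[::-1] if len(idx) else np.array([], dtype=int)
    centers = list(s[idx[order][:n_peaks]])
    while len(centers) < n_peaks:
        centers.append(s[0] + span * (len(centers) + 1) / (n_peaks + 1))
    centers.sort()

    params = Parameters()
    for i, c in enumerate(centers):
        nearest = np.argmin(np.abs(s - c))
        params.add(f"a{i}", value=max(float(y[nearest]), 1e-3 * float(np.ptp(y))), min=0)
        params.add(f"c{i}", value=float(c), min=float(s[0]), max=float(s[-1]))
        params.add(f"w{i}", value=span / (6.0 * n_peaks), min=span / len(s), max=span)

    def residual(pars):
        return _sum_of_gaussians(pars, s, n_peaks) - y

    out = minimize(residual, params, method="leastsq", xtol=1e-12, ftol=1e-12)
    if not out.success:
        raise RuntimeError(f"Gaussian peak fit failed: {out.message}")
    peaks = [
        GaussianPeak(
            center_s=float(out.params[f"c{i}"].value),
            width_s=float(out.params[f"w{i}"].value),
            amplitude=float(out.params[f"a{i}"].value),
            center_stderr=(
                float(out.params[f"c{i}"].stderr)
                if out.params[f"c{i}"].stderr is not None
                else None
            ),
        )
        for i in range(n_peaks)
    ]
    peaks.sort(key=lambda p: p.center_s)
    return peaks


def dominant_peak(peaks: Sequence[GaussianPeak], min_dominance: float = 1.001) -> GaussianPeak:
    """The largest-amplitude peak; ambiguous when the runner-up is within
    the dominance ratio."""
    if not peaks:
        raise AmbiguousPeakError("no peaks fitted")
    ordered = sorted(peaks, key=lambda p: p.amplitude, reverse=True)
    if len(ordered) > 1 and ordered[0].amplitude < min_dominance * ordered[1].amplitude:
        raise AmbiguousPeakError(
            f"top two peak amplitudes are indistinguishable "
            f"({ordered[0].amplitude:.4g} vs {ordered[1].amplitude:.4g})"
        )
    return ordered[0]


def detect_complex_shift(
    profile_free: DcdtProfile,
    profile_mixture: DcdtProfile,
    n_peaks_free: int = 1,
    n_peaks_mixture: int = 1,
) -> float:
    """Shift (S) of the dominant sedimenting species upon complex formation:
    mixture dominant-peak center minus free-species dominant-peak center."""
    free = dominant_peak(fit_gaussian_peaks(profile_free, n_peaks_free))
    mixture = dominant_peak(fit_gaussian_peaks(profile_mixture, n_peaks_mixture))
    return mixture.center_s - free.center_s
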