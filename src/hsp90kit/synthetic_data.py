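"""Seeded generators for every input format the analysis stages consume.

Each generator evaluates the exact forward model of the corresponding
analysis stage and adds i.i.d. Gaussian noise, returning the ground truth
alongside the data so round-trip tests never re-derive targets from noisy
fits alone.  All generators are pure functions of (parameters, seed).

Defaults are chosen to match the study conditions of the assays they
emulate: a two-state ion-pair switching around the 5 Å open/closed
threshold, Eq.-style weighted bi-exponential closing traces with the
0.49/0.51 species weights of 30 % incorporation, a 16 nM–2 µM SEC
dilution series, 42,000 rpm sedimentation boundaries at 3 S (free) and
8 S (complex), and linear NADH-depletion curves with an
inhibitor-defined background phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import erf

from hsp90kit.atpase_rates import EPSILON_NADH_340, ProgressCurve
from hsp90kit.auc_dcdt import RadialScan, RotorParams, SVEDBERG
from hsp90kit.kinetics_fret import FluorescenceTrace
from hsp90kit.md_conformation import DistanceSeries
from hsp90kit.sec_dimerization import ElutionSeries, elution_isotherm
from hsp90kit.structure_io import AtomRecord, StructureModel, Trajectory


@dataclass
class TwoStateParams:
    """Markov two-state ion-pair model: closed/open means with Gaussian
    noise and per-step switching probabilities."""

    mean_closed: float = 3.5  # Å
    mean_open: float = 8.0  # Å
    sigma: float = 0.4  # Å
    p_close_to_open: float = 0.05
    p_open_to_close: float = 0.05
    n_steps: int = 2000
    dt: float = 0.1  # ns
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.mean_closed < self.mean_open):
            raise ValueError("means must be positive with mean_open > mean_closed")
        for p in (self.p_close_to_open, self.p_open_to_close):
            if not 0.0 <= p <= 1.0:
                raise ValueError("transition probabilities must be in [0, 1]")

    @property
    def stationary_closed_fraction(self) -> float:
        """Analytic stationary probability of the closed state."""
        denom = self.p_close_to_open + self.p_open_to_close
        if denom == 0:
            return 0.5
        return self.p_open_to_close / denom


@dataclass
class BoundaryParams:
    """A sedimenting error-function boundary for synthetic radial scans."""

    s: float = 3.0  # Svedberg
    c_plateau: float = 1.0
    # Boundary spread grows as sqrt(2 D t); 9e-4 cm/sqrt(s) corresponds to
    # D ~ 4e-7 cm^2/s, typical for a ~100 kDa protein.
    diffusion_width: float = 9e-4  # cm per sqrt(s)
    # Scans taken once the boundary has cleared the meniscus region, as in
    # practice; early scans make the diffusive spreading term distort the
    # apparent-s peak.
    scan_times: Sequence[float] = (9000.0, 9120.0, 9240.0, 9360.0, 9480.0, 9600.0)  # s
    rotor: RotorParams = field(
        default_factory=lambda: RotorParams(rpm=42000.0, meniscus_radius=6.0)
    )
    radii: Optional[np.ndarray] = None  # cm; default 6.05..7.25, 400 points
    noise_sigma: float = 0.0
    seed: int = 0
    # "sqrt": width grows as diffusion_width * sqrt(t) (diffusive spreading);
    # "constant": width fixed at diffusion_width (non-diffusing boundary).
    width_law: str = "sqrt"

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError("sedimentation coefficient must be non-negative")
        if self.radii is None:
            self.radii = np.linspace(6.05, 7.25, 400)


def gen_two_state_distance_series(params: TwoStateParams) -> tuple[DistanceSeries, np.ndarray]:
    """Simulate the two-state ion-pair distance series.

    Returns the series and the hidden state sequence (0 = closed,
    1 = open).  The initial state is drawn from the stationary
    distribution so the empirical occupancy is unbiased at any length.
    """
    rng = np.random.default_rng(params.seed)
    states = np.empty(params.n_steps, dtype=int)
    p_closed = params.stationary_closed_fraction
    state = 0 if rng.random() < p_closed else 1
    switch = rng.random(params.n_steps)
    for i in range(params.n_steps):
        states[i] = state
        p_flip = params.p_close_to_open if state == 0 else params.p_open_to_close
        if switch[i] < p_flip:
            state = 1 - state
    means = np.where(states == 0, params.mean_closed, params.mean_open)
    values = means + params.sigma * rng.standard_normal(params.n_steps)
    values = np.clip(values, 0.0, None)
    times = np.arange(params.n_steps) * params.dt
    return DistanceSeries(times=times, values=values, label="two-state ion pair"), states


# Template residues of the toy ion-pair fixture: a Glu/Arg pair per chain,
# mirroring the Glu-590/Arg-591 (Cδ-Cζ) convention, plus rigid bystanders.
_TOY_RESIDUES = (
    ("GLU", 590, (("CA", "C"), ("CD", "C"), ("OE1", "O"), ("OE2", "O"))),
    ("ARG", 591, (("CA", "C"), ("CZ", "C"), ("NH1", "N"), ("NH2", "N"))),
)


def gen_toy_trajectory(
    distances_a: np.ndarray,
    distances_b: Optional[np.ndarray] = None,
    dt: float = 0.1,
) -> Trajectory:
    """Build a toy two-chain trajectory whose designated ion-pair atoms
    realise the prescribed distances exactly.

    Chain A's Glu-590 Cδ and Arg-591 Cζ are placed ``distances_a[i]``
    apart in frame ``i`` (chain B likewise for ``distances_b``, defaulting
    to chain A's values); all other atoms are rigid.
    """
    distances_a = np.asarray(distances_a, dtype=float)
    distances_b = (
        distances_a if distances_b is None else np.asarray(distances_b, dtype=float)
    )
    if distances_a.shape != distances_b.shape:
        raise ValueError("both distance series must have equal length")

    frames: list[StructureModel] = []
    for i, (da, db) in enumerate(zip(distances_a, distances_b)):
        atoms: list[AtomRecord] = []
        serial = 1
        for chain, offset, dist in (("A", 0.0, da), ("B", 50.0, db)):
            for resname, resnum, atom_defs in _TOY_RESIDUES:
                for atom_name, element in atom_defs:
                    # The moving pair lies on the x axis; bystanders are rigid.
                    if resname == "GLU" and atom_name == "CD":
                        pos = np.array([offset, 0.0, 0.0])
                    elif resname == "ARG" and atom_name == "CZ":
                        pos = np.array([offset + dist, 0.0, 0.0])
                    else:
                        pos = np.array(
                            [offset + 2.0 * resnum % 7, float(serial % 5), 3.0]
                        )
                    atoms.append(
                        AtomRecord(
                            serial=serial,
                            atom_name=atom_name,
                            residue_name=resname,
                            chain_id=chain,
                            residue_number=resnum,
                            coordinates=pos,
                            element=element,
                        )
                    )
                    serial += 1
        frames.append(StructureModel(atoms=atoms, model_index=i + 1))
    times = np.arange(len(frames)) * dt
    return Trajectory(frames=frames, frame_times=times)


def gen_salt_bridge_model(
    n_bridged: int,
    n_acidic: int = 5,
    n_basic: int = 5,
    cutoff: float = 4.0,
    seed: int = 0,
) -> StructureModel:
    """A model with ``n_bridged`` acidic/basic residue pairs placed inside
    the cutoff between chain A (acidic) and chain B (basic), the rest far
    apart.  For use with a chain-A vs chain-B salt-bridge count."""
    if n_bridged > min(n_acidic, n_basic):
        raise ValueError("n_bridged cannot exceed the smaller group size")
    rng = np.random.default_rng(seed)
    atoms: list[AtomRecord] = []
    serial = 1

    def add(chain, resname, resnum, atom_name, element, pos):
        nonlocal serial
        atoms.append(
            AtomRecord(
                serial=serial, atom_name=atom_name, residue_name=resname,
                chain_id=chain, residue_number=resnum,
                coordinates=np.asarray(pos, dtype=float), element=element,
            )
        )
        serial += 1

    for i in range(n_acidic):
        base = np.array([20.0 * i, 0.0, 0.0])
        add("A", "GLU", i + 1, "OE1", "O", base)
        add("A", "GLU", i + 1, "OE2", "O", base + [0.5, 0.5, 0.0])
    for j in range(n_basic):
        if j < n_bridged:
            # Within cutoff of acidic residue j's OE1.
            pos = np.array([20.0 * j, 0.0, 0.0]) + [0.0, 0.0, 0.5 * cutoff]
        else:
            pos = np.array([20.0 * j, 500.0, 0.0]) + rng.normal(0, 1, 3)
        add("B", "LYS", j + 1, "NZ", "N", pos)
    return StructureModel(atoms=atoms, model_index=1)


def gen_fret_trace(
    A1: float = 1.0,
    t1: float = 60.0,
    y0: float = 0.2,
    t2: Optional[float] = None,
    weights: tuple[float, float] = (1.0, 0.0),
    times: Optional[np.ndarray] = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[FluorescenceTrace, dict]:
    """Mono- or weighted bi-exponential fluorescence trace plus ground truth.

    With ``weights = (1, 0)`` (default) the trace is mono-exponential;
    otherwise ``t2`` must be given and the trace is the fixed-weight
    two-species mixture.
    """
    if times is None:
        times = np.linspace(0.0, 10.0 * t1, 400)
    times = np.asarray(times, dtype=float)
    w1, w2 = weights
    if w2 != 0 and t2 is None:
        raise ValueError("t2 is required when the modified-species weight is nonzero")
    signal = w1 * A1 * np.exp(-times / t1) + y0
    if w2 != 0:
        signal = signal + w2 * A1 * np.exp(-times / t2)
    rng = np.random.default_rng(seed)
    noisy = signal + noise_sigma * rng.standard_normal(times.shape)
    truth = {"A1": A1, "t1": t1, "t2": t2, "y0": y0, "weights": weights,
             "noise_sigma": noise_sigma}
    return FluorescenceTrace(times=times, signal=noisy), truth


def gen_sec_series(
    kd_app: float = 180.0,  # nM
    et_mono: float = 28.0,  # min
    et_dimer: float = 25.0,  # min
    concentrations: Optional[np.ndarray] = None,  # nM
    noise_frac: float = 0.0,  # fraction of elution time
    observed_peak_width: float = 1.6,  # min
    injection_volume: float = 0.2,  # mL
    flow_rate: float = 0.5,  # mL/min
    seed: int = 0,
) -> tuple[ElutionSeries, dict]:
    """Monomer–dimer SEC dilution series from the elution-time isotherm.

    The default concentration grid spans 16 nM–2 µM (12 log-spaced
    points); noise is Gaussian with standard deviation ``noise_frac``
    times the elution time.
    """
    if concentrations is None:
        concentrations = np.geomspace(16.0, 2000.0, 12)
    concentrations = np.asarray(concentrations, dtype=float)
    et = elution_isotherm(concentrations, et_mono, et_dimer, kd_app)
    rng = np.random.default_rng(seed)
    noisy = et + noise_frac * et * rng.standard_normal(et.shape)
    series = ElutionSeries(
        concentrations=concentrations,
        elution_times=noisy,
        observed_peak_width=observed_peak_width,
        injection_volume=injection_volume,
        flow_rate=flow_rate,
    )
    truth = {"KD_app": kd_app, "ET_mono": et_mono, "ET_dimer": et_dimer,
             "noise_frac": noise_frac}
    return series, truth


def gen_atpase_curve(
    k_turnover: float = 0.5,  # min^-1 per protomer
    enzyme_conc: float = 3.0,  # µM (yeast assay condition)
    background_slope: float = 0.0,  # AU/min (negative = residual depletion)
    a340_start: float = 1.0,
    duration: float = 40.0,  # min
    inhibitor_time: Optional[float] = 30.0,  # min; None = no background phase
    n_points: int = 400,
    epsilon: float = EPSILON_NADH_340,
    path_length: float = 1.0,
    noise_sigma: float = 0.0,  # AU
    seed: int = 0,
) -> tuple[ProgressCurve, dict]:
    """Linear NADH-depletion progress curve with an inhibitor-defined
    background phase after ``inhibitor_time``.

    Before the inhibitor both the enzymatic slope and the background slope
    act; afterwards only the background remains, so the two windows allow
    the standard subtraction.
    """
    times = np.linspace(0.0, duration, n_points)
    enzymatic_slope = -k_turnover * enzyme_conc * epsilon * path_length * 1e-6  # AU/min
    slopes = np.full_like(times, enzymatic_slope + background_slope)
    if inhibitor_time is not None:
        slopes[times >= inhibitor_time] = background_slope
    dt = np.diff(times, prepend=0.0)
    absorbance = a340_start + np.cumsum(slopes * dt) - slopes[0] * times[0]
    rng = np.random.default_rng(seed)
    noisy = absorbance + noise_sigma * rng.standard_normal(times.shape)
    curve = ProgressCurve(
        times=times, absorbance=noisy, enzyme_conc=enzyme_conc, path_length=path_length
    )
    truth = {
        "k_turnover": k_turnover,
        "enzymatic_slope": enzymatic_slope,
        "background_slope": background_slope,
        "inhibitor_time": inhibitor_time,
        "rate_window": (0.0, inhibitor_time if inhibitor_time is not None else duration),
        "background_window": (
            (inhibitor_time, duration) if inhibitor_time is not None else None
        ),
    }
    return curve, truth


def gen_auc_scans(
    params: BoundaryParams,
    extra_species: Sequence[tuple[float, float]] = (),
) -> list[RadialScan]:
    """Radial scans of one or more sedimenting error-function boundaries.

    The boundary midpoint follows ``r_b(t) = r_meniscus exp(s omega^2 t)``
    and its width grows as ``diffusion_width * sqrt(t)``.  ``extra_species``
    adds further (s_svedberg, plateau) components, e.g. a complex at 8 S
    next to a free species at 3 S.
    """
    rng = np.random.default_rng(params.seed)
    omega2 = params.rotor.omega**2
    r = np.asarray(params.radii, dtype=float)
    species = [(params.s, params.c_plateau), *extra_species]
    scans: list[RadialScan] = []
    for t in params.scan_times:
        signal = np.zeros_like(r)
        if params.width_law == "constant":
            width = max(params.diffusion_width, 1e-6)
        else:
            width = max(params.diffusion_width * np.sqrt(t), 1e-6)
        for s_i, plateau in species:
            r_boundary = params.rotor.meniscus_radius * np.exp(s_i * SVEDBERG * omega2 * t)
            signal = signal + 0.5 * plateau * (1.0 + erf((r - r_boundary) / (np.sqrt(2) * width)))
        signal = signal + params.noise_sigma * rng.standard_normal(r.shape)
        scans.append(RadialScan(time=float(t), radii=r.copy(), signal=signal))
    return scans
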