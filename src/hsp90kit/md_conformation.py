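"""Conformational observables over structure trajectories.

Implements the per-frame geometric series used to characterise the
C-terminal dimerization interface of the Hsp90 dimer: ion-pair distances
with open/closed occupancy statistics (5 Å convention: closed strictly
below threshold), inter-domain salt-bridge counts, helix-pair
centre-of-mass distances, and Kabsch-superposed backbone RMSD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from hsp90kit.structure_io import (
    AtomRecord,
    SelectionSpec,
    StructureModel,
    Trajectory,
    center_of_mass,
    kabsch_superpose,
    select_atoms,
)

#: Charged side-chain heavy atoms used in the salt-bridge criterion.
ACIDIC_ATOMS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}
BASIC_ATOMS: dict[str, tuple[str, ...]] = {
    "LYS": ("NZ",),
    "ARG": ("NH1", "NH2", "NE"),
    # Mono-methyl-lysine keeps a charged NZ; treated as lysine-equivalent.
    "MLZ": ("NZ",),
}
HISTIDINE_ATOMS: tuple[str, ...] = ("ND1", "NE2")

#: Conventional ion-pair reference atoms per residue type (e.g. Glu Cδ, Arg Cζ).
ION_PAIR_REFERENCE_ATOMS: dict[str, str] = {
    "GLU": "CD",
    "ASP": "CG",
    "ARG": "CZ",
    "LYS": "NZ",
    "MLZ": "NZ",
}

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})


class MissingAtomError(KeyError):
    """An atom required by an observable is absent from some frame."""


@dataclass(frozen=True)
class IonPairDefinition:
    """Two named atoms, one per residue, whose distance defines an ion pair."""

    chain_a: str
    resnum_a: int
    atom_a: str
    chain_b: str
    resnum_b: int
    atom_b: str
    label: str = ""


@dataclass
class DistanceSeries:
    """A per-frame scalar observable (Å) with its time axis (ns)."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if np.any(self.values < 0):
            raise ValueError("distance values must be non-negative")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class OccupancyResult:
    """Open/closed statistics of a distance series at a threshold."""

    threshold: float  # Å
    fraction_closed: float
    fraction_open: float
    n_transitions: int
    histogram_edges: np.ndarray  # Å, len = n_bins + 1
    histogram_percent: np.ndarray  # occurrence %, sums to 100


@dataclass
class SaltBridgeSeries:
    """Per-frame inter-group salt-bridge counts."""

    times: np.ndarray
    counts: np.ndarray  # non-negative integers
    cutoff: float  # Å
    label: str = ""


@dataclass
class HelixPairSeries:
    """Named helix-pair centre-of-mass distance series."""

    pairs: dict[str, DistanceSeries] = field(default_factory=dict)


def ion_pair_distance_series(traj: Trajectory, pairdef: IonPairDefinition) -> DistanceSeries:
    """Per-frame Euclidean distance between the two atoms of ``pairdef``."""
    values = np.empty(len(traj))
    for i, frame in enumerate(traj.frames):
        try:
            atom_a = frame.find_atom(pairdef.chain_a, pairdef.resnum_a, pairdef.atom_a)
        except KeyError as exc:
            raise MissingAtomError(
                f"frame {i}: atom {pairdef.atom_a} of "
                f"{pairdef.chain_a}:{pairdef.resnum_a} not found"
            ) from exc
        try:
            atom_b = frame.find_atom(pairdef.chain_b, pairdef.resnum_b, pairdef.atom_b)
        except KeyError as exc:
            raise MissingAtomError(
                f"frame {i}: atom {pairdef.atom_b} of "
                f"{pairdef.chain_b}:{pairdef.resnum_b} not found"
            ) from exc
        values[i] = np.linalg.norm(atom_a.coordinates - atom_b.coordinates)
    label = pairdef.label or (
        f"{pairdef.chain_a}:{pairdef.resnum_a}:{pairdef.atom_a}-"
        f"{pairdef.chain_b}:{pairdef.resnum_b}:{pairdef.atom_b}"
    )
    return DistanceSeries(times=traj.frame_times, values=values, label=label)


def classify_open_closed(
    series: DistanceSeries,
    threshold: float = 5.0,
    bin_width: float = 0.25,
) -> OccupancyResult:
    """Open/closed occupancy of an ion-pair distance series.

    Closed means strictly ``r < threshold``; a frame exactly at the
    threshold counts as open.  ``n_transitions`` counts state changes
    between consecutive frames; the histogram reports occurrence in
    percent over ``bin_width``-Å bins and sums to 100.
    """
    if len(series) == 0:
        raise ValueError("cannot classify an empty series")
    closed = series.values < threshold
    fraction_closed = float(np.mean(closed))
    n_transitions = int(np.sum(closed[1:] != closed[:-1]))
    lo = np.floor(series.values.min() / bin_width) * bin_width
    hi = np.ceil(series.values.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(series.values, bins=edges)
    percent = 100.0 * counts / counts.sum()
    return OccupancyResult(
        threshold=threshold,
        fraction_closed=fraction_closed,
        fraction_open=1.0 - fraction_closed,
        n_transitions=n_transitions,
        histogram_edges=edges,
        histogram_percent=percent,
    )


def _charged_atoms_by_residue(
    atoms: Sequence[AtomRecord],
    charge: str,
    include_his: bool,
) -> dict[tuple[str, int], np.ndarray]:
    """Map (chain, resnum) -> charged heavy-atom coordinates of one polarity."""
    table = dict(ACIDIC_ATOMS) if charge == "acidic" else dict(BASIC_ATOMS)
    if include_his and charge == "basic":
        table["HIS"] = HISTIDINE_ATOMS
    out: dict[tuple[str, int], list[np.ndarray]] = {}
    for atom in atoms:
        names = table.get(atom.residue_name)
        if names and atom.atom_name in names:
            out.setdefault((atom.chain_id, atom.residue_number), []).append(atom.coordinates)
    return {k: np.array(v) for k, v in out.items()}


def count_interdomain_salt_bridges(
    frame: StructureModel,
    group_a: SelectionSpec,
    group_b: SelectionSpec,
    cutoff: float = 4.0,
    include_his: bool = False,
) -> int:
    """Number of salt bridges between two atom groups in one frame.

    A bridge is an (acidic residue of one group, basic residue of the
    other) pair whose minimum charged heavy-atom distance is below
    ``cutoff`` (Å); each residue pair is counted once regardless of how
    many atom contacts it makes.
    """
    atoms_a = select_atoms(frame, group_a)
    atoms_b = select_atoms(frame, group_b)
    if not atoms_a or not atoms_b:
        warnings.warn("empty selection in salt-bridge count", stacklevel=2)
        return 0
    count = 0
    for acid_side, base_side in ((atoms_a, atoms_b), (atoms_b, atoms_a)):
        acids = _charged_atoms_by_residue(acid_side, "acidic", include_his)
        bases = _charged_atoms_by_residue(base_side, "basic", include_his)
        for acid_coords in acids.values():
            for base_coords in bases.values():
                d = np.linalg.norm(
                    acid_coords[:, None, :] - base_coords[None, :, :], axis=-1
                )
                if d.min() < cutoff:
                    count += 1
    return count


def salt_bridge_series(
    traj: Trajectory,
    group_a: SelectionSpec,
    group_b: SelectionSpec,
    cutoff: float = 4.0,
    include_his: bool = False,
    label: str = "",
) -> SaltBridgeSeries:
    """Per-frame inter-group salt-bridge counts over a trajectory."""
    counts = np.array(
        [
            count_interdomain_salt_bridges(f, group_a, group_b, cutoff, include_his)
            for f in traj.frames
        ],
        dtype=int,
    )
    return SaltBridgeSeries(times=traj.frame_times, counts=counts, cutoff=cutoff, label=label)


def com_distance(
    frame: StructureModel,
    spec_a: SelectionSpec,
    spec_b: SelectionSpec,
    mass_table: Optional[dict[str, float]] = None,
) -> float:
    """Distance (Å) between the centres of mass of two selections."""
    atoms_a = select_atoms(frame, spec_a)
    atoms_b = select_atoms(frame, spec_b)
    if not atoms_a or not atoms_b:
        raise ValueError("com_distance requires non-empty selections on both sides")
    return float(
        np.linalg.norm(
            center_of_mass(atoms_a, mass_table) - center_of_mass(atoms_b, mass_table)
        )
    )


def helix_pair_com_distances(
    traj: Trajectory,
    helix_pairs: dict[str, tuple[SelectionSpec, SelectionSpec]],
    mass_table: Optional[dict[str, float]] = None,
) -> HelixPairSeries:
    """Per-frame COM distances for named helix pairs (e.g. the three
    C-terminal interface helix pairs of the two protomers)."""
    result = HelixPairSeries()
    for name, (spec_a, spec_b) in helix_pairs.items():
        values = np.array(
            [com_distance(frame, spec_a, spec_b, mass_table) for frame in traj.frames]
        )
        result.pairs[name] = DistanceSeries(times=traj.frame_times, values=values, label=name)
    return result


def backbone_rmsd_series(
    traj: Trajectory,
    reference_frame: int = 0,
    atom_names: frozenset[str] = BACKBONE_ATOMS,
) -> DistanceSeries:
    """Per-frame Kabsch-superposed backbone RMSD to a reference frame.

    The default selection is the full backbone (N, CA, C, O); pass
    ``atom_names={"CA"}`` for a Cα-only convention.
    """
    spec = SelectionSpec(atom_names=atom_names)
    ref_atoms = select_atoms(traj.frames[reference_frame], spec)
    if len(ref_atoms) < 3:
        raise ValueError("backbone selection must contain at least 3 atoms")
    ref_coords = np.array([a.coordinates for a in ref_atoms])
    values = np.empty(len(traj))
    for i, frame in enumerate(traj.frames):
        coords = np.array([a.coordinates for a in select_atoms(frame, spec)])
        _, _, rmsd = kabsch_superpose(coords, ref_coords)
        values[i] = rmsd
    return DistanceSeries(times=traj.frame_times, values=values, label="backbone RMSD")
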