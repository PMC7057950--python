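"""Reading, writing and basic geometry of protein structure models.

Structures are handled as ordered lists of :class:`AtomRecord`; a
multi-model PDB file becomes a list of :class:`StructureModel`, and a
fixed atom set observed over time becomes a :class:`Trajectory`.  Parsing
is delegated to Bio.PDB in strict mode (its default alternate-location
resolution keeps the highest-occupancy conformer, first on ties); the
writer emits standard fixed-column multi-model PDB so synthetic
trajectories round-trip through the same reader.

All coordinates are in Ångström; residue numbering is 1-based as in the
source file.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio.Data.IUPACData import atom_weights
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException, PDBConstructionWarning


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be parsed (message names the line)."""


class EmptyStructureError(ValueError):
    """Raised when a structure file contains no atoms."""


class UnknownElementError(KeyError):
    """Raised when an element symbol has no entry in the mass table."""


#: Standard atomic weights keyed by element symbol ("C", "N", "Fe", ...).
ATOMIC_MASSES: dict[str, float] = {
    symbol: weight for symbol, weight in atom_weights.items()
}


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a structure model.

    ``icode`` carries the PDB insertion code (empty for the common case);
    it participates in the identity key alongside the residue number.
    """

    serial: int
    atom_name: str
    residue_name: str
    chain_id: str
    residue_number: int
    coordinates: np.ndarray  # shape (3,), Å
    element: str
    icode: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"atom {self.serial}: coordinates must be a finite 3-vector")
        object.__setattr__(self, "coordinates", coords)
        if self.serial <= 0 or self.residue_number <= 0:
            raise ValueError(
                f"atom {self.atom_name}: serial and residue_number must be positive"
            )

    @property
    def key(self) -> tuple[str, str, str, str]:
        """Identity triple (chain, residue number + insertion code, atom name)."""
        return (self.chain_id, f"{self.residue_number}{self.icode}", self.atom_name,
                self.residue_name)


@dataclass
class StructureModel:
    """An ordered atom list forming one model (one trajectory frame)."""

    atoms: list[AtomRecord]
    model_index: int = 0

    def __post_init__(self) -> None:
        keys = [a.key[:3] for a in self.atoms]
        if len(set(keys)) != len(keys):
            seen: set = set()
            for k in keys:
                if k in seen:
                    raise ValueError(f"duplicate atom identity {k} in model {self.model_index}")
                seen.add(k)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coordinates(self) -> np.ndarray:
        """(N, 3) coordinate array in file order."""
        return np.array([a.coordinates for a in self.atoms], dtype=float)

    def atom_keys(self) -> list[tuple[str, str, str, str]]:
        return [a.key for a in self.atoms]

    def find_atom(self, chain_id: str, residue_number: int, atom_name: str) -> AtomRecord:
        """Return the unique atom with the given identity or raise KeyError."""
        for a in self.atoms:
            if (a.chain_id == chain_id and a.residue_number == residue_number
                    and a.atom_name == atom_name):
                return a
        raise KeyError(f"atom {atom_name} of residue {chain_id}:{residue_number} not found")


@dataclass
class Trajectory:
    """Ordered frames over one fixed atom set, with times in nanoseconds."""

    frames: list[StructureModel]
    frame_times: np.ndarray  # ns

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if len(self.frames) != len(self.frame_times):
            raise ValueError("frames and frame_times must have equal length")
        if len(self.frames) == 0:
            raise ValueError("trajectory must contain at least one frame")
        if len(self.frame_times) > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise ValueError("frame_times must be strictly increasing")
        ref_keys = self.frames[0].atom_keys()
        for frame in self.frames[1:]:
            if frame.atom_keys() != ref_keys:
                raise ValueError(
                    f"frame {frame.model_index} atom identities differ from frame "
                    f"{self.frames[0].model_index}"
                )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return len(self.frames[0])

    def coordinate_array(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) stacked coordinates."""
        return np.array([f.coordinates for f in self.frames])


@dataclass(frozen=True)
class SelectionSpec:
    """Conjunctive atom selection criteria; absent criteria match everything."""

    chain_id: Optional[str] = None
    residue_range: Optional[tuple[int, int]] = None  # inclusive [lo, hi]
    atom_names: Optional[frozenset[str]] = None
    residue_names: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        if self.residue_range is not None:
            lo, hi = self.residue_range
            if lo > hi:
                raise ValueError(f"residue_range lo {lo} > hi {hi}")
        for attr in ("atom_names", "residue_names"):
            value = getattr(self, attr)
            if value is not None and not isinstance(value, frozenset):
                object.__setattr__(self, attr, frozenset(value))

    def matches(self, atom: AtomRecord) -> bool:
        if self.chain_id is not None and atom.chain_id != self.chain_id:
            return False
        if self.residue_range is not None:
            lo, hi = self.residue_range
            if not (lo <= atom.residue_number <= hi):
                return False
        if self.atom_names is not None and atom.atom_name not in self.atom_names:
            return False
        if self.residue_names is not None and atom.residue_name not in self.residue_names:
            return False
        return True


@dataclass
class DomainMap:
    """Named residue ranges per chain, e.g. NTD/linker/M/CTD of an Hsp90 protomer.

    ``ranges`` maps chain id -> {domain name: (lo, hi)} with inclusive bounds;
    ranges within one chain must not overlap.
    """

    ranges: dict[str, dict[str, tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chain, domains in self.ranges.items():
            spans = sorted(domains.values())
            for (lo, hi), (lo2, _hi2) in zip(spans, spans[1:]):
                if lo2 <= hi:
                    raise ValueError(f"overlapping domain ranges in chain {chain}")
            for name, (lo, hi) in domains.items():
                if lo > hi:
                    raise ValueError(f"domain {name} in chain {chain}: lo > hi")

    def selection(self, chain_id: str, domain: str) -> SelectionSpec:
        lo, hi = self.ranges[chain_id][domain]
        return SelectionSpec(chain_id=chain_id, residue_range=(lo, hi))


#: Default yeast Hsp82 domain boundaries (editable configuration, not asserted truth).
DEFAULT_HSP82_DOMAINS = {"NTD": (1, 216), "linker": (217, 261), "M": (262, 526),
                         "CTD": (527, 709)}


def read_structure_models(path: str | Path) -> list[StructureModel]:
    """Read a (multi-model) PDB file into a list of :class:`StructureModel`.

    ATOM and HETATM records are retained; alternate locations are resolved
    to the highest-occupancy conformer (first on ties).  Raises
    :class:`PDBParseError` on malformed records (the message names the
    offending line) and :class:`EmptyStructureError` for atom-free files.
    """
    path = Path(path)
    parser = PDBParser(PERMISSIVE=0, QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        try:
            structure = parser.get_structure(path.stem, str(path))
        except PDBConstructionException as exc:
            raise PDBParseError(f"{path}: {exc}") from exc
        except ValueError as exc:
            raise PDBParseError(f"{path}: malformed numeric field ({exc})") from exc

    models: list[StructureModel] = []
    for bio_model in structure:
        atoms: list[AtomRecord] = []
        for chain in bio_model:
            for residue in chain:
                _hetflag, resseq, icode = residue.id
                for atom in residue:
                    element = (atom.element or "").strip().capitalize()
                    atoms.append(
                        AtomRecord(
                            serial=int(atom.serial_number),
                            atom_name=atom.get_name(),
                            residue_name=residue.get_resname().strip(),
                            chain_id=chain.id,
                            residue_number=int(resseq),
                            icode=icode.strip(),
                            coordinates=np.asarray(atom.coord, dtype=float),
                            element=element,
                            occupancy=float(atom.occupancy if atom.occupancy is not None else 1.0),
                        )
                    )
        if atoms:
            # Bio.PDB groups atoms by chain/residue; restore file order.
            atoms.sort(key=lambda a: a.serial)
            models.append(StructureModel(atoms=atoms, model_index=int(bio_model.id)))
    if not models:
        raise EmptyStructureError(f"{path}: no atoms found")
    return models


def _format_atom_name(name: str, element: str) -> str:
    # Columns 13-16: element-aligned per the PDB convention.
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1 and len(name) <= 3:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_structure_models(path: str | Path, models: Sequence[StructureModel]) -> None:
    """Write models as a standard fixed-column multi-model PDB file."""
    lines: list[str] = []
    multi = len(models) > 1
    for i, model in enumerate(models, start=1):
        if multi:
            lines.append(f"MODEL     {i:4d}")
        for atom in model.atoms:
            x, y, z = atom.coordinates
            lines.append(
                "ATOM  {serial:5d} {name:4s}{alt:1s}{res:3s} {chain:1s}{resnum:4d}{icode:1s}   "
                "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{bfac:6.2f}          {elem:>2s}".format(
                    serial=atom.serial,
                    name=_format_atom_name(atom.atom_name, atom.element),
                    alt=" ",
                    res=atom.residue_name[:3],
                    chain=atom.chain_id[:1] or "A",
                    resnum=atom.residue_number,
                    icode=atom.icode[:1] or " ",
                    x=x, y=y, z=z,
                    occ=atom.occupancy,
                    bfac=0.0,
                    elem=atom.element[:2],
                )
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_trajectory(path: str | Path, traj: Trajectory) -> None:
    """Write a trajectory as multi-model PDB (frame times are not stored)."""
    write_structure_models(path, traj.frames)


def select_atoms(model: StructureModel, spec: SelectionSpec) -> list[AtomRecord]:
    """Atoms of ``model`` matching all criteria of ``spec``, order preserved."""
    return [a for a in model.atoms if spec.matches(a)]


def center_of_mass(
    atoms: Iterable[AtomRecord],
    mass_table: dict[str, float] | None = None,
) -> np.ndarray:
    """Mass-weighted mean coordinate of ``atoms`` (Å).

    Uses standard atomic weights by default; hydrogen-free selections are
    fine (crystal structures commonly lack hydrogens).
    """
    if mass_table is None:
        mass_table = ATOMIC_MASSES
    atoms = list(atoms)
    if not atoms:
        raise ValueError("center_of_mass requires at least one atom")
    missing = sorted({a.element for a in atoms} - set(mass_table))
    if missing:
        raise UnknownElementError(f"elements missing from mass table: {missing}")
    masses = np.array([mass_table[a.element] for a in atoms])
    coords = np.array([a.coordinates for a in atoms])
    return masses @ coords / masses.sum()


def kabsch_superpose(
    mobile_coords: np.ndarray,
    reference_coords: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``coords @ rotation.T + translation`` minimises the RMSD to the
    reference over all proper rotations (determinant +1) and translations.
    """
    from scipy.spatial.transform import Rotation

    mobile = np.asarray(mobile_coords, dtype=float)
    reference = np.asarray(reference_coords, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must be equal-shape (N, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition requires at least 3 points")
    mob_centroid = mobile.mean(axis=0)
    ref_centroid = reference.mean(axis=0)
    rot, rssd = Rotation.align_vectors(reference - ref_centroid, mobile - mob_centroid)
    rotation = rot.as_matrix()
    translation = ref_centroid - rotation @ mob_centroid
    rmsd = float(rssd) / np.sqrt(n)
    return rotation, translation, rmsd
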