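"""Trajectory data model: atoms, topologies, frames, trajectories.

A :class:`Trajectory` is an ordered stack of coordinate frames over one
fixed heavy-atom :class:`Topology`.  Residues are identified by the
author-assigned residue number (kinase-domain numbering 697-1019 in the
motivating system), never by positional index, so deletion mutants with
numbering gaps (e.g. a missing 746-750 stretch) are represented naturally.

Coordinates are always in Angstrom.  Atoms belonging to one residue are
stored contiguously, which lets the analysis layer use segment reductions
instead of per-residue Python loops.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .errors import TopologyError

_HYDROGEN_ELEMENTS = {"H", "D"}


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, chemistry and residue membership.

    ``is_hydrogen`` is derived from the element symbol (H or D), so the
    invariant "is_hydrogen iff element is hydrogen/deuterium" holds by
    construction.
    """

    atom_id: int
    name: str
    element: str
    residue_number: int
    residue_name: str = "UNK"

    def __post_init__(self):
        if self.atom_id < 0:
            raise TopologyError(f"atom_id must be >= 0, got {self.atom_id}")
        if not self.element:
            raise TopologyError(f"atom {self.atom_id}: empty element symbol")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in _HYDROGEN_ELEMENTS


class Topology:
    """Ordered atom list grouped into residues.

    Invariants enforced at construction:

    * atom_ids unique;
    * atoms of one residue are contiguous and residue numbers are strictly
      increasing along the atom list (gaps permitted);
    * every residue has at least one atom.
    """

    def __init__(self, atoms: Sequence[AtomRecord]):
        atoms = tuple(atoms)
        if not atoms:
            raise TopologyError("topology must contain at least one atom")
        ids = [a.atom_id for a in atoms]
        if len(set(ids)) != len(ids):
            seen, dup = set(), None
            for i in ids:
                if i in seen:
                    dup = i
                    break
                seen.add(i)
            raise TopologyError(f"duplicate atom_id {dup} in topology")
        # residue blocks must be contiguous with strictly increasing numbers
        boundaries = [0]
        for k in range(1, len(atoms)):
            prev, cur = atoms[k - 1].residue_number, atoms[k].residue_number
            if cur < prev:
                raise TopologyError(
                    f"residue numbers must be non-decreasing along the atom "
                    f"list (atom {atoms[k].atom_id}: {cur} after {prev})"
                )
            if cur > prev:
                boundaries.append(k)
        self.atoms = atoms
        self._starts = np.asarray(boundaries, dtype=np.intp)
        self.residue_numbers = np.asarray(
            [atoms[s].residue_number for s in boundaries], dtype=np.int64
        )
        if len(set(self.residue_numbers.tolist())) != len(self.residue_numbers):
            raise TopologyError("residue atoms must be contiguous (a residue "
                                "number appears in two separate blocks)")
        self.residue_names = tuple(atoms[s].residue_name for s in boundaries)
        ends = np.append(self._starts[1:], len(atoms))
        self.residue_sizes = (ends - self._starts).astype(np.int64)

    # -- container protocol -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residue_numbers)

    @property
    def residue_starts(self) -> np.ndarray:
        """Index of the first atom of each residue (for segment reductions)."""
        return self._starts

    def residue_atom_ids(self) -> Mapping[int, list]:
        out = {}
        ends = np.append(self._starts[1:], self.n_atoms)
        for num, s, e in zip(self.residue_numbers.tolist(),
                             self._starts.tolist(), ends.tolist()):
            out[num] = [a.atom_id for a in self.atoms[s:e]]
        return out

    def heavy_atom_indices(self) -> np.ndarray:
        return np.asarray(
            [i for i, a in enumerate(self.atoms) if not a.is_hydrogen],
            dtype=np.intp,
        )

    def atom_index_of(self, atom_id: int) -> int:
        try:
            return self._id_index[atom_id]
        except AttributeError:
            self._id_index = {a.atom_id: i for i, a in enumerate(self.atoms)}
            return self._id_index[atom_id]

    def __eq__(self, other) -> bool:
        return isinstance(other, Topology) and self.atoms == other.atoms

    def __hash__(self):
        return hash(self.atoms)

    def __repr__(self):
        return (f"<Topology {self.n_atoms} atoms / {self.n_residues} residues "
                f"({self.residue_numbers[0]}-{self.residue_numbers[-1]})>")


@dataclass
class StructureFrame:
    """A single conformation: coordinates (N, 3) in Angstrom over a topology."""

    topology: Topology
    coordinates: np.ndarray

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        if self.coordinates.shape != (self.topology.n_atoms, 3):
            raise TopologyError(
                f"coordinate array shape {self.coordinates.shape} does not "
                f"match topology ({self.topology.n_atoms} atoms)"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise TopologyError("coordinates contain non-finite values")

    def copy(self) -> "StructureFrame":
        return StructureFrame(self.topology, self.coordinates.copy())


class Trajectory:
    """Ordered frames over one shared topology.

    Frames are stored as a single (J, N, 3) float64 array; ``frames``
    exposes :class:`StructureFrame` views.  ``frame_interval_ps`` is
    metadata only (the study sampled every 2 ps).  ``ligand`` optionally
    holds a separate trajectory of HETATM atoms (inhibitor), excluded from
    residue profiles and fits unless explicitly merged.
    """

    def __init__(
        self,
        topology: Topology,
        coordinates: np.ndarray,
        frame_interval_ps: float = 2.0,
        ligand: Optional["Trajectory"] = None,
        provenance: Optional[dict] = None,
    ):
        coords = np.asarray(coordinates, dtype=np.float64)
        if coords.ndim != 3 or coords.shape[1:] != (topology.n_atoms, 3):
            raise TopologyError(
                f"trajectory coordinates must have shape (J, {topology.n_atoms}, 3); "
                f"got {coords.shape}"
            )
        if coords.shape[0] < 1:
            raise TopologyError("trajectory must contain at least one frame (J >= 1)")
        if not np.all(np.isfinite(coords)):
            raise TopologyError("trajectory coordinates contain non-finite values")
        if frame_interval_ps <= 0:
            raise ValueError("frame_interval_ps must be positive")
        self.topology = topology
        self.coordinates = coords
        self.frame_interval_ps = float(frame_interval_ps)
        self.ligand = ligand
        self.provenance = dict(provenance) if provenance else {}

    @classmethod
    def from_frames(cls, frames: Sequence[StructureFrame], **kw) -> "Trajectory":
        if not frames:
            raise TopologyError("trajectory must contain at least one frame (J >= 1)")
        top = frames[0].topology
        for j, f in enumerate(frames):
            if f.topology != top:
                raise TopologyError(f"frame {j} has a different topology")
        return cls(top, np.stack([f.coordinates for f in frames]), **kw)

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms

    def frame(self, j: int) -> StructureFrame:
        return StructureFrame(self.topology, self.coordinates[j])

    @property
    def frames(self) -> Iterable[StructureFrame]:
        return (self.frame(j) for j in range(self.n_frames))

    def with_coordinates(self, coords: np.ndarray) -> "Trajectory":
        return Trajectory(self.topology, coords, self.frame_interval_ps,
                          ligand=self.ligand, provenance=self.provenance)

    def __repr__(self):
        return (f"<Trajectory J={self.n_frames}, {self.n_atoms} atoms, "
                f"{self.topology.n_residues} residues>")


def strip_hydrogens(traj: Trajectory) -> Trajectory:
    """Drop hydrogen (and deuterium) atoms from topology and every frame.

    Residues left without any heavy atom are removed entirely.  Idempotent;
    a hydrogen-free trajectory is returned unchanged (same object).
    """
    keep = traj.topology.heavy_atom_indices()
    if len(keep) == traj.n_atoms:
        return traj
    if len(keep) == 0:
        raise TopologyError("no heavy atoms remain after hydrogen stripping")
    atoms = [traj.topology.atoms[i] for i in keep]
    new_top = Topology(atoms)
    return Trajectory(new_top, traj.coordinates[:, keep, :],
                      traj.frame_interval_ps, ligand=traj.ligand,
                      provenance=traj.provenance)


def merge_ligand(traj: Trajectory) -> Trajectory:
    """Append the ligand partition as a pseudo-residue for exploration.

    The ligand keeps its own (HETATM) residue number, which must exceed the
    last protein residue number for the merged topology to be valid.
    """
    if traj.ligand is None:
        return traj
    lig = traj.ligand
    atoms = list(traj.topology.atoms) + list(lig.topology.atoms)
    top = Topology(atoms)
    coords = np.concatenate([traj.coordinates, lig.coordinates], axis=1)
    return Trajectory(top, coords, traj.frame_interval_ps,
                      provenance=traj.provenance)
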