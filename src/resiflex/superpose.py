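"""Rigid-body best-fit superposition and the average-structure reference.

Per-frame displacements are only meaningful once the global translation and
rotation of each frame have been removed.  The pipeline replicated here is:
strip hydrogens, least-squares best-fit every frame onto the *original*
structure (all heavy atoms in the fit mask, unweighted), then take the
per-atom arithmetic mean of the aligned frames as the *average structure*,
which serves as the displacement reference.

The fit is the classic Kabsch algorithm: SVD of the cross-covariance of the
centered coordinate sets, with the determinant correction (negating the
smallest singular axis) to exclude reflections.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .errors import DegenerateFitError, TopologyError
from .model import StructureFrame, Trajectory

#: tolerance used for orthogonality / determinant checks
ORTHO_TOL = 1e-8


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion x -> rotation @ x + translation (Angstrom)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=np.float64)
        t = np.asarray(self.translation, dtype=np.float64)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation matrix is not orthogonal")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValueError("rotation matrix must be proper (det +1)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other (apply ``other`` first)."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


def _mask_indices(topology, atom_mask: Optional[Iterable[int]]) -> np.ndarray:
    if atom_mask is None:
        return np.arange(topology.n_atoms, dtype=np.intp)
    idx = np.asarray(sorted(topology.atom_index_of(a) for a in set(atom_mask)),
                     dtype=np.intp)
    return idx


def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> RigidTransform:
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    H = (mobile - mc).T @ (reference - rc)
    U, s, Vt = np.linalg.svd(H)
    # collinear (or fewer than 2 independent directions): fit undetermined
    if s[1] <= max(s[0], 1.0) * 1e-10:
        raise DegenerateFitError(
            "fit atoms are collinear or coincident; rotation is undetermined"
        )
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if d < 0:  # reflection branch: negate the smallest singular axis
        Vt[-1] *= -1.0
    R = Vt.T @ U.T
    return RigidTransform(R, rc - R @ mc)


def kabsch_fit(mobile: StructureFrame, reference: StructureFrame,
               atom_mask: Optional[Iterable[int]] = None) -> RigidTransform:
    """Least-squares rigid fit of ``mobile`` onto ``reference``.

    ``atom_mask`` is a set of atom_ids (default: all atoms of the shared
    topology).  The returned transform minimizes the RMSD of the masked
    atoms; fewer than 3 masked atoms or a collinear configuration raises
    :class:`DegenerateFitError`.
    """
    if mobile.topology != reference.topology:
        raise TopologyError("mobile and reference frames have different topologies")
    idx = _mask_indices(mobile.topology, atom_mask)
    if len(idx) < 3:
        raise DegenerateFitError(
            f"fit mask has {len(idx)} atom(s); at least 3 non-collinear required"
        )
    return _kabsch(mobile.coordinates[idx], reference.coordinates[idx])


def align_trajectory(traj: Trajectory, reference: StructureFrame,
                     atom_mask: Optional[Iterable[int]] = None) -> Trajectory:
    """Best-fit every frame onto ``reference``; transform applied to all atoms.

    The fit is computed on the masked atoms only (default: every atom), but
    the resulting rigid motion moves the whole frame, including the ligand
    partition if present.
    """
    if reference.topology != traj.topology:
        raise TopologyError("reference does not share the trajectory topology")
    idx = _mask_indices(traj.topology, atom_mask)
    if len(idx) < 3:
        raise DegenerateFitError(
            f"fit mask has {len(idx)} atom(s); at least 3 non-collinear required"
        )
    out = np.empty_like(traj.coordinates)
    lig_out = None
    if traj.ligand is not None:
        lig_out = np.empty_like(traj.ligand.coordinates)
    for j in range(traj.n_frames):
        try:
            tf = _kabsch(traj.coordinates[j, idx], reference.coordinates[idx])
        except DegenerateFitError as exc:
            raise DegenerateFitError(f"frame {j}: {exc}") from None
        out[j] = tf.apply(traj.coordinates[j])
        if lig_out is not None:
            lig_out[j] = tf.apply(traj.ligand.coordinates[j])
    ligand = None
    if lig_out is not None:
        ligand = Trajectory(traj.ligand.topology, lig_out,
                            traj.frame_interval_ps)
    return Trajectory(traj.topology, out, traj.frame_interval_ps,
                      ligand=ligand, provenance=traj.provenance)


def average_structure(traj: Trajectory) -> StructureFrame:
    """Per-atom arithmetic mean over frames (the displacement reference).

    The caller is responsible for aligning the trajectory first; the mean of
    unaligned frames mixes internal motion with global drift.  The average
    may be chemically unphysical — it is a statistical reference only and is
    deliberately not re-fit or idealized.
    """
    return StructureFrame(traj.topology, traj.coordinates.mean(axis=0))


def rmsd(a: StructureFrame, b: StructureFrame,
         atom_mask: Optional[Iterable[int]] = None) -> float:
    """Plain (unfitted) RMSD between two frames over the masked atoms."""
    if a.topology != b.topology:
        raise TopologyError("frames have different topologies")
    idx = _mask_indices(a.topology, atom_mask)
    d = a.coordinates[idx] - b.coordinates[idx]
    return float(np.sqrt((d * d).sum() / len(idx)))
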