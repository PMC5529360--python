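import numpy as np
import pytest

from resiflex import (StructureFrame, Topology, Trajectory, AtomRecord,
                      TrajectoryRecipe, generate_trajectory, make_reference)


def toy_topology(residue_atoms, start=700):
    """Topology with the given atoms-per-residue list, all carbon."""
    atoms, aid = [], 0
    for r, k in enumerate(residue_atoms):
        for _ in range(k):
            atoms.append(AtomRecord(atom_id=aid, name=f"X{aid}", element="C",
                                    residue_number=start + r))
            aid += 1
    return Topology(atoms)


def random_frame(topology, rng, scale=10.0):
    return StructureFrame(topology,
                          rng.uniform(-scale, scale, (topology.n_atoms, 3)))


def apply_rigid_motions(traj, seed):
    """Inject an independent random rotation+translation into every frame."""
    rng = np.random.default_rng(seed)
    coords = np.empty_like(traj.coordinates)
    for j in range(traj.n_frames):
        # random rotation via QR of a Gaussian matrix, det corrected to +1
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        t = rng.uniform(-20, 20, 3)
        coords[j] = traj.coordinates[j] @ q.T + t
    return Trajectory(traj.topology, coords, traj.frame_interval_ps)


@pytest.fixture
def small_recipe():
    return TrajectoryRecipe(n_residues=12, atoms_per_residue=4, n_frames=40,
                            per_residue_sigma=0.3, seed=11)


@pytest.fixture
def small_traj(small_recipe):
    ref = make_reference(small_recipe)
    return ref, generate_trajectory(ref, small_recipe)
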