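"""Canonical on-disk fixture format for trajectories.

A fixture is a directory holding

* ``topology.json`` — ``{schema_version, frame_interval_ps, ligand: bool,
  atoms: [{atom_id, name, element, residue_number, residue_name}, ...]}``
* ``coordinates.csv`` — columns ``frame_index, atom_id, x, y, z`` in
  Angstrom, written with shortest round-tripping decimal repr so that
  read(write(T)) reproduces coordinates bit-exactly on any platform.

The format exists so golden tests can pin trajectories as plain text;
multi-model PDB (3 decimals) is the lossy interchange format instead.
"""

from __future__ import annotations

import csv
import json
import os

import numpy as np

from .errors import FormatError
from .model import AtomRecord, Topology, Trajectory

SCHEMA_VERSION = 1

_ATOM_FIELDS = ("atom_id", "name", "element", "residue_number", "residue_name")


def write_fixture(traj: Trajectory, path) -> None:
    """Write ``traj`` (and its ligand partition, if any) to directory ``path``."""
    os.makedirs(path, exist_ok=True)
    _write_one(traj, os.path.join(path, "topology.json"),
               os.path.join(path, "coordinates.csv"),
               has_ligand=traj.ligand is not None)
    if traj.ligand is not None:
        _write_one(traj.ligand, os.path.join(path, "ligand_topology.json"),
                   os.path.join(path, "ligand_coordinates.csv"),
                   has_ligand=False)


def _write_one(traj, top_path, coord_path, has_ligand):
    doc = {
        "schema_version": SCHEMA_VERSION,
        "frame_interval_ps": traj.frame_interval_ps,
        "ligand": bool(has_ligand),
        "atoms": [
            {f: getattr(a, f) for f in _ATOM_FIELDS} for a in traj.topology.atoms
        ],
    }
    with open(top_path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")
    with open(coord_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frame_index", "atom_id", "x", "y", "z"])
        ids = [a.atom_id for a in traj.topology.atoms]
        for j in range(traj.n_frames):
            for i, aid in enumerate(ids):
                x, y, z = traj.coordinates[j, i]
                w.writerow([j, aid, repr(float(x)), repr(float(y)), repr(float(z))])


def read_fixture(path) -> Trajectory:
    """Read a fixture directory back into a :class:`Trajectory`.

    Schema violations raise :class:`FormatError` carrying a JSON-pointer-style
    location of the offending field.
    """
    traj = _read_one(path, "topology.json", "coordinates.csv")
    top_doc = _load_json(os.path.join(path, "topology.json"))
    if top_doc.get("ligand"):
        traj.ligand = _read_one(path, "ligand_topology.json",
                                "ligand_coordinates.csv")
    return traj


def _load_json(path):
    try:
        with open(path) as fh:
            return json.load(fh)
    except FileNotFoundError:
        raise FormatError(f"missing fixture file: {path}") from None
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON ({exc})") from None


def _read_one(path, top_name, coord_name) -> Trajectory:
    top_path = os.path.join(path, top_name)
    doc = _load_json(top_path)
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise FormatError(
            f"{top_path}: /schema_version must be {SCHEMA_VERSION}, "
            f"got {doc.get('schema_version')!r}"
        )
    atoms_doc = doc.get("atoms")
    if not isinstance(atoms_doc, list) or not atoms_doc:
        raise FormatError(f"{top_path}: /atoms must be a non-empty list")
    atoms = []
    for idx, a in enumerate(atoms_doc):
        for f in _ATOM_FIELDS:
            if f not in a:
                raise FormatError(f"{top_path}: /atoms/{idx}/{f} is missing")
        try:
            atoms.append(AtomRecord(
                atom_id=int(a["atom_id"]), name=str(a["name"]),
                element=str(a["element"]),
                residue_number=int(a["residue_number"]),
                residue_name=str(a["residue_name"]),
            ))
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{top_path}: /atoms/{idx}: {exc}") from None
    topology = Topology(atoms)
    index_of = {a.atom_id: i for i, a in enumerate(atoms)}

    coord_path = os.path.join(path, coord_name)
    frames: dict[int, np.ndarray] = {}
    try:
        fh = open(coord_path, newline="")
    except FileNotFoundError:
        raise FormatError(f"missing fixture file: {coord_path}") from None
    with fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["frame_index", "atom_id", "x", "y", "z"]:
            raise FormatError(f"{coord_path}: bad header {header!r}")
        for rowno, row in enumerate(reader, start=2):
            try:
                j = int(row[0])
                aid = int(row[1])
                xyz = [float(row[2]), float(row[3]), float(row[4])]
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{coord_path}: row {rowno}: {exc}") from None
            if aid not in index_of:
                raise FormatError(f"{coord_path}: row {rowno}: unknown atom_id {aid}")
            if not all(np.isfinite(xyz)):
                raise FormatError(f"{coord_path}: row {rowno}: non-finite coordinate")
            frames.setdefault(j, np.full((topology.n_atoms, 3), np.nan))
            frames[j][index_of[aid]] = xyz
    if not frames:
        raise FormatError(f"{coord_path}: no coordinate rows (J >= 1 required)")
    order = sorted(frames)
    if order != list(range(len(order))):
        raise FormatError(f"{coord_path}: frame_index values {order} are not 0..J-1")
    coords = np.stack([frames[j] for j in order])
    if not np.all(np.isfinite(coords)):
        j, i = np.argwhere(~np.isfinite(coords).all(axis=2))[0]
        raise FormatError(
            f"{coord_path}: frame {j} is missing atom_id "
            f"{topology.atoms[i].atom_id}"
        )
    return Trajectory(topology, coords,
                      frame_interval_ps=float(doc.get("frame_interval_ps", 2.0)))
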