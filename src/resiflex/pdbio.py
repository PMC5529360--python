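"""Multi-model PDB reading and writing.

The multi-model PDB (MODEL/ENDMDL blocks) is the interchange format for
trajectories here.  The reader enforces the package's single-chain model:

* topology is built from the first model; later models must present the
  identical atom set, or a :class:`TopologyError` names the first offending
  model;
* author residue numbering is preserved verbatim;
* alternate locations: the highest-occupancy conformer is kept, ties go to
  the first encountered;
* ATOM records form the protein partition; HETATM records (minus waters)
  form a separate ligand partition attached as ``Trajectory.ligand``.

Columns follow the v3.3 fixed-width layout.  An unparsable ATOM/HETATM
record raises :class:`FormatError` with the 1-based line number.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np

from .errors import FormatError, TopologyError
from .model import AtomRecord, Topology, Trajectory

_WATER_RESNAMES = {"HOH", "WAT", "DOD"}


def _guess_element(name: str) -> str:
    s = name.strip()
    if not s:
        return ""
    if s[0].isdigit():  # e.g. "1HB2"
        s = s.lstrip("0123456789")
    if len(s) >= 2 and s[:2].upper() in {"FE", "ZN", "MG", "MN", "CL", "BR", "NA", "CA"}:
        # only trust 2-letter guesses for HETATM metals; atom names like CA
        # (alpha carbon) are ambiguous, so default to the first letter
        return s[0].upper()
    return s[0].upper() if s else ""


def _parse_atom_line(line: str, lineno: int):
    try:
        name = line[12:16].strip()
        altloc = line[16]
        resname = line[17:20].strip()
        chain = line[21]
        resseq = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise FormatError(f"unparsable ATOM/HETATM record at line {lineno}: "
                          f"{line.rstrip()!r} ({exc})") from None
    if not element:
        element = _guess_element(name)
    return dict(name=name, altloc=altloc, resname=resname, chain=chain,
                resseq=resseq, icode=icode, xyz=(x, y, z),
                occupancy=occupancy, element=element,
                is_het=line.startswith("HETATM"))


def _dedupe_altlocs(records: List[dict]) -> List[dict]:
    """Keep one conformer per (resseq, icode, name): highest occupancy,
    ties resolved to the first encountered."""
    best = {}
    order = []
    for rec in records:
        key = (rec["resseq"], rec["icode"], rec["name"], rec["is_het"],
               rec["resname"])
        if key not in best:
            best[key] = rec
            order.append(key)
        elif rec["occupancy"] > best[key]["occupancy"]:
            best[key] = rec
    return [best[k] for k in order]


def _read_models(path) -> List[List[dict]]:
    models: List[List[dict]] = []
    current: List[dict] = []
    in_model = False
    saw_model_card = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                saw_model_card = True
                in_model = True
                current = []
            elif rec == "ENDMDL":
                in_model = False
                models.append(current)
                current = []
            elif rec in ("ATOM", "HETATM"):
                current.append(_parse_atom_line(line, lineno))
    if current or (not saw_model_card and not models):
        if current:
            models.append(current)
    models = [m for m in models if m]
    if not models:
        raise FormatError(f"{path}: no ATOM/HETATM records found")
    return models


def read_multimodel_pdb(path, ligand_as_residue: bool = False) -> Trajectory:
    """Read a (multi-)model PDB file into a :class:`Trajectory`.

    One frame per MODEL block (a file without MODEL cards is a J=1
    trajectory).  The protein (ATOM) partition carries the residue profile;
    HETATM atoms other than water are collected into ``Trajectory.ligand``.
    With ``ligand_as_residue=True`` the ligand is merged into the topology
    as a pseudo-residue instead.
    """
    models = _read_models(path)
    first = _dedupe_altlocs(models[0])
    chains = sorted({r["chain"] for r in first if not r["is_het"]})
    if len(chains) > 1:
        raise TopologyError(
            f"{path}: multiple protein chains {chains}; the residue-stability "
            "model assumes a single kinase-domain chain"
        )

    def split(recs):
        prot = [r for r in recs if not r["is_het"]]
        lig = [r for r in recs
               if r["is_het"] and r["resname"] not in _WATER_RESNAMES]
        return prot, lig

    prot0, lig0 = split(first)
    if not prot0 and not lig0:
        raise FormatError(f"{path}: no usable atoms in first model")

    def key(rec):
        return (rec["resseq"], rec["icode"], rec["name"], rec["resname"])

    ref_keys_prot = [key(r) for r in prot0]
    ref_keys_lig = [key(r) for r in lig0]

    prot_coords, lig_coords = [], []
    for m_index, model in enumerate(models, start=1):
        recs = _dedupe_altlocs(model) if m_index > 1 else first
        prot, lig = split(recs)
        if [key(r) for r in prot] != ref_keys_prot or \
           [key(r) for r in lig] != ref_keys_lig:
            raise TopologyError(
                f"{path}: model {m_index} atom set differs from model 1"
            )
        prot_coords.append([r["xyz"] for r in prot])
        lig_coords.append([r["xyz"] for r in lig])

    def build(recs, id_offset=0):
        atoms = [
            AtomRecord(atom_id=id_offset + i, name=r["name"],
                       element=r["element"], residue_number=r["resseq"],
                       residue_name=r["resname"])
            for i, r in enumerate(recs)
        ]
        return Topology(atoms)

    ligand = None
    if lig0:
        ligand = Trajectory(build(lig0, id_offset=len(prot0)),
                            np.asarray(lig_coords, dtype=np.float64))
    if not prot0:
        # ligand-only file: expose it as the primary partition
        return ligand
    traj = Trajectory(build(prot0), np.asarray(prot_coords, dtype=np.float64),
                      ligand=ligand)
    if ligand_as_residue and ligand is not None:
        from .model import merge_ligand
        return merge_ligand(traj)
    return traj


def write_multimodel_pdb(traj: Trajectory, path, include_ligand: bool = True):
    """Write a trajectory as a multi-model PDB file (one MODEL per frame)."""
    tops: List[Tuple[Topology, np.ndarray, str]] = [
        (traj.topology, traj.coordinates, "ATOM  ")
    ]
    if include_ligand and traj.ligand is not None:
        tops.append((traj.ligand.topology, traj.ligand.coordinates, "HETATM"))
    with open(path, "w") as fh:
        for j in range(traj.n_frames):
            fh.write(f"MODEL     {j + 1:4d}\n")
            serial = 1
            for top, coords, card in tops:
                for i, atom in enumerate(top.atoms):
                    x, y, z = coords[j, i]
                    name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                    fh.write(
                        f"{card}{serial:5d} {name:<4.4s} {atom.residue_name:<3.3s}"
                        f" A{atom.residue_number:4d}    "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                        f"          {atom.element:>2.2s}\n"
                    )
                    serial += 1
            fh.write("ENDMDL\n")
        fh.write("END\n")
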