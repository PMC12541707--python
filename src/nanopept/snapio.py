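"""Snapshot readers and writers.

Trajectories are written as standard multi-model PDB (MODEL/ENDMDL, one
chain identifier per molecule, HETATM for drugs and ions) or as multi-frame
XYZ, always alongside a JSON *manifest* that labels every molecule: its id,
kind, chemical label (sequence + C-terminus for peptides, drug name for
drugs) and atom count, in file order.  The manifest carries provenance
(generator, seed, config hash) so any output can be regenerated.

Reading reconstructs fully-typed molecules: coordinates come from the
coordinate file, while radii and interaction typing are rebuilt from the
manifest labels through the same templates the builders use.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .core import (
    DrugSpec,
    MoleculeInstance,
    PeptideSequence,
    Snapshot,
    drug_spec,
    make_drug_instance,
    make_no3,
    make_zn,
)
from .scaffolds import build_peptide

__all__ = ["Manifest", "ManifestEntry", "write_snapshot", "read_snapshot"]

_CHAIN_IDS = string.ascii_uppercase + string.ascii_lowercase + string.digits


@dataclass(frozen=True)
class ManifestEntry:
    molecule_id: int
    kind: str
    label: dict  # peptide: {sequence, c_terminus}; drug: {drug}; ions: {}
    n_atoms: int


@dataclass(frozen=True)
class Manifest:
    entries: tuple[ManifestEntry, ...]
    provenance: dict

    def __post_init__(self) -> None:
        ids = [e.molecule_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate molecule ids in manifest")

    @classmethod
    def from_snapshot(cls, snapshot: Snapshot, provenance: dict | None = None,
                      ) -> "Manifest":
        entries = []
        for m in snapshot.molecules:
            if m.kind == "peptide":
                label = {"sequence": m.payload.sequence,
                         "c_terminus": m.payload.termini.c_terminus}
            elif m.kind == "drug":
                label = {"drug": m.payload.name}
            else:
                label = {}
            entries.append(ManifestEntry(m.molecule_id, m.kind, label,
                                         len(m.atoms)))
        prov = dict(provenance or {})
        prov.update({k: v for k, v in snapshot.metadata.items()
                     if k not in prov and _jsonable(v)})
        return cls(tuple(entries), prov)

    def to_dict(self) -> dict:
        return {
            "version": 1,
            "provenance": self.provenance,
            "molecules": [
                {"id": e.molecule_id, "kind": e.kind, "label": e.label,
                 "n_atoms": e.n_atoms}
                for e in self.entries
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "Manifest":
        entries = tuple(
            ManifestEntry(m["id"], m["kind"], m.get("label", {}), m["n_atoms"])
            for m in data["molecules"]
        )
        return cls(entries, data.get("provenance", {}))


def _jsonable(value) -> bool:
    try:
        json.dumps(value)
        return True
    except (TypeError, ValueError):
        return False


def _default_manifest_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".manifest.json")


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

_RES_NAME = {"zn": "ZN", "no3": "NO3", "drug": "LIG"}


def _to_atom_array(snapshot: Snapshot) -> struc.AtomArray:
    n = sum(len(m.atoms) for m in snapshot.molecules)
    arr = struc.AtomArray(n)
    coords = np.zeros((n, 3), dtype=np.float32)
    chain, res_id, res_name, atom_name, element, hetero = [], [], [], [], [], []
    i = 0
    for mi, mol in enumerate(snapshot.molecules):
        cid = _CHAIN_IDS[mi % len(_CHAIN_IDS)]
        if mol.kind == "peptide":
            from .core import _residue_table
            table = _residue_table()
            res_counter = 0
            for a in mol.atoms:
                if a.name == "N":
                    res_counter += 1
                coords[i] = a.position
                chain.append(cid)
                res_id.append(max(res_counter, 1))
                code = mol.payload.residues[max(res_counter, 1) - 1].one_letter_code
                res_name.append(table[code]["three_letter"])
                atom_name.append(a.name)
                element.append(a.element)
                hetero.append(False)
                i += 1
        else:
            rname = mol.payload.name[:3].upper() if mol.kind == "drug" \
                else _RES_NAME[mol.kind]
            for a in mol.atoms:
                coords[i] = a.position
                chain.append(cid)
                res_id.append(1)
                res_name.append(rname)
                atom_name.append(a.name or f"{a.element}{a.atom_id + 1}")
                element.append(a.element)
                hetero.append(True)
                i += 1
    arr.coord = coords
    arr.chain_id = np.array(chain)
    arr.res_id = np.array(res_id)
    arr.res_name = np.array(res_name)
    arr.atom_name = np.array(atom_name)
    arr.element = np.array([e.upper() for e in element])
    arr.hetero = np.array(hetero)
    return arr


def write_snapshot(trajectory: Snapshot | Sequence[Snapshot], path: str | Path,
                   manifest_path: str | Path | None = None,
                   provenance: dict | None = None) -> Manifest:
    """Write one snapshot or a trajectory plus its JSON manifest.

    The format is chosen by extension: ``.pdb`` (multi-model) or ``.xyz``
    (multi-frame).  All frames must share the same molecule layout.
    """
    frames = [trajectory] if isinstance(trajectory, Snapshot) else list(trajectory)
    if not frames:
        raise ValueError("nothing to write: empty trajectory")
    manifest = Manifest.from_snapshot(frames[0], provenance)
    for f in frames[1:]:
        if Manifest.from_snapshot(f).entries != manifest.entries:
            raise ValueError("all frames must share the same molecule layout")
    path = Path(path)
    if path.suffix == ".pdb":
        arrays = [_to_atom_array(f) for f in frames]
        stack = struc.stack(arrays)
        pdb = PDBFile()
        pdb.set_structure(stack)
        pdb.write(str(path))
    elif path.suffix == ".xyz":
        with open(path, "w") as fh:
            for f in frames:
                atoms = [(a.element, a.position) for m in f.molecules
                         for a in m.atoms]
                fh.write(f"{len(atoms)}\nnanopept snapshot\n")
                for el, pos in atoms:
                    fh.write(f"{el:<3s} {pos[0]:12.5f} {pos[1]:12.5f} "
                             f"{pos[2]:12.5f}\n")
    else:
        raise ValueError(f"unsupported extension {path.suffix!r} (use .pdb or .xyz)")
    mpath = Path(manifest_path) if manifest_path else _default_manifest_path(path)
    with open(mpath, "w") as fh:
        json.dump(manifest.to_dict(), fh, indent=1)
    return manifest


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _rebuild_molecule(entry: ManifestEntry, coords: np.ndarray) -> MoleculeInstance:
    """Typed molecule from a manifest entry, with coordinates from file."""
    if entry.kind == "peptide":
        seq = PeptideSequence.from_string(entry.label["sequence"],
                                          entry.label.get("c_terminus", "amide"))
        template = build_peptide(seq, entry.molecule_id)
    elif entry.kind == "drug":
        template = make_drug_instance(drug_spec(entry.label["drug"]),
                                      entry.molecule_id)
    elif entry.kind == "zn":
        template = make_zn(entry.molecule_id, np.zeros(3))
    elif entry.kind == "no3":
        template = make_no3(entry.molecule_id, np.zeros(3))
    else:
        raise ValueError(f"unknown kind {entry.kind!r} for molecule "
                         f"{entry.molecule_id}")
    if len(template.atoms) != len(coords):
        raise ValueError(
            f"molecule {entry.molecule_id} ({entry.kind}): manifest declares "
            f"{entry.n_atoms} atoms but template has {len(template.atoms)}")
    return MoleculeInstance(entry.molecule_id, entry.kind, template.payload,
                            [a.moved_to(c) for a, c in zip(template.atoms, coords)])


def _frames_from_file(path: Path) -> list[np.ndarray]:
    if path.suffix == ".pdb":
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None)
        if isinstance(stack, struc.AtomArray):
            return [np.asarray(stack.coord, dtype=float)]
        return [np.asarray(stack.coord[i], dtype=float)
                for i in range(stack.stack_depth())]
    if path.suffix == ".xyz":
        frames = []
        with open(path) as fh:
            lines = fh.read().splitlines()
        i = 0
        while i < len(lines):
            if not lines[i].strip():
                i += 1
                continue
            try:
                n = int(lines[i].strip())
            except ValueError as exc:
                raise ValueError(f"{path}: bad atom count at line {i + 1}") from exc
            block = lines[i + 2:i + 2 + n]
            if len(block) < n:
                raise ValueError(f"{path}: truncated frame at line {i + 1}")
            coords = np.array([[float(x) for x in ln.split()[1:4]]
                               for ln in block])
            frames.append(coords)
            i += 2 + n
        return frames
    raise ValueError(f"unsupported extension {path.suffix!r}")


def read_snapshot(path: str | Path,
                  manifest_path: str | Path | None = None) -> list[Snapshot]:
    """Read a multi-model PDB or multi-frame XYZ plus its manifest into a
    list of fully-typed snapshots (one per model, in file order)."""
    path = Path(path)
    mpath = Path(manifest_path) if manifest_path else _default_manifest_path(path)
    with open(mpath) as fh:
        manifest = Manifest.from_dict(json.load(fh))
    frames = _frames_from_file(path)
    n_expected = sum(e.n_atoms for e in manifest.entries)
    snapshots = []
    for coords in frames:
        if len(coords) != n_expected:
            raise ValueError(
                f"{path}: frame has {len(coords)} atoms but the manifest "
                f"declares {n_expected} over molecules "
                f"{[e.molecule_id for e in manifest.entries]}")
        molecules, offset = [], 0
        for entry in manifest.entries:
            molecules.append(_rebuild_molecule(
                entry, coords[offset:offset + entry.n_atoms]))
            offset += entry.n_atoms
        snapshots.append(Snapshot(molecules,
                                  metadata=dict(manifest.provenance)))
    return snapshots
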