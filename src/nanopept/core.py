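"""Domain types for tetrapeptide nanocarrier systems.

The package models minimal four-residue peptides (acetylated N-terminus,
histidine fixed at position 4 for Zn2+ coordination) that co-assemble with
small-molecule cancer drugs, Zn2+ and NO3- counter-ions.  This module holds
the value types shared by every other module — amino acids, termini
chemistry, peptide sequences, typed atoms, drug specifications, molecule
instances and whole labelled snapshots — plus the charge bookkeeping that
fixes the designed component ratios: ``peptide_net_charge`` and the
integer charge-neutrality solver ``solve_neutrality``.

Built-in residue and drug tables ship as versioned JSON data files; drug
coordinates are generated on first access by seeded distance-geometry
embedding of the stored SMILES (RDKit), so every process sees identical
built-in geometry.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AminoAcid",
    "TerminiSpec",
    "PeptideSequence",
    "AtomRecord",
    "Pose",
    "DrugSpec",
    "MoleculeInstance",
    "Snapshot",
    "SystemComposition",
    "amino_acid",
    "residue_scale",
    "drug_spec",
    "builtin_drug_names",
    "make_zn",
    "make_no3",
    "peptide_net_charge",
    "solve_neutrality",
    "NeutralityError",
]

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

ZN_RADIUS = 1.39  # A, vdW
ZN_CHARGE = 2


def _load_data(name: str) -> dict:
    with resources.files("nanopept.data").joinpath(name).open() as fh:
        return json.load(fh)


@lru_cache(maxsize=None)
def _residue_table() -> dict:
    return _load_data("residues.json")["residues"]


# ---------------------------------------------------------------------------
# residues and peptides
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AminoAcid:
    """One canonical residue: code, pH-7 side-chain charge, named scales."""

    one_letter_code: str
    net_side_chain_charge: int
    residue_scale_values: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.one_letter_code not in CANONICAL_RESIDUES:
            raise ValueError(f"not a canonical residue: {self.one_letter_code!r}")
        for name, value in self.residue_scale_values.items():
            if not math.isfinite(value):
                raise ValueError(f"non-finite scale value {name}={value!r}")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.one_letter_code


@lru_cache(maxsize=None)
def amino_acid(code: str) -> AminoAcid:
    """Look up a canonical residue by one-letter code."""
    try:
        entry = _residue_table()[code]
    except KeyError:
        raise KeyError(f"unknown residue code {code!r}") from None
    return AminoAcid(code, entry["side_chain_charge"], dict(entry["scales"]))


def residue_scale(name: str) -> dict[str, float]:
    """A named per-residue scale (e.g. ``hydrophobicity``, ``beta_propensity``)
    as a code -> value mapping over the 20 canonical residues."""
    table = _residue_table()
    if name not in next(iter(table.values()))["scales"]:
        raise KeyError(f"unknown residue scale {name!r}")
    return {code: entry["scales"][name] for code, entry in table.items()}


@dataclass(frozen=True)
class TerminiSpec:
    """Terminal chemistry of a designed peptide.

    The N-terminus is always acetylated (charge 0).  The C-terminus is either
    a free carboxylate (-1 e) — used with the cationic drugs — or amidated
    (0 e).
    """

    n_terminus: str = "acetyl"
    c_terminus: str = "amide"

    _C_CHARGE = {"carboxylate": -1, "amide": 0}

    def __post_init__(self) -> None:
        if self.n_terminus != "acetyl":
            raise ValueError("the N-terminus is always acetylated")
        if self.c_terminus not in self._C_CHARGE:
            raise ValueError(
                f"c_terminus must be 'carboxylate' or 'amide', got {self.c_terminus!r}"
            )

    @property
    def charge(self) -> int:
        return self._C_CHARGE[self.c_terminus]


@dataclass(frozen=True)
class PeptideSequence:
    """A four-residue designed peptide; His is pinned at position 4 (1-based)."""

    residues: tuple[AminoAcid, AminoAcid, AminoAcid, AminoAcid]
    termini: TerminiSpec = TerminiSpec()

    def __post_init__(self) -> None:
        if len(self.residues) != 4:
            raise ValueError("peptide length must be exactly 4")
        if self.residues[3].one_letter_code != "H":
            raise ValueError("position 4 must be histidine (Zn coordination site)")

    @classmethod
    def from_string(cls, seq: str, c_terminus: str = "amide") -> "PeptideSequence":
        if len(seq) != 4:
            raise ValueError(f"need a 4-letter sequence, got {seq!r}")
        return cls(
            tuple(amino_acid(c) for c in seq.upper()),
            TerminiSpec(c_terminus=c_terminus),
        )

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter_code for r in self.residues)

    def with_residue(self, position: int, code: str) -> "PeptideSequence":
        """Return a copy with ``position`` (1-based, 1..3) replaced."""
        if position not in (1, 2, 3):
            raise ValueError("only positions 1-3 are mutable; position 4 is locked His")
        res = list(self.residues)
        res[position - 1] = amino_acid(code)
        return replace(self, residues=tuple(res))

    def __str__(self) -> str:
        c = "COO-" if self.termini.c_terminus == "carboxylate" else "CONH2"
        return f"Ac-{self.sequence}-{c}"


def peptide_net_charge(peptide: PeptideSequence) -> int:
    """Net charge (e) at pH 7: sum of side-chain charges plus termini charge.

    His is treated as neutral; the acetylated N-terminus contributes 0 and the
    C-terminus -1 (carboxylate) or 0 (amide).
    """
    return sum(r.net_side_chain_charge for r in peptide.residues) + peptide.termini.charge


# ---------------------------------------------------------------------------
# atoms, drugs, ions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomRecord:
    """A heavy atom (or side-chain pseudo-atom) with interaction typing."""

    atom_id: int
    element: str
    position: np.ndarray  # (3,) A
    vdw_radius: float
    hydrophobic: bool = False
    h_bond_donor: bool = False
    h_bond_acceptor: bool = False
    aromatic: bool = False
    metal: bool = False
    charged: bool = False
    formal_charge: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if self.vdw_radius <= 0:
            raise ValueError("vdw_radius must be positive")

    def moved_to(self, position: np.ndarray) -> "AtomRecord":
        return replace(self, position=np.asarray(position, dtype=float))


@dataclass(frozen=True)
class Pose:
    """A rigid-body reference frame: origin plus a right-handed orthonormal triad."""

    origin: np.ndarray  # (3,)
    axes: np.ndarray  # (3, 3), rows are the triad

    def __post_init__(self) -> None:
        origin = np.asarray(self.origin, dtype=float)
        axes = np.asarray(self.axes, dtype=float)
        if origin.shape != (3,) or axes.shape != (3, 3):
            raise ValueError("origin must be (3,), axes must be (3, 3)")
        if not np.allclose(axes @ axes.T, np.eye(3), atol=1e-6):
            raise ValueError("axes must be orthonormal")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "axes", axes)

    def anchor_points(self, scale: float = 3.0) -> np.ndarray:
        """Four anchor points (origin + scaled triad tips) for superposition."""
        return np.vstack([self.origin, self.origin + scale * self.axes])


def pose_from_coords(coords: np.ndarray) -> Pose:
    """Principal-axes frame of a point cloud.

    Raises for degenerate (near-collinear) clouds, where the triad is not
    defined by the geometry.
    """
    coords = np.asarray(coords, dtype=float)
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    cov = centered.T @ centered / len(coords)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[0] <= 0 or evals[1] / evals[0] < 1e-6:
        raise ValueError("degenerate (collinear) geometry: no unique pose frame")
    axes = evecs.T.copy()
    # sign convention: dominant component of each axis positive
    for i in range(2):
        if axes[i, np.argmax(np.abs(axes[i]))] < 0:
            axes[i] = -axes[i]
    axes[2] = np.cross(axes[0], axes[1])  # enforce right-handedness
    return Pose(centroid, axes)


@dataclass(frozen=True)
class DrugSpec:
    """A drug molecule: net charge, typed heavy atoms, reference pose."""

    name: str
    net_charge: int
    atoms: tuple[AtomRecord, ...]
    reference_pose: Pose

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("a drug must have at least one atom")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])


def _atoms_from_rdkit(mol, embed_seed: int) -> list[AtomRecord]:
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = embed_seed
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise RuntimeError("3D embedding failed")
    h_counts = {a.GetIdx(): a.GetTotalNumHs(includeNeighbors=True)
                for a in Chem.RemoveHs(mol).GetAtoms()}
    mol = Chem.RemoveHs(mol)
    pt = Chem.GetPeriodicTable()
    conf = mol.GetConformer()
    atoms = []
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        p = conf.GetAtomPosition(i)
        symbol = atom.GetSymbol()
        neighbors = [n.GetSymbol() for n in atom.GetNeighbors()]
        is_polar = symbol in ("N", "O", "S")
        fc = atom.GetFormalCharge()
        atoms.append(AtomRecord(
            atom_id=i,
            element=symbol,
            position=np.array([p.x, p.y, p.z]),
            vdw_radius=pt.GetRvdw(atom.GetAtomicNum()),
            hydrophobic=symbol == "C" and not any(s in ("N", "O") for s in neighbors),
            h_bond_donor=is_polar and h_counts[i] > 0 and fc >= 0,
            h_bond_acceptor=(symbol in ("N", "O") and fc <= 0
                             and not (symbol == "N" and atom.GetIsAromatic()
                                      and h_counts[i] > 0)),
            aromatic=atom.GetIsAromatic(),
            charged=fc != 0,
            formal_charge=fc,
            name=f"{symbol}{i + 1}",
        ))
    return atoms


@lru_cache(maxsize=None)
def _drug_table() -> dict:
    return _load_data("drugs.json")


def builtin_drug_names() -> list[str]:
    return list(_drug_table()["drugs"])


@lru_cache(maxsize=None)
def drug_spec(name: str) -> DrugSpec:
    """A built-in drug by short name (EPI, DOX, MTX, MIT, 5FU, CPT, CP,
    OrangeG) or the tiny ``toy`` test drug."""
    if name == "toy":
        return _toy_drug()
    table = _drug_table()
    try:
        entry = table["drugs"][name]
    except KeyError:
        raise KeyError(f"unknown drug {name!r}; built-ins: "
                       f"{sorted(table['drugs'])} + ['toy']") from None
    from rdkit import Chem

    mol = Chem.MolFromSmiles(entry["smiles"])
    if mol is None:  # pragma: no cover - data file guards this
        raise ValueError(f"bad SMILES for drug {name}")
    if Chem.GetFormalCharge(mol) != entry["net_charge"]:
        raise ValueError(f"drug table inconsistent for {name}: SMILES charge "
                         f"{Chem.GetFormalCharge(mol)} != {entry['net_charge']}")
    atoms = _atoms_from_rdkit(mol, table["embed_seed"])
    pose = pose_from_coords(np.array([a.position for a in atoms]))
    return DrugSpec(name, entry["net_charge"], tuple(atoms), pose)


def _toy_drug() -> DrugSpec:
    """A 4-atom planar synthetic test drug (neutral; one donor, one acceptor)."""
    atoms = (
        AtomRecord(0, "C", np.array([0.0, 0.0, 0.0]), 1.7, hydrophobic=True, name="C1"),
        AtomRecord(1, "C", np.array([1.5, 0.0, 0.0]), 1.7, hydrophobic=True, name="C2"),
        AtomRecord(2, "O", np.array([2.2, 1.1, 0.0]), 1.52, h_bond_acceptor=True, name="O1"),
        AtomRecord(3, "N", np.array([-0.7, 1.2, 0.0]), 1.55, h_bond_donor=True, name="N1"),
    )
    pose = pose_from_coords(np.array([a.position for a in atoms]))
    return DrugSpec("toy", 0, atoms, pose)


# ---------------------------------------------------------------------------
# molecule instances and snapshots
# ---------------------------------------------------------------------------

MOLECULE_KINDS = ("peptide", "drug", "zn", "no3")

NO3_NO_BOND = 1.24  # A


@dataclass
class MoleculeInstance:
    """One molecule in a snapshot: identity, payload and current coordinates."""

    molecule_id: int
    kind: str
    payload: object  # PeptideSequence | DrugSpec | str ion identity
    atoms: list[AtomRecord]

    def __post_init__(self) -> None:
        if self.kind not in MOLECULE_KINDS:
            raise ValueError(f"kind must be one of {MOLECULE_KINDS}")
        if self.kind == "zn":
            if len(self.atoms) != 1 or not self.atoms[0].charged:
                raise ValueError("a Zn2+ ion has exactly one charged atom")
        if self.kind == "no3" and len(self.atoms) != 4:
            raise ValueError("a NO3- ion has exactly 4 atoms")
        if not self.atoms:
            raise ValueError("molecule has no atoms")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    @property
    def label(self) -> str:
        if self.kind == "peptide":
            return str(self.payload)
        if self.kind == "drug":
            return self.payload.name
        return self.kind

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None,
                    about: np.ndarray | None = None) -> "MoleculeInstance":
        """Rigid-body copy; rotation is applied about ``about`` (default centroid)."""
        coords = self.coords
        if rotation is not None:
            pivot = self.centroid if about is None else np.asarray(about, dtype=float)
            coords = (coords - pivot) @ np.asarray(rotation).T + pivot
        if translation is not None:
            coords = coords + np.asarray(translation, dtype=float)
        return MoleculeInstance(
            self.molecule_id, self.kind, self.payload,
            [a.moved_to(c) for a, c in zip(self.atoms, coords)],
        )


def make_zn(molecule_id: int, position: np.ndarray) -> MoleculeInstance:
    atom = AtomRecord(0, "Zn", np.asarray(position, dtype=float), ZN_RADIUS,
                      metal=True, charged=True, formal_charge=ZN_CHARGE, name="ZN")
    return MoleculeInstance(molecule_id, "zn", "Zn2+", [atom])


def make_no3(molecule_id: int, position: np.ndarray) -> MoleculeInstance:
    """Planar nitrate at ``position``; formal charges follow one Lewis structure
    (N +1, two O -1, one O 0 -> net -1)."""
    center = np.asarray(position, dtype=float)
    atoms = [AtomRecord(0, "N", center, 1.55, charged=True, formal_charge=1, name="N")]
    for k, fc in enumerate((-1, -1, 0)):
        angle = 2.0 * np.pi * k / 3.0
        offset = NO3_NO_BOND * np.array([np.cos(angle), np.sin(angle), 0.0])
        atoms.append(AtomRecord(k + 1, "O", center + offset, 1.52,
                                h_bond_acceptor=True, charged=fc != 0,
                                formal_charge=fc, name=f"O{k + 1}"))
    return MoleculeInstance(molecule_id, "no3", "NO3-", atoms)


def make_drug_instance(spec: DrugSpec, molecule_id: int) -> MoleculeInstance:
    return MoleculeInstance(molecule_id, "drug", spec, list(spec.atoms))


@dataclass
class Snapshot:
    """A labelled multi-molecule coordinate frame."""

    molecules: list[MoleculeInstance]
    box: float | None = None  # cubic box edge, A; None = open boundary
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [m.molecule_id for m in self.molecules]
        if len(set(ids)) != len(ids):
            raise ValueError("molecule ids must be unique within a snapshot")

    def __len__(self) -> int:
        return len(self.molecules)

    def molecule(self, molecule_id: int) -> MoleculeInstance:
        for m in self.molecules:
            if m.molecule_id == molecule_id:
                return m
        raise KeyError(f"no molecule with id {molecule_id}")

    def of_kind(self, kind: str) -> list[MoleculeInstance]:
        return [m for m in self.molecules if m.kind == kind]

    def counts(self) -> dict[str, int]:
        out = {k: 0 for k in MOLECULE_KINDS}
        for m in self.molecules:
            out[m.kind] += 1
        return out

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "Snapshot":
        """Rigid-body transform of the whole frame about the global origin."""
        origin = np.zeros(3)
        mols = [m.transformed(rotation, translation, about=origin)
                for m in self.molecules]
        return Snapshot(mols, self.box, dict(self.metadata))

    def atom_table(self) -> "AtomTable":
        return AtomTable.from_molecules(self.molecules)


@dataclass(frozen=True)
class AtomTable:
    """Column-oriented view of a set of molecules, for vectorized geometry."""

    coords: np.ndarray        # (n, 3)
    radii: np.ndarray         # (n,)
    molecule_index: np.ndarray  # (n,) index into `molecule_ids`
    molecule_ids: np.ndarray  # (m,)
    flags: dict[str, np.ndarray]  # boolean columns
    formal_charges: np.ndarray
    elements: np.ndarray

    _FLAGS = ("hydrophobic", "h_bond_donor", "h_bond_acceptor",
              "aromatic", "metal", "charged")

    @classmethod
    def from_molecules(cls, molecules: Sequence[MoleculeInstance]) -> "AtomTable":
        coords, radii, mol_idx, fcs, elements = [], [], [], [], []
        flags = {f: [] for f in cls._FLAGS}
        for i, mol in enumerate(molecules):
            for a in mol.atoms:
                coords.append(a.position)
                radii.append(a.vdw_radius)
                mol_idx.append(i)
                fcs.append(a.formal_charge)
                elements.append(a.element)
                for f in cls._FLAGS:
                    flags[f].append(getattr(a, f))
        return cls(
            coords=np.array(coords, dtype=float).reshape(-1, 3),
            radii=np.array(radii, dtype=float),
            molecule_index=np.array(mol_idx, dtype=int),
            molecule_ids=np.array([m.molecule_id for m in molecules], dtype=int),
            flags={f: np.array(v, dtype=bool) for f, v in flags.items()},
            formal_charges=np.array(fcs, dtype=int),
            elements=np.array(elements, dtype=object),
        )

    def __len__(self) -> int:
        return len(self.radii)


# ---------------------------------------------------------------------------
# composition and neutrality
# ---------------------------------------------------------------------------

class NeutralityError(ValueError):
    """Raised when no charge-neutral nonnegative integer composition exists."""


@dataclass(frozen=True)
class SystemComposition:
    """Component counts of a designed system plus the chemistry they refer to."""

    n_peptides: int
    n_drugs: int
    n_zn: int
    n_no3: int
    peptide: PeptideSequence
    drug: DrugSpec

    def __post_init__(self) -> None:
        for n in (self.n_peptides, self.n_drugs, self.n_zn, self.n_no3):
            if n < 0:
                raise ValueError("counts must be nonnegative")

    @property
    def total_charge(self) -> int:
        return (self.n_peptides * peptide_net_charge(self.peptide)
                + self.n_drugs * self.drug.net_charge
                + ZN_CHARGE * self.n_zn - self.n_no3)

    @property
    def ratio(self) -> tuple[int, int, int]:
        """peptide : drug : Zn counts as given (not reduced)."""
        return (self.n_peptides, self.n_drugs, self.n_zn)

    @classmethod
    def neutral(cls, n_peptides: int, peptide: PeptideSequence, n_drugs: int,
                drug: DrugSpec, min_zn: int = 1) -> "SystemComposition":
        n_zn, n_no3 = solve_neutrality(n_peptides, peptide, n_drugs, drug, min_zn)
        return cls(n_peptides, n_drugs, n_zn, n_no3, peptide, drug)


def solve_neutrality(n_peptides: int, peptide: PeptideSequence, n_drugs: int,
                     drug: DrugSpec, min_zn: int = 1) -> tuple[int, int]:
    """Smallest ion counts giving an exactly neutral system.

    Finds the minimal ``n_zn >= min_zn`` and ``n_no3 >= 0`` with

        n_peptides * q_pep + n_drugs * q_drug + 2 * n_zn - n_no3 = 0.

    ``min_zn`` defaults to 1: every designed system carries at least one Zn2+
    for His coordination and Zn-enhanced fluorescence.  This reproduces the
    designed peptide:drug:Zn ratios — 4:2:1 for the +1 and neutral drugs
    and 4:2:2 for MTX (-2).
    """
    if n_peptides < 0 or n_drugs < 0 or min_zn < 0:
        raise NeutralityError("counts must be nonnegative")
    base = n_peptides * peptide_net_charge(peptide) + n_drugs * drug.net_charge
    # need n_no3 = base + 2 n_zn >= 0, with n_zn minimal
    n_zn = max(min_zn, math.ceil(-base / 2))
    n_no3 = base + 2 * n_zn
    assert n_no3 >= 0
    return n_zn, n_no3
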