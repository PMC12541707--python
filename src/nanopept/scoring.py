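"""Empirical association-energy scoring and surface/shape descriptors.

The scorer is an empirical pairwise function in the spirit of fast docking
scorers: a single attractive Gaussian plus a quadratic steric repulsion on
the inter-atomic *surface* distance, a linear-switch hydrophobic term for
hydrophobic-hydrophobic contacts, a linear-switch hydrogen-bond term for
donor/acceptor contacts, and a separable Gaussian distance well for Zn2+
coordination by histidine imidazole nitrogens and anionic oxygens.  Default
term weights follow the published Vinardo parameterization; the Zn well
(ideal 2.1 A, tolerance 0.4 A) is a radial simplification of directional
metal-coordination scoring.

A molecule's *association free energy* is the sum of all its pair terms with
every other molecule in the snapshot; the mean over drug copies is the
design objective.  Also here: the Zn-coordination census, Shrake-Rupley
solvent-accessible surface area on a deterministic golden-spiral point set,
burial fractions and radius of gyration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .core import AtomRecord, AtomTable, MoleculeInstance, Snapshot

__all__ = [
    "ScoringParams",
    "AssociationEnergy",
    "ZnContact",
    "ZnCoordinationReport",
    "pair_term_energy",
    "association_energy",
    "all_association_energies",
    "mean_drug_association_energy",
    "zn_coordination_census",
    "sasa",
    "molecule_sasa",
    "burial_fraction",
    "radius_of_gyration",
    "sphere_points",
]

TERMS = ("gauss", "repulsion", "hydrophobic", "h_bond", "zn_coordination")


@dataclass(frozen=True)
class ScoringParams:
    """Weights and shape parameters of the empirical scorer.

    Distances for the gauss/repulsion/switch terms are *surface* distances
    d = |r_ab| - R_a - R_b (A); the Zn well and the hard cutoff act on the
    center distance.  Weights are kcal/mol at full term activation.
    """

    gauss_weight: float = -0.045
    gauss_width: float = 0.8
    repulsion_weight: float = 0.8
    hydrophobic_weight: float = -0.035
    hydrophobic_d_on: float = 0.0
    hydrophobic_d_off: float = 2.5
    h_bond_weight: float = -0.6
    h_bond_d_on: float = -0.6
    h_bond_d_off: float = 0.0
    zn_weight: float = -2.0
    zn_ideal: float = 2.1
    zn_tolerance: float = 0.4
    cutoff: float = 8.0

    def __post_init__(self) -> None:
        if self.gauss_width <= 0 or self.zn_tolerance <= 0:
            raise ValueError("widths/tolerances must be positive")
        if not (self.hydrophobic_d_on < self.hydrophobic_d_off):
            raise ValueError("hydrophobic d_on must be < d_off")
        if not (self.h_bond_d_on < self.h_bond_d_off):
            raise ValueError("h_bond d_on must be < d_off")
        if self.cutoff < max(self.hydrophobic_d_off, self.h_bond_d_off):
            raise ValueError("cutoff must be >= the switch d_off distances")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class AssociationEnergy:
    """Per-molecule association free energy with its term breakdown."""

    molecule_id: int
    energy: float  # kcal/mol
    terms: Mapping[str, float]

    def __post_init__(self) -> None:
        if abs(self.energy - sum(self.terms.values())) > 1e-9 * max(1.0, abs(self.energy)):
            raise ValueError("energy must equal the sum of its term breakdown")


def _switch(d: np.ndarray, d_on: float, d_off: float) -> np.ndarray:
    """1 below d_on, 0 above d_off, linear in between."""
    return np.clip((d_off - d) / (d_off - d_on), 0.0, 1.0)


def _zn_eligible(table: AtomTable) -> np.ndarray:
    """Atoms that may coordinate Zn2+: acceptor nitrogens (His imidazole in the
    reduced peptide model) and anionic oxygens (carboxylates, nitrate, drug
    anions)."""
    n_acc = (table.elements == "N") & table.flags["h_bond_acceptor"]
    o_anion = (table.elements == "O") & (table.formal_charges < 0)
    return n_acc | o_anion


def _atom_zn_eligible(a: AtomRecord) -> bool:
    return ((a.element == "N" and a.h_bond_acceptor)
            or (a.element == "O" and a.formal_charge < 0))


def pair_term_energy(a: AtomRecord, b: AtomRecord,
                     params: ScoringParams = ScoringParams()) -> float:
    """Scalar pair energy between two typed atoms (kcal/mol).

    Exactly zero when the center distance exceeds the hard cutoff.
    """
    r = float(np.linalg.norm(a.position - b.position))
    if r > params.cutoff:
        return 0.0
    d = r - a.vdw_radius - b.vdw_radius
    e = params.gauss_weight * float(np.exp(-((d / params.gauss_width) ** 2)))
    if d < 0:
        e += params.repulsion_weight * d * d
    if a.hydrophobic and b.hydrophobic:
        e += params.hydrophobic_weight * float(
            _switch(np.array(d), params.hydrophobic_d_on, params.hydrophobic_d_off))
    if (a.h_bond_donor and b.h_bond_acceptor) or (b.h_bond_donor and a.h_bond_acceptor):
        e += params.h_bond_weight * float(
            _switch(np.array(d), params.h_bond_d_on, params.h_bond_d_off))
    if (a.metal and _atom_zn_eligible(b)) or (b.metal and _atom_zn_eligible(a)):
        e += params.zn_weight * float(
            np.exp(-(((r - params.zn_ideal) / params.zn_tolerance) ** 2)))
    return e


def _block_terms(table: AtomTable, idx_a: np.ndarray, idx_b: np.ndarray,
                 params: ScoringParams) -> dict[str, float]:
    """Summed term energies over the atom-index block idx_a x idx_b."""
    pa, pb = table.coords[idx_a], table.coords[idx_b]
    r = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
    within = r <= params.cutoff
    d = r - table.radii[idx_a][:, None] - table.radii[idx_b][None, :]
    out = {}
    gauss = params.gauss_weight * np.exp(-((d / params.gauss_width) ** 2))
    out["gauss"] = float(np.sum(gauss * within))
    rep = params.repulsion_weight * np.where(d < 0, d * d, 0.0)
    out["repulsion"] = float(np.sum(rep * within))

    hyd = table.flags["hydrophobic"]
    mask = hyd[idx_a][:, None] & hyd[idx_b][None, :] & within
    out["hydrophobic"] = float(params.hydrophobic_weight * np.sum(
        _switch(d, params.hydrophobic_d_on, params.hydrophobic_d_off) * mask))

    don, acc = table.flags["h_bond_donor"], table.flags["h_bond_acceptor"]
    mask = ((don[idx_a][:, None] & acc[idx_b][None, :])
            | (acc[idx_a][:, None] & don[idx_b][None, :])) & within
    out["h_bond"] = float(params.h_bond_weight * np.sum(
        _switch(d, params.h_bond_d_on, params.h_bond_d_off) * mask))

    met, elig = table.flags["metal"], _zn_eligible(table)
    mask = ((met[idx_a][:, None] & elig[idx_b][None, :])
            | (elig[idx_a][:, None] & met[idx_b][None, :])) & within
    out["zn_coordination"] = float(params.zn_weight * np.sum(
        np.exp(-(((r - params.zn_ideal) / params.zn_tolerance) ** 2)) * mask))
    return out


def association_energy(molecule_id: int, snapshot: Snapshot,
                       params: ScoringParams = ScoringParams()) -> AssociationEnergy:
    """Association free energy of one molecule with the rest of the snapshot."""
    table = snapshot.atom_table()
    mol_pos = list(table.molecule_ids).index(snapshot.molecule(molecule_id).molecule_id)
    own = np.flatnonzero(table.molecule_index == mol_pos)
    other = np.flatnonzero(table.molecule_index != mol_pos)
    if len(other) == 0:
        terms = {t: 0.0 for t in TERMS}
    else:
        terms = _block_terms(table, own, other, params)
    return AssociationEnergy(molecule_id, sum(terms.values()), terms)


def all_association_energies(snapshot: Snapshot,
                             params: ScoringParams = ScoringParams(),
                             ) -> dict[int, AssociationEnergy]:
    """Association energies of every molecule, computed from each unordered
    molecule pair once (each pair contributes to both partners)."""
    table = snapshot.atom_table()
    n_mol = len(table.molecule_ids)
    atom_idx = [np.flatnonzero(table.molecule_index == i) for i in range(n_mol)]
    centroids = np.array([table.coords[ix].mean(axis=0) for ix in atom_idx])
    extents = np.array([
        0.0 if len(ix) == 1 else
        np.max(np.linalg.norm(table.coords[ix] - centroids[i], axis=1))
        for i, ix in enumerate(atom_idx)])
    totals = [{t: 0.0 for t in TERMS} for _ in range(n_mol)]
    tree = cKDTree(centroids)
    reach = params.cutoff + 2 * float(extents.max(initial=0.0))
    for i, j in tree.query_pairs(r=reach):
        terms = _block_terms(table, atom_idx[i], atom_idx[j], params)
        for t, v in terms.items():
            totals[i][t] += v
            totals[j][t] += v
    return {
        int(mid): AssociationEnergy(int(mid), sum(tt.values()), tt)
        for mid, tt in zip(table.molecule_ids, totals)
    }


def mean_drug_association_energy(snapshot: Snapshot,
                                 params: ScoringParams = ScoringParams()) -> float:
    """Arithmetic mean association free energy over all drug copies
    (kcal/mol) — the sequence-design objective."""
    drugs = snapshot.of_kind("drug")
    if not drugs:
        raise ValueError("no drug molecules in snapshot")
    energies = all_association_energies(snapshot, params)
    return float(np.mean([energies[m.molecule_id].energy for m in drugs]))


# ---------------------------------------------------------------------------
# Zn coordination census
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ZnContact:
    zn_molecule_id: int
    partner_molecule_id: int
    partner_kind: str
    atom_name: str
    category: str  # his_nitrogen | carboxylate_oxygen | nitrate_oxygen | drug_anion | other
    distance: float


@dataclass(frozen=True)
class ZnCoordinationReport:
    """Per-Zn coordination partners and the fraction of His-coordinated Zn."""

    contacts: tuple[ZnContact, ...]
    n_zn: int
    cutoff: float
    percent_his_coordinated: float | None  # None when the snapshot has no Zn

    def contacts_of(self, zn_molecule_id: int) -> list[ZnContact]:
        return [c for c in self.contacts if c.zn_molecule_id == zn_molecule_id]


def _contact_category(mol: MoleculeInstance, atom: AtomRecord) -> str:
    if mol.kind == "peptide" and atom.element == "N" and atom.h_bond_acceptor:
        return "his_nitrogen"
    if mol.kind == "peptide" and atom.element == "O" and atom.formal_charge < 0:
        return "carboxylate_oxygen"
    if mol.kind == "no3":
        return "nitrate_oxygen"
    if mol.kind == "drug" and atom.formal_charge < 0:
        return "drug_anion"
    return "other"


def zn_coordination_census(snapshot: Snapshot, cutoff: float = 3.0) -> ZnCoordinationReport:
    """Census of Zn2+ coordination partners within ``cutoff`` (A).

    Eligible partners are His imidazole nitrogens, carboxylate oxygens,
    nitrate oxygens and anionic drug atoms; the summary statistic is the
    percentage of Zn ions touching at least one His nitrogen.
    """
    zns = snapshot.of_kind("zn")
    contacts: list[ZnContact] = []
    his_bound = 0
    for zn in zns:
        zpos = zn.atoms[0].position
        bound_his = False
        for mol in snapshot.molecules:
            if mol.molecule_id == zn.molecule_id:
                continue
            for atom in mol.atoms:
                if not _atom_zn_eligible(atom):
                    continue
                dist = float(np.linalg.norm(atom.position - zpos))
                if dist <= cutoff:
                    cat = _contact_category(mol, atom)
                    contacts.append(ZnContact(zn.molecule_id, mol.molecule_id,
                                              mol.kind, atom.name, cat, dist))
                    bound_his = bound_his or cat == "his_nitrogen"
        his_bound += bound_his
    percent = None if not zns else 100.0 * his_bound / len(zns)
    return ZnCoordinationReport(tuple(contacts), len(zns), cutoff, percent)


# ---------------------------------------------------------------------------
# SASA, burial, radius of gyration
# ---------------------------------------------------------------------------

def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral unit-sphere quadrature points, shape (n, 3)."""
    k = np.arange(n, dtype=float)
    phi = np.arccos(1.0 - 2.0 * (k + 0.5) / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def _atom_sasa(table: AtomTable, subset_atoms: np.ndarray, probe: float,
               points: np.ndarray) -> np.ndarray:
    """Shrake-Rupley accessible area per atom of ``subset_atoms`` against the
    full table context."""
    n_pts = len(points)
    expanded = table.radii + probe
    tree = cKDTree(table.coords)
    out = np.zeros(len(subset_atoms))
    max_r = float(expanded.max())
    for k, i in enumerate(subset_atoms):
        r_i = expanded[i]
        neighbors = tree.query_ball_point(table.coords[i], r_i + max_r)
        neighbors = [j for j in neighbors if j != i
                     and np.linalg.norm(table.coords[j] - table.coords[i])
                     < r_i + expanded[j]]
        pts = table.coords[i] + r_i * points
        if neighbors:
            nb = np.asarray(neighbors)
            d = np.linalg.norm(pts[:, None, :] - table.coords[nb][None, :, :], axis=-1)
            accessible = np.all(d >= expanded[nb][None, :], axis=1)
        else:
            accessible = np.ones(n_pts, dtype=bool)
        out[k] = 4.0 * np.pi * r_i * r_i * accessible.mean()
    return out


def sasa(snapshot: Snapshot, subset: Iterable[int] | None = None,
         probe_radius: float = 1.4, n_points: int = 960,
         ) -> tuple[dict[int, float], float]:
    """Solvent-accessible surface area (A^2) per molecule and in total.

    ``subset`` selects the molecules whose areas are reported; every atom in
    the snapshot still occludes.  Uses Shrake-Rupley quadrature with a
    deterministic golden-spiral point set (``n_points`` per atom, >= 100).
    """
    if n_points < 100:
        raise ValueError("n_points must be >= 100 for a meaningful quadrature")
    all_ids = [m.molecule_id for m in snapshot.molecules]
    ids = all_ids if subset is None else list(subset)
    if not ids:
        raise ValueError("empty molecule subset")
    table = snapshot.atom_table()
    pts = sphere_points(n_points)
    id_to_pos = {mid: i for i, mid in enumerate(table.molecule_ids)}
    per_molecule: dict[int, float] = {}
    for mid in ids:
        atoms = np.flatnonzero(table.molecule_index == id_to_pos[mid])
        per_molecule[int(mid)] = float(_atom_sasa(table, atoms, probe_radius, pts).sum())
    return per_molecule, float(sum(per_molecule.values()))


def molecule_sasa(molecule: MoleculeInstance, probe_radius: float = 1.4,
                  n_points: int = 960) -> float:
    """SASA of a molecule in isolation (its own atoms as sole context)."""
    snap = Snapshot([molecule])
    per, total = sasa(snap, probe_radius=probe_radius, n_points=n_points)
    return total


def burial_fraction(molecule_id: int, snapshot: Snapshot, probe: float = 1.4,
                    n_points: int = 960) -> float:
    """SASA in the assembly divided by SASA in isolation; 1 = fully exposed."""
    mol = snapshot.molecule(molecule_id)
    alone = molecule_sasa(mol, probe, n_points)
    if alone <= 0:
        raise ValueError(f"molecule {molecule_id} has zero isolated SASA "
                         "(degenerate geometry)")
    per, _ = sasa(snapshot, [molecule_id], probe, n_points)
    return per[molecule_id] / alone


def radius_of_gyration(source: MoleculeInstance | Sequence[AtomRecord] | np.ndarray,
                       masses: np.ndarray | None = None) -> float:
    """Radius of gyration (A) about the centroid; mass-unweighted by default."""
    if isinstance(source, MoleculeInstance):
        coords = source.coords
    elif isinstance(source, np.ndarray):
        coords = np.asarray(source, dtype=float).reshape(-1, 3)
    else:
        coords = np.array([a.position for a in source])
    if len(coords) == 0:
        raise ValueError("need at least one atom")
    w = np.ones(len(coords)) if masses is None else np.asarray(masses, dtype=float)
    w = w / w.sum()
    center = (coords * w[:, None]).sum(axis=0)
    return float(np.sqrt(np.sum(w * np.sum((coords - center) ** 2, axis=1))))
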