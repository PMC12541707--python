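"""Assembly builders and fixture generators.

Peptides use a reduced representation: an acetyl cap carbon, backbone N, CA,
C, O per residue, one typed side-chain pseudo-atom per residue, and a
terminal carboxylate oxygen (or amide nitrogen).  Strands are built on an
idealized extended geometry whose hydrogen-bonding faces are laid out so
that two strands placed at the default 4.8 A inter-strand spacing form an
exact antiparallel beta pair (N...O about 2.9 A).

Builders:

* ``build_ips`` — ordered "initially prepared scaffold": stacked pocket
  units of one drug sandwiched between two antiparallel peptide pairs, with
  Zn2+ at coordination distance from His imidazoles and NO3- completing
  charge neutrality.  Purely deterministic.
* ``build_ses_like`` — compact, partially disordered variant: seeded
  rigid-body jitter plus centroid compaction with an overlap guard.
* ``generate_random_snapshot`` — dispersed random arrangements at the
  designed component ratio (early-stage co-assembly starting states).
* ``plant_clusters`` — spatially separated aggregates with known
  ground-truth membership, for validating cluster detection.
* ``superpose_drug`` — rigid-body least-squares placement of a drug onto a
  reference pose frame (Kabsch).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .core import (
    AtomRecord,
    DrugSpec,
    MoleculeInstance,
    PeptideSequence,
    Pose,
    Snapshot,
    SystemComposition,
    _residue_table,
    make_drug_instance,
    make_no3,
    make_zn,
)

__all__ = [
    "PocketGeometry",
    "ScaffoldSpec",
    "build_peptide",
    "build_ips",
    "build_ses_like",
    "superpose_drug",
    "generate_random_snapshot",
    "plant_clusters",
    "PackingError",
]


class PackingError(RuntimeError):
    """Raised when a random placement cannot satisfy its distance constraints."""


# ---------------------------------------------------------------------------
# peptide geometry
# ---------------------------------------------------------------------------

_RESIDUE_PITCH = 3.4   # A along the strand axis per residue
_CARBONYL_Y = 1.2      # A lateral offset of the carbonyl O from the strand axis
_AMIDE_Y = 0.7         # A lateral inset of N, opposite its residue's carbonyl
_PLEAT_Z = 0.6         # A CA pleat amplitude
_SC_STICKOUT = 1.9     # A side-chain pseudo-atom offset beyond CA
# antiparallel partner at spacing S gives N...O = S - _CARBONYL_Y - _AMIDE_Y


def _strand_template(seq: PeptideSequence) -> list[AtomRecord]:
    """Extended-strand reduced-representation atoms for one peptide at the
    origin, axis along +x, hydrogen-bonding carbonyls alternating in +/-y."""
    table = _residue_table()
    atoms: list[AtomRecord] = []
    aid = 0

    def add(element, pos, radius, name, **flags):
        nonlocal aid
        atoms.append(AtomRecord(aid, element, np.asarray(pos, float), radius,
                                name=name, **flags))
        aid += 1

    # acetyl cap (methyl carbon stand-in)
    add("C", [-1.6, 0.0, 0.0], 1.7, "CAY", hydrophobic=True)
    for i, res in enumerate(seq.residues):
        s = 1.0 if i % 2 == 0 else -1.0
        x = _RESIDUE_PITCH * i
        entry = table[res.one_letter_code]["side_chain"]
        add("N", [x, -_AMIDE_Y * s, 0.0], 1.55, "N", h_bond_donor=True)
        add("C", [x + 1.15, 0.0, _PLEAT_Z * s], 1.7, "CA")
        add("C", [x + 2.3, 0.0, 0.0], 1.7, "C")
        add("O", [x + 2.3, _CARBONYL_Y * s, 0.0], 1.52, "O", h_bond_acceptor=True)
        add(entry["element"],
            [x + 1.15, 0.0, (_PLEAT_Z + _SC_STICKOUT) * s],
            entry["radius"], "CB",
            hydrophobic=entry["hydrophobic"],
            h_bond_donor=entry["h_bond_donor"],
            h_bond_acceptor=entry["h_bond_acceptor"],
            aromatic=entry["aromatic"],
            charged=entry["charged"],
            formal_charge=entry["formal_charge"])
    x_end = _RESIDUE_PITCH * 3 + 2.3
    if seq.termini.c_terminus == "carboxylate":
        add("O", [x_end + 1.0, -0.8, 0.0], 1.52, "OXT",
            h_bond_acceptor=True, charged=True, formal_charge=-1)
    else:
        add("N", [x_end + 1.0, -0.8, 0.0], 1.55, "NT", h_bond_donor=True)
    return atoms


def build_peptide(seq: PeptideSequence, molecule_id: int,
                  rotation: np.ndarray | None = None,
                  translation: np.ndarray | None = None) -> MoleculeInstance:
    """One reduced-representation peptide in extended conformation."""
    mol = MoleculeInstance(molecule_id, "peptide", seq, _strand_template(seq))
    if rotation is not None or translation is not None:
        mol = mol.transformed(rotation, translation, about=np.zeros(3))
    return mol


def _antiparallel_partner(mol: MoleculeInstance, spacing: float) -> np.ndarray:
    """Transform template coords into the antiparallel H-bond partner: 180
    degrees about z through the backbone mid-plane, then +y by ``spacing``."""
    cx = (_RESIDUE_PITCH * 3 + 2.3) / 2.0
    coords = mol.coords.copy()
    coords[:, 0] = 2.0 * cx - coords[:, 0]
    coords[:, 1] = spacing - coords[:, 1]
    return coords


# ---------------------------------------------------------------------------
# ordered assemblies (IPS) and their perturbed variants (SES-like)
# ---------------------------------------------------------------------------

def _drug_clearance(drug_xy: np.ndarray, drug_z: np.ndarray,
                    drug_radii: np.ndarray, layer_coords: np.ndarray,
                    layer_radii: np.ndarray, gap: float) -> tuple[float, float]:
    """Vertical clearances for a drug sandwiched between two parallel copies
    of a peptide layer.

    Returns ``(z_lo, z_hi)``: the minimum height of the drug frame origin
    above the lower layer, and the minimum extra separation to the upper
    layer, so that every drug/peptide atom pair keeps a surface gap >= ``gap``.
    """
    dxy2 = np.sum((drug_xy[:, None, :] - layer_coords[None, :, :2]) ** 2, axis=-1)
    s2 = (drug_radii[:, None] + layer_radii[None, :] + gap) ** 2 - dxy2
    s = np.sqrt(np.maximum(s2, 0.0))
    active = s2 > 0
    dz = layer_coords[None, :, 2] - drug_z[:, None]
    z_lo = float(np.max(np.where(active, dz + s, 0.0), initial=0.0))
    z_hi = float(np.max(np.where(active, -dz + s, 0.0), initial=0.0))
    return z_lo, z_hi


@dataclass(frozen=True)
class PocketGeometry:
    """Geometry of one pocket unit (all lengths in A)."""

    inter_strand_spacing: float = 4.8
    layer_separation: float = 10.0
    unit_gap: float = 4.0   # gap between successive pocket units along x
    zn_distance: float = 2.1
    no3_offset: float = 4.0  # nitrate distance from its Zn


@dataclass(frozen=True)
class ScaffoldSpec:
    """What to build: ordered (IPS) or perturbed-compact (SES-like)."""

    kind: str = "IPS"
    n_pocket_units: int = 1
    min_zn: int = 1
    geometry: PocketGeometry = PocketGeometry()
    perturbation: float = 0.0   # A, SES-like only
    compaction: float = 1.0     # SES-like only
    seed: int = 0               # SES-like only

    def __post_init__(self) -> None:
        if self.kind not in ("IPS", "SES-like"):
            raise ValueError("kind must be 'IPS' or 'SES-like'")
        if self.kind == "IPS" and self.perturbation != 0.0:
            raise ValueError("IPS scaffolds are unperturbed by definition")
        if self.n_pocket_units < 1:
            raise ValueError("need at least one pocket unit")
        if not (0.0 < self.compaction <= 1.0):
            raise ValueError("compaction must be in (0, 1]")


def build_ips(spec: ScaffoldSpec, seq: PeptideSequence, drug: DrugSpec) -> Snapshot:
    """Deterministic ordered assembly with the pocket architecture.

    Each pocket unit holds one drug between two layers; each layer is an
    antiparallel peptide pair, and the two layers are parallel copies of one
    another.  Zn2+ ions sit at coordination distance from His side-chain
    imidazole pseudo-atoms; NO3- counter-ions complete exact neutrality
    (composition from the charge solver with ``spec.min_zn``).
    """
    geo = spec.geometry
    n_units = spec.n_pocket_units
    comp = SystemComposition.neutral(4 * n_units, seq, n_units, drug, spec.min_zn)

    template = build_peptide(seq, 0)
    pair0 = template.coords
    pair1 = _antiparallel_partner(template, geo.inter_strand_spacing)
    unit_width = (_RESIDUE_PITCH * 3 + 2.3) + 2.6 + geo.unit_gap

    # drug geometry in its principal frame (long axis -> x, thin axis -> z)
    pose0 = drug.reference_pose
    drug_local = (drug.coords - pose0.origin) @ pose0.axes.T
    drug_radii = np.array([a.vdw_radius for a in drug.atoms])
    # layer separation: at least the default, expanded so that every
    # drug/peptide atom pair keeps a positive vdW surface gap
    layer_coords = np.vstack([pair0, pair1])
    layer_radii = np.tile(np.array([a.vdw_radius for a in template.atoms]), 2)
    drug_xy = drug_local[:, :2] + np.array([
        (_RESIDUE_PITCH * 3 + 2.3) / 2.0, geo.inter_strand_spacing / 2.0])
    z_lo, _ = _drug_clearance(drug_xy, drug_local[:, 2], drug_radii,
                              layer_coords, layer_radii, gap=0.3)
    # the upper layer is the z-mirror of the lower one (side chains point
    # outward on both faces), so its clearance uses negated layer z
    mirrored = layer_coords * np.array([1.0, 1.0, -1.0])
    _, z_hi = _drug_clearance(drug_xy, drug_local[:, 2], drug_radii,
                              mirrored, layer_radii, gap=0.3)
    layer_sep = max(geo.layer_separation, z_lo + z_hi)

    molecules: list[MoleculeInstance] = []
    his_sites: list[tuple[np.ndarray, np.ndarray]] = []  # (SC pos, CA pos)
    mid = 0
    for u in range(n_units):
        shift = np.array([u * unit_width, 0.0, 0.0])
        for layer in range(2):
            dz = np.array([0.0, 0.0, layer * layer_sep])
            flip = np.array([1.0, 1.0, -1.0]) if layer == 1 else np.ones(3)
            for coords in (pair0, pair1):
                mol = MoleculeInstance(mid, "peptide", seq,
                                       [a.moved_to(c * flip + shift + dz)
                                        for a, c in zip(template.atoms, coords)])
                molecules.append(mol)
                mid += 1
                names = [a.name for a in mol.atoms]
                sc = mol.atoms[len(names) - 1 - names[::-1].index("CB")]
                ca_i = max(i for i, n in enumerate(names) if n == "CA")
                his_sites.append((sc.position, mol.atoms[ca_i].position))
        # drug centered between the layers, principal axes aligned to the
        # pocket: long axis along the strands (x), thin axis across the
        # layer gap (z)
        z_center = float(np.clip(layer_sep / 2.0, z_lo, layer_sep - z_hi))
        center = np.array([
            shift[0] + (_RESIDUE_PITCH * 3 + 2.3) / 2.0,
            geo.inter_strand_spacing / 2.0,
            z_center,
        ])
        coords = drug_local + center
        molecules.append(MoleculeInstance(
            mid, "drug", drug,
            [a.moved_to(c) for a, c in zip(drug.atoms, coords)]))
        mid += 1

    # Zn at coordination distance along each His CA->SC direction, outward
    zn_sites: list[tuple[np.ndarray, np.ndarray]] = []  # (position, outward dir)
    for sc, ca in his_sites[:comp.n_zn]:
        direction = sc - ca
        direction /= np.linalg.norm(direction)
        zn_sites.append((sc + geo.zn_distance * direction, direction))
    if comp.n_zn > len(his_sites):
        # overflow Zn (not the designed regime): line them up clear of the unit
        down = np.array([0.0, 0.0, -1.0])
        for k in range(comp.n_zn - len(his_sites)):
            zn_sites.append((np.array([-8.0 - 4.0 * k, -8.0, -8.0]), down))
    for zpos, _d in zn_sites:
        molecules.append(make_zn(mid, zpos))
        mid += 1
    # nitrates continue outward along their Zn's His->Zn axis, stacked when
    # several share one Zn
    for k in range(comp.n_no3):
        if zn_sites:
            anchor, direction = zn_sites[k % len(zn_sites)]
            distance = geo.no3_offset * (1 + k // len(zn_sites))
        else:
            anchor, direction = np.zeros(3), np.array([0.0, 0.0, -1.0])
            distance = geo.no3_offset * (1 + k)
        molecules.append(make_no3(mid, anchor + distance * direction))
        mid += 1

    snap = Snapshot(molecules, metadata={
        "builder": "ips", "sequence": seq.sequence,
        "c_terminus": seq.termini.c_terminus, "drug": drug.name,
        "n_pocket_units": n_units,
        "composition": {"n_peptides": comp.n_peptides, "n_drugs": comp.n_drugs,
                        "n_zn": comp.n_zn, "n_no3": comp.n_no3},
    })
    return snap


def _random_rotation(rng: np.random.Generator, max_angle: float | None = None) -> np.ndarray:
    if max_angle is None:
        return Rotation.random(random_state=rng).as_matrix()
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.0, max_angle)
    return Rotation.from_rotvec(angle * axis).as_matrix()


def _guard_radii(mol: MoleculeInstance) -> np.ndarray:
    """Steric-guard radii: metals count at 45% of vdW, since Zn coordination
    bonds (about 2.1 A to N/O) are legitimately sub-vdW contacts."""
    return np.array([a.vdw_radius * (0.45 if a.metal else 1.0)
                     for a in mol.atoms])


def _min_gap_ok(placed_tree: cKDTree | None, placed_radii: np.ndarray,
                coords: np.ndarray, radii: np.ndarray, factor: float) -> bool:
    """True if no atom pair comes below factor * (r_i + r_j)."""
    if placed_tree is None:
        return True
    rmax = placed_radii.max()
    for c, r in zip(coords, radii):
        for j in placed_tree.query_ball_point(c, factor * (r + rmax)):
            d = np.linalg.norm(placed_tree.data[j] - c)
            if d < factor * (r + placed_radii[j]):
                return False
    return True


def build_ses_like(ips: Snapshot, perturbation: float, compaction: float,
                   seed: int, max_retries: int = 200) -> Snapshot:
    """Compact, partially disordered variant of an ordered assembly.

    Molecule centroids are scaled toward the global centroid by
    ``compaction``; each molecule then receives a seeded random rigid-body
    jitter (translation bounded by ``perturbation`` A, rotation bounded by
    0.15 rad per A of perturbation).  Placements violating the steric guard
    (atom-pair distance >= 0.7 x sum of radii) are retried.
    """
    if perturbation < 0:
        raise ValueError("perturbation must be >= 0")
    if not (0.0 < compaction <= 1.0):
        raise ValueError("compaction must be in (0, 1]")
    if perturbation == 0.0 and compaction == 1.0:
        return Snapshot([m.transformed() for m in ips.molecules], ips.box,
                        {**ips.metadata, "builder": "ses"})
    rng = np.random.default_rng(seed)
    global_center = np.mean([m.centroid for m in ips.molecules], axis=0)
    placed: list[MoleculeInstance] = []
    placed_coords: list[np.ndarray] = []
    placed_radii: list[np.ndarray] = []
    for mol in ips.molecules:
        target = global_center + compaction * (mol.centroid - global_center)
        ok = False
        for _ in range(max_retries):
            jitter = rng.normal(size=3)
            norm = np.linalg.norm(jitter)
            jitter = jitter / norm * rng.uniform(0, perturbation) if norm > 0 else jitter
            rot = _random_rotation(rng, 0.15 * perturbation)
            cand = mol.transformed(rot, target + jitter - mol.centroid)
            tree = cKDTree(np.vstack(placed_coords)) if placed_coords else None
            radii_flat = np.concatenate(placed_radii) if placed_radii else np.empty(0)
            cand_radii = _guard_radii(cand)
            if _min_gap_ok(tree, radii_flat, cand.coords, cand_radii, 0.7):
                placed.append(cand)
                placed_coords.append(cand.coords)
                placed_radii.append(_guard_radii(cand))
                ok = True
                break
        if not ok:
            raise PackingError(
                f"could not place molecule {mol.molecule_id} without steric "
                f"overlap after {max_retries} retries (compaction too strong?)")
    return Snapshot(placed, ips.box, {**ips.metadata, "builder": "ses",
                                      "perturbation": perturbation,
                                      "compaction": compaction, "seed": seed})


# ---------------------------------------------------------------------------
# drug superposition
# ---------------------------------------------------------------------------

def superpose_drug(drug: DrugSpec, reference: Pose | MoleculeInstance,
                   molecule_id: int = 0) -> tuple[MoleculeInstance, float]:
    """Rigid-body least-squares placement of a drug onto a reference frame.

    The drug's own pose frame (origin + triad anchor points) is aligned onto
    the reference frame's anchors by the optimal rotation + translation
    (Kabsch); returns the placed molecule and the anchor-point RMSD.
    ``reference`` may be another molecule carrying a DrugSpec payload, in
    which case its current principal-axes frame is the target.
    """
    if isinstance(reference, MoleculeInstance):
        from .core import pose_from_coords
        ref_pose = pose_from_coords(reference.coords)
    else:
        ref_pose = reference
    src = drug.reference_pose.anchor_points()
    dst = ref_pose.anchor_points()
    src_c, dst_c = src.mean(axis=0), dst.mean(axis=0)
    rot, rssd = Rotation.align_vectors(dst - dst_c, src - src_c)
    rmsd = float(rssd / math.sqrt(len(src)))
    R = rot.as_matrix()
    coords = (drug.coords - src_c) @ R.T + dst_c
    mol = MoleculeInstance(molecule_id, "drug", drug,
                           [a.moved_to(c) for a, c in zip(drug.atoms, coords)])
    return mol, rmsd


# ---------------------------------------------------------------------------
# random-arrangement and planted-cluster fixtures
# ---------------------------------------------------------------------------

def _component_templates(comp: SystemComposition) -> list[tuple[str, MoleculeInstance]]:
    out = []
    pep = build_peptide(comp.peptide, 0)
    for _ in range(comp.n_peptides):
        out.append(("peptide", pep))
    drug = make_drug_instance(comp.drug, 0)
    for _ in range(comp.n_drugs):
        out.append(("drug", drug))
    for _ in range(comp.n_zn):
        out.append(("zn", make_zn(0, np.zeros(3))))
    for _ in range(comp.n_no3):
        out.append(("no3", make_no3(0, np.zeros(3))))
    return out


def _scaled_composition(comp: SystemComposition, n_copies: int) -> SystemComposition:
    return SystemComposition(comp.n_peptides * n_copies, comp.n_drugs * n_copies,
                             comp.n_zn * n_copies, comp.n_no3 * n_copies,
                             comp.peptide, comp.drug)


def generate_random_snapshot(composition: SystemComposition, n_copies: int = 1,
                             box: float = 60.0, min_separation: float = 5.0,
                             seed: int = 0, max_retries: int = 2000) -> Snapshot:
    """Dispersed random arrangement at the designed component ratio.

    All components of ``composition`` (scaled by ``n_copies``) are placed
    with seeded random orientation and position inside a cubic box of edge
    ``box`` A, keeping every inter-molecule atom distance >= ``min_separation``.
    """
    comp = _scaled_composition(composition, n_copies)
    templates = _component_templates(comp)
    # coarse feasibility check: excluded-sphere volume must fit in the box
    r_eff = [np.max(np.linalg.norm(t.coords - t.centroid, axis=1))
             + min_separation / 2.0 for _, t in templates]
    occupancy = sum((4.0 / 3.0) * np.pi * r ** 3 for r in r_eff)
    if occupancy > 0.35 * box ** 3:
        raise PackingError(
            f"box {box} A too small for {len(templates)} molecules at "
            f"min_separation {min_separation} A")
    rng = np.random.default_rng(seed)
    molecules: list[MoleculeInstance] = []
    coords_list: list[np.ndarray] = []
    for mid, (kind, template) in enumerate(templates):
        for attempt in range(max_retries):
            rot = _random_rotation(rng)
            pos = rng.uniform(0.0, box, size=3)
            cand = MoleculeInstance(mid, kind, template.payload, template.atoms)
            cand = cand.transformed(rot, pos - template.centroid)
            if coords_list:
                tree = cKDTree(np.vstack(coords_list))
                d, _ = tree.query(cand.coords, k=1)
                if d.min() < min_separation:
                    continue
            molecules.append(cand)
            coords_list.append(cand.coords)
            break
        else:
            raise PackingError(f"failed to place molecule {mid} after "
                               f"{max_retries} attempts")
    return Snapshot(molecules, box=box, metadata={
        "builder": "random", "seed": seed, "min_separation": min_separation,
        "ratio": comp.ratio,
    })


def plant_clusters(composition_per_cluster: list[SystemComposition],
                   spacing: float = 40.0, contact_distance: float = 3.5,
                   seed: int = 0, max_retries: int = 500,
                   ) -> tuple[Snapshot, list[set[int]]]:
    """Spatially separated aggregates with known ground-truth membership.

    Cluster centers sit on a cubic grid of pitch ``spacing``; within each
    cluster, molecules are chained so that each touches an already-placed
    member at ``contact_distance`` (minimum atom-pair gap) while staying
    clear of everything else.  Returns the snapshot and, per cluster, the
    set of member molecule ids.
    """
    rng = np.random.default_rng(seed)
    molecules: list[MoleculeInstance] = []
    truth: list[set[int]] = []
    mid = 0
    n_side = max(1, math.ceil(len(composition_per_cluster) ** (1.0 / 3.0)))
    for c_idx, comp in enumerate(composition_per_cluster):
        center = spacing * np.array([c_idx % n_side, (c_idx // n_side) % n_side,
                                     c_idx // (n_side * n_side)], dtype=float)
        members: set[int] = set()
        cluster_mols: list[MoleculeInstance] = []
        for kind, template in _component_templates(comp):
            placed = None
            for _ in range(max_retries):
                rot = _random_rotation(rng)
                cand = MoleculeInstance(mid, kind, template.payload, template.atoms)
                if not cluster_mols:
                    cand = cand.transformed(rot, center - template.centroid)
                    placed = cand
                    break
                anchor = cluster_mols[rng.integers(len(cluster_mols))]
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                cand0 = cand.transformed(rot, anchor.centroid - template.centroid)
                # slide outward until the min gap to the anchor equals the target
                lo, hi = 0.0, 60.0
                tree = cKDTree(anchor.coords)
                for _ in range(40):
                    t = 0.5 * (lo + hi)
                    d, _i = tree.query(cand0.coords + t * direction, k=1)
                    if d.min() < contact_distance:
                        lo = t
                    else:
                        hi = t
                cand = cand0.transformed(translation=hi * direction)
                others = [m for m in cluster_mols if m is not anchor]
                if others:
                    otree = cKDTree(np.vstack([m.coords for m in others]))
                    d, _i = otree.query(cand.coords, k=1)
                    if d.min() < 0.8 * contact_distance:
                        continue
                placed = cand
                break
            if placed is None:
                raise PackingError(f"failed to grow cluster {c_idx}")
            cluster_mols.append(placed)
            members.add(mid)
            mid += 1
        molecules.extend(cluster_mols)
        truth.append(members)
    snap = Snapshot(molecules, metadata={"builder": "planted", "seed": seed,
                                         "spacing": spacing,
                                         "contact_distance": contact_distance})
    return snap, truth
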