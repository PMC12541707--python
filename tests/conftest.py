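"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's accelerated code paths: cluster
detection is re-derived with a dense distance matrix plus BFS, association
energies with a scalar double loop over atom pairs, and mediation with raw
triple enumeration.
"""

from __future__ import annotations

import numpy as np
import pytest

from nanopept.core import (
    PeptideSequence,
    Snapshot,
    SystemComposition,
    drug_spec,
)
from nanopept.scaffolds import generate_random_snapshot
from nanopept.scoring import ScoringParams, pair_term_energy


@pytest.fixture(scope="session")
def pep_amide() -> PeptideSequence:
    return PeptideSequence.from_string("FFWH", "amide")


@pytest.fixture(scope="session")
def pep_coo() -> PeptideSequence:
    return PeptideSequence.from_string("FFWH", "carboxylate")


@pytest.fixture(scope="session")
def toy_drug():
    return drug_spec("toy")


@pytest.fixture(scope="session")
def toy_composition(pep_amide, toy_drug) -> SystemComposition:
    return SystemComposition.neutral(4, pep_amide, 2, toy_drug, min_zn=1)


def random_toy_snapshot(seed: int, n_copies: int = 2, box: float = 70.0,
                        min_separation: float = 4.0) -> Snapshot:
    """A dispersed peptide/toy-drug/ion snapshot, deterministic in ``seed``."""
    pep = PeptideSequence.from_string("FFWH", "amide")
    comp = SystemComposition.neutral(4, pep, 2, drug_spec("toy"), min_zn=1)
    return generate_random_snapshot(comp, n_copies=n_copies, box=box,
                                    min_separation=min_separation, seed=seed)


@pytest.fixture
def snapshot_factory():
    return random_toy_snapshot


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def min_distance_matrix(snapshot: Snapshot) -> np.ndarray:
    """Dense molecule-by-molecule minimum atom-pair distance matrix."""
    mols = snapshot.molecules
    n = len(mols)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = np.linalg.norm(
                mols[i].coords[:, None, :] - mols[j].coords[None, :, :], axis=-1)
            out[i, j] = out[j, i] = d.min()
    return out


def brute_force_partition(snapshot: Snapshot, cutoff: float) -> set[frozenset[int]]:
    """Connected components by BFS over the dense contact matrix."""
    mols = snapshot.molecules
    n = len(mols)
    dmin = min_distance_matrix(snapshot)
    seen = [False] * n
    partition = set()
    for s in range(n):
        if seen[s]:
            continue
        comp, queue = [], [s]
        seen[s] = True
        while queue:
            u = queue.pop()
            comp.append(u)
            for v in range(n):
                if not seen[v] and dmin[u, v] <= cutoff:
                    seen[v] = True
                    queue.append(v)
        partition.add(frozenset(mols[k].molecule_id for k in comp))
    return partition


def brute_force_association(snapshot: Snapshot, molecule_id: int,
                            params: ScoringParams) -> float:
    """Scalar double loop over all atom pairs (molecule vs rest)."""
    target = snapshot.molecule(molecule_id)
    total = 0.0
    for other in snapshot.molecules:
        if other.molecule_id == molecule_id:
            continue
        for a in target.atoms:
            for b in other.atoms:
                total += pair_term_energy(a, b, params)
    return total


def brute_force_pair_sum(snapshot: Snapshot, params: ScoringParams) -> float:
    """Sum of pair terms over unordered intermolecular molecule pairs."""
    mols = snapshot.molecules
    total = 0.0
    for i in range(len(mols)):
        for j in range(i + 1, len(mols)):
            for a in mols[i].atoms:
                for b in mols[j].atoms:
                    total += pair_term_energy(a, b, params)
    return total


def brute_force_mediation(snapshot: Snapshot, cutoff: float) -> tuple[float, float]:
    """(P(drug bridges two peptides), P(... and a Zn)) by raw enumeration."""
    def touching(a, b):
        d = np.linalg.norm(a.coords[:, None, :] - b.coords[None, :, :], axis=-1)
        return d.min() <= cutoff

    drugs = snapshot.of_kind("drug")
    peptides = snapshot.of_kind("peptide")
    zns = snapshot.of_kind("zn")
    if not drugs:
        return 0.0, 0.0
    n2 = n3 = 0
    for d in drugs:
        bridges = False
        for i in range(len(peptides)):
            for j in range(i + 1, len(peptides)):
                if touching(d, peptides[i]) and touching(d, peptides[j]):
                    bridges = True
        zn_touch = any(touching(d, z) for z in zns)
        n2 += bridges
        n3 += bridges and zn_touch
    return n2 / len(drugs), n3 / len(drugs)
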