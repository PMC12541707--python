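"""Evolution-guided "lock & design as you go" sequence optimization.

Each design iteration proposes a single substitution-matrix-guided mutation
at positions 1-3 (position 4 stays His for Zn coordination), evaluates the
mean drug association free energy of the mutated peptide over every
(scaffold, drug-pose) combination, and re-locks the sequence only on strict
improvement.  Per-drug design runs are then cross-referenced: sequences
that every drug's runs visited (or accepted) are *consensus peptides*, and
they are ranked by the consensus energy penalty — the mean, over drugs, of
the energy gap to that drug's best peptide — with an aggregation-propensity
scale as the complementary selection criterion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .core import CANONICAL_RESIDUES, DrugSpec, PeptideSequence, Snapshot, residue_scale
from .scaffolds import ScaffoldSpec, build_ips, build_ses_like
from .scoring import ScoringParams, mean_drug_association_energy

__all__ = [
    "EvolutionModel",
    "HistoryEntry",
    "DesignState",
    "DesignRun",
    "ConsensusTable",
    "Scaffold",
    "default_pose_set",
    "propose_mutation",
    "evaluate_design",
    "run_lock_and_design",
    "find_consensus",
    "consensus_energy_penalty",
    "aggregation_propensity",
    "select_top_designs",
]


# ---------------------------------------------------------------------------
# evolution model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvolutionModel:
    """Row-stochastic residue substitution probabilities with a temperature.

    ``probabilities[a][b]`` is P(replace a by b).  ``temperature`` != 1
    re-normalizes each row after raising it to the power 1/T (T > 1 flattens,
    T < 1 sharpens).
    """

    probabilities: Mapping[str, Mapping[str, float]]
    temperature: float = 1.0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        for a, row in self.probabilities.items():
            total = sum(row.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"row {a!r} sums to {total}, not 1")
            if any(p < 0 for p in row.values()):
                raise ValueError(f"row {a!r} has negative probabilities")

    @classmethod
    def default(cls, temperature: float = 1.0) -> "EvolutionModel":
        """Built-in table: half-bit softmax of a standard substitution matrix
        (shipped as a data file so a different published matrix can be
        dropped in)."""
        with resources.files("nanopept.data").joinpath(
                "substitution_probs.json").open() as fh:
            data = json.load(fh)
        return cls(data["probabilities"], temperature)

    def row(self, code: str, exclude_self: bool = True,
            ) -> tuple[list[str], np.ndarray]:
        """Replacement codes and probabilities for current residue ``code``."""
        raw = self.probabilities[code]
        codes = [c for c in raw if not (exclude_self and c == code)]
        p = np.array([raw[c] for c in codes], dtype=float)
        if self.temperature != 1.0:
            p = p ** (1.0 / self.temperature)
        p = p / p.sum()
        return codes, p


def propose_mutation(seq: PeptideSequence, model: EvolutionModel,
                     rng: np.random.Generator) -> tuple[int, str]:
    """Draw one mutation: position uniform over {1, 2, 3}, replacement from
    the model row of the current residue (self-substitution excluded)."""
    position = int(rng.integers(1, 4))
    current = seq.residues[position - 1].one_letter_code
    codes, p = model.row(current)
    new = codes[int(rng.choice(len(codes), p=p))]
    return position, new


# ---------------------------------------------------------------------------
# scaffolds-as-evaluation-substrate and poses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scaffold:
    """A rebuildable evaluation scaffold.

    ``realize`` threads a candidate sequence onto the scaffold geometry: the
    ordered assembly is rebuilt with the new side-chain identities (the
    reduced-representation backbone is sequence-independent), and SES-like
    scaffolds reapply their stored seeded perturbation so that all candidate
    sequences see the same disorder.
    """

    spec: ScaffoldSpec

    def realize(self, seq: PeptideSequence, drug: DrugSpec) -> Snapshot:
        ips = build_ips(ScaffoldSpec(kind="IPS",
                                     n_pocket_units=self.spec.n_pocket_units,
                                     min_zn=self.spec.min_zn,
                                     geometry=self.spec.geometry), seq, drug)
        if self.spec.kind == "IPS":
            return ips
        return build_ses_like(ips, self.spec.perturbation,
                              self.spec.compaction, self.spec.seed)


def default_pose_set(n_poses: int = 4) -> list[np.ndarray]:
    """A deterministic set of drug orientations (rotation matrices applied
    about each drug's centroid): identity plus evenly spread rotations."""
    if n_poses < 1:
        raise ValueError("need at least one pose")
    poses = [np.eye(3)]
    axes = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0],
                     [1.0, 1.0, 0], [0, 1.0, 1.0], [1.0, 0, 1.0]])
    k = 0
    while len(poses) < n_poses:
        axis = axes[k % len(axes)] / np.linalg.norm(axes[k % len(axes)])
        angle = np.pi * (0.5 + 0.25 * (k // len(axes)))
        poses.append(Rotation.from_rotvec(angle * axis).as_matrix())
        k += 1
    return poses


def _apply_pose(snapshot: Snapshot, pose: np.ndarray) -> Snapshot:
    mols = [m.transformed(pose) if m.kind == "drug" else m
            for m in snapshot.molecules]
    return Snapshot(mols, snapshot.box, dict(snapshot.metadata))


def evaluate_design(seq: PeptideSequence, drug: DrugSpec,
                    scaffolds: Sequence[Scaffold],
                    params: ScoringParams = ScoringParams(),
                    pose_set: Sequence[np.ndarray] | None = None) -> float:
    """Best (minimum) mean drug association energy of a candidate sequence
    over every (scaffold, drug pose) combination, kcal/mol."""
    if not scaffolds:
        raise ValueError("scaffold set is empty")
    poses = list(pose_set) if pose_set is not None else default_pose_set()
    if not poses:
        raise ValueError("pose set is empty")
    best = np.inf
    for scaffold in scaffolds:
        base = scaffold.realize(seq, drug)
        for pose in poses:
            e = mean_drug_association_energy(_apply_pose(base, pose), params)
            best = min(best, e)
    return float(best)


# ---------------------------------------------------------------------------
# the lock & design loop
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HistoryEntry:
    iteration: int
    sequence: str
    energy: float
    accepted: bool


@dataclass
class DesignState:
    locked_sequence: PeptideSequence
    locked_energy: float
    iteration: int
    history: list[HistoryEntry] = field(default_factory=list)


@dataclass
class DesignRun:
    """Complete record of one seeded design run for one drug."""

    drug: DrugSpec
    seed: int
    state: DesignState
    visited: dict[str, float]  # sequence -> best energy seen
    stalled: bool = False

    @property
    def accepted_sequences(self) -> set[str]:
        return {h.sequence for h in self.state.history if h.accepted}

    @property
    def visited_sequences(self) -> set[str]:
        return set(self.visited)

    def locked_energy_trace(self) -> list[float]:
        trace, current = [], np.inf
        for h in self.state.history:
            if h.accepted:
                current = h.energy
            trace.append(current)
        return trace

    def to_dict(self) -> dict:
        return {
            "drug": self.drug.name,
            "seed": self.seed,
            "final_sequence": self.state.locked_sequence.sequence,
            "final_energy": self.state.locked_energy,
            "iterations": self.state.iteration,
            "stalled": self.stalled,
            "history": [
                {"iteration": h.iteration, "sequence": h.sequence,
                 "energy": h.energy, "accepted": h.accepted}
                for h in self.state.history
            ],
        }


def run_lock_and_design(drug: DrugSpec, start: PeptideSequence,
                        model: EvolutionModel,
                        scaffolds: Sequence[Scaffold] | None,
                        params: ScoringParams = ScoringParams(),
                        budget: int = 500, seed: int = 0,
                        pose_set: Sequence[np.ndarray] | None = None,
                        stall_length: int = 200,
                        evaluator: Callable[[PeptideSequence], float] | None = None,
                        ) -> DesignRun:
    """Iterative evolution-guided design of one peptide for one drug.

    Per iteration one mutation of the locked sequence is proposed and
    evaluated; the proposal replaces the lock only on strict energy
    improvement.  Stops at ``budget`` iterations or after ``stall_length``
    consecutive rejections.  ``evaluator`` overrides the physical objective
    (used for synthetic test scorers); by default the objective is
    ``evaluate_design`` over the given scaffolds and poses.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if evaluator is None:
        if not scaffolds:
            raise ValueError("need scaffolds when no custom evaluator is given")
        def evaluator(s: PeptideSequence) -> float:  # noqa: F811
            return evaluate_design(s, drug, scaffolds, params, pose_set)
    rng = np.random.default_rng(seed)
    e0 = float(evaluator(start))
    state = DesignState(start, e0, 0, [HistoryEntry(0, start.sequence, e0, True)])
    visited = {start.sequence: e0}
    rejections = 0
    stalled = False
    for it in range(1, budget + 1):
        position, code = propose_mutation(state.locked_sequence, model, rng)
        candidate = state.locked_sequence.with_residue(position, code)
        energy = float(evaluator(candidate))
        key = candidate.sequence
        visited[key] = min(energy, visited.get(key, np.inf))
        accepted = energy < state.locked_energy  # strict improvement only
        state.history.append(HistoryEntry(it, key, energy, accepted))
        state.iteration = it
        if accepted:
            state.locked_sequence = candidate
            state.locked_energy = energy
            rejections = 0
        else:
            rejections += 1
            if rejections >= stall_length:
                stalled = True
                break
    return DesignRun(drug, seed, state, visited, stalled)


# ---------------------------------------------------------------------------
# consensus across drugs
# ---------------------------------------------------------------------------

def find_consensus(runs_by_drug: Mapping[str, Sequence[DesignRun]],
                   criterion: str = "accepted") -> set[str]:
    """Sequences appearing in every drug's design output.

    ``criterion`` selects the membership notion: ``accepted`` (locked at
    least once) or ``visited`` (evaluated at all).
    """
    if len(runs_by_drug) < 2:
        raise ValueError("consensus needs runs for at least 2 drugs")
    if criterion not in ("accepted", "visited"):
        raise ValueError("criterion must be 'accepted' or 'visited'")
    per_drug: list[set[str]] = []
    for drug_name, runs in runs_by_drug.items():
        if not runs:
            raise ValueError(f"empty run collection for drug {drug_name!r}")
        seqs: set[str] = set()
        for run in runs:
            seqs |= (run.accepted_sequences if criterion == "accepted"
                     else run.visited_sequences)
        per_drug.append(seqs)
    return set.intersection(*per_drug)


@dataclass
class ConsensusTable:
    """Best-energy matrix E(peptide, drug) plus the consensus peptide set."""

    energies: pd.DataFrame  # index: sequence str, columns: drug names
    consensus: set[str]

    def __post_init__(self) -> None:
        missing = self.consensus - set(self.energies.index)
        if missing:
            raise ValueError(f"consensus peptides missing from table: {missing}")

    @classmethod
    def from_runs(cls, runs_by_drug: Mapping[str, Sequence[DesignRun]],
                  criterion: str = "accepted") -> "ConsensusTable":
        consensus = find_consensus(runs_by_drug, criterion)
        records: dict[str, dict[str, float]] = {}
        for drug_name, runs in runs_by_drug.items():
            for run in runs:
                for seq, e in run.visited.items():
                    records.setdefault(seq, {})
                    records[seq][drug_name] = min(e, records[seq].get(drug_name, np.inf))
        frame = pd.DataFrame.from_dict(records, orient="index").sort_index()
        return cls(frame, consensus)


def consensus_energy_penalty(table: ConsensusTable) -> pd.Series:
    """Mean energy gap to the per-drug best, for each consensus peptide.

    penalty(p) = (1/D) sum_d [E(p, d) - min_q E(q, d)] >= 0, with 0 iff the
    peptide attains the per-drug minimum for every drug.  Sorted ascending,
    ties broken lexicographically by sequence.
    """
    peptides = sorted(table.consensus)
    sub = table.energies.loc[peptides]
    if sub.isna().any().any():
        bad = sub.index[sub.isna().any(axis=1)].tolist()
        raise ValueError(f"missing energy matrix cells for: {bad}")
    col_min = table.energies.min(axis=0)
    penalties = (sub - col_min).mean(axis=1)
    order = sorted(penalties.index, key=lambda s: (penalties[s], s))
    out = penalties.loc[order]
    out.name = "consensus_energy_penalty"
    return out


def aggregation_propensity(seq: PeptideSequence,
                           scale: str = "beta_propensity") -> float:
    """Sum of a named per-residue scale over all four positions; higher means
    more aggregation-prone under that scale."""
    values = residue_scale(scale)
    return float(sum(values[r.one_letter_code] for r in seq.residues))


def select_top_designs(table: ConsensusTable, penalties: pd.Series,
                       propensities: pd.Series, k_energy: int,
                       k_propensity: int) -> pd.DataFrame:
    """Two-criterion selection: the ``k_energy`` lowest-penalty consensus
    peptides, plus the ``k_propensity`` most aggregation-prone among the
    remainder.  Rows carry the criterion that selected them."""
    pool = sorted(table.consensus)
    if k_energy + k_propensity > len(pool):
        raise ValueError(f"requested {k_energy}+{k_propensity} from a pool of "
                         f"{len(pool)} consensus peptides")
    by_energy = sorted(pool, key=lambda s: (penalties[s], s))
    energy_picks = by_energy[:k_energy]
    remainder = [s for s in pool if s not in energy_picks]
    by_prop = sorted(remainder, key=lambda s: (-propensities[s], s))
    prop_picks = by_prop[:k_propensity]
    rows = [
        {"sequence": s, "criterion": "energy", "penalty": float(penalties[s]),
         "propensity": float(propensities[s])}
        for s in energy_picks
    ] + [
        {"sequence": s, "criterion": "propensity", "penalty": float(penalties[s]),
         "propensity": float(propensities[s])}
        for s in prop_picks
    ]
    return pd.DataFrame(rows, columns=["sequence", "criterion", "penalty",
                                       "propensity"])
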