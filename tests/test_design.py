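"""The lock-&-design loop, consensus ranking, and selection criteria."""

import numpy as np
import pandas as pd
import pytest

from nanopept.core import PeptideSequence, drug_spec
from nanopept.design import (
    ConsensusTable,
    EvolutionModel,
    Scaffold,
    aggregation_propensity,
    consensus_energy_penalty,
    default_pose_set,
    evaluate_design,
    find_consensus,
    propose_mutation,
    run_lock_and_design,
    select_top_designs,
)
from nanopept.scaffolds import ScaffoldSpec
from nanopept.scoring import ScoringParams

# separable synthetic objective with the unique optimum WWW at positions 1-3
_BONUS = {c: 0.05 * i for i, c in enumerate("ACDEFGHIKLMNPQRSTVY")}
_BONUS.update(W=2.0, Y=1.5, F=1.2)


def separable_energy(seq: PeptideSequence) -> float:
    return -sum(_BONUS[r.one_letter_code] for r in seq.residues[:3])


@pytest.fixture(scope="module")
def model():
    return EvolutionModel.default()


class TestEvolutionModel:
    def test_rows_are_normalized_distributions(self, model):
        for code in "ACDEFGHIKLMNPQRSTVWY":
            codes, p = model.row(code)
            assert code not in codes  # self-substitution excluded
            assert p.sum() == pytest.approx(1.0)
            assert (p >= 0).all()

    def test_degenerate_row_always_returns_its_mass_point(self):
        probs = {c: {"W": 1.0} for c in "FW"}
        m = EvolutionModel({"F": {"W": 1.0}, "W": {"F": 1.0}})
        rng = np.random.default_rng(0)
        seq = PeptideSequence.from_string("FFFH")
        for _ in range(20):
            _pos, code = propose_mutation(seq, m, rng)
            assert code == "W"

    def test_malformed_rows_rejected(self):
        with pytest.raises(ValueError, match="sums to"):
            EvolutionModel({"F": {"W": 0.5}})

    def test_proposal_frequencies_recover_model_row(self, model):
        """Empirical draw frequencies stay within 3-sigma binomial bands."""
        rng = np.random.default_rng(123)
        seq = PeptideSequence.from_string("FFFH")
        codes, p = model.row("F")
        n = 100_000
        counts = {c: 0 for c in codes}
        for _ in range(n):
            _pos, code = propose_mutation(seq, model, rng)
            counts[code] += 1
        for c, pi in zip(codes, p):
            sigma = np.sqrt(n * pi * (1 - pi))
            assert abs(counts[c] - n * pi) <= 3.5 * sigma

    def test_seeded_proposals_are_reproducible(self, model):
        seq = PeptideSequence.from_string("FFWH")
        a = propose_mutation(seq, model, np.random.default_rng(9))
        b = propose_mutation(seq, model, np.random.default_rng(9))
        assert a == b

    def test_temperature_flattens_distribution(self):
        sharp = EvolutionModel.default(temperature=1.0)
        flat = EvolutionModel.default(temperature=10.0)
        _, p1 = sharp.row("F")
        _, p2 = flat.row("F")
        assert p2.max() < p1.max()


class TestEvaluateDesign:
    def test_single_scaffold_single_pose_equals_direct_energy(self, pep_amide,
                                                              toy_drug):
        from nanopept.scoring import mean_drug_association_energy
        scaffold = Scaffold(ScaffoldSpec())
        params = ScoringParams()
        direct = mean_drug_association_energy(
            scaffold.realize(pep_amide, toy_drug), params)
        e = evaluate_design(pep_amide, toy_drug, [scaffold], params,
                            pose_set=[np.eye(3)])
        assert e == pytest.approx(direct)

    def test_duplicate_pose_changes_nothing(self, pep_amide, toy_drug):
        scaffold = Scaffold(ScaffoldSpec())
        poses = default_pose_set(2)
        e1 = evaluate_design(pep_amide, toy_drug, [scaffold], pose_set=poses)
        e2 = evaluate_design(pep_amide, toy_drug, [scaffold],
                             pose_set=poses + [poses[0]])
        assert e1 == e2

    def test_minimum_over_scaffolds(self, pep_amide, toy_drug):
        """With per-scaffold energies known, the best (lowest) one is kept."""
        scaffolds = [Scaffold(ScaffoldSpec()),
                     Scaffold(ScaffoldSpec(kind="SES-like", perturbation=1.0,
                                           compaction=0.97, seed=5))]
        singles = [evaluate_design(pep_amide, toy_drug, [s],
                                   pose_set=[np.eye(3)]) for s in scaffolds]
        joint = evaluate_design(pep_amide, toy_drug, scaffolds,
                                pose_set=[np.eye(3)])
        assert joint == pytest.approx(min(singles))

    def test_sequence_identity_changes_the_objective(self, toy_drug):
        scaffold = Scaffold(ScaffoldSpec())
        e_fwh = evaluate_design(PeptideSequence.from_string("FFWH"), toy_drug,
                                [scaffold], pose_set=[np.eye(3)])
        e_ddh = evaluate_design(PeptideSequence.from_string("DDDH"), toy_drug,
                                [scaffold], pose_set=[np.eye(3)])
        assert e_fwh != e_ddh


class TestLockAndDesign:
    def test_locked_energy_trace_is_monotone(self, model, toy_drug):
        run = run_lock_and_design(toy_drug, PeptideSequence.from_string("AAAH"),
                                  model, None, budget=300, seed=1,
                                  evaluator=separable_energy)
        trace = run.locked_energy_trace()
        assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))

    def test_same_seed_gives_identical_history(self, model, toy_drug):
        kw = dict(budget=150, seed=42, evaluator=separable_energy)
        r1 = run_lock_and_design(toy_drug, PeptideSequence.from_string("FFWH"),
                                 model, None, **kw)
        r2 = run_lock_and_design(toy_drug, PeptideSequence.from_string("FFWH"),
                                 model, None, **kw)
        assert r1.to_dict() == r2.to_dict()

    def test_budget_one_with_worsening_proposal_keeps_start(self, toy_drug):
        m = EvolutionModel({"A": {"C": 1.0}, "C": {"A": 1.0},
                            "W": {"A": 1.0}, "F": {"A": 1.0}})
        run = run_lock_and_design(toy_drug, PeptideSequence.from_string("WWWH"),
                                  m, None, budget=1, seed=0,
                                  evaluator=separable_energy)
        assert run.state.locked_sequence.sequence == "WWWH"
        assert not run.state.history[1].accepted

    def test_planted_optimum_recovery_rate(self, model, toy_drug):
        """>= 95% of seeded runs find the constructed global optimum."""
        wins = 0
        for seed in range(50):
            run = run_lock_and_design(
                toy_drug, PeptideSequence.from_string("AAAH"), model, None,
                budget=500, seed=seed, evaluator=separable_energy,
                stall_length=200)
            wins += run.state.locked_sequence.sequence == "WWWH"
        assert wins >= 48  # 95% of 50, rounded up

    def test_stall_terminates_early(self, toy_drug):
        m = EvolutionModel({"W": {"A": 1.0}, "A": {"W": 1.0}})
        run = run_lock_and_design(toy_drug, PeptideSequence.from_string("WWWH"),
                                  m, None, budget=10_000, seed=0,
                                  evaluator=separable_energy, stall_length=25)
        assert run.stalled and run.state.iteration < 10_000


def _fake_run(drug, accepted, toy_drug):
    """DesignRun with a hand-written accepted/visited record."""
    from nanopept.design import DesignRun, DesignState, HistoryEntry
    history = [HistoryEntry(i, s, e, True) for i, (s, e) in enumerate(accepted)]
    state = DesignState(PeptideSequence.from_string(accepted[-1][0]),
                        accepted[-1][1], len(accepted), history)
    return DesignRun(toy_drug, 0, state, dict(accepted))


class TestConsensus:
    def test_intersection_of_hand_listed_sets(self, toy_drug):
        runs = {
            "EPI": [_fake_run("EPI", [("WWWH", -5.0), ("YWWH", -4.0)], toy_drug)],
            "MTX": [_fake_run("MTX", [("WWWH", -6.0), ("FFWH", -3.0)], toy_drug)],
            "CPT": [_fake_run("CPT", [("WWWH", -2.0), ("YWWH", -1.0)], toy_drug)],
        }
        assert find_consensus(runs) == {"WWWH"}

    def test_disjoint_sets_give_empty_consensus(self, toy_drug):
        runs = {
            "EPI": [_fake_run("EPI", [("WWWH", -5.0)], toy_drug)],
            "MTX": [_fake_run("MTX", [("FFWH", -3.0)], toy_drug)],
        }
        assert find_consensus(runs) == set()

    def test_single_drug_rejected(self, toy_drug):
        runs = {"EPI": [_fake_run("EPI", [("WWWH", -5.0)], toy_drug)]}
        with pytest.raises(ValueError, match="at least 2"):
            find_consensus(runs)

    def test_empty_collection_rejected(self, toy_drug):
        runs = {"EPI": [_fake_run("EPI", [("WWWH", -5.0)], toy_drug)],
                "MTX": []}
        with pytest.raises(ValueError, match="empty"):
            find_consensus(runs)


class TestConsensusPenalty:
    def _table(self, data, consensus):
        frame = pd.DataFrame(data).T
        return ConsensusTable(frame, consensus)

    def test_best_for_every_drug_scores_zero(self):
        table = self._table(
            {"WWWH": {"EPI": -10.0, "MTX": -8.0},
             "YWWH": {"EPI": -9.0, "MTX": -7.0}},
            consensus={"WWWH", "YWWH"})
        pen = consensus_energy_penalty(table)
        assert pen["WWWH"] == 0.0
        assert pen["YWWH"] == pytest.approx(1.0)

    def test_hand_enumerated_three_by_two_table(self):
        table = self._table(
            {"AAWH": {"d1": -4.0, "d2": -9.0},
             "BBWH": {"d1": -6.0, "d2": -5.0},
             "CCWH": {"d1": -5.0, "d2": -7.0}},
            consensus={"AAWH", "BBWH", "CCWH"})
        pen = consensus_energy_penalty(table)
        # per-drug minima: d1 -> -6 (BBWH), d2 -> -9 (AAWH)
        assert pen["AAWH"] == pytest.approx((2.0 + 0.0) / 2)
        assert pen["BBWH"] == pytest.approx((0.0 + 4.0) / 2)
        assert pen["CCWH"] == pytest.approx((1.0 + 2.0) / 2)
        assert list(pen.index) == ["AAWH", "CCWH", "BBWH"]  # ascending penalty

    def test_column_shift_invariance(self):
        base = {"AAWH": {"d1": -4.0, "d2": -9.0},
                "BBWH": {"d1": -6.0, "d2": -5.0}}
        shifted = {k: {"d1": v["d1"] + 7.0, "d2": v["d2"]}
                   for k, v in base.items()}
        p0 = consensus_energy_penalty(self._table(base, {"AAWH", "BBWH"}))
        p1 = consensus_energy_penalty(self._table(shifted, {"AAWH", "BBWH"}))
        assert np.allclose(p0.values, p1.loc[p0.index].values)

    def test_missing_cell_raises(self):
        frame = pd.DataFrame({"d1": {"AAWH": -1.0, "BBWH": -2.0},
                              "d2": {"AAWH": -1.0, "BBWH": np.nan}})
        table = ConsensusTable(frame, {"AAWH", "BBWH"})
        with pytest.raises(ValueError, match="missing"):
            consensus_energy_penalty(table)

    def test_penalty_floor_is_nonnegative(self, toy_drug):
        rng = np.random.default_rng(5)
        seqs = ["AAWH", "CCWH", "DDWH", "EEWH"]
        frame = pd.DataFrame(rng.normal(-5, 2, size=(4, 3)), index=seqs,
                             columns=["d1", "d2", "d3"])
        pen = consensus_energy_penalty(ConsensusTable(frame, set(seqs)))
        assert (pen.values >= 0).all()
        assert pen.min() >= 0


class TestAggregationPropensity:
    def test_toy_scale_direct_sum(self, monkeypatch):
        import nanopept.design as design_mod
        toy = {c: 0.0 for c in "ACDEFGHIKLMNPQRSTVWY"}
        toy.update(F=1.0, W=2.0, H=0.0)
        monkeypatch.setattr(design_mod, "residue_scale", lambda name: toy)
        seq = PeptideSequence.from_string("FFWH")
        assert aggregation_propensity(seq, "toy") == pytest.approx(4.0)

    def test_position_permutation_invariance(self):
        a = aggregation_propensity(PeptideSequence.from_string("FWYH"))
        b = aggregation_propensity(PeptideSequence.from_string("YWFH"))
        assert a == pytest.approx(b)

    def test_unknown_scale_rejected(self, pep_amide):
        with pytest.raises(KeyError, match="unknown"):
            aggregation_propensity(pep_amide, "no-such-scale")


class TestSelection:
    def _inputs(self):
        seqs = ["AAWH", "CCWH", "DDWH", "EEWH", "FFWH"]
        frame = pd.DataFrame({"d": dict.fromkeys(seqs, -1.0)})
        table = ConsensusTable(frame, set(seqs))
        penalties = pd.Series({"AAWH": 0.0, "CCWH": 0.5, "DDWH": 0.5,
                               "EEWH": 2.0, "FFWH": 3.0})
        propensities = pd.Series({"AAWH": 1.0, "CCWH": 9.0, "DDWH": 2.0,
                                  "EEWH": 8.0, "FFWH": 5.0})
        return table, penalties, propensities

    def test_whole_pool_by_energy(self):
        table, pen, prop = self._inputs()
        sel = select_top_designs(table, pen, prop, k_energy=5, k_propensity=0)
        assert (sel.criterion == "energy").all()
        assert len(sel) == 5

    def test_two_criteria_hand_ranking(self):
        table, pen, prop = self._inputs()
        sel = select_top_designs(table, pen, prop, k_energy=2, k_propensity=2)
        # energy picks: AAWH (0.0), then CCWH via lexicographic tie with DDWH
        assert list(sel[sel.criterion == "energy"].sequence) == ["AAWH", "CCWH"]
        # propensity among the remainder: EEWH (8.0) then FFWH (5.0)
        assert list(sel[sel.criterion == "propensity"].sequence) == ["EEWH", "FFWH"]

    def test_overdraw_rejected(self):
        table, pen, prop = self._inputs()
        with pytest.raises(ValueError, match="pool"):
            select_top_designs(table, pen, prop, k_energy=4, k_propensity=3)
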