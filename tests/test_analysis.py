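"""Cluster statistics, beta-sheet assignment, mediation, and profiles."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from nanopept.analysis import (
    BetaSheetCriteria,
    assign_beta_sheet,
    cluster_size_series,
    composition_ratio,
    detect_clusters,
    encapsulation_profile,
    energy_burial_profile,
    mediation_stats,
    select_representative_cluster,
)
from nanopept.core import PeptideSequence, Snapshot, SystemComposition, drug_spec
from nanopept.scaffolds import ScaffoldSpec, build_ips, build_peptide, plant_clusters
from nanopept.scoring import ScoringParams

from conftest import (
    brute_force_mediation,
    brute_force_partition,
    random_toy_snapshot,
)


def _partition_of(cluster_set):
    return set(cluster_set.partition())


class TestDetectClusters:
    def test_contact_pair_merges_at_cutoff(self, pep_amide):
        a = build_peptide(pep_amide, 0)
        b = build_peptide(pep_amide, 1, translation=np.array([0.0, 0.0, 4.0]))
        snap = Snapshot([a, b])
        dmin = float(np.min(np.linalg.norm(
            a.coords[:, None] - b.coords[None], axis=-1)))
        merged = detect_clusters(snap, contact_cutoff=dmin + 0.1)
        split = detect_clusters(snap, contact_cutoff=dmin - 0.1)
        assert len(merged.clusters) == 1 and merged.clusters[0].size == 2
        assert not split.clusters and len(split.singletons) == 2

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("cutoff", [4.5, 8.0, 14.0])
    def test_equals_brute_force_bfs(self, seed, cutoff):
        snap = random_toy_snapshot(seed, n_copies=1, box=45.0,
                                   min_separation=3.0)
        fast = _partition_of(detect_clusters(snap, cutoff))
        slow = brute_force_partition(snap, cutoff)
        assert fast == slow

    def test_permutation_invariance(self):
        snap = random_toy_snapshot(11, n_copies=1, box=45.0, min_separation=3.0)
        rng = np.random.default_rng(0)
        order = rng.permutation(len(snap.molecules))
        shuffled = Snapshot([snap.molecules[i] for i in order])
        assert (_partition_of(detect_clusters(snap, 8.0))
                == _partition_of(detect_clusters(shuffled, 8.0)))

    def test_monotone_refinement_in_cutoff(self):
        """Raising the cutoff only merges components, never splits them."""
        snap = random_toy_snapshot(2, n_copies=1, box=45.0, min_separation=3.0)
        small = detect_clusters(snap, 5.0).partition()
        large = detect_clusters(snap, 10.0).partition()
        for fine in small:
            assert any(fine <= coarse for coarse in large)

    def test_conservation_of_molecules(self):
        snap = random_toy_snapshot(4, n_copies=2, box=70.0, min_separation=4.0)
        cs = detect_clusters(snap, 6.0)
        covered = set().union(*cs.partition())
        assert covered == {m.molecule_id for m in snap.molecules}
        assert sum(c.size for c in cs.clusters) + len(cs.singletons) == len(snap)


class TestClusterSizeSeries:
    def test_static_trajectory_constant_histogram(self):
        snap = random_toy_snapshot(1, n_copies=1, box=45.0, min_separation=3.0)
        series = cluster_size_series([snap, snap, snap], cutoff=6.0)
        assert series.histograms[0] == series.histograms[1] == series.histograms[2]

    def test_merge_increases_largest_trace(self, pep_amide, toy_drug):
        comp = SystemComposition.neutral(4, pep_amide, 2, toy_drug)
        merged, _ = plant_clusters([comp], seed=1)
        # frame 0: spread the same molecules far apart
        apart = Snapshot([
            m.transformed(translation=np.array([60.0 * i, 0.0, 0.0]))
            for i, m in enumerate(merged.molecules)
        ])
        series = cluster_size_series([apart, merged], cutoff=4.5)
        assert series.largest[1] > series.largest[0]

    def test_histogram_totals_equal_molecule_count(self):
        snap = random_toy_snapshot(9, n_copies=2, box=70.0, min_separation=4.0)
        series = cluster_size_series([snap], cutoff=7.0)
        total = sum(s * c for s, c in series.histograms[0].items())
        assert total == len(snap)


class TestEncapsulation:
    def test_all_drugs_in_one_cluster(self, pep_amide, toy_drug):
        comp = SystemComposition.neutral(4, pep_amide, 2, toy_drug)
        snap, _ = plant_clusters([comp], seed=3)
        cs = detect_clusters(snap, 4.5)
        prof = encapsulation_profile(cs, snap)
        size = cs.clusters[0].size
        assert prof.per_bin["drug"][size] == 100.0
        assert prof.cumulative["drug"][1] == 100.0

    def test_monomeric_snapshot_is_zero_above_size_one(self):
        snap = random_toy_snapshot(0, n_copies=1, box=70.0, min_separation=8.0)
        cs = detect_clusters(snap, 4.0)
        if cs.clusters:  # dispersed by construction; guard anyway
            pytest.skip("fixture unexpectedly clustered")
        prof = encapsulation_profile(cs, snap)
        for kind in prof.totals:
            assert prof.cumulative[kind][1] == 100.0
            assert all(v == 0.0 for s, v in prof.per_bin[kind].items() if s >= 2)

    def test_partial_encapsulation_fraction(self, pep_amide, toy_drug):
        """6 of 8 drugs inside clusters -> 75% cumulative at size >= 2."""
        comp_in = SystemComposition(1, 3, 0, 0, pep_amide, toy_drug)
        snap, _ = plant_clusters([comp_in, comp_in], spacing=50.0, seed=4)
        # add two far-away singleton drugs
        from nanopept.core import make_drug_instance
        d1 = make_drug_instance(toy_drug, 90).transformed(
            translation=np.array([200.0, 0, 0]))
        d2 = make_drug_instance(toy_drug, 91).transformed(
            translation=np.array([260.0, 0, 0]))
        full = Snapshot(snap.molecules + [d1, d2])
        cs = detect_clusters(full, 4.5)
        prof = encapsulation_profile(cs, full)
        cumulative_ge2 = prof.cumulative["drug"][min(
            s for s in prof.cumulative["drug"] if s >= 2)]
        assert cumulative_ge2 == pytest.approx(75.0)

    def test_cumulative_profile_is_non_increasing(self):
        snap = random_toy_snapshot(6, n_copies=2, box=60.0, min_separation=3.5)
        cs = detect_clusters(snap, 6.5)
        prof = encapsulation_profile(cs, snap)
        for kind, cum in prof.cumulative.items():
            vals = [cum[s] for s in sorted(cum)]
            assert all(b <= a + 1e-9 for a, b in zip(vals, vals[1:]))


class TestCompositionRatio:
    def test_designed_ratio_recovered(self):
        from nanopept.analysis import Cluster
        c = Cluster(frozenset(range(14)),
                    {"peptide": 8, "drug": 4, "zn": 2}, 10.0)
        assert composition_ratio(c) == pytest.approx((4.0, 2.0, 1.0))

    def test_mtx_like_ratio(self):
        from nanopept.analysis import Cluster
        c = Cluster(frozenset(range(8)), {"peptide": 4, "drug": 2, "zn": 2}, 8.0)
        assert composition_ratio(c) == pytest.approx((4.0, 2.0, 2.0))

    def test_peptide_free_cluster_unnormalized(self):
        from nanopept.analysis import Cluster
        c = Cluster(frozenset(range(3)), {"drug": 2, "zn": 1}, 5.0)
        assert composition_ratio(c) == (0.0, 2.0, 1.0)


class TestBetaSheet:
    def test_isolated_peptide_is_not_strand(self, pep_amide):
        snap = Snapshot([build_peptide(pep_amide, 0)])
        out = assign_beta_sheet(snap)
        assert out.percent_strand == 0.0

    def test_ips_dimer_is_fully_strand(self, pep_coo):
        snap = build_ips(ScaffoldSpec(), pep_coo, drug_spec("EPI"))
        assert assign_beta_sheet(snap).percent_strand == 100.0

    def test_separated_dimer_is_not_strand(self, pep_amide):
        a = build_peptide(pep_amide, 0)
        b = build_peptide(pep_amide, 1, translation=np.array([0.0, 20.0, 0.0]))
        assert assign_beta_sheet(Snapshot([a, b])).percent_strand == 0.0

    def test_rigid_motion_invariance(self, pep_coo):
        snap = build_ips(ScaffoldSpec(), pep_coo, drug_spec("EPI"))
        rot = Rotation.from_euler("xyz", [0.4, 1.2, -0.8]).as_matrix()
        moved = snap.transformed(rot, np.array([-30.0, 12.0, 7.0]))
        assert (assign_beta_sheet(moved).percent_strand
                == assign_beta_sheet(snap).percent_strand)

    def test_axis_angle_criterion_rejects_crossed_strands(self, pep_amide):
        a = build_peptide(pep_amide, 0)
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        b = build_peptide(pep_amide, 1, rotation=rot,
                          translation=np.array([6.0, 2.0, 1.0]))
        out = assign_beta_sheet(Snapshot([a, b]),
                                BetaSheetCriteria(hbond_max_distance=8.0))
        assert out.percent_strand == 0.0

    def test_missing_backbone_is_reported(self, pep_amide):
        broken = build_peptide(pep_amide, 7)
        broken.atoms = [a for a in broken.atoms if a.name != "CA"]
        with pytest.raises(ValueError, match="7"):
            assign_beta_sheet(Snapshot([broken]))


class TestMediation:
    def test_definitional_two_peptide_case(self, pep_amide, toy_drug):
        comp = SystemComposition(2, 1, 0, 0, pep_amide, toy_drug)
        snap, _ = plant_clusters([comp], seed=6)
        cs = detect_clusters(snap, 4.5)
        stats = mediation_stats(cs, snap, 4.5)
        expected2, expected3 = brute_force_mediation(snap, 4.5)
        assert stats.p_two_peptides == pytest.approx(expected2)
        assert stats.p_two_peptides_and_zn == pytest.approx(expected3)
        assert stats.p_two_peptides_and_zn == 0.0  # no Zn in the system

    def test_no_contacts_gives_zero(self):
        snap = random_toy_snapshot(0, n_copies=1, box=80.0, min_separation=10.0)
        cs = detect_clusters(snap, 4.0)
        stats = mediation_stats(cs, snap, 4.0)
        assert stats.p_two_peptides == 0.0
        assert stats.p_two_peptides_and_zn == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_brute_force_triple_enumeration(self, seed):
        snap = random_toy_snapshot(seed, n_copies=1, box=40.0,
                                   min_separation=3.0)
        cs = detect_clusters(snap, 6.0)
        stats = mediation_stats(cs, snap, 6.0)
        b2, b3 = brute_force_mediation(snap, 6.0)
        assert stats.p_two_peptides == pytest.approx(b2)
        assert stats.p_two_peptides_and_zn == pytest.approx(b3)

    def test_probabilities_bounded(self):
        snap = random_toy_snapshot(13, n_copies=2, box=55.0, min_separation=3.0)
        cs = detect_clusters(snap, 7.0)
        stats = mediation_stats(cs, snap, 7.0)
        assert 0.0 <= stats.p_two_peptides_and_zn <= stats.p_two_peptides <= 1.0


class TestRepresentativeCluster:
    def test_growing_cluster_selected_from_final_frame(self, pep_amide,
                                                       toy_drug):
        comp = SystemComposition.neutral(4, pep_amide, 2, toy_drug)
        final, truth = plant_clusters([comp], seed=1)
        apart = Snapshot([
            m.transformed(translation=np.array([70.0 * i, 0.0, 0.0]))
            for i, m in enumerate(final.molecules)
        ])
        frame, cluster = select_representative_cluster([apart, final], 4.5)
        assert frame == 1
        assert cluster.members == frozenset(truth[0])

    def test_single_frame_trajectory(self, pep_amide, toy_drug):
        comp = SystemComposition.neutral(4, pep_amide, 2, toy_drug)
        snap, _ = plant_clusters([comp], seed=5)
        frame, cluster = select_representative_cluster([snap], 4.5)
        assert frame == 0 and cluster.size == len(snap)

    def test_no_clusters_anywhere_raises(self):
        snap = random_toy_snapshot(0, n_copies=1, box=80.0, min_separation=10.0)
        with pytest.raises(ValueError, match="no cluster"):
            select_representative_cluster([snap], 4.0)


class TestEnergyBurialProfile:
    def test_isolated_molecule_row(self, pep_amide):
        snap = Snapshot([build_peptide(pep_amide, 0)])
        table = energy_burial_profile([0], snap, n_points=480)
        row = table.iloc[0]
        assert row.burial_fraction == pytest.approx(1.0)
        assert row.association_energy == 0.0

    def test_buried_molecule_is_low_exposure_and_bound(self, pep_amide,
                                                       toy_drug):
        comp = SystemComposition(4, 1, 0, 0, pep_amide, toy_drug)
        snap, truth = plant_clusters([comp], contact_distance=3.2, seed=8)
        drug_id = next(m.molecule_id for m in snap.molecules
                       if m.kind == "drug")
        table = energy_burial_profile(sorted(truth[0]), snap, n_points=480)
        drug_row = table[table.molecule_id == drug_id].iloc[0]
        assert drug_row.burial_fraction < 1.0
        assert drug_row.association_energy < 0.0
        assert set(table.kind) == {"peptide", "drug"}
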