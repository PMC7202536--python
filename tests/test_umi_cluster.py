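"""Metric LCS, greedy side clustering and paired-UMI molecule building."""

from collections import Counter
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from longumi.preprocess import UmiPair
from longumi.umi_cluster import (
    MoleculeCluster,
    build_molecule_clusters,
    cluster_side,
    lcs_length,
    metric_lcs_distance,
)
from longumi.simdata import SimConfig, simulate_dataset
from longumi.preprocess import preprocess_reads, default_min_length


def brute_force_lcs(a: str, b: str) -> int:
    """Independent oracle: enumerate all subsequences of the shorter string."""
    if len(a) > len(b):
        a, b = b, a
    best = 0
    for k in range(len(a), 0, -1):
        for idxs in combinations(range(len(a)), k):
            sub = "".join(a[i] for i in idxs)
            it = iter(b)
            if all(c in it for c in sub):
                return k
    return best


class TestLcsLength:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACTGACTG", "ACTGACTG", 8),
            ("ACT", "", 0),
            ("", "", 0),
            ("AGCAT", "GAC", 2),  # frozen from the brute-force oracle
        ],
    )
    def test_known_values(self, a, b, expected):
        assert lcs_length(a, b) == expected

    @given(
        st.text(alphabet="ACGT", max_size=7),
        st.text(alphabet="ACGT", max_size=9),
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_matches_brute_force_enumeration(self, a, b):
        assert lcs_length(a, b) == brute_force_lcs(a, b)
        assert lcs_length(a, b) == lcs_length(b, a)


class TestMetricLcsDistance:
    def test_identity_is_zero(self):
        for x in ("A", "ACGT", "ACT" * 8):
            assert metric_lcs_distance(x, x) == 0.0

    def test_disjoint_alphabets_distance_one(self):
        assert metric_lcs_distance("AAAA", "CCCC") == 1.0

    def test_three_g_substitutions_on_24mer_sit_at_pruning_threshold(self):
        # G occurs nowhere in an H-alphabet UMI, so 3 G-substitutions force
        # |LCS| = 21 and a distance of exactly 3/24 = 0.125
        umi = "ACTTCATCATCCATCATACTTCAT"
        corrupted = "G" + umi[1:10] + "G" + umi[11:17] + "G" + umi[18:]
        assert len(corrupted) == 24
        assert metric_lcs_distance(umi, corrupted) == pytest.approx(0.125)
        # a fourth difference crosses the threshold: 3 is the maximum tolerated
        worse = corrupted[:5] + "G" + corrupted[6:]
        assert metric_lcs_distance(umi, worse) > 0.125

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            metric_lcs_distance("", "")

    @given(
        st.text(alphabet="ACGT", min_size=1, max_size=10),
        st.text(alphabet="ACGT", min_size=1, max_size=10),
        st.text(alphabet="ACGT", min_size=1, max_size=10),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_metric_axioms(self, a, b, c):
        dab = metric_lcs_distance(a, b)
        assert 0.0 <= dab <= 1.0
        assert dab == metric_lcs_distance(b, a)
        assert (dab == 0.0) == (a == b)
        assert dab <= metric_lcs_distance(a, c) + metric_lcs_distance(c, b) + 1e-12


class TestClusterSide:
    def test_distinct_far_umis_one_cluster_each(self):
        umis = {"AAAAAAAA": 5, "CCCCCCCC": 3, "TTTTTTTT": 2}
        assignment = cluster_side(umis, 0.125)
        assert assignment == {u: u for u in umis}

    def test_small_corruption_absorbed_by_supported_centroid(self):
        centroid = "ACTTCATCATCCATCATACTTCAT"
        corrupted = "G" + centroid[1:12] + "G" + centroid[13:]  # distance 2/24
        assert metric_lcs_distance(centroid, corrupted) == pytest.approx(2 / 24)
        assignment = cluster_side({centroid: 10, corrupted: 1}, 0.125)
        assert assignment[corrupted] == centroid

    def test_four_substitutions_left_unassigned(self):
        centroid = "ACTTCATCATCCATCATACTTCAT"
        bad = "G" + centroid[1:6] + "G" + centroid[7:12] + "G" + centroid[13:18] + "G" + centroid[19:]
        assert metric_lcs_distance(centroid, bad) == pytest.approx(4 / 24)
        assignment = cluster_side({centroid: 10, bad: 1}, 0.125)
        assert assignment[bad] == bad  # its own singleton, not absorbed

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            cluster_side({"ACGT": 1}, 1.5)


def _pairs(triples):
    return [
        UmiPair(read_id=f"r{i}", umi5=u5, umi3=u3, flank_edit_5=0, flank_edit_3=0)
        for i, (u5, u3) in enumerate(triples)
    ]


class TestBuildMoleculeClusters:
    U1 = "ACTTCATCATCCATCATACTTCAT"
    U2 = "TCCTATACTTACCCTATTCAACTA"
    V1 = "CATTCTTCAACATACTACTCCTAT"
    V2 = "AACTCTATCCACTTATCACTTCCA"

    def test_discordant_pair_read_flagged_chimeric(self):
        triples = [(self.U1, self.V1)] * 20 + [(self.U2, self.V2)] * 20 + [(self.U1, self.V2)]
        result = build_molecule_clusters(_pairs(triples), min_depth=20)
        assert sorted(c.depth for c in result.clusters) == [20, 20]
        assert result.chimeric_read_ids == ["r40"]

    def test_zero_error_cluster_count_matches_manifest(self, zero_error_dataset):
        config, reference, design, reads, manifest = zero_error_dataset
        pre = preprocess_reads(reads, design, default_min_length(design, len(reference)))
        result = build_molecule_clusters(pre.pairs, min_depth=2)
        by_mol = Counter(m for m, _ in manifest.read_assignments.values())
        expected = sum(1 for n in by_mol.values() if n >= 2)
        assert len(result.clusters) == expected
        # centroids are exactly the true UMI pairs
        truth = {(m.umi5, m.umi3) for m in manifest.molecules}
        assert {(c.centroid5, c.centroid3) for c in result.clusters} <= truth

    def test_injected_low_depth_chimeras_all_flagged(self):
        # abundant error-free parents + single-read chimeras: every chimeric
        # read is flagged and no surviving cluster contains one
        cfg = SimConfig(
            reference_length=300, n_molecules=20, mutation_rate=0.0, depth_mean=10.0,
            depth_min=5, sub_rate=0.0, ins_rate=0.0, del_rate=0.0,
            chimera_fraction=0.1, chimera_depth_mean=1e-9, seed=23,
        )
        reference, design, reads, manifest = simulate_dataset(cfg)
        pre = preprocess_reads(reads, design, default_min_length(design, len(reference)))
        result = build_molecule_clusters(pre.pairs, min_depth=5)
        chimeric_truth = {
            rid for rid, (mol, _) in manifest.read_assignments.items()
            if manifest.molecule(mol).is_chimera
        }
        assert chimeric_truth  # the scenario actually contains chimeras
        assert chimeric_truth <= set(result.chimeric_read_ids)
        for cluster in result.clusters:
            assert not chimeric_truth & set(cluster.read_ids)

    def test_partition_recovery_with_up_to_three_umi_errors(self):
        # reads with <= 3 substitutions per UMI: the recovered read partition
        # must match the true molecule partition (ARI >= 0.99)
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(42)
        _reference, _design, _reads, manifest = simulate_dataset(
            SimConfig(reference_length=300, n_molecules=40, mutation_rate=0.0,
                      depth_mean=1.0, depth_min=1, sub_rate=0, ins_rate=0, del_rate=0,
                      chimera_fraction=0.0, seed=31)
        )
        molecules = [m for m in manifest.molecules]
        pairs, truth_labels = [], []
        k_choices, k_probs = [0, 1, 2, 3], [0.4, 0.3, 0.2, 0.1]
        for mi, mol in enumerate(molecules):
            for j in range(12):
                umis = []
                for umi in (mol.umi5, mol.umi3):
                    k = rng.choice(k_choices, p=k_probs)
                    u = list(umi)
                    for pos in rng.choice(24, size=k, replace=False):
                        u[pos] = str(rng.choice([b for b in "ACGT" if b != umi[pos]]))
                    umis.append("".join(u))
                pairs.append(
                    UmiPair(read_id=f"m{mi}_{j}", umi5=umis[0], umi3=umis[1],
                            flank_edit_5=0, flank_edit_3=0)
                )
                truth_labels.append(mi)
        result = build_molecule_clusters(pairs, min_depth=5)
        label_of = {}
        for ci, cluster in enumerate(result.clusters):
            for rid in cluster.read_ids:
                label_of[rid] = ci
        predicted = [label_of.get(p.read_id, -1 - i) for i, p in enumerate(pairs)]
        assert adjusted_rand_score(truth_labels, predicted) >= 0.99

    def test_no_read_in_two_clusters_and_chimeric_in_none(self, noisy_preprocessed):
        result = build_molecule_clusters(noisy_preprocessed.pairs, min_depth=5)
        seen: set[str] = set()
        for cluster in result.clusters:
            ids = set(cluster.read_ids)
            assert not ids & seen
            seen |= ids
        assert not seen & set(result.chimeric_read_ids)

    def test_min_depth_monotonicity(self, noisy_preprocessed):
        counts = [
            len(build_molecule_clusters(noisy_preprocessed.pairs, min_depth=d).clusters)
            for d in (2, 5, 10, 20)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_molecule_clusters([])
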