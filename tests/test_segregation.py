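import numpy as np
import pytest

from gripseg import (ConnectivityMatrix, NetworkPartition, edge_fc,
                     network_pairs, prepare_matrix, profile_subject,
                     segregation, within_between_means)
from conftest import random_partition, random_prepared_matrix


def enumeration_oracle(m, p):
    """Brute-force double loop over all unordered region pairs."""
    ids = list(m.region_ids)
    nets = p.networks
    sums = {}
    counts = {}
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = p.assignment[ids[i]], p.assignment[ids[j]]
            key = (a,) if a == b else tuple(sorted((a, b), key=nets.index))
            sums[key] = sums.get(key, 0.0) + m.z[i, j]
            counts[key] = counts.get(key, 0) + 1
    zw = {k: sums[(k,)] / counts[(k,)] for k in nets}
    zb = {}
    for k in nets:
        s = sum(v for key, v in sums.items() if len(key) == 2 and k in key)
        c = sum(v for key, v in counts.items() if len(key) == 2 and k in key)
        zb[k] = s / c
    w_sum = sum(sums[(k,)] for k in nets)
    w_n = sum(counts[(k,)] for k in nets)
    b_sum = sum(v for key, v in sums.items() if len(key) == 2)
    b_n = sum(v for key, v in counts.items() if len(key) == 2)
    inter = {key: sums[key] / counts[key] for key in sums if len(key) == 2}
    return {"zw": zw, "zb": zb, "zw_g": w_sum / w_n, "zb_g": b_sum / b_n,
            "inter": inter}


class TestWithinBetweenMeans:
    def test_constant_blocks(self, two_block_matrix, two_block_partition):
        for scope in ("A", "B", "global"):
            zw, zb = within_between_means(two_block_matrix, two_block_partition,
                                          scope)
            assert zw == pytest.approx(0.6)
            assert zb == pytest.approx(0.2)

    def test_six_region_fixture_matches_enumeration(self):
        rng = np.random.default_rng(6)
        ids = tuple(f"r{i}" for i in range(6))
        m = random_prepared_matrix(rng, ids)
        p = NetworkPartition({"r0": "A", "r1": "A", "r2": "A",
                              "r3": "B", "r4": "B", "r5": "B"}, ("A", "B"))
        oracle = enumeration_oracle(m, p)
        for net in ("A", "B"):
            zw, zb = within_between_means(m, p, net)
            assert zw == pytest.approx(oracle["zw"][net], abs=1e-12)
            assert zb == pytest.approx(oracle["zb"][net], abs=1e-12)
        zw, zb = within_between_means(m, p, "global")
        assert zw == pytest.approx(oracle["zw_g"], abs=1e-12)
        assert zb == pytest.approx(oracle["zb_g"], abs=1e-12)

    def test_zeroed_negative_edge_counts_as_zero(self):
        ids = tuple(f"r{i}" for i in range(4))
        z = np.full((4, 4), 0.5)
        z[0, 1] = z[1, 0] = -0.4  # within-network edge, will be zeroed
        np.fill_diagonal(z, 0.0)
        m = prepare_matrix(ConnectivityMatrix("s", z, ids))
        p = NetworkPartition({"r0": "A", "r1": "A", "r2": "B", "r3": "B"},
                             ("A", "B"))
        zw, _ = within_between_means(m, p, "A")
        assert zw == 0.0  # the single within pair contributes a 0, not 0.5

    def test_singleton_network_rejected(self):
        ids = ("r0", "r1", "r2")
        z = np.zeros((3, 3))
        m = ConnectivityMatrix("s", z, ids, prepared=True)
        p = NetworkPartition({"r0": "A", "r1": "A", "r2": "B"}, ("A", "B"))
        with pytest.raises(ValueError, match="fewer than 2"):
            within_between_means(m, p, "B")


class TestSegregationFormula:
    @pytest.mark.parametrize("zw, zb, expected", [
        (0.5, 0.0, 1.0),
        (0.4, 0.4, 0.0),
        (0.6, 0.2, 2.0 / 3.0),
    ])
    def test_direct_substitution(self, zw, zb, expected):
        assert segregation(zw, zb) == pytest.approx(expected)

    def test_zero_within_mean_rejected_naming_scope(self):
        with pytest.raises(ValueError, match="visual"):
            segregation(0.0, 0.1, scope="visual")


class TestNetworkPairs:
    @pytest.mark.parametrize("n, expected", [(22, 231), (2, 1), (5, 10)])
    def test_pair_counts(self, n, expected):
        p = NetworkPartition({f"r{i:02d}": "A" for i in range(n)}, ("A",))
        pairs = network_pairs(p, "A")
        assert len(pairs) == expected
        # exhaustive double-loop oracle: each unordered pair exactly once
        regions = sorted(p.assignment)
        oracle = [(a, b) for i, a in enumerate(regions)
                  for b in regions[i + 1:]]
        assert pairs == oracle

    def test_unknown_label_rejected(self, two_block_partition):
        with pytest.raises(KeyError, match="unknown network"):
            network_pairs(two_block_partition, "nope")


class TestEdgeFC:
    def test_symmetric_access_and_zeroing(self):
        ids = ("a", "b")
        z = np.array([[0.0, -0.2], [-0.2, 0.0]])
        m = prepare_matrix(ConnectivityMatrix("s", z, ids))
        assert edge_fc(m, ("a", "b")) == 0.0
        z2 = np.array([[0.0, 0.3], [0.3, 0.0]])
        m2 = ConnectivityMatrix("s", z2, ids, prepared=True)
        assert edge_fc(m2, ("a", "b")) == pytest.approx(0.3)
        assert edge_fc(m2, ("b", "a")) == edge_fc(m2, ("a", "b"))

    def test_unknown_region_rejected(self, two_block_matrix):
        with pytest.raises(KeyError, match="unknown region"):
            edge_fc(two_block_matrix, ("a1", "zz"))


class TestProfileSubject:
    def test_constant_blocks_profile(self, two_block_matrix, two_block_partition):
        pr = profile_subject(two_block_matrix, two_block_partition)
        assert pr.seg_global == pytest.approx(2.0 / 3.0)
        for k in ("A", "B"):
            assert pr.seg[k] == pytest.approx(2.0 / 3.0)
            assert pr.intra[k] == pr.zw[k]
        assert pr.inter[("A", "B")] == pytest.approx(0.2)

    def test_nine_network_fixture_matches_enumeration(self):
        rng = np.random.default_rng(9)
        ids = tuple(f"r{i:02d}" for i in range(20))
        m = random_prepared_matrix(rng, ids)
        nets = tuple(f"N{j}" for j in range(9))
        # 9 networks x 2 regions + 2 extra in N0
        assignment = {ids[i]: nets[i // 2] for i in range(18)}
        assignment[ids[18]] = "N0"
        assignment[ids[19]] = "N0"
        p = NetworkPartition(assignment, nets)
        pr = profile_subject(m, p)
        oracle = enumeration_oracle(m, p)
        assert pr.zw_global == pytest.approx(oracle["zw_g"], abs=1e-12)
        assert pr.zb_global == pytest.approx(oracle["zb_g"], abs=1e-12)
        for k in nets:
            assert pr.zw[k] == pytest.approx(oracle["zw"][k], abs=1e-12)
            assert pr.zb[k] == pytest.approx(oracle["zb"][k], abs=1e-12)
            assert pr.seg[k] == pytest.approx(
                (oracle["zw"][k] - oracle["zb"][k]) / oracle["zw"][k], abs=1e-12)
        for key, v in oracle["inter"].items():
            assert pr.inter[key] == pytest.approx(v, abs=1e-12)

    def test_all_zero_matrix_rejected(self, two_block_partition):
        m = ConnectivityMatrix("s", np.zeros((4, 4)),
                               ("a1", "a2", "b1", "b2"), prepared=True)
        with pytest.raises(ValueError, match="undefined"):
            profile_subject(m, two_block_partition)


class TestProfileInvariants:
    def _random_case(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13))
        ids = tuple(f"r{i:02d}" for i in range(n))
        m = random_prepared_matrix(rng, ids)
        p = random_partition(rng, ids)
        return m, p

    def test_scale_invariance_of_segregation(self):
        m, p = self._random_case(101)
        pr1 = profile_subject(m, p)
        m2 = ConnectivityMatrix(m.subject_id, 3.5 * m.z, m.region_ids,
                                prepared=True)
        pr2 = profile_subject(m2, p)
        assert pr2.seg_global == pytest.approx(pr1.seg_global, abs=1e-12)
        for k in p.networks:
            assert pr2.seg[k] == pytest.approx(pr1.seg[k], abs=1e-12)
            assert pr2.intra[k] == pytest.approx(3.5 * pr1.intra[k], abs=1e-12)
        assert pr2.zw_global == pytest.approx(3.5 * pr1.zw_global, abs=1e-12)

    def test_region_permutation_invariance(self):
        m, p = self._random_case(202)
        pr1 = profile_subject(m, p)
        rng = np.random.default_rng(0)
        perm = rng.permutation(m.n_regions)
        m2 = ConnectivityMatrix(m.subject_id, m.z[np.ix_(perm, perm)],
                                tuple(m.region_ids[i] for i in perm),
                                prepared=True)
        pr2 = profile_subject(m2, p)
        assert pr2.seg_global == pytest.approx(pr1.seg_global, abs=1e-12)
        assert pr2.seg == pytest.approx(pr1.seg, abs=1e-12)

    def test_global_means_are_pair_count_weighted(self):
        m, p = self._random_case(303)
        pr = profile_subject(m, p)
        sizes = {k: p.size_of(k) for k in p.networks}
        w_n = {k: s * (s - 1) / 2 for k, s in sizes.items()}
        zw_weighted = (sum(pr.intra[k] * w_n[k] for k in p.networks)
                       / sum(w_n.values()))
        assert pr.zw_global == pytest.approx(zw_weighted, abs=1e-12)
        b_n = {key: sizes[key[0]] * sizes[key[1]] for key in pr.inter}
        zb_weighted = (sum(pr.inter[key] * b_n[key] for key in pr.inter)
                       / sum(b_n.values()))
        assert pr.zb_global == pytest.approx(zb_weighted, abs=1e-12)

    def test_segregation_bounds(self):
        for seed in range(10):
            m, p = self._random_case(1000 + seed)
            pr = profile_subject(m, p)
            assert pr.seg_global <= 1.0
            assert (pr.seg_global >= 0.0) == (pr.zw_global >= pr.zb_global)


def test_partition_validation():
    with pytest.raises(ValueError, match="empty network"):
        NetworkPartition({"r0": "A", "r1": "A"}, ("A", "B"))
    with pytest.raises(ValueError, match="unknown network"):
        NetworkPartition({"r0": "A", "r1": "C"}, ("A",))


def test_partition_tsv_round_trip(tmp_path, two_block_partition):
    from gripseg.segregation import write_partition
    from gripseg import read_partition

    path = tmp_path / "p.tsv"
    write_partition(two_block_partition, path)
    back = read_partition(path)
    assert back.assignment == two_block_partition.assignment
    assert set(back.networks) == set(two_block_partition.networks)
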