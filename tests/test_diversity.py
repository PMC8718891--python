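import numpy as np
import pandas as pd
import pytest
from scipy.spatial import procrustes
from scipy.spatial.distance import pdist, squareform

from aadrisk.diversity import (
    DissimilarityMatrix,
    bray_curtis,
    cluster_baseline,
    correlation_distance,
    jensen_shannon_distance,
    pairwise_distances,
    pcoa,
    permanova,
    shannon,
)


class TestShannon:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.25, 0.25, 0.25, 0.25], 2.0),
            ([1.0], 0.0),
            ([0.5, 0.25, 0.25], 1.5),
            ([0.5, 0.5, 0.0], 1.0),  # 0 log 0 = 0
        ],
    )
    def test_known_entropies_in_bits(self, p, expected):
        assert shannon(p) == pytest.approx(expected, abs=1e-12)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            shannon([1.2, -0.2])

    def test_natural_log_base_available(self):
        assert shannon([0.5, 0.5], base=np.e) == pytest.approx(np.log(2))


class TestJensenShannon:
    def test_identical_distributions_have_zero_distance(self):
        assert jensen_shannon_distance([0.3, 0.7], [0.3, 0.7]) == 0.0

    def test_disjoint_supports_reach_one(self):
        assert jensen_shannon_distance([1, 0], [0, 1]) == pytest.approx(1.0)

    def test_hand_derived_value(self):
        # m=(0.75,0.25): H(m)-0.5*H(q) = 0.811278 - 0.5 = 0.311278; sqrt
        assert jensen_shannon_distance([1, 0], [0.5, 0.5]) == pytest.approx(
            0.5579, abs=1e-4
        )

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            jensen_shannon_distance([1, 0], [0.5, 0.25, 0.25])


class TestBrayCurtis:
    @pytest.mark.parametrize(
        "u, v, expected",
        [
            ([2, 2], [2, 2], 0.0),
            ([1, 0], [0, 3], 1.0),
            ([2, 2], [2, 0], 1 / 3),
        ],
    )
    def test_formula(self, u, v, expected):
        assert bray_curtis(u, v) == pytest.approx(expected)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis([0, 0], [0, 0])


def test_pairwise_distance_matrices_are_valid_and_bounded(default_study):
    sub = default_study.count_table.counts.iloc[:, :8]
    for metric in ("braycurtis", "jensenshannon"):
        dm = pairwise_distances(sub, metric)
        assert np.allclose(dm.data, dm.data.T)
        assert np.allclose(np.diag(dm.data), 0)
        assert (dm.data <= 1 + 1e-12).all() and (dm.data >= 0).all()


class TestPcoa:
    def test_collinear_points_explained_by_first_axis(self):
        pts = np.array([[0.0], [1.0], [2.0]])
        d = squareform(pdist(pts))
        result = pcoa(DissimilarityMatrix(["a", "b", "c"], d), 2)
        assert result.proportion_explained[0] == pytest.approx(1.0)
        assert result.proportion_explained[1] == pytest.approx(0.0, abs=1e-9)

    def test_all_zero_matrix_gives_zero_coordinates(self):
        dm = DissimilarityMatrix(list("abc"), np.zeros((3, 3)))
        result = pcoa(dm, 2)
        assert np.allclose(result.coordinates.to_numpy(), 0.0)

    def test_unit_square_splits_variance_evenly(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        d = squareform(pdist(pts))
        result = pcoa(DissimilarityMatrix(list("abcd"), d), 2)
        assert result.eigenvalues[0] == pytest.approx(result.eigenvalues[1])
        assert result.proportion_explained.tolist() == pytest.approx([0.5, 0.5])

    def test_recovers_planted_configuration(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(12, 2))
        d = squareform(pdist(pts))
        result = pcoa(DissimilarityMatrix([str(i) for i in range(12)], d), 2)
        _, _, disparity = procrustes(pts, result.coordinates.to_numpy())
        assert disparity < 1e-8

    def test_asymmetric_input_rejected(self):
        d = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            DissimilarityMatrix(["a", "b"], d)


class TestPermanova:
    @pytest.fixture
    def iid_dm(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(16, 4))
        return DissimilarityMatrix(
            [str(i) for i in range(16)], squareform(pdist(pts))
        )

    def test_group_name_relabeling_leaves_f_unchanged(self, iid_dm):
        groups = np.array(["x"] * 8 + ["y"] * 8)
        renamed = np.array(["blue"] * 8 + ["red"] * 8)
        f1 = permanova(iid_dm, groups, 99, seed=0).pseudo_f
        f2 = permanova(iid_dm, renamed, 99, seed=0).pseudo_f
        assert f1 == pytest.approx(f2)

    def test_p_invariant_to_consistent_sample_permutation(self, iid_dm):
        groups = np.array(["x"] * 8 + ["y"] * 8)
        rng = np.random.default_rng(2)
        perm = rng.permutation(16)
        dm2 = DissimilarityMatrix(
            [iid_dm.ids[i] for i in perm], iid_dm.data[np.ix_(perm, perm)]
        )
        r1 = permanova(iid_dm, groups, 199, seed=1)
        r2 = permanova(dm2, groups[perm], 199, seed=1)
        assert r1.pseudo_f == pytest.approx(r2.pseudo_f)
        # permuted-label null is exchangeable: p-values agree closely
        assert abs(r1.p - r2.p) < 0.08

    def test_matches_reference_implementation(self, iid_dm):
        skbio = pytest.importorskip("skbio")
        groups = np.array(["x"] * 8 + ["y"] * 8)
        mine = permanova(iid_dm, groups, 99, seed=0)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(iid_dm.data, iid_dm.ids),
            groups, permutations=99,
        )
        assert mine.pseudo_f == pytest.approx(ref["test statistic"])

    def test_single_group_rejected(self, iid_dm):
        with pytest.raises(ValueError, match="2 groups"):
            permanova(iid_dm, ["a"] * 16, 99, seed=0)


class TestClusterBaseline:
    def test_identical_profiles_share_a_cluster_merged_at_zero(self):
        profiles = pd.DataFrame(
            [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [3.0, 2.0, 1.0]],
            index=["a", "b", "c"],
        )
        result = cluster_baseline(profiles, threshold=0.4)
        assert result.clusters["a"] == result.clusters["b"]
        assert result.clusters["c"] != result.clusters["a"]
        assert result.linkage[0, 2] == pytest.approx(0.0)

    def test_anticorrelated_pair_distance_two_separate_clusters(self):
        profiles = pd.DataFrame([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]],
                                index=["a", "b"])
        dm = correlation_distance(profiles)
        assert dm.data[0, 1] == pytest.approx(2.0)
        result = cluster_baseline(profiles, threshold=0.4)
        assert result.clusters.nunique() == 2

    def test_two_block_structure_cut_into_two_clusters(self):
        rng = np.random.default_rng(0)
        base1, base2 = rng.normal(size=(2, 20))
        rows = [base1 + rng.normal(0, 0.2, 20) for _ in range(3)]
        rows += [base2 + rng.normal(0, 0.2, 20) for _ in range(3)]
        profiles = pd.DataFrame(rows, index=list("abcdef"))
        result = cluster_baseline(profiles, threshold=0.4)
        assert result.clusters.nunique() == 2
        assert len(set(result.clusters[list("abc")])) == 1
        assert len(set(result.clusters[list("def")])) == 1

    def test_zero_variance_subject_named_in_error(self):
        profiles = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]],
                                index=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            cluster_baseline(profiles)
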