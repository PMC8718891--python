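import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from aadrisk.group_stats import bonferroni, compare_taxa, mann_whitney_u, spearman
from aadrisk.tables import aggregate


class TestMannWhitney:
    def test_fully_separated_small_samples_exact_p(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(2 / 20)  # 2 * 1/C(6,3)

    def test_identical_samples_give_p_near_one(self):
        _, p = mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
        assert p > 0.9

    def test_scale_invariance_of_u_and_p(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=9), rng.normal(0.5, size=11)
        u1, p1 = mann_whitney_u(x, y)
        u2, p2 = mann_whitney_u(17.3 * x, 17.3 * y)
        assert u1 == u2 and p1 == pytest.approx(p2)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney_u([], [1.0])

    @pytest.mark.parametrize("n1,n2", [(3, 5), (6, 6), (8, 8), (4, 8)])
    def test_exact_branch_matches_scipy_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 31 + n2)
        for _ in range(20):
            x = rng.normal(size=n1)
            y = rng.normal(0.4, size=n2)
            u, p = mann_whitney_u(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_tied_large_samples_match_scipy_asymptotic(self):
        rng = np.random.default_rng(9)
        x = np.round(rng.normal(size=25), 1)
        y = np.round(rng.normal(0.3, size=30), 1)
        u, p = mann_whitney_u(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)


class TestBonferroni:
    def test_multiplies_by_family_size(self):
        assert bonferroni([0.02], family_size=5)[0] == pytest.approx(0.10)

    def test_caps_at_one(self):
        assert bonferroni([0.5, 0.9], family_size=2).tolist() == [1.0, 1.0]

    def test_family_of_one_is_identity(self):
        assert bonferroni([0.31], family_size=1)[0] == pytest.approx(0.31)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=10))
    def test_corrected_values_stay_in_unit_interval(self, ps):
        out = bonferroni(ps)
        assert ((0 <= out) & (out <= 1)).all()


class TestSpearman:
    def test_monotone_pairs(self):
        assert spearman([1, 2, 3, 5], [2, 4, 9, 10])[0] == pytest.approx(1.0)
        assert spearman([1, 2, 3, 5], [10, 9, 4, 2])[0] == pytest.approx(-1.0)

    def test_hand_derived_rho(self):
        rho, _ = spearman([1, 2, 3, 4], [1, 3, 2, 4])
        assert rho == pytest.approx(0.8)  # 1 - 6*2/(4*15)

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(4)
        x = np.round(rng.normal(size=20), 1)
        y = x + rng.normal(size=20)
        rho, p = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_invariant_under_strictly_monotone_transform(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0.1, 5, size=15)
        y = rng.uniform(0.1, 5, size=15)
        rho1, _ = spearman(x, y)
        rho2, _ = spearman(np.log(x), y ** 3)
        assert rho1 == pytest.approx(rho2)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1, 1, 1], [1, 2, 3])


class TestCompareTaxa:
    def test_identical_groups_never_significant(self, toy_table):
        # duplicate a sample into both groups so distributions coincide
        counts = pd.concat(
            [toy_table.counts[["s1"]].rename(columns={"s1": f"c{i}"})
             for i in range(6)], axis=1,
        )
        meta = pd.DataFrame(
            {"subject_id": [f"u{i}" for i in range(6)], "day": [0] * 6},
            index=pd.Index([f"c{i}" for i in range(6)], name="sample_id"),
        )
        table = type(toy_table)(counts, toy_table.lineages, meta)
        profile = aggregate(table, "family")
        labels = pd.Series([True, True, True, False, False, False],
                           index=[f"u{i}" for i in range(6)])
        out = compare_taxa(profile, labels)
        assert (out["p_bonf"] == 1.0).all()

    def test_family_size_one_leaves_p_uncorrected(self, family_profile, default_study):
        labels = default_study.truth["group"] == "AAD"
        out = compare_taxa(family_profile, labels, days=[0],
                           taxa=["Ruminococcaceae"], family_size=1)
        assert len(out) == 1
        assert out["p_bonf"].iloc[0] == pytest.approx(out["p_raw"].iloc[0])

    def test_declared_family_size_recorded(self, family_profile, default_study):
        labels = default_study.truth["group"] == "AAD"
        out = compare_taxa(family_profile, labels, days=[0, 2])
        assert (out["family_size"] == len(out)).all()
        assert set(out["day"]) == {0, 2}

    def test_undersized_group_skipped_with_warning(self, family_profile, default_study):
        labels = pd.Series(False, index=default_study.truth.index)
        labels.iloc[0] = True  # one-sample group
        with pytest.warns(UserWarning, match="<2 samples"):
            out = compare_taxa(family_profile, labels, days=[0])
        assert out.empty


def test_exact_and_asymptotic_branches_agree_for_n8():
    """The normal approximation tracks full enumeration closely at n=8."""
    rng = np.random.default_rng(12)
    for _ in range(200):
        x = rng.normal(size=8)
        y = rng.normal(rng.uniform(-1, 1), size=8)
        _, p_exact = mann_whitney_u(x, y, method="exact")
        _, p_asym = mann_whitney_u(x, y, method="asymptotic")
        assert abs(p_exact - p_asym) <= 0.02
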