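import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pankit.errors import DomainError
from pankit.matrix_io import OrthologMatrix, partition_groups
from pankit.profiles import (
    DEFAULT_EXCLUDED_FAMILIES,
    FamilyProfile,
    bh_adjust,
    family_distribution_test,
    gc_content,
    gh_pca,
    holm_adjust,
    length_summary,
    mann_whitney_exact,
    partition_enrichment,
)


class TestGcContent:
    def test_all_gc(self):
        assert gc_content("GGCC") == 1.0

    def test_ambiguous_excluded_from_denominator(self):
        assert gc_content("ATATNN") == 0.0
        assert gc_content("GCNN") == 1.0

    def test_case_and_order_invariance(self):
        assert gc_content({"a": "acgt", "b": "GGCC"}) == gc_content({"b": "ggcc", "a": "ACGT"})

    def test_reverse_complement_invariance(self):
        s = "ACGGTTACGGAT"
        rc = s.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        assert gc_content(s) == gc_content(rc)

    def test_no_unambiguous_bases(self):
        with pytest.raises(DomainError):
            gc_content("NNNN")


class TestMannWhitney:
    def test_exact_separated_groups(self):
        # {1,2,3} vs {4,5,6}: U = 0; exact two-sided p = 2/20 = 0.1
        U, p = mann_whitney_exact([1, 2, 3], [4, 5, 6])
        assert U == 0.0
        assert p == pytest.approx(0.1)

    def test_enumeration_oracle_with_ties(self):
        x, y = [1.0, 2.0, 2.0], [2.0, 3.0, 4.0]
        U_obs, p = mann_whitney_exact(x, y)
        ranks = stats.rankdata(np.concatenate([x, y]))
        mu = 4.5
        count = sum(
            abs(ranks[list(c)].sum() - 6.0 - mu) >= abs(U_obs - mu) - 1e-9
            for c in itertools.combinations(range(6), 3)
        )
        assert p == pytest.approx(count / 20)

    def test_large_samples_use_asymptotic(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 30)
        y = rng.normal(1, 1, 30)
        _, p = mann_whitney_exact(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert p == pytest.approx(ref)


class TestLengthSummary:
    def test_contig_sum(self):
        res = length_summary({"g": {"c1": "A" * 100, "c2": "C" * 50}})
        assert res.lengths["g"] == 150
        assert res.median == 150

    def test_presummed_values_accepted(self):
        res = length_summary({"a": 10.0, "b": 30.0, "c": 20.0})
        assert res.median == 20.0

    def test_group_comparison(self):
        genomes = {f"s{i}": float(v) for i, v in enumerate([1, 2, 3, 4, 5, 6])}
        labels = {f"s{i}": ("low" if i < 3 else "high") for i in range(6)}
        res = length_summary(genomes, labels, compare=("low", "high"))
        assert res.comparison["p"] == pytest.approx(0.1)

    def test_missing_group_skips_comparison(self):
        res = length_summary({"a": 1.0}, {"a": "x"}, compare=("x", "y"))
        assert res.comparison is None


def _profile(counts: np.ndarray, families, labels=None) -> FamilyProfile:
    df = pd.DataFrame(counts, index=[f"s{i}" for i in range(counts.shape[0])], columns=families)
    return FamilyProfile(df, labels)


class TestFamilyProfile:
    def test_default_exclusion(self):
        fams = ["GH13", "GH23", "GH25", "GH73", "GH103", "GH20"]
        prof = _profile(np.ones((3, 6)), fams)
        assert set(prof.excluded_found) == {"GH23", "GH25", "GH73", "GH103"}
        assert prof.families == ["GH13", "GH20"]

    def test_exclusion_matches_bare_numbers(self):
        prof = _profile(np.ones((3, 3)), ["23", "13", "gh103"])
        assert prof.families == ["13"]
        assert DEFAULT_EXCLUDED_FAMILIES == {"GH23", "GH25", "GH73", "GH103"}


class TestGhPca:
    def test_identical_profiles_zero_variance(self):
        prof = _profile(np.tile([3.0, 1.0, 2.0], (4, 1)), ["GH1", "GH2", "GH3"])
        coords, loadings, evr = gh_pca(prof, scaled=False)
        assert np.allclose(coords.to_numpy(), 0.0)

    def test_cluster_separation(self):
        rng = np.random.default_rng(1)
        blocks = []
        for c in range(3):
            base = np.zeros(6)
            base[2 * c : 2 * c + 2] = 8
            blocks.append(base + rng.poisson(0.3, size=(5, 6)))
        prof = _profile(np.vstack(blocks), [f"GH{i}" for i in range(1, 7)])
        coords, _, _ = gh_pca(prof, scaled=True)
        from sklearn.metrics import silhouette_score

        labels = np.repeat([0, 1, 2], 5)
        assert silhouette_score(coords.iloc[:, :2], labels) > 0.5

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(2)
        X = rng.poisson(3, size=(6, 4)).astype(float)
        prof = _profile(X, ["GH1", "GH2", "GH4", "GH5"])
        _, loadings, _ = gh_pca(prof, scaled=True)
        for pc in loadings.columns:
            col = loadings[pc]
            assert col.iloc[np.argmax(np.abs(col.to_numpy()))] > 0

    def test_strain_reordering_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.poisson(4, size=(7, 5)).astype(float)
        fams = ["GH1", "GH2", "GH4", "GH5", "GH6"]
        a, _, _ = gh_pca(_profile(X, fams), scaled=True)
        perm = rng.permutation(7)
        df = pd.DataFrame(X[perm], index=[f"s{i}" for i in perm], columns=fams)
        b, _, _ = gh_pca(FamilyProfile(df), scaled=True)
        np.testing.assert_allclose(
            a.loc[b.index].to_numpy(), b.to_numpy(), atol=1e-9
        )

    def test_too_few_usable_families(self):
        prof = _profile(np.ones((4, 2)), ["GH1", "GH2"])
        with pytest.raises(DomainError):
            gh_pca(prof, scaled=True)  # both zero-variance


class TestAdjustments:
    @pytest.mark.parametrize("pvals", [
        [0.01, 0.02, 0.03],
        [0.5, 0.001, 0.04, 0.9, 0.04],
        [1.0, 1.0],
    ])
    def test_holm_matches_direct_formula(self, pvals):
        adj = holm_adjust(pvals)
        m = len(pvals)
        order = np.argsort(pvals)
        expected = np.empty(m)
        running = 0.0
        for r, i in enumerate(order):
            running = max(running, (m - r) * pvals[i])
            expected[i] = min(1.0, running)
        np.testing.assert_allclose(adj, expected)
        assert (adj >= np.asarray(pvals) - 1e-12).all()
        assert (adj <= 1.0).all()

    @pytest.mark.parametrize("pvals", [
        [0.01, 0.02, 0.03],
        [0.5, 0.001, 0.04, 0.9, 0.04],
    ])
    def test_bh_monotone_and_bounded(self, pvals):
        q = bh_adjust(pvals)
        order = np.argsort(pvals)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= np.asarray(pvals) - 1e-12).all()
        assert (q <= 1.0).all()

    def test_bh_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        p = [0.04, 0.001, 0.3, 0.7, 0.02, 0.02]
        np.testing.assert_allclose(
            bh_adjust(p), multipletests(p, method="fdr_bh")[1]
        )

    def test_holm_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        p = [0.04, 0.001, 0.3, 0.7, 0.02, 0.02]
        np.testing.assert_allclose(
            holm_adjust(p), multipletests(p, method="holm")[1]
        )


class TestFamilyDistributionTest:
    def _labels(self, sizes):
        labels = {}
        i = 0
        for gname, size in sizes.items():
            for _ in range(size):
                labels[f"s{i}"] = gname
                i += 1
        return labels

    def test_identical_family_not_flagged(self):
        counts = np.column_stack([np.full(9, 4.0), np.arange(9.0)])
        prof = _profile(counts, ["GH1", "GH2"], self._labels({"a": 3, "b": 3, "c": 3}))
        res = family_distribution_test(prof)
        assert not res.loc["GH1", "non_uniform"]
        assert res.loc["GH1", "p"] == 1.0

    def test_separated_family_flagged(self):
        counts = np.column_stack(
            [
                np.array([0, 0, 0, 0, 5, 6, 7, 8, 0, 0, 1, 0], dtype=float),
                np.full(12, 2.0),
            ]
        )
        prof = _profile(counts, ["GH1", "GH2"], self._labels({"a": 4, "b": 4, "c": 4}))
        res = family_distribution_test(prof)
        # rank-statistic oracle for the raw Kruskal-Wallis p of GH1
        raw = stats.kruskal(
            counts[:4, 0], counts[4:8, 0], counts[8:, 0]
        ).pvalue
        assert res.loc["GH1", "p"] == pytest.approx(raw)
        assert res.loc["GH1", "p"] < res.loc["GH2", "p"]
        assert res.loc["GH1", "non_uniform"]

    def test_requires_two_groups(self):
        prof = _profile(np.ones((4, 2)), ["GH1", "GH2"], {f"s{i}": "only" for i in range(4)})
        with pytest.raises(DomainError):
            family_distribution_test(prof)


class TestPartitionEnrichment:
    def _matrix(self):
        # 20 groups: 5 core, 10 moderate, 5 rare over 4 strains
        occ = np.zeros((4, 20), dtype=int)
        occ[:, :5] = 1
        occ[:2, 5:15] = 1
        occ[0, 15:] = 1
        return OrthologMatrix(
            list("ABCD"), [f"g{j}" for j in range(20)], occ
        )

    def test_fisher_hand_oracle(self):
        # [[10, 0], [0, 10]] -> two-sided p = 2 / C(20,10)
        _, p = stats.fisher_exact([[10, 0], [0, 10]])
        assert p == pytest.approx(2 / math.comb(20, 10))
        assert p == pytest.approx(1.083e-5, rel=1e-3)

    def test_uniform_classes_not_significant(self):
        m = self._matrix()
        part = partition_groups(m)
        classes = {f"g{j}": ("X" if j % 2 else "Y") for j in range(20)}
        table = partition_enrichment(m, part, classes)
        assert not table["significant"].any()

    def test_concentrated_class_detected(self):
        occ = np.zeros((4, 40), dtype=int)
        occ[:, :20] = 1        # 20 core
        occ[0, 20:] = 1        # 20 rare
        m = OrthologMatrix(list("ABCD"), [f"g{j}" for j in range(40)], occ)
        part = partition_groups(m)
        classes = {f"g{j}": ("mob" if j >= 20 else "house") for j in range(40)}
        table = partition_enrichment(m, part, classes).set_index(["class", "cell"])
        assert table.loc[("mob", "rare"), "q"] < 0.05

    def test_unlabeled_groups_excluded(self):
        m = self._matrix()
        part = partition_groups(m)
        classes = {"g0": "X", "g1": "", "g2": None}
        table = partition_enrichment(m, part, classes)
        assert set(table["a"] + table["b"]) <= {1}

    def test_q_at_least_p(self):
        m = self._matrix()
        part = partition_groups(m)
        classes = {f"g{j}": ("X" if j < 7 else "Y") for j in range(20)}
        table = partition_enrichment(m, part, classes)
        assert (table["q"] >= table["p"] - 1e-12).all()

    def test_no_annotations_empty_table(self):
        m = self._matrix()
        part = partition_groups(m)
        table = partition_enrichment(m, part, {})
        assert table.empty
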