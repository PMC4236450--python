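"""Structure pipeline: subset filter, LD pruning, PCA, distances, Mantel,
neighbor joining."""

import io
import itertools

import numpy as np
import pandas as pd
import pytest

import popvar as pv
from popvar.errors import ContractError
from popvar.structure import _window_r2
from tests.test_variants import tiny_matrix


class TestSubsetPolymorphicFilter:
    def _cohort(self):
        rng = np.random.default_rng(5)
        dosage = rng.integers(0, 3, size=(40, 200)).astype(np.int8)
        dosage[:, 0] = 0                     # monomorphic everywhere
        dosage[:20, 1] = 0                   # monomorphic within population A
        m = tiny_matrix(dosage)
        panel = pv.make_panel(m.samples, ["A"] * 20 + ["B"] * 20)
        return m, panel

    def test_monomorphic_in_one_subset_removed(self):
        m, panel = self._cohort()
        filtered, subsets = pv.subset_polymorphic_filter(m, panel, 16, seed=1)
        kept = set(filtered.variant_keys())
        assert m.variant_keys()[0] not in kept
        assert m.variant_keys()[1] not in kept
        assert all(len(s) == 16 for s in subsets.values())

    def test_small_population_used_whole(self):
        m, panel = self._cohort()
        _, subsets = pv.subset_polymorphic_filter(m, panel, 30, seed=1)
        assert len(subsets["A"]) == 20

    def test_same_seed_reproduces(self):
        m, panel = self._cohort()
        f1, s1 = pv.subset_polymorphic_filter(m, panel, 16, seed=42)
        f2, s2 = pv.subset_polymorphic_filter(m, panel, 16, seed=42)
        assert s1 == s2
        assert f1.variant_keys() == f2.variant_keys()

    def test_kept_variants_polymorphic_in_every_subset(self):
        m, panel = self._cohort()
        filtered, subsets = pv.subset_polymorphic_filter(m, panel, 16, seed=3)
        for subset in subsets.values():
            alt, total = pv.allele_counts_array(filtered, subset)
            assert ((alt > 0) & (alt < total)).all()


class TestLdPrune:
    def test_duplicated_columns_lose_one_copy(self):
        rng = np.random.default_rng(2)
        base = rng.integers(0, 3, size=(30, 10)).astype(np.int8)
        dosage = np.repeat(base, 2, axis=1)  # adjacent duplicates, r^2 = 1
        m = tiny_matrix(dosage)
        kept = pv.ld_prune(m, window=6, step=2, r2_max=0.5)
        assert len(kept) == 10
        assert (np.diff(sorted(kept)) == 2).all()  # one of each pair

    def test_independent_variants_all_retained(self):
        rng = np.random.default_rng(3)
        m = tiny_matrix(rng.integers(0, 3, size=(200, 40)).astype(np.int8))
        kept = pv.ld_prune(m)
        assert len(kept) == 40

    def test_hand_built_window(self):
        # r^2(1,2) > 0.5, r^2(1,3) and r^2(2,3) < 0.5: variant 2 (the later
        # of the offending pair) is removed
        v1 = np.array([0, 0, 1, 1, 2, 2, 0, 1, 2, 0])
        v2 = np.array([0, 0, 1, 2, 2, 2, 0, 1, 2, 0])
        v3 = np.array([2, 0, 1, 2, 0, 1, 1, 0, 2, 1])
        r2 = np.corrcoef(np.c_[v1, v2, v3].T) ** 2
        assert r2[0, 1] > 0.5 and r2[0, 2] < 0.5 and r2[1, 2] < 0.5
        m = tiny_matrix(np.c_[v1, v2, v3])
        kept = pv.ld_prune(m, window=3, step=1, r2_max=0.5)
        assert kept.tolist() == [0, 2]

    def test_no_retained_window_pair_exceeds_threshold(self, small_sim):
        _, sim = small_sim
        m = pv.drop_missing_variants(sim["matrix"])
        kept = pv.ld_prune(m, window=50, step=5, r2_max=0.5)
        pruned = m.take_variants(kept)
        chroms = pruned.variants["chrom"].to_numpy()
        for chrom in dict.fromkeys(chroms):
            idx = np.flatnonzero(chroms == chrom)
            for start in range(0, max(1, len(idx) - 1), 5):
                win = idx[start : start + 50]
                if len(win) < 2:
                    continue
                r2 = _window_r2(pruned.dosage[:, win])
                np.fill_diagonal(r2, 0.0)
                assert r2.max() <= 0.5 + 1e-9

    def test_zero_variance_variant_is_inert(self):
        rng = np.random.default_rng(4)
        dosage = rng.integers(0, 3, size=(30, 5)).astype(np.int8)
        dosage[:, 2] = 1
        m = tiny_matrix(dosage)
        kept = pv.ld_prune(m, window=5, step=1, r2_max=0.5)
        assert 2 in kept.tolist()


class TestPca:
    def test_scores_orthogonal(self, rng):
        coded = rng.integers(1, 4, size=(20, 100))
        res = pv.pca(coded)
        g = res.scores.T @ res.scores
        off = g - np.diag(np.diag(g))
        assert np.abs(off).max() < 1e-8

    def test_explained_fractions_sorted_and_normalized(self, rng):
        res = pv.pca(rng.integers(1, 4, size=(15, 60)))
        ef = res.explained_fraction
        assert (np.diff(ef) <= 1e-12).all()
        assert ef.sum() == pytest.approx(1.0)

    def test_identical_rows_flagged_degenerate(self):
        row = np.array([1, 2, 3, 1, 2, 3])
        with pytest.warns(Warning):
            res = pv.pca(np.tile(row, (5, 1)))
        assert res.degenerate
        assert np.allclose(res.explained_fraction, 0.0)

    def test_two_populations_separate_on_pc1(self):
        cfg = pv.SimConfig(
            n_populations=2, samples_per_population=16, n_snps=3000,
            fst=0.15, n_gwas_snps=0, n_planted_outliers=0, n_rare=0,
            n_low_count_private=0, n_private=0, seed=9,
        )
        m, _, panel, _ = pv.simulate_genotypes(cfg)
        coded = pv.code_genotypes(pv.drop_missing_variants(m))
        res = pv.pca(coded, m.samples)
        pc1 = res.scores[:, 0]
        a, b = pc1[:16], pc1[16:]
        assert a.max() < b.min() or b.max() < a.min()


class TestGeneticDistance:
    def test_identical_samples_zero(self):
        d = pv.genetic_distance(np.array([[1, 2, 3], [1, 2, 3]]), ["a", "b"])
        assert d.values[0, 1] == 0.0

    def test_opposite_homozygotes_max_distance(self):
        d = pv.genetic_distance(np.array([[1, 1], [3, 3]]), ["a", "b"])
        assert d.values[0, 1] == 1.0

    def test_direct_formula(self):
        d = pv.genetic_distance(np.array([[0, 1, 2], [2, 1, 0]]), ["a", "b"])
        assert d.values[0, 1] == pytest.approx(2 / 3)

    def test_euclidean_alternative(self):
        d = pv.genetic_distance(
            np.array([[1, 1], [3, 3]]), ["a", "b"], metric="euclidean"
        )
        assert d.values[0, 1] == pytest.approx(np.sqrt(8))


class TestGeographicDistance:
    def test_quarter_circumference(self):
        panel = pv.make_panel(["a", "b"], ["P", "P"], [0.0, 0.0], [0.0, 90.0])
        d = pv.geographic_distance(panel)
        assert d.values[0, 1] == pytest.approx(np.pi / 2 * 6371.0, rel=1e-9)

    def test_same_point_zero(self):
        panel = pv.make_panel(["a", "b"], ["P", "P"], [39.0, 39.0],
                              [32.0, 32.0])
        assert pv.geographic_distance(panel).values[0, 1] == 0.0

    def test_missing_coordinates_listed(self):
        panel = pv.make_panel(["a", "b"], ["P", "P"], [1.0, np.nan],
                              [1.0, 2.0])
        with pytest.raises(ContractError, match="b"):
            pv.geographic_distance(panel)


def random_distance_matrix(rng, n, ids=None):
    v = rng.uniform(0.1, 1.0, size=(n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    return pv.DistanceMatrix(ids or [f"s{i}" for i in range(n)], v)


class TestMantel:
    def test_perfect_monotone_association(self, rng):
        d1 = random_distance_matrix(rng, 12)
        d2 = pv.DistanceMatrix(d1.ids, 2 * d1.values)
        r, p = pv.mantel_test(d1, d2, n_perm=199, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 200)

    def test_r_bounded(self, rng):
        for seed in range(5):
            d1 = random_distance_matrix(rng, 10)
            d2 = random_distance_matrix(rng, 10)
            r, p = pv.mantel_test(d1, d2, n_perm=99, seed=seed)
            assert -1.0 <= r <= 1.0
            assert 0.0 < p <= 1.0

    def test_constant_matrix_rejected(self):
        ids = list("abcd")
        flat = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(ContractError):
            pv.mantel_test(
                pv.DistanceMatrix(ids, flat), pv.DistanceMatrix(ids, flat),
                n_perm=99, seed=0,
            )

    def test_agrees_with_independent_implementation(self, rng):
        # oracle: rank-free Pearson Mantel statistic recomputed from scratch
        d1 = random_distance_matrix(rng, 10)
        d2 = random_distance_matrix(rng, 10)
        r, _ = pv.mantel_test(d1, d2, n_perm=99, seed=0)
        iu = np.triu_indices(10, 1)
        expected = np.corrcoef(d1.values[iu], d2.values[iu])[0, 1]
        assert r == pytest.approx(expected, abs=1e-12)


def random_additive_matrix(rng, n):
    """Pairwise path-length distances on a random binary tree with positive
    branch lengths: an additive matrix with a known generating topology."""
    comps = [({i}, {i: 0.0}) for i in range(n)]
    d = np.zeros((n, n))
    while len(comps) > 1:
        i, j = sorted(rng.choice(len(comps), size=2, replace=False))
        (xa, da), (xb, db) = comps[i], comps[j]
        la, lb = rng.uniform(0.1, 2.0, size=2)
        for a in xa:
            for b in xb:
                d[a, b] = d[b, a] = da[a] + la + db[b] + lb
        merged = {a: da[a] + la for a in xa}
        merged.update({b: db[b] + lb for b in xb})
        comps = [c for k, c in enumerate(comps) if k not in (i, j)]
        comps.append((xa | xb, merged))
    return d


def dendropy_nj(ids, d):
    """Independent neighbor-joining oracle (dendropy's implementation)."""
    import dendropy

    src = io.StringIO(
        "," + ",".join(ids) + "\n"
        + "\n".join(
            t + "," + ",".join(repr(float(x)) for x in row)
            for t, row in zip(ids, np.asarray(d))
        )
    )
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(src, delimiter=",")
    return pdm.nj_tree()


class TestNeighborJoining:
    def test_three_taxon_exact_solution(self):
        d = pv.DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], dtype=float),
        )
        newick = pv.nj_tree(d)
        assert newick == "(A:1,B:1,C:2);"

    def test_two_identical_taxa_form_zero_length_cherry(self):
        d = pv.DistanceMatrix(
            ["A", "B", "C", "D"],
            np.array(
                [[0, 0, 5, 5], [0, 0, 5, 5], [5, 5, 0, 2], [5, 5, 2, 0]],
                dtype=float,
            ),
        )
        newick = pv.nj_tree(d)
        assert "A:0" in newick and "B:0" in newick

    def test_additive_four_taxon_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:4)); path-length distances are additive
        d = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        dm = pv.DistanceMatrix(list("ABCD"), d)
        newick = pv.nj_tree(dm)
        import dendropy

        tns = dendropy.TaxonNamespace()
        mine = dendropy.Tree.get(
            data=newick, schema="newick", taxon_namespace=tns
        )
        # recovered tree must reproduce the additive distances exactly
        pdm = mine.phylogenetic_distance_matrix()
        for i, a in enumerate("ABCD"):
            for j, b in enumerate("ABCD"):
                if i < j:
                    ta = tns.get_taxon(a)
                    tb = tns.get_taxon(b)
                    assert pdm.distance(ta, tb) == pytest.approx(d[i, j])

    def test_matches_independent_oracle_on_random_additive_matrices(self, rng):
        import dendropy

        for trial in range(5):
            n = 6
            ids = [f"t{i}" for i in range(n)]
            d = random_additive_matrix(rng, n)
            newick = pv.nj_tree(pv.DistanceMatrix(ids, d))
            tns = dendropy.TaxonNamespace()
            mine = dendropy.Tree.get(
                data=newick, schema="newick", taxon_namespace=tns
            )
            oracle = dendropy.Tree.get(
                data=dendropy_nj(ids, d).as_string(schema="newick"),
                schema="newick", taxon_namespace=tns,
            )
            mine.encode_bipartitions()
            oracle.encode_bipartitions()
            rf = dendropy.calculate.treecompare.symmetric_difference(
                mine, oracle
            )
            assert rf == 0
            # additive input: path distances must be reproduced exactly
            pdm = mine.phylogenetic_distance_matrix()
            for i in range(n):
                for j in range(i + 1, n):
                    assert pdm.distance(
                        tns.get_taxon(ids[i]), tns.get_taxon(ids[j])
                    ) == pytest.approx(d[i, j], abs=1e-9)

    def test_star_matrix_gives_equal_terminal_branches(self):
        n = 6
        ids = [f"s{i}" for i in range(n)]
        d = np.full((n, n), 2.0)
        np.fill_diagonal(d, 0.0)
        newick = pv.nj_tree(pv.DistanceMatrix(ids, d))
        import re

        lengths = [float(x) for x in re.findall(r":([0-9.eE+-]+)", newick)]
        terminal = lengths  # every split is length 1 or 0 on a star
        assert all(
            l == pytest.approx(1.0) or l == pytest.approx(0.0)
            for l in terminal
        )

    def test_negative_distances_rejected(self):
        d = np.array([[0, -1, 1], [-1, 0, 1], [1, 1, 0]], dtype=float)
        with pytest.raises(ContractError):
            pv.nj_tree(pv.DistanceMatrix(list("abc"), d))
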