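"""Distances, deterministic agglomeration, and multiscale-bootstrap AU."""

import numpy as np
import pandas as pd
import pytest

from mirrescue import au_bootstrap, hierarchical_cluster, sample_distance
from mirrescue.cluster import _fit_au


def _df(arr, columns):
    return pd.DataFrame(arr, columns=columns)


class TestSampleDistance:
    def test_identical_samples_have_zero_distance(self):
        x = np.random.default_rng(0).normal(size=20)
        d = sample_distance(_df(np.column_stack([x, x, x]), ["a", "b", "c"]))
        assert d.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_samples_have_distance_two(self):
        x = np.array([1.0, -1.0, 2.0, -2.0, 0.5, -0.5])
        d = sample_distance(_df(np.column_stack([x, -x, x * 2]),
                                ["a", "b", "c"]))
        assert d.loc["a", "b"] == pytest.approx(2.0)

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(1)
        d = sample_distance(_df(rng.normal(size=(30, 5)), list("abcde")))
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)

    def test_constant_vector_rejected_under_correlation(self):
        arr = np.column_stack([np.ones(10), np.arange(10), np.arange(10) ** 2])
        with pytest.raises(ValueError, match="constant"):
            sample_distance(_df(arr, ["a", "b", "c"]))

    def test_euclidean_option(self):
        arr = np.column_stack([np.zeros(4), np.full(4, 2.0), np.ones(4)])
        d = sample_distance(_df(arr, ["a", "b", "c"]), metric="euclidean")
        assert d.loc["a", "b"] == pytest.approx(4.0)


class TestHierarchicalCluster:
    def test_unique_minimum_merges_first(self):
        d = pd.DataFrame([[0.0, 0.1, 0.9], [0.1, 0.0, 0.9], [0.9, 0.9, 0.0]],
                         index=list("ABC"), columns=list("ABC"))
        tree = hierarchical_cluster(d)
        assert tree.clades[0].members == frozenset({"A", "B"})

    def test_n_minus_one_internal_nodes(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(7, 7))
        d = np.abs(x - x.T)
        np.fill_diagonal(d, 0)
        labels = list("ABCDEFG")
        tree = hierarchical_cluster(pd.DataFrame(d, index=labels,
                                                 columns=labels))
        assert len(tree.clades) == 6

    def test_duplicate_sample_joins_twin_at_height_zero(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(25, 4))
        data = np.column_stack([data, data[:, 0]])  # e duplicates a
        d = sample_distance(_df(data, list("abcde")))
        tree = hierarchical_cluster(d)
        assert tree.clades[0].members == frozenset({"a", "e"})
        assert tree.clades[0].height == pytest.approx(0.0, abs=1e-12)

    def test_matches_scipy_average_linkage(self):
        from scipy.cluster import hierarchy
        from scipy.spatial.distance import squareform
        rng = np.random.default_rng(4)
        for _ in range(10):
            pts = rng.normal(size=(8, 3))
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            labels = [f"s{i}" for i in range(8)]
            tree = hierarchical_cluster(pd.DataFrame(d, index=labels,
                                                     columns=labels))
            Z = hierarchy.linkage(squareform(d), method="average")
            assert np.allclose(sorted(c.height for c in tree.clades),
                               sorted(Z[:, 2]))
            ref = {frozenset(labels[i] for i in leaves) for leaves in
                   _scipy_clades(Z, 8)}
            assert {c.members for c in tree.clades} == ref

    def test_rejects_asymmetric_matrix(self):
        d = pd.DataFrame([[0, 1, 2], [9, 0, 1], [2, 1, 0]],
                         index=list("abc"), columns=list("abc"))
        with pytest.raises(ValueError):
            hierarchical_cluster(d)


def _scipy_clades(Z, n):
    members = {i: [i] for i in range(n)}
    out = []
    for k, (a, b, _, _) in enumerate(Z):
        merged = members[int(a)] + members[int(b)]
        members[n + k] = merged
        out.append(merged)
    return out


class TestAuFit:
    def test_always_present_clade_has_full_support(self):
        au, degenerate = _fit_au(np.ones(10), np.linspace(0.5, 1.4, 10), 1000)
        assert au == 100.0 and not degenerate

    def test_never_observed_clade_flagged_degenerate(self):
        au, degenerate = _fit_au(np.zeros(10), np.linspace(0.5, 1.4, 10), 1000)
        assert au == 0.0 and degenerate

    @pytest.mark.parametrize("bp", [0.45, 0.50, 0.55])
    def test_flat_bp_profile_gives_au_near_bp(self, bp):
        # constant BP across scales degenerates the probit fit to AU ~ BP
        scales = np.round(np.arange(0.5, 1.41, 0.1), 1)
        au, _ = _fit_au(np.full(10, bp), scales, 1000)
        assert abs(au - 100 * bp) < 5.0


@pytest.fixture(scope="module")
def clustered_data():
    rng = np.random.default_rng(11)
    centers = {"a": 0.0, "b": 0.0, "c": 4.0, "d": 4.0, "e": 8.0}
    arr = np.column_stack([rng.normal(mu, 1.0, 300)
                           for mu in centers.values()])
    base = rng.normal(0, 2.0, 300)  # shared structure for correlation
    return pd.DataFrame(arr + base[:, None], columns=list(centers))


class TestAuBootstrap:
    def test_same_seed_reproduces_support_values(self, clustered_data):
        t1 = au_bootstrap(clustered_data, n_boot=100, seed=5)
        t2 = au_bootstrap(clustered_data, n_boot=100, seed=5)
        assert [(c.au, c.bp) for c in t1.clades] \
            == [(c.au, c.bp) for c in t2.clades]

    def test_support_in_range_and_root_certain(self, clustered_data):
        tree = au_bootstrap(clustered_data, n_boot=100, seed=5)
        for clade in tree.clades:
            assert 0.0 <= clade.au <= 100.0
            assert 0.0 <= clade.bp <= 100.0
        root = tree.find(set(clustered_data.columns))
        assert root.au == 100.0 and root.bp == 100.0

    def test_newick_round_trips_through_dendropy(self, clustered_data):
        import dendropy
        tree = au_bootstrap(clustered_data, n_boot=50, seed=5)
        parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        taxa = {leaf.taxon.label for leaf in parsed.leaf_node_iter()}
        assert taxa == set(clustered_data.columns)

    def test_requires_enough_samples_and_scales(self, clustered_data):
        with pytest.raises(ValueError):
            au_bootstrap(clustered_data.iloc[:, :2], n_boot=10, seed=0)
        with pytest.raises(ValueError):
            au_bootstrap(clustered_data, n_boot=10, scales=[1.0], seed=0)
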