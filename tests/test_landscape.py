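"""PCA, eps calibration, DBSCAN, census, populations and the dG landscape."""

import warnings

import numpy as np
import pytest

from conflock.errors import InsufficientDataError, ParameterError
from conflock.io import Ensemble
from conflock.landscape import (
    KB_KCAL,
    ClusterParams,
    ConformationalLandscape,
    NoElbowWarning,
    census,
    dbscan,
    fel,
    kdistance_eps,
    pca_project,
    population_table,
)


def brute_force_dbscan(X, eps, min_samples):
    """Independent density-reachability oracle: O(n^2), union-find on cores."""
    n = len(X)
    D = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
    neighbors = [np.flatnonzero(D[i] <= eps) for i in range(n)]
    core = np.array([len(nb) >= min_samples for nb in neighbors])
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        if not core[i]:
            continue
        for j in neighbors[i]:
            if core[j]:
                parent[find(i)] = find(j)
    labels = np.full(n, -1)
    roots = {}
    for i in range(n):
        if core[i]:
            r = find(i)
            labels[i] = roots.setdefault(r, len(roots))
    for i in range(n):
        if not core[i]:
            for j in neighbors[i]:
                if core[j]:
                    labels[i] = labels[j]
                    break
    return labels, core


def _partition_of_cores(labels, core):
    groups = {}
    for i in np.flatnonzero(core):
        groups.setdefault(labels[i], set()).add(int(i))
    return set(frozenset(g) for g in groups.values())


class TestPca:
    def test_rank_one_variation_dominates(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(-5, 5, size=(10, 3))
        direction = rng.normal(size=(10, 3))
        direction /= np.linalg.norm(direction)
        amp = rng.normal(size=50)
        coords = base[None] + amp[:, None, None] * direction[None]
        pc = pca_project(Ensemble(coords), np.arange(10), pre_aligned=True)
        assert pc.explained_variance[0] >= 0.99

    def test_isotropic_noise_has_no_dominant_pc(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(400, 10, 3))
        pc = pca_project(Ensemble(coords), np.arange(10), pre_aligned=True)
        assert pc.explained_variance[0] < 3.0 / (3 * 10 - 6)

    def test_duplicating_frames_leaves_eigenvectors_unchanged(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(30, 6, 3))
        pc1 = pca_project(Ensemble(coords), np.arange(6), pre_aligned=True)
        pc2 = pca_project(Ensemble(np.concatenate([coords, coords])), np.arange(6),
                          pre_aligned=True)
        assert np.allclose(np.abs(pc1.eigenvectors), np.abs(pc2.eigenvectors), atol=1e-8)

    def test_eigenvector_orthonormality_and_ordering(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(size=(40, 8, 3)) * np.linspace(1, 3, 8)[None, :, None]
        pc = pca_project(Ensemble(coords), np.arange(8), pre_aligned=True)
        G = pc.eigenvectors @ pc.eigenvectors.T
        assert np.allclose(G, np.eye(2), atol=1e-8)
        assert np.all(np.diff(pc.eigenvalues) <= 1e-9)

    def test_too_few_frames_raises(self):
        with pytest.raises(InsufficientDataError):
            pca_project(Ensemble(np.zeros((2, 4, 3))), np.arange(4))


class TestKdistanceEps:
    def test_separates_blob_scale_from_outlier_scale(self):
        rng = np.random.default_rng(4)
        blobs = np.concatenate([
            rng.normal(scale=0.3, size=(100, 2)),
            rng.normal(scale=0.3, size=(100, 2)) + [10, 0],
        ])
        outliers = rng.uniform(-30, 30, size=(22, 2))
        X = np.concatenate([blobs, outliers])
        eps = kdistance_eps(X, k=4)
        from scipy.spatial import cKDTree

        tree = cKDTree(X)
        d, _ = tree.query(outliers, k=5)
        outlier_kdist = d[:, 4]
        assert eps < np.percentile(outlier_kdist, 5)

    def test_uniform_grid_warns_and_returns_finite(self):
        g = np.linspace(0, 9, 10)
        X = np.array([[x, y] for x in g for y in g])
        with pytest.warns(NoElbowWarning):
            eps = kdistance_eps(X, k=4)
        assert np.isfinite(eps) and eps > 0

    def test_homogeneous_scaling(self):
        rng = np.random.default_rng(5)
        X = np.concatenate([rng.normal(scale=0.2, size=(80, 2)),
                            rng.uniform(-5, 5, size=(10, 2))])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert kdistance_eps(3.5 * X) == pytest.approx(3.5 * kdistance_eps(X), rel=1e-9)

    def test_too_few_points_raises(self):
        with pytest.raises(InsufficientDataError):
            kdistance_eps(np.zeros((4, 2)), k=4)


class TestDbscan:
    def test_two_blobs_with_distant_outliers(self):
        rng = np.random.default_rng(6)
        X = np.concatenate([
            rng.normal(scale=0.3, size=(50, 2)),
            rng.normal(scale=0.3, size=(50, 2)) + [10, 0],
            [[5.0, 5.0], [5.0, -5.0]],
        ])
        labels = dbscan(X, ClusterParams(eps=1.2, min_samples=4))
        oracle, core = brute_force_dbscan(X, 1.2, 4)
        assert census(labels).n_states == 2
        assert labels[100] == -1 and labels[101] == -1
        assert np.array_equal(labels == -1, oracle == -1)
        assert _partition_of_cores(labels, core) == _partition_of_cores(oracle, core)

    def test_identical_points_single_cluster(self):
        X = np.zeros((10, 2))
        labels = dbscan(X, ClusterParams(eps=0.5, min_samples=5))
        assert np.all(labels == 0)

    def test_min_samples_one_forbids_noise(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(-100, 100, size=(40, 2))
        labels = dbscan(X, ClusterParams(eps=1e-6, min_samples=1))
        assert np.all(labels >= 0)

    def test_order_invariance_of_noise_and_core_partition(self):
        rng = np.random.default_rng(8)
        X = np.concatenate([rng.normal(scale=0.5, size=(60, 2)),
                            rng.normal(scale=0.5, size=(60, 2)) + [6, 0],
                            rng.uniform(-20, 20, size=(15, 2))])
        p = ClusterParams(eps=1.0, min_samples=4)
        labels = dbscan(X, p)
        perm = rng.permutation(len(X))
        labels_p = dbscan(X[perm], p)
        back = np.empty_like(labels_p)
        back[perm] = labels_p
        _oracle, core = brute_force_dbscan(X, 1.0, 4)
        assert np.array_equal(labels == -1, back == -1)
        assert _partition_of_cores(labels, core) == _partition_of_cores(back, core)

    def test_agrees_with_sklearn_reference(self):
        """Cross-check against the library implementation the field uses."""
        from sklearn.cluster import DBSCAN as SkDBSCAN

        rng = np.random.default_rng(9)
        X = np.concatenate([rng.normal(scale=0.4, size=(70, 2)),
                            rng.normal(scale=0.4, size=(70, 2)) + [8, 3],
                            rng.uniform(-15, 15, size=(20, 2))])
        ours = dbscan(X, ClusterParams(eps=1.1, min_samples=4))
        ref = SkDBSCAN(eps=1.1, min_samples=4).fit_predict(X)
        core = np.zeros(len(X), bool)
        sk = SkDBSCAN(eps=1.1, min_samples=4).fit(X)
        core[sk.core_sample_indices_] = True
        assert np.array_equal(ours == -1, ref == -1)
        assert _partition_of_cores(ours, core) == _partition_of_cores(ref, core)


class TestCensusAndPopulations:
    def test_small_label_arithmetic(self):
        c = census(np.array([0, 0, 1, -1]))
        assert c.n_states == 2
        assert c.noise_fraction == 0.25
        assert c.largest_state_fraction == 0.5

    def test_all_noise(self):
        c = census(np.array([-1, -1, -1]))
        assert c.n_states == 0 and c.noise_fraction == 1.0
        assert c.largest_state_fraction == 0.0

    def test_populations_sum_with_noise_to_one(self):
        rng = np.random.default_rng(10)
        labels = rng.choice([-1, 0, 1, 2, 5], size=500)
        c = census(labels)
        assert c.populations.sum() + c.noise_fraction == pytest.approx(1.0, abs=1e-9)

    def test_population_table_two_states(self):
        c = census(np.array([0] * 60 + [1] * 40))
        table = dict(population_table(c))
        assert table["S1"] == pytest.approx(0.6)
        assert table["S2"] == pytest.approx(0.4)
        assert table["Other"] == 0.0

    def test_population_table_ten_equal_states(self):
        c = census(np.repeat(np.arange(10), 10))
        table = dict(population_table(c))
        for i in range(1, 7):
            assert table[f"S{i}"] == pytest.approx(0.1)
        assert table["Other"] == pytest.approx(0.4)

    def test_long_tail_other_exceeds_minor_states(self):
        rng = np.random.default_rng(11)
        sizes = (400 / np.arange(1, 31) ** 1.5).astype(int) + 1
        labels = np.concatenate([np.full(s, i) for i, s in enumerate(sizes)])
        table = dict(population_table(census(labels)))
        for name in ("S4", "S5", "S6"):
            assert table["Other"] > table[name]


class TestFreeEnergyLandscape:
    def test_single_occupied_bin(self):
        X = np.zeros((50, 2))
        L = fel(X, n_bins=5)
        assert np.count_nonzero(L.delta_g == 0.0) == 1
        assert np.all(L.delta_g[L.probability == 0] == L.cap)

    def test_two_to_one_occupancy_free_energy_gap(self):
        X = np.array([[0.25, 0.5]] * 40 + [[0.75, 0.5]] * 20, dtype=float)
        L = fel(X, temperature=310.0, n_bins=2)
        occupied = np.sort(L.delta_g[L.probability > 0])
        assert occupied[0] == 0.0
        assert occupied[1] == pytest.approx(KB_KCAL * 310.0 * np.log(2.0), abs=1e-4)
        assert occupied[1] == pytest.approx(0.427, abs=5e-3)

    def test_uniform_occupancy_is_flat(self):
        pts = np.array([[i + 0.5, j + 0.5] for i in range(3) for j in range(3)], float)
        L = fel(np.repeat(pts, 4, axis=0), n_bins=3)
        assert np.allclose(L.delta_g, 0.0, atol=1e-12)

    def test_probability_normalised(self):
        rng = np.random.default_rng(13)
        L = fel(rng.normal(size=(200, 2)), n_bins=10)
        assert L.probability.sum() == pytest.approx(1.0)

    def test_bad_bins_raise(self):
        with pytest.raises(ParameterError):
            fel(np.zeros((5, 2)), n_bins=1)


class TestModelResults:
    def _fit(self, seed=0):
        from conflock.io import concatenate
        from conflock.selection import select
        from conflock.synthetic import SyntheticSpec, simulate

        spec = SyntheticSpec(n_basins=2, n_frames=250, n_replicates=2, seed=seed)
        top, ens, truth = simulate(spec)
        model = ConformationalLandscape(concatenate(ens), select(top, "calpha"))
        return model.fit(), truth

    def test_summary_reports_census(self):
        fit, _truth = self._fit()
        text = fit.summary()
        assert "stable states" in text and "noise" in text
        assert str(fit.n_states) in text

    def test_fit_deterministic(self):
        a, _ = self._fit(seed=3)
        b, _ = self._fit(seed=3)
        assert a.to_dict() == b.to_dict()

    def test_fixed_eps_respected(self):
        from conflock.io import concatenate
        from conflock.selection import select
        from conflock.synthetic import SyntheticSpec, simulate

        spec = SyntheticSpec(n_basins=2, n_frames=200, n_replicates=1, seed=5)
        top, ens, _ = simulate(spec)
        fit = ConformationalLandscape(concatenate(ens), select(top, "calpha")).fit(eps=1.2)
        assert fit.params.eps == 1.2 and not fit.eps_calibrated

    def test_plots_written(self, tmp_path):
        fit, _ = self._fit(seed=7)
        fit.plot_landscape(tmp_path / "fel.png")
        fit.plot_states(tmp_path / "states.png")
        assert (tmp_path / "fel.png").stat().st_size > 0
        assert (tmp_path / "states.png").stat().st_size > 0
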