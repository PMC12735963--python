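"""Superposition and stability metrics against closed forms and naive oracles."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from conflock.errors import DegeneracyError, InsufficientDataError
from conflock.geometry import (
    kabsch_superpose,
    radius_of_gyration,
    rmsd,
    rmsd_series,
    rmsf_profile,
)
from conflock.io import Ensemble
from conflock.synthetic import SyntheticSpec, make_basins

from conftest import make_ca_topology


def _brute_force_min_rmsd(P, Q, n_grid=12):
    """Exhaustive Euler-angle grid + local refinement, translations removed."""
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)

    def cost(angles):
        R = Rotation.from_euler("zyx", angles).as_matrix()
        return np.sqrt(np.mean(np.sum((Pc @ R.T - Qc) ** 2, axis=1)))

    best = np.inf
    grid = np.linspace(0, 2 * np.pi, n_grid, endpoint=False)
    for a in grid:
        for b in grid:
            for c in grid:
                res = minimize(cost, x0=[a, b, c], method="Nelder-Mead",
                               options={"xatol": 1e-10, "fatol": 1e-12})
                best = min(best, res.fun)
    return best


class TestKabsch:
    def test_identity_on_self(self):
        P = np.random.default_rng(0).normal(size=(6, 3))
        R, t, aligned = kabsch_superpose(P, P)
        assert np.allclose(R, np.eye(3), atol=1e-10)
        assert np.allclose(t, 0, atol=1e-10)
        assert rmsd(aligned, P) < 1e-12

    def test_recovers_rigid_transform(self):
        rng = np.random.default_rng(1)
        P = rng.normal(size=(10, 3))
        Rtrue = Rotation.random(random_state=2).as_matrix()
        Q = P @ Rtrue.T + np.array([3.0, -2.0, 7.0])
        _R, _t, aligned = kabsch_superpose(P, Q)
        assert rmsd(aligned, Q) <= 1e-9

    def test_proper_rotation_even_for_near_planar_sets(self):
        rng = np.random.default_rng(3)
        P = rng.normal(size=(8, 3)) * np.array([1.0, 1.0, 1e-4])
        Q = rng.normal(size=(8, 3))
        R, _t, _a = kabsch_superpose(P, Q)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-8)

    def test_matches_brute_force_rotation_search(self):
        P = np.array([[0.0, 0.0, 0.0], [1.7, 0.2, -0.4],
                      [0.3, 2.1, 0.8], [-1.2, 0.5, 1.9]])
        Q = np.array([[0.1, -0.3, 0.2], [1.9, 0.1, 0.3],
                      [0.6, 1.8, -0.7], [-1.5, 0.9, 1.2]])
        _R, _t, aligned = kabsch_superpose(P, Q)
        ours = rmsd(aligned, Q)
        oracle = _brute_force_min_rmsd(P, Q)
        assert ours == pytest.approx(oracle, abs=1e-6)
        assert ours <= oracle + 1e-9  # least squares optimum

    def test_collinear_mask_raises(self):
        P = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(DegeneracyError):
            kabsch_superpose(P, P + 1.0)


class TestRmsdSeries:
    def test_static_ensemble_is_zero(self):
        coords = np.tile(np.random.default_rng(0).normal(size=(5, 3)), (4, 1, 1))
        series = rmsd_series(Ensemble(coords), np.arange(5))
        assert np.allclose(series.values, 0, atol=1e-12)

    def test_rigid_motion_removed_by_fitting(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(6, 3))
        frames = []
        for _ in range(5):
            R = Rotation.random(random_state=rng.integers(1 << 31)).as_matrix()
            frames.append(base @ R.T + rng.normal(size=3) * 10)
        series = rmsd_series(Ensemble(np.asarray(frames)), np.arange(6))
        assert np.max(series.values) <= 1e-9

    def test_two_basin_series_is_bimodal_at_known_levels(self):
        spec = SyntheticSpec(n_basins=2, intra_basin_sigma=0.0, basin_separation=6.0,
                             n_frames=120, n_replicates=1, seed=5)
        basins = make_basins(spec)
        from conflock.synthetic import simulate
        _top, ens, truth = simulate(spec)
        series = rmsd_series(ens[0], np.arange(spec.n_residues))
        labels = truth.frame_labels[: ens[0].n_frames]
        start = labels[0]
        # frames in the starting basin sit at 0; frames in the other basin at
        # the inter-basin RMSD (after optimal fitting)
        _R, _t, aligned = kabsch_superpose(basins[1 - start], basins[start])
        inter = rmsd(aligned, basins[start])
        assert np.allclose(series.values[labels == start], 0, atol=1e-9)
        other = series.values[(labels >= 0) & (labels != start)]
        assert other.size > 0
        assert np.allclose(other, inter, atol=1e-9)


class TestRadiusOfGyration:
    def test_single_atom_zero(self):
        ens = Ensemble(np.ones((3, 1, 3)))
        assert np.allclose(radius_of_gyration(ens, [0]).values, 0)

    def test_two_equal_masses_half_distance(self):
        d = 4.2
        coords = np.array([[[0.0, 0, 0], [d, 0, 0]]])
        assert radius_of_gyration(Ensemble(coords), [0, 1]).values[0] == pytest.approx(d / 2)

    def test_unit_cube_corners(self):
        corners = np.array([[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)], float)
        val = radius_of_gyration(Ensemble(corners[None]), np.arange(8)).values[0]
        assert val == pytest.approx(np.sqrt(3) / 2, abs=1e-12)

    def test_rigid_invariance_and_scaling(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(1, 9, 3))
        ens = Ensemble(base)
        rg0 = radius_of_gyration(ens, np.arange(9)).values[0]
        R = Rotation.random(random_state=0).as_matrix()
        moved = Ensemble(base @ R.T + 13.0)
        assert radius_of_gyration(moved, np.arange(9)).values[0] == pytest.approx(rg0)
        assert radius_of_gyration(Ensemble(3 * base), np.arange(9)).values[0] == pytest.approx(3 * rg0)

    def test_mass_weighting_changes_result(self):
        top = make_ca_topology(2)
        top.masses[:] = [1.0, 3.0]
        coords = np.array([[[0.0, 0, 0], [4.0, 0, 0]]])
        ens = Ensemble(coords)
        unweighted = radius_of_gyration(ens, [0, 1], top, mass_weighted=False).values[0]
        weighted = radius_of_gyration(ens, [0, 1], top, mass_weighted=True).values[0]
        # com at 3.0; rg = sqrt((1*9 + 3*1)/4) = sqrt(3)
        assert unweighted == pytest.approx(2.0)
        assert weighted == pytest.approx(np.sqrt(3.0))


class TestRmsf:
    def test_static_ensemble_zero(self):
        coords = np.tile(np.random.default_rng(0).normal(size=(6, 3)), (5, 1, 1))
        prof = rmsf_profile(Ensemble(coords), np.arange(6))
        assert np.allclose(prof.values, 0, atol=1e-9)

    def test_isotropic_gaussian_matches_chi_mean_square(self):
        rng = np.random.default_rng(4)
        sigma = 0.5
        base = make_ca_topology(30)
        chain = rng.uniform(-20, 20, size=(30, 3))
        coords = chain[None] + rng.normal(scale=sigma, size=(800, 30, 3))
        prof = rmsf_profile(Ensemble(coords), np.arange(30))
        assert prof.values.mean() == pytest.approx(sigma * np.sqrt(3), rel=0.05)

    def test_planted_mobile_loop_has_top_rmsf(self):
        from conflock.synthetic import SyntheticSpec, simulate

        spec = SyntheticSpec(n_basins=1, n_frames=400, n_replicates=1, seed=6,
                             flexible_residues=tuple(range(20, 26)),
                             flexible_extra_sigma=1.5)
        top, ens, _truth = simulate(spec)
        prof = rmsf_profile(ens[0], np.arange(spec.n_residues), top, grouping="by_residue")
        top6 = np.argsort(prof.values)[-6:]
        assert set(np.asarray(prof.labels)[top6]) == set(range(20, 26))

    def test_frame_permutation_invariance(self):
        rng = np.random.default_rng(7)
        base = rng.uniform(-10, 10, size=(8, 3))
        coords = base[None] + 0.3 * rng.normal(size=(40, 8, 3))
        a = rmsf_profile(Ensemble(coords), np.arange(8)).values
        b = rmsf_profile(Ensemble(coords[rng.permutation(40)]), np.arange(8)).values
        assert np.allclose(a, b, atol=1e-9)

    def test_single_frame_raises(self):
        with pytest.raises(InsufficientDataError):
            rmsf_profile(Ensemble(np.zeros((1, 4, 3))), np.arange(4))


class TestNaiveOracles:
    """Direct-summation re-implementations on tiny inputs, 1e-6 A agreement."""

    def test_rg_oracle(self):
        rng = np.random.default_rng(8)
        coords = rng.normal(size=(10, 10, 3))
        vals = radius_of_gyration(Ensemble(coords), np.arange(10)).values
        for f in range(10):
            com = coords[f].mean(axis=0)
            acc = sum(np.dot(coords[f, i] - com, coords[f, i] - com) for i in range(10))
            assert vals[f] == pytest.approx(np.sqrt(acc / 10), abs=1e-6)

    def test_rmsd_oracle(self):
        rng = np.random.default_rng(9)
        coords = rng.normal(size=(10, 8, 3))
        series = rmsd_series(Ensemble(coords), np.arange(8))
        for f in range(10):
            _R, _t, aligned = kabsch_superpose(coords[f], coords[0], np.arange(8))
            acc = sum(np.dot(aligned[i] - coords[0, i], aligned[i] - coords[0, i]) for i in range(8))
            assert series.values[f] == pytest.approx(np.sqrt(acc / 8), abs=1e-6)

    def test_rmsf_oracle(self):
        from conflock.geometry import iterative_mean_align

        rng = np.random.default_rng(10)
        coords = rng.normal(size=(10, 6, 3)) * 0.3 + rng.normal(size=(1, 6, 3)) * 5
        ens = Ensemble(coords)
        prof = rmsf_profile(ens, np.arange(6)).values
        aligned = iterative_mean_align(ens, np.arange(6))
        mean = aligned.mean(axis=0)
        for i in range(6):
            acc = sum(np.dot(aligned[f, i] - mean[i], aligned[f, i] - mean[i]) for f in range(10))
            assert prof[i] == pytest.approx(np.sqrt(acc / 10), abs=1e-6)
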