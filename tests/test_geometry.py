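import numpy as np
import pytest
from scipy.optimize import minimize as scipy_minimize
from scipy.spatial.transform import Rotation

from flexbind import geometry
from flexbind.geometry import (AnchorPair, contact_fraction, find_disulfide_modules,
                               fit_quadratic_curve, gyration_descriptors,
                               interdomain_angle, max_curvature, mode_overlap,
                               pair_distribution, pca, project, rmsd_series,
                               superpose, angle_series, apply_transform)
from flexbind.structure import Atom, Structure, Trajectory
from flexbind.synth import (HingeTrajectorySpec, ModuleChainSpec, ToyComplexSpec,
                            make_hinge_trajectory, make_module_chain,
                            make_toy_complex)


def _atoms_from_coords(coords, name="CA", resname="GLY", chain="A", mass=12.0):
    return Structure([Atom(name=name, element="C", resname=resname, resid=i + 1,
                           chain=chain, xyz=np.array(c, dtype=float), mass=mass)
                      for i, c in enumerate(coords)])


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

class TestSuperpose:
    def test_identical_sets(self, rng):
        pts = rng.normal(0, 5, (8, 3))
        rot, trans, rmsd = superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(rot, np.eye(3), atol=1e-10)

    def test_recovers_known_transform(self, rng):
        pts = rng.normal(0, 5, (10, 3))
        r_true = Rotation.from_euler("zyx", [30, -40, 75], degrees=True).as_matrix()
        t_true = np.array([1.0, -2.0, 3.0])
        moved = pts @ r_true.T + t_true
        rot, trans, rmsd = superpose(moved, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(rot @ r_true, np.eye(3), atol=1e-9)

    def test_matches_rotation_space_minimization(self, rng):
        """Independent oracle: minimize RMSD over Euler angles directly."""
        a = rng.normal(0, 3, (5, 3))
        b = rng.normal(0, 3, (5, 3))
        _, _, rmsd_kabsch = superpose(a, b)

        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)

        def f(euler):
            r = Rotation.from_euler("zyx", euler).as_matrix()
            return np.sqrt(((ac @ r.T - bc) ** 2).sum(axis=1).mean())

        best = np.inf
        for seed_angles in ([0, 0, 0], [1, 1, 1], [2, -1, 0.5], [-2, 2, -2],
                            [3, 0, 1.5], [0.5, -2.5, 2.5]):
            res = scipy_minimize(f, seed_angles, method="Nelder-Mead",
                                 options={"xatol": 1e-10, "fatol": 1e-12,
                                          "maxiter": 5000})
            best = min(best, res.fun)
        assert rmsd_kabsch == pytest.approx(best, abs=1e-3)

    def test_proper_rotation_enforced(self, rng):
        a = rng.normal(0, 2, (6, 3))
        b = a.copy()
        b[:, 0] *= -1  # mirrored target
        rot, _, _ = superpose(a, b)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_points(self):
        line = np.stack([np.arange(4.0), np.zeros(4), np.zeros(4)], axis=1)
        with pytest.raises(ValueError, match="collinear"):
            superpose(line, line + 1.0)

    def test_fitted_rmsd_never_exceeds_unfitted(self, rng):
        for _ in range(5):
            a = rng.normal(0, 4, (7, 3))
            b = rng.normal(0, 4, (7, 3))
            _, _, fitted = superpose(a, b)
            unfitted = np.sqrt(((a - b) ** 2).sum(axis=1).mean())
            assert fitted <= unfitted + 1e-12


class TestRmsdSeries:
    def test_copies_of_reference_are_zero(self, rng):
        ref = rng.normal(0, 5, (10, 3))
        traj = Trajectory([ref.copy() for _ in range(4)])
        out = rmsd_series(traj, ref, range(10), range(10))
        assert np.allclose(out, 0.0, atol=1e-10)

    def test_rigid_translation_removed(self, rng):
        ref = rng.normal(0, 5, (10, 3))
        traj = Trajectory([ref + [i, -i, 2 * i] for i in range(4)])
        out = rmsd_series(traj, ref, range(10), range(10))
        assert np.allclose(out, 0.0, atol=1e-9)

    def test_hinge_fixture_matches_per_frame_oracle(self, toy):
        traj, _ = make_hinge_trajectory(
            toy, HingeTrajectorySpec(mean_angle=115.0, sd=8.0, n_frames=6, seed=4))
        # fit on domain 1 C-alphas, measure on domain 2 C-alphas
        fit_idx = [i for i, a in enumerate(toy.structure.atoms)
                   if a.chain == "A" and a.resid <= 9 and a.name == "CA"]
        meas_idx = [i for i, a in enumerate(toy.structure.atoms)
                    if a.chain == "A" and a.resid >= toy.domain2_first_resid
                    and a.name == "CA"]
        ref = toy.structure.coords
        out = rmsd_series(traj, ref, fit_idx, meas_idx)
        for f, frame in enumerate(traj.frames):
            rot, trans, _ = superpose(frame[fit_idx], ref[fit_idx])
            fitted = apply_transform(frame[meas_idx], rot, trans)
            direct = np.sqrt(((fitted - ref[meas_idx]) ** 2).sum(axis=1).mean())
            assert out[f] == pytest.approx(direct, abs=1e-12)

    def test_empty_selection_errors(self, rng):
        traj = Trajectory([rng.normal(0, 1, (5, 3))])
        with pytest.raises(ValueError):
            rmsd_series(traj, traj.frames[0], [], range(5))


# ---------------------------------------------------------------------------
# Interdomain angle
# ---------------------------------------------------------------------------

def _four_point_structure(v1, v2, offset=(0, 0, 0)):
    offset = np.asarray(offset, dtype=float)
    coords = [offset, offset + v1, offset + [10, 10, 10], offset + [10, 10, 10] + v2]
    atoms = []
    for i, c in enumerate(coords):
        atoms.append(Atom(name="CA", element="C", resname="GLY", resid=i + 1,
                          chain="A", xyz=np.array(c, dtype=float), mass=12.0))
    return Structure(atoms)


ANCHORS4 = AnchorPair(v1=(("A", 1, "CA"), ("A", 2, "CA")),
                      v2=(("A", 3, "CA"), ("A", 4, "CA")))


class TestInterdomainAngle:
    def test_parallel_is_zero(self):
        st = _four_point_structure(np.array([1, 2, 3.0]), np.array([2, 4, 6.0]))
        assert interdomain_angle(st, ANCHORS4) == pytest.approx(0.0, abs=1e-9)

    def test_antiparallel_is_180(self):
        st = _four_point_structure(np.array([1, 2, 3.0]), np.array([-1, -2, -3.0]))
        assert interdomain_angle(st, ANCHORS4) == pytest.approx(180.0, abs=1e-9)

    def test_hinge_fixture_at_120(self, toy):
        traj, _ = make_hinge_trajectory(
            toy, HingeTrajectorySpec(mean_angle=120.0, sd=0.0, n_frames=1,
                                     thermal_noise_rms=0.0))
        st = toy.structure.copy()
        st.coords = traj.frames[0]
        assert interdomain_angle(st, toy.anchors) == pytest.approx(120.0, abs=1e-6)

    def test_invariant_under_rigid_motion(self, toy, rng):
        base = interdomain_angle(toy.structure, toy.anchors)
        rot = Rotation.from_euler("xyz", rng.normal(0, 2, 3)).as_matrix()
        st = toy.structure.copy()
        st.coords = toy.structure.coords @ rot.T + [5.0, -3.0, 12.0]
        assert interdomain_angle(st, toy.anchors) == pytest.approx(base, abs=1e-9)

    def test_zero_length_vector_errors(self):
        st = _four_point_structure(np.array([0.0, 0, 0]), np.array([1.0, 0, 0]))
        with pytest.raises(ValueError, match="zero-length"):
            interdomain_angle(st, ANCHORS4)

    def test_missing_anchor_errors(self, toy):
        bad = AnchorPair(v1=(("A", 999, "CA"), ("A", 2, "CA")),
                         v2=(("A", 12, "CA"), ("A", 20, "CA")))
        with pytest.raises(ValueError, match="not found"):
            interdomain_angle(toy.structure, bad)


class TestAngleSeries:
    def test_constant_conformation_single_bin(self, toy):
        traj, _ = make_hinge_trajectory(
            toy, HingeTrajectorySpec(mean_angle=110.0, sd=0.0, n_frames=20))
        angles, hist = angle_series(traj, toy.structure, toy.anchors)
        assert np.allclose(angles, 110.0, atol=1e-6)
        assert (hist.weights > 0).sum() == 1

    def test_histogram_total_equals_frame_count(self, toy):
        traj, _ = make_hinge_trajectory(
            toy, HingeTrajectorySpec(mean_angle=110.0, sd=6.0, n_frames=37, seed=5))
        _, hist = angle_series(traj, toy.structure, toy.anchors)
        assert hist.weights.sum() == 37

    def test_gaussian_mean_recovery(self, toy):
        traj, targets = make_hinge_trajectory(
            toy, HingeTrajectorySpec(mean_angle=110.0, sd=5.0, n_frames=2000,
                                     seed=42))
        angles, _ = angle_series(traj, toy.structure, toy.anchors)
        assert abs(angles.mean() - 110.0) < 0.3
        assert np.allclose(angles, targets, atol=1e-6)


# ---------------------------------------------------------------------------
# Disulfide modules, curvature
# ---------------------------------------------------------------------------

class TestDisulfideModules:
    def test_engineered_bridges_found(self, toy):
        mods = find_disulfide_modules(toy.structure, (1, 9))
        assert [m.cys_pair for m in mods] == [(3, 4), (6, 7)]
        assert [m.member_resids for m in mods] == [(3, 4), (6, 7)]

    def test_three_bridges_constructed_spans(self):
        spec = ToyComplexSpec(
            domain1_sequence=("GLY", "CYS", "CYS", "ALA", "CYS", "CYS",
                              "ALA", "CYS", "CYS", "ALA"),
            disulfide_pairs=((2, 3), (5, 6), (8, 9)))
        toy3 = make_toy_complex(spec)
        mods = find_disulfide_modules(toy3.structure, (1, 10))
        assert [m.cys_pair for m in mods] == [(2, 3), (5, 6), (8, 9)]

    def test_no_cysteines_empty(self, toy):
        assert find_disulfide_modules(toy.structure, (12, 20)) == []

    def test_com_is_mass_weighted(self, toy):
        mods = find_disulfide_modules(toy.structure, (1, 9))
        m = mods[0]
        member = [i for i, a in enumerate(toy.structure.atoms)
                  if a.chain == "A" and m.member_resids[0] <= a.resid <= m.member_resids[1]]
        w = toy.structure.masses[member]
        expect = (w[:, None] * toy.structure.coords[member]).sum(0) / w.sum()
        assert np.allclose(m.com, expect, atol=1e-12)


class TestQuadraticCurve:
    def test_collinear_gives_zero_a(self):
        pts = np.stack([np.arange(7.0) * 2, np.zeros(7), np.zeros(7)], axis=1)
        fit = fit_quadratic_curve(pts)
        assert fit.a == pytest.approx(0.0, abs=1e-12)
        assert max_curvature(fit) == 0.0

    def test_constructed_parabola_recovered(self):
        u = np.linspace(-10, 10, 7)
        pts = np.stack([u, 0.125 * u ** 2, np.zeros(7)], axis=1)
        fit = fit_quadratic_curve(pts)
        assert abs(fit.a) == pytest.approx(0.125, abs=1e-9)
        assert fit.residual == pytest.approx(0.0, abs=1e-9)

    def test_vertex_inside_range_gives_2a(self):
        u = np.linspace(-10, 10, 7)
        pts = np.stack([u, 0.125 * u ** 2, np.zeros(7)], axis=1)
        assert max_curvature(fit_quadratic_curve(pts)) == pytest.approx(0.25, abs=1e-9)

    def test_max_curvature_matches_dense_grid_scan(self):
        # one-sided data: check the range-restricted maximum against a
        # dense evaluation of kappa(u) on the fitted coefficients
        u = np.linspace(5, 15, 7)
        pts = np.stack([u, 0.125 * u ** 2, np.zeros(7)], axis=1)
        fit = fit_quadratic_curve(pts)
        a, b = fit.a, fit.b
        grid = np.linspace(fit.u_range[0], fit.u_range[1], 200001)
        expect = (np.abs(2 * a) / (1 + (2 * a * grid + b) ** 2) ** 1.5).max()
        assert max_curvature(fit) == pytest.approx(expect, rel=1e-6)

    def test_coincident_points_error(self):
        with pytest.raises(ValueError, match="coincident"):
            fit_quadratic_curve(np.zeros((5, 3)))

    def test_rigid_motion_invariance_and_scaling(self, rng):
        pts = make_module_chain(ModuleChainSpec(target_curvature=0.2, seed=8))
        k0 = max_curvature(fit_quadratic_curve(pts))
        rot = Rotation.from_euler("xyz", rng.normal(0, 2, 3)).as_matrix()
        k_rot = max_curvature(fit_quadratic_curve(pts @ rot.T + [3, 4, 5]))
        assert k_rot == pytest.approx(k0, rel=1e-9)
        k_scaled = max_curvature(fit_quadratic_curve(pts * 2.0))
        assert k_scaled == pytest.approx(k0 / 2.0, rel=1e-9)

    def test_arc_curvature_recovery(self):
        pts = make_module_chain(ModuleChainSpec(target_curvature=0.25, seed=1))
        k = max_curvature(fit_quadratic_curve(pts))
        assert abs(k - 0.25) / 0.25 < 0.02


# ---------------------------------------------------------------------------
# Gyration, P(r)
# ---------------------------------------------------------------------------

class TestGyration:
    def test_single_atom(self):
        d = gyration_descriptors(np.array([[1.0, 2.0, 3.0]]), np.array([12.0]))
        assert np.allclose(d.gyration_eigenvalues, 0.0)
        assert d.rg == 0.0
        assert d.dmax == 0.0

    def test_two_unit_masses_closed_form(self):
        coords = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        d = gyration_descriptors(coords, np.array([1.0, 1.0]))
        assert np.allclose(d.gyration_eigenvalues, [25.0, 0.0, 0.0], atol=1e-12)
        assert d.rg == pytest.approx(5.0)
        assert d.dmax == pytest.approx(10.0)

    def test_matches_covariance_oracle(self, toy):
        coords = toy.structure.coords
        masses = toy.structure.masses
        d = gyration_descriptors(coords, masses)
        w = masses / masses.sum()
        center = (w[:, None] * coords).sum(0)
        tensor = np.zeros((3, 3))
        for wi, ci in zip(w, coords):
            dd = ci - center
            tensor += wi * np.outer(dd, dd)
        evs = np.sort(np.linalg.eigvalsh(tensor))[::-1]
        assert np.allclose(d.gyration_eigenvalues, evs, atol=1e-10)

    def test_rg_squared_equals_eigenvalue_sum(self, toy, rng):
        for _ in range(3):
            n = rng.integers(2, 30)
            coords = rng.normal(0, 8, (int(n), 3))
            masses = rng.uniform(1, 20, int(n))
            d = gyration_descriptors(coords, masses)
            assert d.rg ** 2 == pytest.approx(d.gyration_eigenvalues.sum(), rel=1e-10)


class TestPairDistribution:
    def test_two_atoms_single_bin(self):
        h = pair_distribution(np.array([[0.0, 0, 0], [5.0, 0, 0]]), bin_width=1.0)
        assert h.weights.sum() == 1
        centers = h.bin_centers
        assert h.weights[np.argmax(h.weights)] == 1
        assert 5.0 - 1.0 <= centers[np.argmax(h.weights)] <= 5.0 + 1.0

    def test_raw_total_n_pairs(self, rng):
        coords = rng.normal(0, 10, (17, 3))
        h = pair_distribution(coords, bin_width=0.5)
        assert h.weights.sum() == pytest.approx(17 * 16 / 2)

    def test_equilateral_triangle(self):
        s = 4.2   # mid-bin side length avoids edge-of-bin float ambiguity
        coords = np.array([[0, 0, 0], [s, 0, 0], [s / 2, s * np.sqrt(3) / 2, 0]])
        h = pair_distribution(coords, bin_width=1.0)
        assert h.weights[int(s)] == pytest.approx(3.0)
        assert h.weights.sum() == pytest.approx(3.0)

    def test_multi_frame_average(self, rng):
        f1 = rng.normal(0, 5, (6, 3))
        f2 = rng.normal(0, 5, (6, 3))
        h12 = pair_distribution([f1, f2], bin_width=1.0)
        assert h12.weights.sum() == pytest.approx(15.0)

    def test_normalized_unit_area(self, rng):
        h = pair_distribution(rng.normal(0, 5, (10, 3)), bin_width=0.7,
                              normalize=True)
        assert (h.weights * 0.7).sum() == pytest.approx(1.0)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            pair_distribution(np.zeros((2, 3)), bin_width=0.0)
        with pytest.raises(ValueError):
            pair_distribution(np.zeros((1, 3)))

    def test_support_covers_dmax(self, toy):
        coords = toy.structure.coords
        h = pair_distribution(coords, bin_width=1.0)
        from scipy.spatial.distance import pdist
        assert h.bin_edges[-1] >= pdist(coords).max()


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

class TestPCA:
    def _single_axis_trajectory(self, n_frames=50):
        rng = np.random.default_rng(7)
        base = rng.normal(0, 3, (4, 3))
        frames = []
        for t in range(n_frames):
            f = base.copy()
            f[0, 0] += np.sin(0.3 * t) * 2.0
            frames.append(f)
        return Trajectory(frames)

    def test_single_axis_mode(self):
        traj = self._single_axis_trajectory()
        res = pca(traj, range(4), n_modes=3)
        mode = res.modes[0].reshape(4, 3)
        # superposition removes the rigid-body part of the single-atom motion,
        # so the first mode is dominated (not exhausted) by atom 0 along x
        assert abs(mode[0, 0]) > 0.8
        assert abs(mode[0, 0]) == pytest.approx(np.abs(mode).max())
        assert res.variances[0] > 10 * res.variances[1]

    def test_self_overlap_identity(self):
        traj = self._single_axis_trajectory()
        res = pca(traj, range(4), n_modes=3)
        ov = mode_overlap(res.modes, res.modes, 3)
        assert np.allclose(ov, np.eye(3), atol=1e-10)

    def test_modes_orthonormal_variances_sorted(self, toy):
        traj, _ = make_hinge_trajectory(
            toy, HingeTrajectorySpec(mean_angle=110, sd=6, n_frames=30, seed=2,
                                     thermal_noise_rms=0.05))
        sel = [i for i, a in enumerate(toy.structure.atoms) if a.name == "CA"]
        res = pca(traj, sel, n_modes=10)
        assert np.allclose(res.modes @ res.modes.T, np.eye(10), atol=1e-10)
        assert np.all(np.diff(res.variances) <= 1e-12)

    def test_total_variance_equals_trace(self):
        traj = self._single_axis_trajectory()
        res = pca(traj, range(4), n_modes=12)
        # full mode set: sum of variances = total fitted coordinate variance
        proj_var = res.projections.var(axis=0, ddof=1)
        assert np.allclose(proj_var, res.variances, atol=1e-10)

    def test_two_mode_variance_ratio(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 5, (6, 3))
        # displacement patterns orthogonal to the rigid-body modes of the base
        # geometry, so the superposition step leaves them intact
        rigid = []
        for k in range(3):
            t = np.zeros((6, 3))
            t[:, k] = 1.0
            rigid.append(t.reshape(-1))
        centered = base - base.mean(axis=0)
        for k in range(3):
            e = np.zeros(3)
            e[k] = 1.0
            rigid.append(np.cross(centered, e).reshape(-1))
        q, _ = np.linalg.qr(np.stack(rigid, axis=1))

        def orthogonalize(p):
            v = p.reshape(-1)
            v = v - q @ (q.T @ v)
            return (v / np.linalg.norm(v)).reshape(6, 3)

        p1 = np.zeros((6, 3))
        p1[1, 1] = 1.0
        p2 = np.zeros((6, 3))
        p2[3, 2] = 1.0
        p1 = orthogonalize(p1)
        p2 = orthogonalize(p2 - (p2.reshape(-1) @ p1.reshape(-1)) * p1)
        frames = [base + rng.normal(0, 2) * p1 + rng.normal(0, 1) * p2
                  for _ in range(500)]
        res = pca(Trajectory(frames), range(6), n_modes=2)
        ratio = res.variances[0] / res.variances[1]
        assert abs(ratio - 4.0) / 4.0 < 0.10

    def test_too_many_modes_errors(self):
        traj = self._single_axis_trajectory(n_frames=5)
        with pytest.raises(ValueError):
            pca(traj, range(4), n_modes=11)

    def test_projection_shape(self):
        traj = self._single_axis_trajectory()
        res = pca(traj, range(4), n_modes=3)
        pr = project(traj, range(4), res, 2)
        assert pr.shape == (len(traj), 2)


# ---------------------------------------------------------------------------
# Contact fraction
# ---------------------------------------------------------------------------

class TestContactFraction:
    def _traj_with_distances(self, dists):
        frames = []
        for d in dists:
            frames.append(np.array([[0.0, 0, 0], [d, 0, 0]]))
        return Trajectory(frames)

    def test_always_inside(self):
        traj = self._traj_with_distances([3.0] * 5)
        assert contact_fraction(traj, 0, 1, 4.0) == 1.0

    def test_always_outside(self):
        traj = self._traj_with_distances([5.0] * 5)
        assert contact_fraction(traj, 0, 1, 4.0) == 0.0

    def test_nine_of_ten(self):
        traj = self._traj_with_distances([3.0] * 9 + [5.0])
        assert contact_fraction(traj, 0, 1, 4.0) == pytest.approx(0.9)
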