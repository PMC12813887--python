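"""Superposition, RMSD/RMSF/Rgyr metrics, and the apo/holo contrast arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from cardyn.errors import NumericalError, SelectionError
from cardyn.geometry import (DecompositionResult, MetricSeries, compare_states,
                             center_distance_series, decompose_domains,
                             decompose_interdomain, domain_center,
                             end_to_end_series, kabsch_superpose,
                             radius_of_gyration, rmsd, rmsd_series,
                             rmsf_profile, superposed_rmsd)
from cardyn.model import AtomSelection

from conftest import ca_atom, ca_chain_frame, trajectory_from_coords

finite_points = st.lists(
    st.lists(st.floats(-50, 50), min_size=3, max_size=3), min_size=4, max_size=10)


def _const_series(name: str, value: float, n: int = 10) -> MetricSeries:
    return MetricSeries(name=name, per_frame_values=np.full(n, value))


class TestKabsch:
    def test_identity(self):
        pts = np.array([[0., 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        tf, aligned = kabsch_superpose(pts, pts)
        np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-10)
        assert rmsd(aligned, pts) < 1e-10

    def test_recovers_rigid_motion(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(size=(6, 3))
        rot = Rotation.from_euler("z", 90, degrees=True)
        mobile = rot.apply(ref) + np.array([3.0, 4.0, 0.0])
        _, aligned = kabsch_superpose(mobile, ref)
        assert rmsd(aligned, ref) < 1e-8

    def test_degenerate_inputs(self):
        line = np.array([[0., 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(NumericalError):
            kabsch_superpose(line, line)
        with pytest.raises(NumericalError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_no_reflection(self):
        """A mirrored point set must map through a proper rotation only."""
        rng = np.random.default_rng(1)
        ref = rng.normal(size=(6, 3))
        mirrored = ref * np.array([-1.0, 1.0, 1.0])
        tf, _ = kabsch_superpose(mirrored, ref)
        assert np.isclose(np.linalg.det(tf.rotation), 1.0, atol=1e-9)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(finite_points, finite_points)
    def test_superposed_never_worse(self, a, b):
        a = np.asarray(a)
        b = np.asarray(b)
        if min(np.linalg.matrix_rank(a - a.mean(0), tol=1e-6),
               np.linalg.matrix_rank(b - b.mean(0), tol=1e-6)) < 2:
            return
        if len(a) != len(b):
            return
        assert superposed_rmsd(a, b) <= rmsd(a, b) + 1e-9


class TestRmsd:
    def test_identical(self):
        pts = np.arange(12.0).reshape(4, 3)
        assert rmsd(pts, pts) == 0.0

    def test_translation_closed_form(self):
        pts = np.arange(12.0).reshape(4, 3)
        assert rmsd(pts, pts + np.array([3.0, 4.0, 0.0])) == pytest.approx(5.0)

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(7, 3))
        b = rng.normal(size=(7, 3))
        naive = np.sqrt(sum((a[i] - b[i]) @ (a[i] - b[i]) for i in range(7)) / 7)
        assert rmsd(a, b) == pytest.approx(naive, rel=1e-12)

    def test_mismatched_counts(self):
        with pytest.raises(SelectionError):
            rmsd(np.zeros((3, 3)), np.zeros((4, 3)))

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(finite_points)
    def test_symmetry_and_rigid_invariance(self, pts):
        a = np.asarray(pts)
        rng = np.random.default_rng(3)
        b = a + rng.normal(size=a.shape)
        assert rmsd(a, b) == pytest.approx(rmsd(b, a))
        rot = Rotation.from_euler("xyz", [20, -40, 75], degrees=True)
        t = np.array([1.0, -2.0, 3.0])
        assert rmsd(rot.apply(a) + t, rot.apply(b) + t) == pytest.approx(
            rmsd(a, b), abs=1e-9)


class TestRmsdSeries:
    def _rigid_motion_traj(self, n_frames=5):
        rng = np.random.default_rng(11)
        base_coords = rng.normal(size=(6, 3)) * 4
        topo = [ca_atom(i + 1, i + 1, base_coords[i]) for i in range(6)]
        coords = []
        for k in range(n_frames):
            rot = Rotation.from_euler("y", 17 * k, degrees=True)
            coords.append(rot.apply(base_coords) + [k, 2 * k, 0])
        return trajectory_from_coords(topo, coords)

    def test_rigid_motion_is_zero(self):
        traj = self._rigid_motion_traj()
        sel = AtomSelection(tuple(range(6)), "all")
        series = rmsd_series(traj, None, sel, sel)
        np.testing.assert_allclose(series.per_frame_values, 0.0, atol=1e-8)

    def test_two_frame_closed_form(self):
        # fit atoms (0-2) static; one of four measured atoms (3-6) moves 2 Å
        topo = [ca_atom(i + 1, i + 1, (0, 0, 0)) for i in range(7)]
        f0 = [[0, 0, 0], [4, 0, 0], [0, 4, 0], [10, 0, 0], [14, 0, 0],
              [10, 4, 0], [14, 4, 0]]
        f1 = [row[:] for row in f0]
        f1[3] = [10, 0, 2.0]
        traj = trajectory_from_coords(topo, [f0, f1])
        fit = AtomSelection((0, 1, 2), "fit")
        meas = AtomSelection((3, 4, 5, 6), "meas")
        series = rmsd_series(traj, None, fit, meas)
        assert series.per_frame_values[0] == pytest.approx(0.0, abs=1e-10)
        assert series.per_frame_values[1] == pytest.approx(1.0)  # sqrt(4/4)

    def test_fit_to_self_vs_fit_to_anchor(self):
        """A rigidly translating domain: fit-to-self flat, fit-to-anchor grows."""
        topo = [ca_atom(i + 1, i + 1, (0, 0, 0)) for i in range(8)]
        anchor = np.array([[0, 0, 0], [4, 0, 0], [0, 4, 0], [0, 0, 4.]])
        domain = np.array([[10, 0, 0], [14, 0, 0], [10, 4, 0], [10, 0, 4.]])
        coords = [np.vstack([anchor, domain + [0, 0, 5.0 * k]]) for k in range(4)]
        traj = trajectory_from_coords(topo, coords)
        fit_anchor = AtomSelection((0, 1, 2, 3), "anchor")
        dom_sel = AtomSelection((4, 5, 6, 7), "domain")
        to_self = rmsd_series(traj, None, dom_sel, dom_sel)
        to_anchor = rmsd_series(traj, None, fit_anchor, dom_sel)
        np.testing.assert_allclose(to_self.per_frame_values, 0.0, atol=1e-8)
        assert to_anchor.per_frame_values[-1] > 10.0


class TestRmsf:
    def test_constant_trajectory_zero(self):
        pts = np.array([[0, 0, 0], [4, 0, 0], [0, 4, 0], [0, 0, 4], [3, 3, 3.]])
        topo = [ca_atom(i + 1, i + 1, pts[i]) for i in range(5)]
        traj = trajectory_from_coords(topo, [pts] * 4)
        sel = AtomSelection(tuple(range(5)), "all")
        profile = rmsf_profile(traj, sel, sel)
        np.testing.assert_allclose(profile.values, 0.0, atol=1e-10)

    def test_alternating_displacement(self):
        # fit atoms static; last atom alternates x = ±1 about its mean
        topo = [ca_atom(i + 1, i + 1, (0, 0, 0)) for i in range(4)]
        base = np.array([[0, 0, 0], [4, 0, 0], [0, 4, 0], [10, 0, 0.]])
        frames = []
        for k in range(20):
            f = base.copy()
            f[3, 0] += 1.0 if k % 2 == 0 else -1.0
            frames.append(f)
        traj = trajectory_from_coords(topo, frames)
        fit = AtomSelection((0, 1, 2), "fit")
        meas = AtomSelection((3,), "probe")
        profile = rmsf_profile(traj, fit, meas)
        assert profile.values[0] == pytest.approx(1.0, abs=1e-8)

    def test_sinusoid_closed_form(self):
        """RMS of a sinusoid of amplitude a is a/√2."""
        a = 2.5
        topo = [ca_atom(i + 1, i + 1, (0, 0, 0)) for i in range(4)]
        base = np.array([[0, 0, 0], [4, 0, 0], [0, 4, 0], [10, 0, 0.]])
        n = 4000
        frames = []
        for k in range(n):
            f = base.copy()
            f[3, 0] += a * np.sin(2 * np.pi * k / 200)
            frames.append(f)
        traj = trajectory_from_coords(topo, frames)
        profile = rmsf_profile(traj, AtomSelection((0, 1, 2), "fit"),
                               AtomSelection((3,), "probe"))
        assert profile.values[0] == pytest.approx(a / np.sqrt(2), rel=0.02)

    def test_gaussian_displacement_sigma_sqrt3(self):
        """Isotropic Gaussian jitter of width σ per coordinate → RMSF σ√3."""
        sigma = 0.7
        rng = np.random.default_rng(8)
        topo = [ca_atom(i + 1, i + 1, (0, 0, 0)) for i in range(4)]
        base = np.array([[0, 0, 0], [4, 0, 0], [0, 4, 0], [10, 0, 0.]])
        coords = np.repeat(base[None], 20000, axis=0)
        coords[:, 3, :] += rng.normal(0, sigma, (20000, 3))
        traj = trajectory_from_coords(topo, coords)
        profile = rmsf_profile(traj, AtomSelection((0, 1, 2), "fit"),
                               AtomSelection((3,), "probe"))
        assert profile.values[0] == pytest.approx(sigma * np.sqrt(3), rel=0.03)

    def test_single_frame_rejected(self):
        base = ca_chain_frame(5)
        traj = trajectory_from_coords(base.topology, [base.coords])
        sel = AtomSelection(tuple(range(5)), "all")
        with pytest.raises(NumericalError):
            rmsf_profile(traj, sel, sel)


class TestRgyrAndCenters:
    def test_closed_forms(self):
        f1 = ca_chain_frame(1)
        assert radius_of_gyration(f1, AtomSelection((0,), "one")) == 0.0
        topo = [ca_atom(1, 1, (0, 0, 0)), ca_atom(2, 2, (2, 0, 0))]
        f2 = trajectory_from_coords(topo, [[[0, 0, 0], [2, 0, 0]]]).frame(0)
        assert radius_of_gyration(f2, AtomSelection((0, 1), "two")) == pytest.approx(1.0)
        sq = [[0, 0, 0], [2, 0, 0], [2, 2, 0], [0, 2, 0]]
        topo4 = [ca_atom(i + 1, i + 1, sq[i]) for i in range(4)]
        f4 = trajectory_from_coords(topo4, [sq]).frame(0)
        assert radius_of_gyration(f4, AtomSelection(tuple(range(4)), "sq")) == \
            pytest.approx(np.sqrt(2))

    def test_rgyr_rigid_invariance_and_scaling(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(10, 3)) * 5
        topo = [ca_atom(i + 1, i + 1, pts[i]) for i in range(10)]
        sel = AtomSelection(tuple(range(10)), "all")
        f = trajectory_from_coords(topo, [pts]).frame(0)
        rg = radius_of_gyration(f, sel)
        rot = Rotation.from_euler("zx", [33, -71], degrees=True)
        f_rot = trajectory_from_coords(topo, [rot.apply(pts) + 7.0]).frame(0)
        assert radius_of_gyration(f_rot, sel) == pytest.approx(rg, rel=1e-12)
        f_scaled = trajectory_from_coords(topo, [pts * 3.0]).frame(0)
        assert radius_of_gyration(f_scaled, sel) == pytest.approx(3 * rg, rel=1e-12)

    def test_domain_center(self):
        topo = [ca_atom(1, 1, (0, 0, 0)), ca_atom(2, 2, (2, 0, 0))]
        f = trajectory_from_coords(topo, [[[0, 0, 0], [2, 0, 0]]]).frame(0)
        np.testing.assert_allclose(
            domain_center(f, AtomSelection((0, 1), "d")), [1, 0, 0])
        np.testing.assert_allclose(
            domain_center(f, AtomSelection((0,), "d")), [0, 0, 0])

    def test_center_distance_static(self):
        # two 4-atom blobs, centers 50 Å apart along z, plus static fit atoms
        blob = np.array([[0, 0, 0], [4, 0, 0], [0, 4, 0], [0, 0, 4.]])
        fit = blob - [20, 0, 0]
        coords = np.vstack([fit, blob - blob.mean(0), blob - blob.mean(0) + [0, 0, 50]])
        topo = [ca_atom(i + 1, i + 1, coords[i]) for i in range(12)]
        traj = trajectory_from_coords(topo, [coords] * 3)
        fit_sel = AtomSelection((0, 1, 2, 3), "fit")
        a = AtomSelection((4, 5, 6, 7), "A")
        b = AtomSelection((8, 9, 10, 11), "B")
        series = center_distance_series(traj, a, b, fit_sel)
        np.testing.assert_allclose(series.per_frame_values, 50.0, atol=1e-9)

    def test_end_to_end(self):
        f = ca_chain_frame(2)
        traj = trajectory_from_coords(f.topology, [f.coords])
        assert end_to_end_series(traj).per_frame_values[0] == pytest.approx(3.8)
        n = 9
        f = ca_chain_frame(n)
        traj = trajectory_from_coords(f.topology, [f.coords])
        assert end_to_end_series(traj).per_frame_values[0] == \
            pytest.approx(3.8 * (n - 1))

    def test_end_to_end_orders_conformers(self):
        extended = ca_chain_frame(10)
        collapsed = extended.coords * np.array([0.3, 1.0, 1.0])
        traj = trajectory_from_coords(extended.topology,
                                      [extended.coords, collapsed])
        vals = end_to_end_series(traj).per_frame_values
        assert vals[0] > vals[1]


class TestDecomposition:
    @pytest.mark.parametrize("overall, intra, expected", [
        (71.5, 0.5, 71.0),   # antigen-binding domain arithmetic
        (5.0, 5.0, 0.0),
        (10.0, 12.0, -2.0),  # negative inter-domain contribution is allowed
    ])
    def test_worked_examples(self, overall, intra, expected):
        assert decompose_interdomain(overall, intra) == pytest.approx(expected)

    def test_exact_identity_per_domain(self):
        results = decompose_domains(
            {"AB": 71.5, "HI": 1.1, "CS": 75.6, "SI": 32.3},
            {"AB": 0.5, "HI": 3.1, "CS": 1.9, "SI": 2.5})
        for r in results:
            assert r.inter_diff == r.overall_diff - r.intra_diff

    def test_non_finite_rejected(self):
        with pytest.raises(NumericalError):
            decompose_interdomain(float("nan"), 0.0)


class TestCompareStates:
    def test_printed_distance_differences(self):
        c = compare_states(_const_series("dist_AB_TM", 54.8),
                           _const_series("dist_AB_TM", 49.9))
        assert c.abs_diff == pytest.approx(4.9)
        assert c.signed_diff == pytest.approx(-4.9)
        c = compare_states(_const_series("dist_SI_TM", 43.7),
                           _const_series("dist_SI_TM", 56.1))
        assert c.abs_diff == pytest.approx(12.4)
        assert c.signed_diff == pytest.approx(12.4)

    def test_identical_series(self):
        s = MetricSeries(name="x", per_frame_values=np.arange(10.0))
        c = compare_states(s, s, equilibration_cut=3)
        assert c.signed_diff == 0.0
        assert c.apo_mean == pytest.approx(np.mean(np.arange(3, 10)))

    def test_cut_beyond_length(self):
        s = _const_series("x", 1.0, n=5)
        with pytest.raises(NumericalError):
            compare_states(s, s, equilibration_cut=5)
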