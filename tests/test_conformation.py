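"""Hydrogen bonds, propensities, clustering, coverage, rotational tumbling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycoleus.conformation import (
    HBondCriterion,
    PropensityRegions,
    classify_backbone,
    cluster_conformations,
    coverage_curves,
    detect_hbonds,
    phi_bin_preferences,
    propensities,
    rotational_tau,
    vector_autocorrelation,
)
from glycoleus.geometry import measure_angle
from glycoleus.reweight import FrameWeights
from glycoleus.toy_system import CartesianFrame, DihedralTrajectory, sample_rotational_diffusion


def _frame(positions: dict):
    names = list(positions)
    coords = np.array([positions[n] for n in names], dtype=float)
    elements = ["H" if n.startswith("H") else n[0] for n in names]
    return CartesianFrame(names, elements, coords)


class TestHBonds:
    def test_linear_geometry_detected(self):
        crit = HBondCriterion()
        assert crit.is_hbond([0, 0, 0], [0.1, 0, 0], [0.3, 0, 0])  # d(H,A)=0.20, 180 deg

    def test_distance_gate(self):
        crit = HBondCriterion()
        assert not crit.is_hbond([0, 0, 0], [0.1, 0, 0], [0.36, 0, 0])  # d(H,A)=0.26

    def test_angle_gate(self):
        crit = HBondCriterion()
        # d(H,A)=0.2 but DHA angle 90 deg
        assert not crit.is_hbond([0, 0, 0], [0.1, 0, 0], [0.1, 0.2, 0])

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(17)
        donors = [("D1", "H1"), ("D2", "H2")]
        acceptors = ["A1", "A2", "A3"]
        atom_names = ["D1", "H1", "D2", "H2", "A1", "A2", "A3"]
        frames = []
        for _ in range(100):
            pos = {n: 0.45 * rng.random(3) for n in atom_names}
            # keep each H near its donor so angles are well defined
            pos["H1"] = pos["D1"] + 0.1 * _unit(rng)
            pos["H2"] = pos["D2"] + 0.1 * _unit(rng)
            frames.append(_frame(pos))
        w = FrameWeights.uniform(100)
        crit = HBondCriterion()
        got = detect_hbonds(frames, w, donors, acceptors, crit, report_threshold=0.0)

        expect = {}
        for d, h in donors:
            for a in acceptors:
                count = 0
                for fr in frames:
                    hp, ap, dp = fr.position(h), fr.position(a), fr.position(d)
                    if (
                        np.linalg.norm(hp - ap) < 0.25
                        and measure_angle(dp, hp, ap) > 135.0
                    ):
                        count += 1
                expect[f"{h}-{a}"] = 100.0 * count / 100.0
        assert got == pytest.approx(expect, abs=1e-9)

    def test_missing_hydrogen_rejected(self):
        fr = _frame({"D1": [0, 0, 0], "A1": [0.3, 0, 0]})
        with pytest.raises(KeyError):
            detect_hbonds([fr], FrameWeights.uniform(1), [("D1", "H1")], ["A1"])


def _unit(rng):
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


class TestPropensities:
    def test_canonical_helical_point(self):
        assert classify_backbone(-60.0, -45.0) == "alpha"

    def test_canonical_extended_point(self):
        assert classify_backbone(-140.0, 150.0) == "beta"

    def test_canonical_pii_point(self):
        assert classify_backbone(-70.0, 150.0) == "P_II"

    @given(
        st.lists(
            st.tuples(st.floats(-180, 179.9), st.floats(-180, 179.9)),
            min_size=1,
            max_size=50,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_partition_sums_to_one(self, points):
        angles = np.array(points)
        traj = DihedralTrajectory(
            ("phi_P", "psi_P"), angles, np.arange(1.0, len(angles) + 1.0)
        )
        props = propensities(traj, FrameWeights.uniform(len(angles)))
        assert sum(props.values()) == pytest.approx(1.0, abs=1e-9)

    def test_regions_disjoint_on_grid(self):
        regions = PropensityRegions()
        boxes = [regions.beta, regions.p_ii, regions.alpha]
        for phi in np.arange(-180, 180, 7.5):
            for psi in np.arange(-180, 180, 7.5):
                assert sum(b.contains(phi, psi) for b in boxes) <= 1


class TestPhiBinPreferences:
    def _traj(self, phis):
        a = np.column_stack([phis, np.zeros(len(phis))])
        return DihedralTrajectory(("phi_P", "psi_P"), a, np.arange(1.0, len(phis) + 1.0))

    def test_single_bin(self):
        traj = self._traj([-120.0] * 5)
        fracs = phi_bin_preferences(traj, FrameWeights.uniform(5))
        assert fracs == pytest.approx([100.0, 0.0, 0.0], abs=1e-12)

    def test_uniform_fractions_proportional_to_widths(self):
        phis = np.arange(-180.0, 180.0, 0.5)
        traj = self._traj(phis)
        fracs = phi_bin_preferences(traj, FrameWeights.uniform(len(phis)))
        widths = np.array([80.0, 100.0, 180.0]) / 360.0 * 100.0
        assert fracs == pytest.approx(widths.tolist(), abs=0.2)

    def test_sum_is_hundred(self):
        rng = np.random.default_rng(3)
        traj = self._traj(rng.uniform(-180, 180, 500))
        assert sum(phi_bin_preferences(traj, FrameWeights.uniform(500))) == pytest.approx(
            100.0, abs=1e-9
        )


def _jittered_frames(rng, base, n, scale):
    frames = []
    for _ in range(n):
        coords = base + rng.normal(0.0, scale, size=base.shape)
        names = [f"A{i}" for i in range(len(base))]
        frames.append(CartesianFrame(names, ["C"] * len(base), coords))
    return frames


class TestClustering:
    def test_identical_frames_single_cluster(self):
        base = np.random.default_rng(0).random((5, 3))
        frames = _jittered_frames(np.random.default_rng(1), base, 6, 0.0)
        names = frames[0].names
        res = cluster_conformations(frames, names, names, cutoff=0.1)
        assert res.n_clusters == 1
        assert len(res.clusters[0]) == 6

    def test_two_separated_groups(self):
        rng = np.random.default_rng(2)
        base_a = rng.random((6, 3))
        base_b = base_a + np.array([0.0, 0.0, 0.0])
        base_b = base_a.copy()
        base_b[0] += 0.8  # large internal distortion: >0.1 nm RMSD after fit
        frames = _jittered_frames(rng, base_a, 5, 0.005) + _jittered_frames(
            rng, base_b, 4, 0.005
        )
        names = frames[0].names
        res = cluster_conformations(frames, names, names, cutoff=0.1)
        assert res.n_clusters == 2
        assert [len(c) for c in res.clusters] == [5, 4]

    def test_huge_cutoff_single_cluster(self):
        rng = np.random.default_rng(3)
        frames = _jittered_frames(rng, rng.random((4, 3)), 7, 0.2)
        names = frames[0].names
        res = cluster_conformations(frames, names, names, cutoff=1e3)
        assert res.n_clusters == 1

    def test_clusters_partition_frames(self):
        rng = np.random.default_rng(4)
        frames = _jittered_frames(rng, rng.random((4, 3)), 12, 0.05)
        names = frames[0].names
        res = cluster_conformations(frames, names, names, cutoff=0.08)
        all_members = sorted(i for c in res.clusters for i in c)
        assert all_members == list(range(12))
        sizes = [len(c) for c in res.clusters]
        assert sizes == sorted(sizes, reverse=True)

    def test_superposition_removes_rigid_motion(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(5)
        base = rng.random((6, 3))
        rot = Rotation.from_euler("xyz", [30, -60, 12], degrees=True)
        moved = rot.apply(base) + np.array([1.0, -2.0, 0.5])
        names = [f"A{i}" for i in range(6)]
        frames = [
            CartesianFrame(names, ["C"] * 6, base),
            CartesianFrame(list(names), ["C"] * 6, moved),
        ]
        res = cluster_conformations(frames, names, names, cutoff=1e-6)
        assert res.n_clusters == 1


class TestCoverageCurves:
    def _result(self, membership):
        from glycoleus.conformation import ClusterResult

        clusters = {}
        for i, c in enumerate(membership):
            clusters.setdefault(c, []).append(i)
        ordered = sorted(clusters.values(), key=lambda m: (-len(m), m[0]))
        return ClusterResult(ordered, [m[0] for m in ordered], 0.1)

    def test_single_cluster_all_ones(self):
        res = self._result([0] * 10)
        curves = coverage_curves(res, np.arange(10.0))
        for level, counts in curves.items():
            assert counts == [1] * 10

    def test_two_equal_clusters(self):
        res = self._result([0, 1] * 5)
        curves = coverage_curves(res, np.arange(10.0), coverage_levels=(0.5, 0.99))
        assert curves[0.5][-1] == 1
        assert curves[0.99][-1] == 2

    def test_monotone_in_level(self):
        rng = np.random.default_rng(6)
        res = self._result(rng.integers(0, 4, size=40).tolist())
        curves = coverage_curves(res, np.arange(40.0), coverage_levels=(0.5, 0.75, 0.95, 0.99))
        for k in range(40):
            vals = [curves[l][k] for l in (0.5, 0.75, 0.95, 0.99)]
            assert vals == sorted(vals)


class TestRotationalTau:
    def test_static_vector_unresolvable(self):
        v = np.tile([0.0, 0.0, 1.0], (200, 1))
        fit = rotational_tau(v, dt_ps=1.0)
        assert not fit.resolvable
        assert fit.tau_ps is None

    def test_iid_vectors_have_no_correlation(self):
        rng = np.random.default_rng(7)
        v = rng.normal(size=(4000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        acf = vector_autocorrelation(v, order=2, max_lag=20)
        assert acf[0] == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.abs(acf[1:]) < 3.0 / np.sqrt(len(v)))

    def test_known_diffusion_constant_recovered(self):
        d_r = 0.002  # 1/ps
        v = sample_rotational_diffusion(d_r, 1.0, 30000, seed=8)
        fit = rotational_tau(v, dt_ps=1.0, order=2, max_lag=1500)
        assert fit.resolvable
        assert fit.tau_ps == pytest.approx(1.0 / (6.0 * d_r), rel=0.2)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            rotational_tau(np.random.default_rng(0).normal(size=(50, 3)), dt_ps=1.0)
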