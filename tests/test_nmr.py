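"""Karplus couplings, virtual sites, r^-6 NOE averaging and violations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycoleus.nmr import (
    KARPLUS_PRESETS,
    KarplusRelation,
    VirtualSiteRule,
    distance_distribution,
    ensemble_j,
    karplus_j,
    noe_average,
    noe_report,
    place_virtual_sites,
    proton_distances,
)
from glycoleus.reweight import FrameWeights
from glycoleus.toy_system import CartesianFrame, DihedralTrajectory, build_model_frame


def _traj(phi_values, name="phi_P"):
    phi = np.asarray(phi_values, dtype=float)[:, None]
    return DihedralTrajectory((name,), phi, np.arange(1.0, len(phi) + 1.0))


class TestKarplus:
    def test_amide_alpha_form_at_right_angle(self):
        rel = KARPLUS_PRESETS["3J_HN_HA"]
        assert rel.j_from_karplus_angle(90.0) == pytest.approx(1.60, abs=1e-12)

    def test_amide_alpha_form_at_anti(self):
        rel = KARPLUS_PRESETS["3J_HN_HA"]
        assert rel.j_from_karplus_angle(180.0) == pytest.approx(9.87, abs=1e-12)

    def test_acetamide_form_at_anti(self):
        rel = KARPLUS_PRESETS["3J_HN2_H2"]
        assert rel.j_from_karplus_angle(180.0) == pytest.approx(12.10, abs=1e-12)

    def test_offset_applied_to_raw_dihedral(self):
        # phi_P = -60 with the -60 offset gives Karplus angle -120
        rel = KARPLUS_PRESETS["3J_HN_HA"]
        expect = 6.51 * 0.25 + 1.76 * 0.5 + 1.60
        assert karplus_j(-60.0, rel) == pytest.approx(expect, abs=1e-12)

    def test_alpha_beta_presets_share_form_but_not_offset(self):
        thr = KARPLUS_PRESETS["3J_HA_HB_thr"]
        ser2 = KARPLUS_PRESETS["3J_HA_HB2_ser"]
        ser3 = KARPLUS_PRESETS["3J_HA_HB3_ser"]
        assert (thr.a, thr.b, thr.c) == (ser2.a, ser2.b, ser2.c) == (ser3.a, ser3.b, ser3.c)
        assert ser2.offset_deg == 0.0
        assert thr.offset_deg == ser3.offset_deg == -120.0


class TestEnsembleJ:
    def test_single_point_ensemble_closed_form(self):
        rel = KARPLUS_PRESETS["3J_HN_HA"]
        traj = _traj([-60.0] * 8)
        j, err = ensemble_j(traj, FrameWeights.uniform(8), rel)
        assert j == pytest.approx(4.1075, abs=1e-12)
        assert err == 0.0

    def test_delta_ensemble_equals_pointwise(self):
        rel = KARPLUS_PRESETS["3J_HN2_H2"]
        traj = _traj([37.0] * 4, name="theta_amide")
        j, _ = ensemble_j(traj, FrameWeights.uniform(4), rel)
        assert j == pytest.approx(karplus_j(37.0, rel), abs=1e-12)

    def test_two_point_mixture(self):
        rel = KARPLUS_PRESETS["3J_HN_HA"]
        # raw dihedrals 60 and -120 map to Karplus angles 0 and -180
        traj = _traj([60.0, -120.0])
        j, _ = ensemble_j(traj, FrameWeights.uniform(2), rel)
        assert j == pytest.approx((6.35 + 9.87) / 2.0, abs=1e-12)

    @given(st.lists(st.floats(-180, 179.99), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_ensemble_j_within_analytic_range(self, dihedrals):
        rel = KARPLUS_PRESETS["3J_HN_HA"]
        traj = _traj(dihedrals)
        j, _ = ensemble_j(traj, FrameWeights.uniform(len(dihedrals)), rel)
        lo, hi = rel.j_range
        assert lo - 1e-9 <= j <= hi + 1e-9


def _tetrahedral_frame():
    """United CH1 carbon with three ideal tetrahedral heavy neighbours."""
    c = np.zeros(3)
    d = 0.15
    verts = d * np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1]], dtype=float
    ) / np.sqrt(3.0)
    names = ["C0", "X1", "X2", "X3"]
    coords = np.vstack([c, verts])
    return CartesianFrame(
        names, ["C", "C", "C", "C"], coords, [(0, 1), (0, 2), (0, 3)], {"C0"}
    )


class TestVirtualSites:
    def test_ch1_ideal_geometry(self):
        fr = _tetrahedral_frame()
        out = place_virtual_sites(fr, [VirtualSiteRule("C0", "CH1", ("H0",))])
        h = out.position("H0")
        assert np.linalg.norm(h) == pytest.approx(0.10, abs=1e-12)
        from glycoleus.geometry import measure_angle

        for x in ("X1", "X2", "X3"):
            ang = measure_angle(h, out.position("C0"), out.position(x))
            assert ang == pytest.approx(109.471, abs=0.01)

    def test_ch2_mirror_pair_and_label_swap(self):
        names = ["CB", "CA", "OG"]
        coords = np.array([[0.0, 0, 0], [0.15, 0, 0], [-0.05, 0.13, 0]])
        fr = CartesianFrame(names, ["C", "C", "O"], coords, [(0, 1), (0, 2)], {"CB"})
        out = place_virtual_sites(fr, [VirtualSiteRule("CB", "CH2", ("HB1", "HB2"))])
        h1, h2 = out.position("HB1"), out.position("HB2")
        # mirror-symmetric about the heavy-neighbour plane (z=0 here)
        assert h1[2] == pytest.approx(-h2[2], abs=1e-12)
        assert h1[:2] == pytest.approx(h2[:2], abs=1e-12)
        from glycoleus.geometry import measure_angle

        assert measure_angle(h1, out.position("CB"), h2) == pytest.approx(109.471, abs=0.01)
        # swapping neighbour order only swaps the labels
        fr_swapped = CartesianFrame(names, ["C", "C", "O"], coords, [(0, 2), (0, 1)], {"CB"})
        out2 = place_virtual_sites(fr_swapped, [VirtualSiteRule("CB", "CH2", ("HB1", "HB2"))])
        assert out2.position("HB1") == pytest.approx(h2, abs=1e-12)
        assert out2.position("HB2") == pytest.approx(h1, abs=1e-12)

    def test_ch3_pseudo_site_vs_explicit_rotor(self):
        """Corrected pseudo-site distances bound the explicit-rotor r^-6 average."""
        ch = 0.10
        t = np.radians(180.0 - 109.471)
        ring = np.array(
            [
                [ch * np.sin(t) * np.cos(a), ch * np.sin(t) * np.sin(a), ch * np.cos(t)]
                for a in np.radians(np.arange(0.0, 360.0, 1.0))
            ]
        )
        corr = 0.3  # Angstrom, the configured default
        for d_nm in (0.3, 0.45, 0.6):
            for direction in ([1.0, 0, 0], [0, 0, 1.0], [0.6, 0, 0.8]):
                probe = d_nm * np.asarray(direction)
                r = 10.0 * np.linalg.norm(ring - probe, axis=1)
                rotor = float(np.mean(r**-6.0) ** (-1.0 / 6.0))
                pseudo = 10.0 * d_nm  # site at the carbon
                # the rotor average sits below the centre distance (closest-H
                # dominance); the +corr pseudo distance is a conservative
                # upper proxy within a bounded margin
                assert rotor <= pseudo + corr
                assert (pseudo + corr) - rotor <= 3.0 * corr

    def test_wrong_neighbor_count_rejected(self):
        fr = _tetrahedral_frame()
        with pytest.raises(ValueError, match="C0"):
            place_virtual_sites(fr, [VirtualSiteRule("C0", "CH2", ("HA", "HB"))])

    def test_sites_deterministic_across_runs(self):
        fr = build_model_frame({"phi_P": -70.0, "psi_P": 145.0}, "ser_glyco")
        rules = [
            VirtualSiteRule("CA", "CH1", ("HA",)),
            VirtualSiteRule("CB", "CH2", ("HB1", "HB2")),
        ]
        a = place_virtual_sites(fr, rules)
        b = place_virtual_sites(fr, rules)
        assert np.array_equal(a.coords, b.coords)


class TestNOEAverage:
    def test_constant_distance(self):
        avg, err = noe_average(np.full(8, 3.3), FrameWeights.uniform(8))
        assert avg == pytest.approx(3.3, abs=1e-12)
        assert err == 0.0

    def test_two_frame_arithmetic(self):
        avg, _ = noe_average([2.0, 4.0], FrameWeights.uniform(2))
        expect = (0.5 * (2.0**-6 + 4.0**-6)) ** (-1.0 / 6.0)
        assert avg == pytest.approx(expect, abs=1e-12)
        assert avg == pytest.approx(2.24, abs=0.005)

    @given(st.lists(st.floats(0.5, 20.0), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_power_mean_bounds(self, distances):
        r = np.asarray(distances)
        avg, _ = noe_average(r, FrameWeights.uniform(len(r)))
        assert r.min() - 1e-9 <= avg <= r.mean() + 1e-9

    def test_adding_closer_frame_decreases_average(self):
        base = np.array([3.0, 3.5, 4.0, 3.2])
        avg0, _ = noe_average(base, FrameWeights.uniform(4))
        closer = np.append(base, 2.0)  # below the current average
        avg1, _ = noe_average(closer, FrameWeights.uniform(5))
        assert avg1 < avg0

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            noe_average([2.0, 0.0], FrameWeights.uniform(2))


class TestNOEReport:
    def test_violation_arithmetic_significant(self):
        w = FrameWeights.uniform(4)
        recs = noe_report({"d(HT,HB1)": np.full(4, 3.5)}, {"d(HT,HB1)": 2.5}, w)
        assert recs[0].violation_A == pytest.approx(1.0, abs=1e-12)
        assert recs[0].significant

    def test_violation_above_threshold(self):
        w = FrameWeights.uniform(4)
        recs = noe_report({"d(HT,H)": np.full(4, 4.0)}, {"d(HT,H)": 2.8}, w)
        assert recs[0].violation_A == pytest.approx(1.2, abs=1e-12)
        assert recs[0].significant

    def test_satisfied_bound_clamps_to_zero(self):
        w = FrameWeights.uniform(4)
        recs = noe_report({"d(HA,H)": np.full(4, 2.6)}, {"d(HA,H)": 2.9}, w)
        assert recs[0].violation_A == 0.0
        assert not recs[0].significant

    def test_missing_pair_rejected(self):
        with pytest.raises(KeyError):
            noe_report({}, {"d(HT,H)": 2.8}, FrameWeights.uniform(1))


class TestDistanceDistribution:
    def test_single_bin(self):
        edges, hist, mean = distance_distribution(np.full(6, 3.14), FrameWeights.uniform(6), 0.5)
        assert hist.sum() == pytest.approx(1.0, abs=1e-12)
        assert (hist > 0).sum() == 1

    def test_mass_normalized_and_mean_by_enumeration(self):
        r = np.array([2.0, 2.4, 3.7, 5.1])
        edges, hist, mean = distance_distribution(r, FrameWeights.uniform(4), 0.5)
        assert hist.sum() == pytest.approx(1.0, abs=1e-12)
        assert mean == pytest.approx(r.mean(), abs=1e-12)


def test_proton_distances_resolves_virtual_names():
    frames = [
        build_model_frame({"phi_P": p, "psi_P": 140.0}, "thr_glyco") for p in (-60.0, -120.0)
    ]
    rules = [VirtualSiteRule("CA", "CH1", ("HA",)), VirtualSiteRule("CB", "CH1", ("HB",))]
    d = proton_distances(frames, {"d(HA,HB)": ("HA", "HB"), "d(HT,H)": ("HT", "H")}, rules)
    assert set(d) == {"d(HA,HB)", "d(HT,H)"}
    assert np.all(d["d(HA,HB)"] > 0)
    with pytest.raises(KeyError, match="H99"):
        proton_distances(frames, {"bad": ("H99", "H")}, rules)
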