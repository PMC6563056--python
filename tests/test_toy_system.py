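"""Toy surfaces, the Metropolis sampler, and the Cartesian model builder."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chisquare

from glycoleus.constants import KB
from glycoleus.geometry import measure_dihedral, wrap_angle
from glycoleus.toy_system import (
    AnalyticSurface,
    GaussianWell,
    SamplerConfig,
    build_model_frame,
    sample_dihedrals,
    sample_rotational_diffusion,
    surface_energy,
)


class TestAnalyticSurface:
    def test_empty_surface_is_zero(self):
        s = AnalyticSurface()
        assert surface_energy(s, 12.3, -45.6) == 0.0

    def test_well_center_is_global_minimum(self):
        s = AnalyticSurface((GaussianWell(60.0, 60.0, -10.0, 25.0),))
        g = np.arange(-180.0, 180.0, 5.0)
        pp, ss = np.meshgrid(g, g)
        assert surface_energy(s, 60.0, 60.0) <= surface_energy(s, pp, ss).min()

    def test_nearest_image_distance_governs_energy(self):
        # well at (170, 0): the point at -170 is 20 deg away through the seam,
        # the point at 130 is 40 deg away; brute-force periodic distances agree
        s = AnalyticSurface((GaussianWell(170.0, 0.0, -10.0, 20.0),))
        d1 = min(abs(-170 - 170 + k * 360) for k in (-1, 0, 1))
        d2 = min(abs(130 - 170 + k * 360) for k in (-1, 0, 1))
        assert (d1, d2) == (20, 40)
        assert surface_energy(s, -170.0, 0.0) < surface_energy(s, 130.0, 0.0)

    @given(
        phi=st.floats(-180, 180, allow_nan=False),
        psi=st.floats(-180, 180, allow_nan=False),
        shift=st.sampled_from([-720, -360, 360, 720]),
    )
    @settings(max_examples=50, deadline=None)
    def test_periodicity(self, phi, psi, shift):
        s = AnalyticSurface(
            (GaussianWell(30.0, -100.0, -8.0, 40.0), GaussianWell(-120.0, 60.0, -5.0, 20.0)),
            offset=2.0,
            torsion_terms=((1.5, 30.0, 3, 0),),
        )
        assert surface_energy(s, phi, psi) == pytest.approx(
            surface_energy(s, phi + shift, psi - shift), abs=1e-9
        )


class TestSampler:
    def test_flat_surface_gives_uniform_histogram(self, flat_surface):
        # chi-square needs near-independent draws: thin far beyond the
        # random-walk decorrelation time (~(360/step)^2 steps on a flat circle)
        traj = sample_dihedrals(
            flat_surface, SamplerConfig(n_steps=200000, seed=3, step_size=60.0, record_every=100)
        )
        for name in traj.angle_names:
            hist, _ = np.histogram(traj.column(name), bins=18, range=(-180, 180))
            _, p = chisquare(hist)
            assert p > 0.01

    def test_two_well_occupancy_matches_quadrature(self):
        s = AnalyticSurface(
            (GaussianWell(-60.0, 0.0, -11.0, 30.0), GaussianWell(100.0, 0.0, -8.0, 30.0)),
            angle_names=("phi", "psi"),
        )
        g, dens = s.boltzmann_grid(300.0, 1.0)
        in_a = (g >= -160) & (g < 20)
        ratio_oracle = dens.sum(axis=1)[~in_a].sum() / dens.sum(axis=1)[in_a].sum()

        traj = sample_dihedrals(s, SamplerConfig(n_steps=400000, seed=5, record_every=10))
        phi = traj.column("phi")
        in_b = ~((phi >= -160) & (phi < 20))
        ratios = [blk.mean() / (1 - blk.mean()) for blk in np.array_split(in_b, 4)]
        se = np.std(ratios) / np.sqrt(4)
        assert abs(in_b.mean() / (1 - in_b.mean()) - ratio_oracle) < 3.0 * se

    def test_bias_cancelling_surface_gives_uniform(self, two_basin):
        from glycoleus.leus import BiasPotential

        class ExactNegative(BiasPotential):
            def energy(self, phi, psi):
                return -float(two_basin.energy(phi, psi))

        bias = ExactNegative(two_basin.angle_names)
        traj = sample_dihedrals(
            two_basin,
            SamplerConfig(n_steps=200000, seed=9, step_size=60.0, record_every=100),
            bias=bias,
        )
        hist, _ = np.histogram(traj.column("phi"), bins=18, range=(-180, 180))
        _, p = chisquare(hist)
        assert p > 0.01

    def test_identical_seed_gives_bit_identical_trajectory(self, two_basin):
        cfg = SamplerConfig(n_steps=5000, seed=42, record_every=5)
        t1 = sample_dihedrals(two_basin, cfg)
        t2 = sample_dihedrals(two_basin, cfg)
        assert np.array_equal(t1.angles, t2.angles)
        assert np.array_equal(t1.times, t2.times)

    def test_histogram_converges_with_chain_length(self, two_basin):
        """Total variation to the quadrature density decreases along a step ladder."""
        g, dens = two_basin.boltzmann_grid(300.0, 10.0)
        target = dens.sum(axis=1)

        def tv(n_steps):
            traj = sample_dihedrals(
                two_basin, SamplerConfig(n_steps=n_steps, seed=13, record_every=5)
            )
            hist, _ = np.histogram(
                traj.column("phi"), bins=len(g), range=(-180, 180), density=False
            )
            return 0.5 * np.abs(hist / hist.sum() - target).sum()

        assert tv(200000) < tv(4000)

    def test_all_angles_canonical(self, unbiased_two_basin):
        assert np.all(unbiased_two_basin.angles >= -180.0)
        assert np.all(unbiased_two_basin.angles < 180.0)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SamplerConfig(n_steps=10, temperature=-1.0)
        with pytest.raises(ValueError):
            SamplerConfig(n_steps=10, step_size=200.0)
        with pytest.raises(ValueError):
            SamplerConfig(n_steps=-1)


class TestModelFrames:
    @pytest.mark.parametrize("template", ["ser_glyco", "thr_glyco"])
    @pytest.mark.parametrize(
        "angles",
        [
            {"phi_P": -60.0, "psi_P": -45.0},
            {"phi_P": -140.0, "psi_P": 150.0, "chi_S": -60.0, "phi_S": 72.5, "psi_S": -110.0},
            {"theta_amide": 150.0, "chi_S": 179.0},
        ],
    )
    def test_requested_dihedrals_round_trip(self, template, angles):
        fr = build_model_frame(angles, template)
        measured = {
            "phi_P": fr.dihedral("CX", "N", "CA", "C"),
            "psi_P": fr.dihedral("N", "CA", "C", "NT"),
            "chi_S": fr.dihedral("N", "CA", "CB", "O1"),
            "phi_S": fr.dihedral("O5", "C1", "O1", "CB"),
            "psi_S": fr.dihedral("C1", "O1", "CB", "CA"),
            "theta_amide": fr.dihedral("C7", "N2", "C2", "C1"),
        }
        for name, want in angles.items():
            assert measured[name] == pytest.approx(want, abs=1e-6)

    def test_identical_request_is_deterministic(self):
        a = build_model_frame({"phi_P": -70.0, "psi_P": 140.0}, "thr_glyco")
        b = build_model_frame({"phi_P": -70.0, "psi_P": 140.0}, "thr_glyco")
        assert np.array_equal(a.coords, b.coords)  # RMSD 0 without superposition

    def test_chi_mirror_symmetry(self):
        plus = build_model_frame({"chi_S": 60.0}, "ser_glyco")
        minus = build_model_frame({"chi_S": -60.0}, "ser_glyco")
        assert plus.dihedral("N", "CA", "CB", "O1") == pytest.approx(60.0, abs=1e-6)
        assert minus.dihedral("N", "CA", "CB", "O1") == pytest.approx(-60.0, abs=1e-6)
        # O1 positions are mirror images through the N-CA-CB plane: same
        # distances to the in-plane atoms
        for ref in ("N", "CA", "CB"):
            d_plus = np.linalg.norm(plus.position("O1") - plus.position(ref))
            d_minus = np.linalg.norm(minus.position("O1") - minus.position(ref))
            assert d_plus == pytest.approx(d_minus, abs=1e-9)

    def test_unknown_template_and_angle_rejected(self):
        with pytest.raises(KeyError):
            build_model_frame({}, "nonexistent")
        with pytest.raises(KeyError):
            build_model_frame({"bogus_angle": 10.0}, "ser_glyco")

    def test_united_carbons_have_heavy_neighbors(self):
        fr = build_model_frame({}, "thr_glyco")
        for c in fr.united_atoms:
            heavies = [n for n in fr.bonded_to(c) if fr.elements[fr.index(n)] != "H"]
            assert len(heavies) >= 1


def test_rotational_diffusion_returns_unit_vectors():
    v = sample_rotational_diffusion(0.01, 1.0, 500, seed=4)
    assert v.shape == (500, 3)
    assert np.allclose(np.linalg.norm(v, axis=1), 1.0, atol=1e-12)
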