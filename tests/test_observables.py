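"""Profiles, bulk density, excess adsorption, thickness, peaks, shape."""

import numpy as np
import pytest

from brushmd import observables as obs
from brushmd.fixtures import (
    bump_profile,
    constant_profile,
    decay_profile,
    make_mechanical_fixtures,
    sample_positions_from_profile,
    shell_profile,
)


def profile_from_points(pts, r_min, r_max, bw=0.05, center=None):
    return obs.radial_profile([pts], None, bw, center, r_min=r_min, r_max=r_max)


class TestRadialProfile:
    def test_uniform_points_give_flat_profile(self):
        prof_spec = constant_profile(0.05, (2.0, 12.0))
        pts = sample_positions_from_profile(prof_spec, 40_000, seed=1)
        prof = profile_from_points(pts, 2.0, 12.0, bw=0.5)
        # actual density: N / shell volume
        rho = 40_000 / (4 * np.pi / 3 * (12.0**3 - 2.0**3))
        inner = prof.density[1:-1]
        assert np.all(np.abs(inner - rho) < 5 * np.sqrt(rho / prof.shell_volumes[1:-1]))

    def test_anchor_spike_in_single_bin(self):
        from brushmd.build import build_hairy_particle
        from brushmd.model import SEGMENT

        cfg = build_hairy_particle(4.0, 20, 1, "M1", box=30.0, seed=3)
        center = 0.5 * np.asarray(cfg.box.lengths)
        prof = obs.radial_profile(
            [cfg.positions], cfg.species == SEGMENT, 0.05, center, r_min=2.0, r_max=15.0
        )
        k = np.argmax(prof.density)
        assert prof.centers[k] == pytest.approx(2.5)
        assert prof.total_count() == pytest.approx(20.0)

    def test_normalization_exact(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-5, 5, size=(500, 3))
        r = np.linalg.norm(pts, axis=1)
        inside = (r >= 1.0) & (r <= 4.0)
        prof = profile_from_points(pts, 1.0, 4.0)
        inside = (r >= prof.bin_edges[0]) & (r < prof.bin_edges[-1])
        assert prof.total_count() == pytest.approx(inside.sum())

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            obs.radial_profile([np.zeros((3, 3))], np.zeros(3, bool), 0.1)

    def test_prescribed_profile_recovered(self):
        spec = shell_profile(0.0, 0.3, 4.0, 6.0, (2.0, 10.0))
        pts = sample_positions_from_profile(spec, 30_000, seed=2)
        prof = profile_from_points(pts, 2.0, 10.0, bw=0.2)
        c = prof.centers
        occupied = (c > 4.2) & (c < 5.8)
        vacant = (c < 3.8) | (c > 6.2)
        assert prof.density[vacant].max() == 0.0
        ratio = prof.density[occupied].std() / prof.density[occupied].mean()
        assert ratio < 0.1  # flat within counting noise


class TestPlanarProfile:
    def test_uniform_fluid_flat(self):
        rng = np.random.default_rng(4)
        pts = np.column_stack([rng.uniform(0, 5, (2000, 2)), rng.uniform(0, 20, 2000)])
        prof = obs.planar_profile([pts], None, 1.0, area=25.0, z_max=20.0)
        rho = 2000 / (25.0 * 20.0)
        sig = np.sqrt(rho / (25.0 * np.diff(prof.bin_edges)))
        assert np.all(np.abs(prof.density - rho) < 5 * sig)

    def test_anchors_single_bin(self):
        from brushmd.build import build_flat_brush
        from brushmd.model import SEGMENT

        cfg = build_flat_brush(20, 1, rho_gr=0.398, Lz=40.0, seed=5)
        area = cfg.box.lengths[0] * cfg.box.lengths[1]
        prof = obs.planar_profile(
            [cfg.positions], cfg.species == SEGMENT, 0.05, area=area, z_max=40.0
        )
        assert prof.centers[np.argmax(prof.density)] == pytest.approx(0.5)


class TestBulkDensity:
    def test_constant_profile_exact(self):
        spec = constant_profile(0.05, (2.0, 15.0))
        edges = np.linspace(2.0, 15.0, 101)
        prof = obs.RadialProfile(edges, np.full(100, 0.05), "P", 1)
        assert obs.estimate_bulk_density(prof) == pytest.approx(0.05)

    def test_decay_reaches_plateau(self):
        spec = decay_profile(0.02, 0.5, 0.8, 3.0, (2.5, 15.0))
        edges = np.arange(2.5, 15.05, 0.05)
        centers = 0.5 * (edges[:-1] + edges[1:])
        prof = obs.RadialProfile(edges, spec.rho(centers), "P", 1)
        rho_b = obs.estimate_bulk_density(prof, window=(10.0, 15.0))
        assert rho_b == pytest.approx(0.02, rel=1e-3)

    def test_window_in_corona_flagged(self):
        spec = decay_profile(0.02, 0.5, 0.8, 3.0, (2.5, 15.0))
        edges = np.arange(2.5, 15.05, 0.05)
        centers = 0.5 * (edges[:-1] + edges[1:])
        prof = obs.RadialProfile(edges, spec.rho(centers), "P", 1)
        with pytest.warns(UserWarning, match="plateau"):
            obs.estimate_bulk_density(prof, window=(3.0, 5.0))

    def test_empty_window_rejected(self):
        edges = np.linspace(2.0, 15.0, 11)
        prof = obs.RadialProfile(edges, np.full(10, 0.1), "P", 1)
        with pytest.raises(ValueError):
            obs.estimate_bulk_density(prof, window=(20.0, 30.0))


class TestExcessAdsorption:
    def make_profile(self, spec, r_range, bw=0.01):
        edges = np.arange(r_range[0], r_range[1] + bw / 2, bw)
        centers = 0.5 * (edges[:-1] + edges[1:])
        return obs.RadialProfile(edges, spec.rho(centers), "P", 1)

    def test_bulk_only_zero(self):
        prof = self.make_profile(constant_profile(0.05, (2, 15)), (2, 15))
        assert obs.excess_adsorption_spherical(prof, 0.05) == pytest.approx(0.0)

    def test_top_hat_closed_form(self):
        """Shell-exact quadrature must hit the closed form to 1e-10."""
        spec = shell_profile(0.05, 0.2, 4.0, 6.0, (2.0, 15.0))
        # bin edges aligned with the discontinuities -> quadrature exact
        prof = self.make_profile(spec, (2.0, 15.0), bw=0.05)
        gamma = obs.excess_adsorption_spherical(prof, 0.05)
        expected = 4 * np.pi * 0.2 * (6.0**3 - 4.0**3) / 3
        assert gamma == pytest.approx(expected, abs=1e-10)
        assert spec.gamma_excess(0.05) == pytest.approx(expected, abs=1e-10)

    def test_closed_forms_match_quadrature(self):
        for spec in (
            constant_profile(0.05, (2.0, 12.0)),
            shell_profile(0.01, 0.3, 3.0, 5.0, (2.0, 12.0)),
            decay_profile(0.02, 0.4, 0.7, 2.5, (2.5, 14.0)),
        ):
            assert spec.gamma_excess(0.01) == pytest.approx(
                spec.gamma_numeric(0.01), abs=1e-8
            )

    def test_flat_top_hat(self):
        edges = np.arange(0.0, 20.0001, 0.05)
        centers = 0.5 * (edges[:-1] + edges[1:])
        rho = 0.05 + np.where((centers > 2) & (centers < 5), 0.3, 0.0)
        prof = obs.PlanarProfile(edges, rho, "P", 1, area=25.0)
        assert obs.excess_adsorption_flat(prof, 0.05) == pytest.approx(0.3 * 3.0)

    def test_mass_balance_identities(self):
        assert obs.excess_adsorption_mass_balance(100.0, 50.0, rho_0=0.01, rho_b=0.01) == 0.0
        v = np.pi * 57.0**3 / 6
        assert obs.excess_adsorption_mass_balance(
            0.0, v, rho_0=0.01, rho_b=0.008
        ) == pytest.approx(193.9, abs=0.1)

    def test_integral_equals_mass_balance_on_fixture(self):
        """Both routes measure the same Gibbs excess when the virtual
        volume is the accessible shell [Rc, R']."""
        spec = shell_profile(0.03, 0.2, 4.0, 6.0, (2.0, 14.0))
        pts = sample_positions_from_profile(spec, 25_000, seed=7)
        prof = profile_from_points(pts, 2.0, 14.0, bw=0.05)
        # the sampled profile sets its own scale; take rho_b from its plateau
        rho_b = obs.estimate_bulk_density(prof, window=(10.0, 14.0))
        gamma_int = obs.excess_adsorption_spherical(prof, rho_b)
        v_acc = 4 * np.pi / 3 * (14.0**3 - 2.0**3)
        gamma_mb = obs.excess_adsorption_mass_balance(
            prof.total_count(), v_acc, rho_b=rho_b
        )
        assert gamma_int == pytest.approx(gamma_mb, rel=1e-10)

    def test_negative_bulk_rejected(self):
        prof = self.make_profile(constant_profile(0.05, (2, 15)), (2, 15))
        with pytest.raises(ValueError):
            obs.excess_adsorption_spherical(prof, -0.1)


class TestNormalization:
    def test_sphere_area(self):
        assert obs.normalize_adsorption(50.0, "sphere", 4.0) == pytest.approx(
            50.0 / (16 * np.pi)
        )

    def test_zero(self):
        assert obs.normalize_adsorption(0.0, "sphere", 4.0) == 0.0

    def test_flat_identity(self):
        assert obs.normalize_adsorption(0.7, "flat") == 0.7


class TestThickness:
    def test_delta_shell_limit(self):
        edges = np.arange(2.0, 15.0001, 0.01)
        rho = np.zeros(len(edges) - 1)
        k = np.argmin(np.abs(0.5 * (edges[:-1] + edges[1:]) - 7.0))
        rho[k] = 1.0
        prof = obs.RadialProfile(edges, rho, "s", 1)
        H = obs.corona_thickness_spherical(prof, 2.0)
        assert H == pytest.approx(2 * (7.0 - 2.0), abs=0.02)

    def test_uniform_shell_closed_form(self):
        Rc, t = 2.0, 5.0
        spec = shell_profile(0.0, 1.0, Rc, Rc + t, (Rc, 15.0))
        edges = np.arange(Rc, 15.0001, 0.05)
        centers = 0.5 * (edges[:-1] + edges[1:])
        prof = obs.RadialProfile(edges, spec.rho(centers), "s", 1)
        H = obs.corona_thickness_spherical(prof, Rc)
        expected = 2 * (0.75 * ((Rc + t) ** 4 - Rc**4) / ((Rc + t) ** 3 - Rc**3) - Rc)
        assert H == pytest.approx(expected, rel=1e-10)
        assert spec.thickness(Rc) == pytest.approx(expected, rel=1e-12)

    def test_hedgehog_discrete_oracle(self):
        """Rigid ligands at exact radii 2.5..11.5: H from the binned
        profile must match the discrete moment-sum oracle."""
        cfg, oracle = make_mechanical_fixtures()["hedgehog"]
        from brushmd.model import SEGMENT

        center = 0.5 * np.asarray(cfg.box.lengths)
        prof = obs.radial_profile(
            [cfg.positions], cfg.species == SEGMENT, 0.01, center,
            r_min=2.0, r_max=28.5,
        )
        H = obs.corona_thickness_spherical(prof, 2.0)
        assert H == pytest.approx(oracle["H"], abs=0.02)
        assert oracle["H"] == pytest.approx(2 * (7.0 - 2.0))  # mean radius 7

    def test_flat_all_mass_at_z0(self):
        edges = np.arange(0, 10.0001, 0.01)
        rho = np.zeros(len(edges) - 1)
        rho[np.argmin(np.abs(0.5 * (edges[:-1] + edges[1:]) - 3.0))] = 1.0
        prof = obs.PlanarProfile(edges, rho, "s", 1)
        assert obs.brush_thickness_flat(prof) == pytest.approx(6.0, abs=0.02)

    def test_flat_uniform_layer(self):
        edges = np.arange(0, 10.0001, 0.05)
        centers = 0.5 * (edges[:-1] + edges[1:])
        rho = np.where(centers < 4.0, 1.0, 0.0)
        prof = obs.PlanarProfile(edges, rho, "s", 1)
        assert obs.brush_thickness_flat(prof) == pytest.approx(4.0, rel=1e-10)

    def test_relative_thickness(self):
        assert obs.relative_thickness(10.0, 20) == 0.5
        assert obs.relative_thickness(0.0, 5) == 0.0

    def test_zero_profile_rejected(self):
        edges = np.linspace(2, 10, 11)
        prof = obs.RadialProfile(edges, np.zeros(10), "s", 1)
        with pytest.raises(ValueError):
            obs.corona_thickness_spherical(prof, 2.0)


class TestPeaks:
    def test_constructed_bumps_recovered(self):
        spec = bump_profile((2.5, 3.5, 4.5), (1.0, 0.6, 0.4), 0.08, (2.0, 8.0))
        edges = np.arange(2.0 - 0.025, 8.0, 0.05)
        centers = 0.5 * (edges[:-1] + edges[1:])
        prof = obs.RadialProfile(edges, spec.rho(centers), "s", 1)
        peaks = obs.peak_positions(prof)
        assert len(peaks) == 3
        for (pos, _), expected in zip(peaks, (2.5, 3.5, 4.5)):
            assert abs(pos - expected) <= 0.05

    def test_flat_profile_no_peaks(self):
        edges = np.linspace(2, 10, 101)
        prof = obs.RadialProfile(edges, np.full(100, 0.3), "P", 1)
        assert obs.peak_positions(prof) == []

    def test_sampled_bumps_recovered(self):
        spec = bump_profile((2.5, 3.5, 4.5), (1.0, 0.6, 0.4), 0.08, (2.0, 8.0))
        pts = sample_positions_from_profile(spec, 60_000, seed=11)
        prof = profile_from_points(pts, 2.0, 8.0, bw=0.05)
        got = [p for p, _ in obs.peak_positions(prof, 0.05 * prof.density.max())]
        for expected in (2.5, 3.5, 4.5):
            assert min(abs(g - expected) for g in got) <= 0.05


class TestAsymmetry:
    def test_hedgehog_symmetric(self):
        cfg, _ = make_mechanical_fixtures()["hedgehog"]
        from brushmd.model import SEGMENT

        center = 0.5 * np.asarray(cfg.box.lengths)
        off, kappa = obs.asymmetry_metrics(
            [cfg.positions], cfg.species == SEGMENT, center, 2.0, 10
        )
        assert off < 0.1
        assert 0.0 <= kappa <= 1.0

    def test_collapsed_pole_offset(self):
        rng = np.random.default_rng(3)
        # all chains bundled around +z: centroid clearly displaced
        pts = np.array([0.0, 0.0, 5.0]) + 0.8 * rng.normal(size=(200, 3))
        off, _ = obs.asymmetry_metrics(
            [pts], np.ones(200, bool), np.zeros(3), 2.0, 10
        )
        assert off > 0.3

    def test_single_chain_rod_limit(self):
        pts = np.column_stack([np.zeros(10), np.zeros(10), 2.5 + np.arange(10)])
        _, kappa = obs.asymmetry_metrics([pts], np.ones(10, bool), np.zeros(3), 2.0, 10)
        assert kappa > 0.95
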