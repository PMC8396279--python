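"""Force kernels, integrator, thermostat, walls, and protocol execution."""

import numpy as np
import pytest

from brushmd.build import BoxSpec, Configuration, build_flat_brush, insert_fluid
from brushmd.engine import (
    EngineState,
    InstabilityError,
    Protocol,
    apply_walls,
    compute_forces,
    n_dof,
    run_protocol,
    step_nvt,
)
from brushmd.fixtures import make_mechanical_fixtures
from conftest import two_bead


def bulk_fluid(rho, L, seed=3, table=None):
    box = BoxSpec.cubic(L)
    empty = Configuration(
        np.zeros((0, 3)), np.zeros((0, 3)), np.zeros(0, np.int8),
        np.zeros(0, bool), np.zeros((0, 2), np.int64), box, {"variant": "M1"},
    )
    return insert_fluid(empty, rho, seed=seed, table=table)


class TestForces:
    def test_bonded_dimer_at_rest_length(self, table_m1):
        cfg = two_bead(1.0, (1, 1), bonded=True)
        f, e = compute_forces(cfg, table_m1)
        assert np.allclose(f, 0.0, atol=1e-12)
        assert e == pytest.approx(0.0, abs=1e-12)

    def test_repulsive_pair_beyond_contact(self, table_m1):
        cfg = two_bead(1.2, (1, 1))
        f, _ = compute_forces(cfg, table_m1)
        assert np.allclose(f, 0.0)

    def test_cell_list_equals_brute_force_oracle(self, table_m1):
        """Cell-list forces must match the independent numpy O(N^2) path
        on the 50-bead fixture to near machine precision."""
        cfg, oracle = make_mechanical_fixtures()["random50"]
        f_ref, e_ref = oracle["forces"], oracle["energy"]
        for method in ("cell", "brute"):
            f, e = compute_forces(cfg, table_m1, method=method)
            assert e == pytest.approx(e_ref, rel=1e-10)
            assert np.abs(f - f_ref).max() < 1e-9

    def test_momentum_conservation(self, table_m1):
        cfg = bulk_fluid(0.2, 10.0, table=table_m1)
        f, _ = compute_forces(cfg, table_m1)
        assert np.abs(f.sum(axis=0)).max() < 1e-9

    def test_overlap_raises_singularity(self, table_m1):
        from brushmd.engine import SingularityError

        cfg = two_bead(1e-9, (1, 1))
        with pytest.raises(SingularityError):
            compute_forces(cfg, table_m1)


class TestIntegrator:
    def test_static_system_stays_put(self, table_m1):
        cfg = two_bead(1.2, (1, 1))
        st = EngineState(cfg, table_m1)
        step_nvt(st, nsteps=10, thermostat=False)
        assert np.allclose(cfg.positions[:, 0], [10.0, 11.2])

    def test_dimer_oscillation_frequency(self, table_m1):
        """Free bonded dimer: reduced mass m/2, stiffness 2*kss, so
        omega = 2 sqrt(kss/m) ~ 63.25 / tau; measured by zero crossings."""
        cfg = two_bead(1.05, (1, 1), bonded=True)
        st = EngineState(cfg, table_m1, dt=0.0005)
        ext, times = [], []
        for k in range(4000):
            step_nvt(st, nsteps=1, dt=0.0005, thermostat=False)
            ext.append(cfg.positions[1, 0] - cfg.positions[0, 0] - 1.05 / 2 - 0.525)
        x = np.asarray(ext) - np.mean(ext)
        crossings = np.where(np.diff(np.sign(x)) != 0)[0]
        # refine by linear interpolation, average over many half periods
        t = crossings + x[crossings] / (x[crossings] - x[crossings + 1])
        half_period = np.diff(t).mean() * 0.0005
        omega = np.pi / half_period
        assert omega == pytest.approx(2 * np.sqrt(1000.0), rel=0.01)

    def test_nve_energy_conservation(self, table_m1):
        cfg = bulk_fluid(0.2, 8.0, table=table_m1)
        st = EngineState(cfg, table_m1)
        step_nvt(st, nsteps=2000, T_star=1.0)  # settle from random insertion
        st2 = EngineState(st.config.copy(), table_m1)
        e0 = st2.e_total
        step_nvt(st2, nsteps=10_000, thermostat=False)
        assert abs(st2.e_total - e0) / abs(e0) < 1e-4

    def test_nvt_temperature_and_fluctuations(self, table_m1):
        cfg = bulk_fluid(0.15, 10.0, seed=5, table=table_m1)
        st = EngineState(cfg, table_m1)
        step_nvt(st, nsteps=2000, T_star=1.0)
        temps = []
        for _ in range(300):
            step_nvt(st, nsteps=50, T_star=1.0)
            temps.append(st.temperature)
        temps = np.asarray(temps[50:])
        assert temps.mean() == pytest.approx(1.0, abs=0.02)
        # canonical relative variance 2/ndof, within a loose 3x band
        rel_var = temps.var() / temps.mean() ** 2
        expect = 2.0 / n_dof(cfg)
        assert expect / 3 < rel_var < 3 * expect

    def test_frozen_beads_never_move(self, table_m1):
        from brushmd.build import build_hairy_particle

        cfg = build_hairy_particle(4.0, 5, 5, "M1", box=30.0, seed=1)
        cfg = insert_fluid(cfg, 0.02, seed=2, table=table_m1)
        frozen = ~cfg.mobile
        ref = cfg.positions[frozen].copy()
        st = EngineState(cfg, table_m1)
        step_nvt(st, nsteps=500, T_star=1.0)
        assert np.array_equal(st.config.positions[frozen], ref)

    def test_instability_error_on_huge_dt(self, table_m1):
        cfg = bulk_fluid(0.2, 8.0, table=table_m1)
        st = EngineState(cfg, table_m1)
        with pytest.raises(InstabilityError):
            step_nvt(st, nsteps=100, dt=0.5, thermostat=False)

    def test_determinism(self, table_m1):
        runs = []
        for _ in range(2):
            cfg = bulk_fluid(0.1, 8.0, seed=13, table=table_m1)
            st = EngineState(cfg, table_m1)
            step_nvt(st, nsteps=200, T_star=1.0)
            runs.append(st.config.positions.copy())
        assert np.array_equal(runs[0], runs[1])


class TestWalls:
    def test_specular_reflection_conserves_speed(self):
        cfg = build_flat_brush(0, 5, Lz=20.0, seed=0)
        pos = np.array([[1.0, 1.0, 0.2], [1.0, 1.0, 19.9]])
        vel = np.array([[0.3, 0.1, -1.0], [0.0, 0.2, 0.7]])
        cfg = Configuration(
            pos.copy(), vel.copy(), np.array([2, 2], np.int8), np.ones(2, bool),
            np.zeros((0, 2), np.int64), cfg.box, {},
        )
        apply_walls(cfg)
        assert cfg.positions[0, 2] == pytest.approx(0.8)  # mirrored at z=0.5
        assert cfg.velocities[0, 2] == pytest.approx(1.0)
        assert cfg.positions[1, 2] == pytest.approx(19.1)
        assert cfg.velocities[1, 2] == pytest.approx(-0.7)
        assert np.linalg.norm(cfg.velocities[0]) == pytest.approx(np.linalg.norm(vel[0]))

    def test_frozen_anchor_exempt(self):
        cfg = build_flat_brush(5, 5, rho_gr=0.2, Lz=20.0, seed=1)
        anchors_before = cfg.positions[~cfg.mobile].copy()
        apply_walls(cfg)
        assert np.array_equal(cfg.positions[~cfg.mobile], anchors_before)

    def test_slab_nve_conservation(self, table_m1):
        """Specular walls conserve energy to the bulk tolerance for pair
        interactions; bond-free fluid isolates the wall handling itself."""
        cfg = build_flat_brush(0, 5, Lz=20.0, seed=2, table=table_m1)
        cfg = insert_fluid(cfg, 0.05, seed=3, table=table_m1)
        st = EngineState(cfg, table_m1)
        step_nvt(st, nsteps=2000, T_star=1.0)
        st2 = EngineState(st.config.copy(), table_m1)
        e0 = st2.e_total
        step_nvt(st2, nsteps=10_000, thermostat=False)
        assert abs(st2.e_total - e0) / abs(e0) < 1e-4

    def test_slab_brush_energy_noise_bounded(self, table_m1):
        """Wall bounces of stiffly bonded segments inject O(dt) energy
        noise per event; it must stay small (production runs thermostat)."""
        cfg = build_flat_brush(5, 5, rho_gr=0.2, Lz=20.0, seed=2, table=table_m1)
        st = EngineState(cfg, table_m1)
        step_nvt(st, nsteps=2000, T_star=1.0)
        st2 = EngineState(st.config.copy(), table_m1)
        e0 = st2.e_total
        step_nvt(st2, nsteps=10_000, thermostat=False)
        assert abs(st2.e_total - e0) / abs(e0) < 0.02

    def test_fluid_stays_inside_walls(self, table_m1):
        cfg = build_flat_brush(0, 5, Lz=15.0, seed=4)
        cfg = insert_fluid(cfg, 0.1, seed=5, table=table_m1)
        st = EngineState(cfg, table_m1)
        step_nvt(st, nsteps=3000, T_star=1.0)
        z = st.config.positions[:, 2]
        assert z.min() >= 0.5 - 1e-9
        assert z.max() <= 15.0 - 0.5 + 1e-9


class TestProtocol:
    def test_zero_production_gives_empty_frames(self, table_m1):
        cfg = bulk_fluid(0.05, 8.0, table=table_m1)
        proto = Protocol(equilibration_steps=500, production_steps=0,
                         sample_interval=100)
        traj = run_protocol(cfg, table_m1, proto)
        assert traj.frames == []

    def test_sample_interval_must_divide(self):
        with pytest.raises(ValueError):
            Protocol(production_steps=1000, sample_interval=300)

    def test_trajectory_determinism(self, table_m1):
        trajs = []
        for _ in range(2):
            cfg = bulk_fluid(0.05, 8.0, seed=21, table=table_m1)
            proto = Protocol(equilibration_steps=500, production_steps=500,
                             sample_interval=100)
            trajs.append(run_protocol(cfg, table_m1, proto))
        assert np.array_equal(trajs[0].frames[-1], trajs[1].frames[-1])
        assert trajs[0].scalars.equals(trajs[1].scalars)

    def test_anneal_phases_recorded(self, table_m1):
        cfg = bulk_fluid(0.05, 8.0, table=table_m1)
        proto = Protocol(anneal_schedule=[(1.5, 300), (1.0, 300)],
                         equilibration_steps=300, production_steps=300,
                         sample_interval=100)
        traj = run_protocol(cfg, table_m1, proto)
        assert set(traj.scalars.phase) == {"anneal", "equilibration", "production"}

    def test_energy_stationarity_on_settled_fluid(self, table_m1):
        """A pre-equilibrated fluid passes the sliding-window drift check."""
        cfg = bulk_fluid(0.1, 8.0, seed=2, table=table_m1)
        st = EngineState(cfg, table_m1)
        step_nvt(st, nsteps=5000, T_star=1.0)
        proto = Protocol(equilibration_steps=5000, production_steps=1000,
                         sample_interval=200)
        traj = run_protocol(st.config, table_m1, proto)
        assert traj.equilibrated
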