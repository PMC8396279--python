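"""NVT/NVE molecular dynamics of a :class:`~brushmd.build.Configuration`.

Velocity-Verlet integration with a single Nose-Hoover thermostat
(Martyna-Tuckerman-Klein splitting), frozen-bead support (core, anchors,
rigid ligands), specular hard walls for slab geometry, and the
anneal -> equilibrate -> produce protocol.  The heavy loops live in
:mod:`brushmd._kernels` (numba); a pure-numpy O(N^2) reference force
implementation is kept as an independent cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .build import BoxSpec, Configuration
from .model import InteractionTable

__all__ = [
    "EngineState",
    "Protocol",
    "Trajectory",
    "InstabilityError",
    "SingularityError",
    "compute_forces",
    "step_nvt",
    "apply_walls",
    "run_protocol",
    "kinetic_temperature",
]

DEFAULT_DT = 0.002  # ~50 steps per stiff-bond period (k=1000 -> T ~ 0.1 tau)
DEFAULT_TAU_DAMP = 0.1


class InstabilityError(RuntimeError):
    """Per-step displacement exceeded 0.5 sigma; reduce dt."""


class SingularityError(RuntimeError):
    """Two beads (nearly) overlap; forces are singular."""


def _pair_tables(table: InteractionTable):
    """Precompute (c12, c6, rc2, rc, Fc, Uc) 3x3 coefficient matrices."""
    sig = table.sigma_ij_matrix
    eps = table.eps_ij_matrix
    rc = table.rcut_ij_matrix
    c12 = 4.0 * eps * sig**12
    c6 = 4.0 * eps * sig**6
    rc6 = rc**6
    rc12 = rc6 * rc6
    uc = c12 / rc12 - c6 / rc6
    fc = (12.0 * c12 / rc12 - 6.0 * c6 / rc6) / rc
    return (
        np.ascontiguousarray(c12),
        np.ascontiguousarray(c6),
        np.ascontiguousarray(rc**2),
        np.ascontiguousarray(rc),
        np.ascontiguousarray(fc),
        np.ascontiguousarray(uc),
    )


def _exclusions(n: int, bonds: np.ndarray) -> np.ndarray:
    """Per-bead bonded partners (chain beads have at most two), -1 padded."""
    excl = np.full((n, 2), -1, dtype=np.int64)
    slot = np.zeros(n, dtype=np.int64)
    for i, j in bonds:
        for a, b in ((i, j), (j, i)):
            if slot[a] >= 2:
                raise ValueError("more than two bonds on one bead")
            excl[a, slot[a]] = b
            slot[a] += 1
    return excl


def _cell_grid(box: BoxSpec, rcut: float):
    """Cell counts for the linked-cell kernel, or None if not applicable."""
    if box.geometry != "cubic":
        return None
    nc = np.array([int(np.floor(L / rcut)) for L in box.lengths], dtype=np.int64)
    if np.any(nc < 4):
        return None
    return nc


def compute_forces(
    config: Configuration,
    table: InteractionTable,
    method: str = "auto",
) -> tuple[np.ndarray, float]:
    """Total force on every bead and the potential energy.

    ``method``: "auto" (cell list when the box admits one), "cell",
    "brute" (numba O(N^2)), or "reference" (independent vectorized numpy
    O(N^2) oracle).  Forces on immobile beads are reported but never
    applied by the integrator.
    """
    if method == "reference":
        return _reference_forces(config, table)
    c12, c6, rc2, rcm, fcm, ucm = _pair_tables(table)
    L = np.asarray(config.box.lengths)
    per = np.asarray(config.box.periodic)
    excl = _exclusions(config.n_beads, config.bonds)
    forces = np.zeros_like(config.positions)
    bonds = np.ascontiguousarray(config.bonds, dtype=np.int64)
    pos = np.ascontiguousarray(config.positions)
    species = np.ascontiguousarray(config.species)
    grid = _cell_grid(config.box, table.rcut_mobile_max) if method in ("auto", "cell") else None
    if method == "cell" and grid is None:
        raise ValueError("cell list not applicable to this box")
    if grid is not None:
        head = np.empty(int(np.prod(grid)), dtype=np.int64)
        nxt = np.empty(config.n_beads, dtype=np.int64)
        epot = _kernels.forces_cell(
            pos, species, L, c12, c6, rc2, rcm, fcm, ucm, excl,
            bonds, table.kss, table.sigma_species[1], forces, grid, head, nxt,
        )
    else:
        epot = _kernels.forces_n2(
            pos, species, L, per, c12, c6, rc2, rcm, fcm, ucm, excl,
            bonds, table.kss, table.sigma_species[1], forces,
        )
    if np.isnan(epot):
        raise SingularityError("overlapping beads (r < 1e-6 sigma)")
    return forces, float(epot)


def _reference_forces(config: Configuration, table: InteractionTable):
    """Vectorized numpy shifted-force LJ + bonds; the O(N^2) oracle."""
    pos = config.positions
    n = len(pos)
    L = np.asarray(config.box.lengths)
    per = np.asarray(config.box.periodic)
    d = pos[:, None, :] - pos[None, :, :]
    for a in range(3):
        if per[a]:
            d[..., a] -= L[a] * np.round(d[..., a] / L[a])
    r = np.sqrt((d**2).sum(axis=-1))
    np.fill_diagonal(r, np.inf)
    for i, j in config.bonds:  # bonded pairs excluded from the pair sum
        r[i, j] = r[j, i] = np.inf
    sp = config.species
    sig = table.sigma_ij_matrix[sp[:, None], sp[None, :]]
    eps = table.eps_ij_matrix[sp[:, None], sp[None, :]]
    rc = table.rcut_ij_matrix[sp[:, None], sp[None, :]]
    inside = r < rc
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        sr6 = np.where(inside, (sig / r) ** 6, 0.0)
        u_lj = 4 * eps * (sr6**2 - sr6)
        f_lj = np.where(inside, 24 * eps * (2 * sr6**2 - sr6) / r, 0.0)
        src6 = (sig / rc) ** 6
        u_c = 4 * eps * (src6**2 - src6)
        f_c = 24 * eps * (2 * src6**2 - src6) / rc
        u = np.where(inside, u_lj - u_c + (r - rc) * f_c, 0.0)
        fmag = np.where(inside, f_lj - f_c, 0.0)
        fhat = np.where(inside[..., None], d / np.where(r[..., None] > 0, r[..., None], 1.0), 0.0)
    forces = (fmag[..., None] * fhat).sum(axis=1)
    epot = 0.5 * u.sum()
    # bonds
    k = table.kss
    r0 = table.sigma_species[1]
    for i, j in config.bonds:
        dij = pos[i] - pos[j]
        for a in range(3):
            if per[a]:
                dij[a] -= L[a] * np.round(dij[a] / L[a])
        rb = np.linalg.norm(dij)
        epot += k * (rb - r0) ** 2
        fb = -2.0 * k * (rb - r0) / rb * dij
        forces[i] += fb
        forces[j] -= fb
    return forces, float(epot)


def n_dof(config: Configuration) -> int:
    """Thermostatted degrees of freedom: mobile beads only.

    Three COM degrees of freedom are subtracted only when every bead is
    mobile in a fully periodic box (momentum then being conserved).
    """
    n_mob = int(config.mobile.sum())
    dof = 3 * n_mob
    if config.mobile.all() and config.box.geometry == "cubic":
        dof -= 3
    return max(dof, 1)


def kinetic_temperature(config: Configuration) -> float:
    v2 = (config.velocities[config.mobile] ** 2).sum()
    return float(v2 / n_dof(config))


@dataclass
class EngineState:
    """Mutable integration state bound to one configuration."""

    config: Configuration
    table: InteractionTable
    dt: float = DEFAULT_DT
    forces: np.ndarray | None = None
    epot: float = 0.0
    ekin: float = 0.0
    vxi: np.ndarray = field(default_factory=lambda: np.zeros(1))
    step: int = 0

    def __post_init__(self) -> None:
        if self.forces is None:
            self.forces, self.epot = compute_forces(self.config, self.table)
        self.ekin = 0.5 * float((self.config.velocities[self.config.mobile] ** 2).sum())

    @property
    def e_total(self) -> float:
        return self.epot + self.ekin

    @property
    def temperature(self) -> float:
        return 2.0 * self.ekin / n_dof(self.config)


class _Runner:
    """Holds the contiguous arrays handed to the numba integrator."""

    def __init__(self, state: EngineState):
        cfg = state.config
        t = state.table
        self.state = state
        self.pos = np.ascontiguousarray(cfg.positions)
        self.vel = np.ascontiguousarray(cfg.velocities)
        self.vel[~cfg.mobile] = 0.0
        self.forces = np.zeros_like(self.pos)
        self.species = np.ascontiguousarray(cfg.species)
        self.mobile = np.ascontiguousarray(cfg.mobile)
        self.L = np.asarray(cfg.box.lengths, dtype=np.float64)
        self.per = np.asarray(cfg.box.periodic)
        (self.c12, self.c6, self.rc2, self.rcm, self.fcm, self.ucm) = _pair_tables(t)
        self.excl = _exclusions(cfg.n_beads, cfg.bonds)
        self.bonds = np.ascontiguousarray(cfg.bonds, dtype=np.int64)
        grid = _cell_grid(cfg.box, t.rcut_mobile_max)
        self.use_cell = grid is not None and cfg.n_beads >= 200
        self.ncell = grid if grid is not None else np.ones(3, dtype=np.int64)
        self.head = np.empty(int(np.prod(self.ncell)), dtype=np.int64)
        self.nxt = np.empty(cfg.n_beads, dtype=np.int64)
        self.ndof = n_dof(cfg)
        self.slab = cfg.box.geometry == "slab"
        self.wall_off = 0.5 * np.asarray(t.sigma_species, dtype=np.float64)

    def run(self, nsteps: int, dt: float, thermostat: bool, T_target: float,
            tau_damp: float) -> None:
        st = self.state
        Q = self.ndof * max(T_target, 1e-12) * tau_damp**2
        epot, ekin, status = _kernels.integrate(
            self.pos, self.vel, self.forces, self.species, self.mobile,
            self.L, self.per,
            self.c12, self.c6, self.rc2, self.rcm, self.fcm, self.ucm,
            self.excl, self.bonds, st.table.kss, st.table.sigma_species[1],
            dt, nsteps, self.use_cell, self.ncell, self.head, self.nxt,
            thermostat, T_target, self.ndof, Q, st.vxi,
            self.slab, self.wall_off,
        )
        if status == 1:
            raise SingularityError("overlapping beads during integration")
        if status == 2:
            raise InstabilityError(
                f"displacement > 0.5 sigma in one step (dt={dt}); reduce dt"
            )
        st.epot, st.ekin = float(epot), float(ekin)
        st.step += nsteps
        st.config.positions = self.pos
        st.config.velocities = self.vel
        st.forces = self.forces


def step_nvt(
    state: EngineState,
    nsteps: int = 1,
    dt: float | None = None,
    T_star: float = 1.0,
    tau_damp: float = DEFAULT_TAU_DAMP,
    thermostat: bool = True,
) -> EngineState:
    """Advance ``nsteps`` velocity-Verlet steps (NVT, or NVE with
    ``thermostat=False``).  Mutates and returns ``state``."""
    runner = getattr(state, "_runner", None)
    if runner is None or runner.state is not state:
        runner = _Runner(state)
        state._runner = runner
    runner.run(nsteps, dt if dt is not None else state.dt, thermostat, T_star, tau_damp)
    return state


def apply_walls(config: Configuration, sigma_species=(4.0, 1.0, 1.0)) -> Configuration:
    """Specular reflection of mobile beads off the slab hard walls.

    Mirrors the in-kernel wall handling for direct testing: beads closer
    to a wall than half their diameter are reflected (position mirrored,
    normal velocity reversed, speed conserved).  Frozen beads (including
    the grafted anchor segments at z = 0.5 sigma) are never touched.
    """
    if config.box.geometry != "slab":
        raise ValueError("walls apply to slab geometry only")
    Lz = config.box.lengths[2]
    off = 0.5 * np.asarray(sigma_species, dtype=float)[config.species]
    z = config.positions[:, 2]
    vz = config.velocities[:, 2]
    mob = config.mobile
    low = mob & (z < off)
    z[low] = 2 * off[low] - z[low]
    vz[low] *= -1.0
    high = mob & (z > Lz - off)
    z[high] = 2 * (Lz - off[high]) - z[high]
    vz[high] *= -1.0
    return config


@dataclass
class Protocol:
    """Anneal / equilibrate / produce schedule.

    ``anneal_schedule`` is a list of ``(T_star, steps)`` phases (used for
    alternating heating and cooling of the system); the equilibration
    and production phases run at ``T_star``.
    """

    anneal_schedule: list[tuple[float, int]] = field(default_factory=list)
    equilibration_steps: int = 100_000
    production_steps: int = 100_000
    sample_interval: int = 500
    scalar_interval: int = 100
    dt: float = DEFAULT_DT
    T_star: float = 1.0
    tau_damp: float = DEFAULT_TAU_DAMP
    thermostat: bool = True

    def __post_init__(self) -> None:
        if self.production_steps and self.production_steps % self.sample_interval:
            raise ValueError("sample_interval must divide production_steps")


@dataclass
class Trajectory:
    """Sampled production frames plus scalar time series."""

    frames: list[np.ndarray]
    species: np.ndarray
    box: BoxSpec
    scalars: pd.DataFrame
    config: Configuration
    equilibrated: bool = True

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def production_temperature(self) -> float:
        prod = self.scalars[self.scalars.phase == "production"]
        return float(prod["T"].mean())


def _stationary(series: np.ndarray) -> bool:
    """Loose sliding-window drift test on an energy series."""
    n = len(series)
    if n < 8:
        return True
    half = series[n // 2:]
    a, b = np.array_split(half, 2)
    se = np.sqrt(a.var() / max(len(a), 1) + b.var() / max(len(b), 1))
    if se == 0:
        return np.isclose(a.mean(), b.mean())
    return abs(a.mean() - b.mean()) < 5.0 * se


def run_protocol(
    config: Configuration,
    table: InteractionTable,
    protocol: Protocol,
) -> Trajectory:
    """Execute anneal -> equilibration -> production on a copy of ``config``.

    Production frames (bead positions) are collected every
    ``sample_interval`` steps; potential/kinetic energy and kinetic
    temperature every ``scalar_interval`` steps in every phase.
    A non-stationary equilibration energy series sets
    ``equilibrated=False`` and emits a warning, never fails silently.
    """
    cfg = config.copy()
    state = EngineState(cfg, table, dt=protocol.dt)
    rows: list[tuple] = []
    frames: list[np.ndarray] = []

    def advance(total: int, T: float, phase: str, collect_frames: bool) -> list[float]:
        etot: list[float] = []
        done = 0
        while done < total:
            chunk = min(protocol.scalar_interval, total - done)
            step_nvt(
                state, nsteps=chunk, dt=protocol.dt, T_star=T,
                tau_damp=protocol.tau_damp, thermostat=protocol.thermostat,
            )
            done += chunk
            T_kin = 2.0 * state.ekin / n_dof(cfg)
            rows.append((state.step, phase, state.epot, state.ekin, T_kin))
            etot.append(state.e_total)
            if collect_frames and done % protocol.sample_interval == 0:
                frames.append(state.config.positions.copy())
        return etot

    for T_phase, steps in protocol.anneal_schedule:
        advance(steps, T_phase, "anneal", False)
    e_eq = advance(protocol.equilibration_steps, protocol.T_star, "equilibration", False)
    equilibrated = _stationary(np.asarray(e_eq))
    if not equilibrated:
        warnings.warn(
            "equilibration energy not stationary within budget; "
            "results flagged as non-equilibrated",
            stacklevel=2,
        )
    advance(protocol.production_steps, protocol.T_star, "production", True)

    scalars = pd.DataFrame(rows, columns=["step", "phase", "E_pot", "E_kin", "T"])
    return Trajectory(
        frames=frames,
        species=cfg.species.copy(),
        box=cfg.box,
        scalars=scalars,
        config=cfg,
        equilibrated=equilibrated,
    )
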