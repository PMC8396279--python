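"""Initial-configuration builders: hairy nanoparticles, flat brushes, fluid.

A spherical hairy particle is one immobile core bead at the box center
with ``f`` chains of ``M`` segments each.  The first segment (anchor) of
every chain is frozen at distance ``sigma_cs = (sigma_c + sigma_s)/2``
from the core center, at a random point of the sphere; the remaining
beads are grown outward (flexible chains) or placed collinearly with the
anchor direction (rigid "hedgehog" ligands, which are entirely frozen).

A planar brush is the same construction on the wall at z=0 of a slab box
(periodic in x and y, hard walls at z=0 and z=Lz).

Fluid particles are inserted uniformly at random, rejecting any position
closer than ``0.9 sigma_ij`` to an existing bead, and receive
Maxwell-Boltzmann velocities at the requested temperature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    CORE,
    PARTICLE,
    SEGMENT,
    ConfigurationError,
    InteractionTable,
)

__all__ = [
    "BoxSpec",
    "Configuration",
    "GraftingLayout",
    "PackingError",
    "place_anchors",
    "grow_chain",
    "build_hairy_particle",
    "build_flat_brush",
    "insert_fluid",
    "grafting_density",
]

MIN_DIST_FACTOR = 0.9  # build-time overlap criterion, in units of sigma_ij


class PackingError(RuntimeError):
    """Raised when random placement cannot satisfy the overlap criterion."""


class BoxTooSmallError(ConfigurationError):
    """Raised when the box cannot hold the particle with stretched ligands."""


@dataclass(frozen=True)
class BoxSpec:
    """Simulation cell: fully periodic cube or x/y-periodic slab.

    For ``geometry="slab"`` hard walls sit at z=0 (grafted) and z=Lz (bare).
    """

    geometry: str  # "cubic" | "slab"
    lengths: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.geometry not in ("cubic", "slab"):
            raise ConfigurationError(f"unknown geometry {self.geometry!r}")
        if any(L <= 0 for L in self.lengths):
            raise ConfigurationError("box lengths must be positive")

    @classmethod
    def cubic(cls, L: float) -> "BoxSpec":
        return cls("cubic", (float(L), float(L), float(L)))

    @classmethod
    def slab(cls, Lx: float, Ly: float, Lz: float) -> "BoxSpec":
        return cls("slab", (float(Lx), float(Ly), float(Lz)))

    @property
    def periodic(self) -> tuple[bool, bool, bool]:
        return (True, True, self.geometry == "cubic")

    @property
    def volume(self) -> float:
        return float(np.prod(self.lengths))


@dataclass(frozen=True)
class GraftingLayout:
    """Anchor directions (unit vectors) and the grafting density f/A."""

    anchor_directions: np.ndarray  # (f, 3) unit vectors
    grafting_density: float


@dataclass
class Configuration:
    """One system snapshot: coordinates, velocities, topology and box."""

    positions: np.ndarray  # (N, 3)
    velocities: np.ndarray  # (N, 3)
    species: np.ndarray  # (N,) int8: CORE / SEGMENT / PARTICLE
    mobile: np.ndarray  # (N,) bool
    bonds: np.ndarray  # (B, 2) int64
    box: BoxSpec
    spec: dict = field(default_factory=dict)

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    def count(self, species_id: int) -> int:
        return int(np.sum(self.species == species_id))

    def copy(self) -> "Configuration":
        return Configuration(
            self.positions.copy(),
            self.velocities.copy(),
            self.species.copy(),
            self.mobile.copy(),
            self.bonds.copy(),
            self.box,
            dict(self.spec),
        )


def grafting_density(f: int, geometry: str, sigma_c: float | None = None,
                     area: float | None = None) -> float:
    """Chains per unit substrate area, rho_gr = f / A.

    ``A = pi * sigma_c**2`` for the sphere, the given ``area`` (Lx*Ly) for
    the flat wall.
    """
    if geometry in ("sphere", "spherical"):
        if sigma_c is None or sigma_c <= 0:
            raise ConfigurationError("sphere grafting density needs sigma_c > 0")
        area = np.pi * sigma_c**2
    elif geometry in ("flat", "planar", "slab"):
        if area is None or area <= 0:
            raise ConfigurationError("flat grafting density needs area > 0")
    else:
        raise ConfigurationError(f"unknown geometry {geometry!r}")
    return f / area


def _random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def place_anchors(
    f: int,
    sigma_c: float,
    min_separation: float = 0.9,
    seed: int = 0,
    sigma_s: float = 1.0,
    max_retries: int = 20000,
) -> GraftingLayout:
    """Sample ``f`` grafting directions uniformly on the sphere.

    Anchor beads sit at radius ``sigma_cs = (sigma_c + sigma_s)/2``; the
    pairwise distance between anchors at that radius must be at least
    ``min_separation``.
    """
    if f < 1:
        raise ConfigurationError("need at least one chain (f >= 1)")
    rng = np.random.default_rng(seed)
    r_anchor = 0.5 * (sigma_c + sigma_s)
    dirs: list[np.ndarray] = []
    tries = 0
    while len(dirs) < f:
        tries += 1
        if tries > max_retries:
            raise PackingError(
                f"could not place {f} anchors with min separation "
                f"{min_separation} on sphere of radius {r_anchor}"
            )
        cand = _random_unit_vectors(rng, 1)[0]
        ok = True
        for d in dirs:
            if np.linalg.norm((cand - d) * r_anchor) < min_separation:
                ok = False
                break
        if ok:
            dirs.append(cand)
    rho_gr = grafting_density(f, "sphere", sigma_c=sigma_c)
    return GraftingLayout(np.asarray(dirs), rho_gr)


def _grow_flexible(
    start: np.ndarray,
    outward: np.ndarray,
    M: int,
    existing: np.ndarray,
    core_center: np.ndarray | None,
    core_exclusion: float,
    rng: np.random.Generator,
    bond_length: float = 1.0,
    min_dist: float = MIN_DIST_FACTOR,
    z_floor: float | None = None,
    retries: int = 200,
    box: "BoxSpec | None" = None,
) -> np.ndarray:
    """Outward-biased self-avoiding random growth with fixed bond length.

    Distances to already-placed beads honor the periodic directions of
    ``box`` when given (needed for dense flat brushes in small cells).
    """

    def too_close(cand: np.ndarray, pool: np.ndarray) -> bool:
        if len(pool) == 0:
            return False
        d = pool - cand
        if box is not None:
            d = _min_image(d, box)
        return bool(np.min(np.linalg.norm(d, axis=1)) < min_dist)

    beads = [start]
    direction = outward.copy()
    for _ in range(M - 1):
        placed = False
        for _ in range(retries):
            step = direction + 0.8 * _random_unit_vectors(rng, 1)[0]
            step /= np.linalg.norm(step)
            cand = beads[-1] + bond_length * step
            if core_center is not None and np.linalg.norm(cand - core_center) < core_exclusion:
                continue
            if z_floor is not None and cand[2] < z_floor:
                continue
            if too_close(cand, np.asarray(beads[:-1])) or too_close(cand, existing):
                continue
            beads.append(cand)
            direction = step
            placed = True
            break
        if not placed:
            raise PackingError("chain growth dead-end")
    return np.asarray(beads)


def grow_chain(
    anchor_direction: np.ndarray,
    M: int,
    mode: str = "flexible",
    seed: int = 0,
    sigma_c: float = 4.0,
    sigma_s: float = 1.0,
    core_center: np.ndarray | None = None,
    existing: np.ndarray | None = None,
) -> np.ndarray:
    """Bead positions of one chain grown from an anchor direction.

    ``rigid`` chains are collinear with the anchor direction at radii
    ``sigma_cs + k`` (k = 0..M-1) from the core center; ``flexible``
    chains are grown as an outward-biased self-avoiding walk with bond
    length ``sigma_s``, never entering the core.
    """
    if M < 1:
        raise ConfigurationError("chain length M must be >= 1")
    if mode not in ("flexible", "rigid"):
        raise ConfigurationError(f"unknown chain mode {mode!r}")
    center = np.zeros(3) if core_center is None else np.asarray(core_center, float)
    d = np.asarray(anchor_direction, float)
    d = d / np.linalg.norm(d)
    sigma_cs = 0.5 * (sigma_c + sigma_s)
    if mode == "rigid":
        radii = sigma_cs + sigma_s * np.arange(M)
        return center + radii[:, None] * d[None, :]
    rng = np.random.default_rng(seed)
    start = center + sigma_cs * d
    pool = np.zeros((0, 3)) if existing is None else np.asarray(existing, float)
    for attempt in range(50):  # dead-end -> rebuild with a fresh sub-seed
        try:
            return _grow_flexible(
                start, d, M, pool, center, sigma_cs, rng, bond_length=sigma_s
            )
        except PackingError:
            rng = np.random.default_rng(np.random.default_rng((seed, attempt)).integers(2**31))
    raise PackingError("chain growth failed after rebuild budget")


def _chain_bonds(offset: int, M: int) -> np.ndarray:
    if M < 2:
        return np.zeros((0, 2), dtype=np.int64)
    idx = offset + np.arange(M - 1)
    return np.stack([idx, idx + 1], axis=1).astype(np.int64)


def build_hairy_particle(
    sigma_c: float,
    f: int,
    M: int,
    variant: str = "M1",
    box: BoxSpec | float = 57.0,
    seed: int = 0,
    table: InteractionTable | None = None,
    min_separation: float = 0.9,
) -> Configuration:
    """Spherical hairy particle (no fluid yet) at the center of a cubic box."""
    if isinstance(box, (int, float)):
        box = BoxSpec.cubic(box)
    if table is None:
        from .model import make_interaction_table

        table = make_interaction_table(variant, sigma_c=sigma_c)
    sigma_s = table.sigma_species[1]
    L = min(box.lengths)
    reach = 0.5 * sigma_c + M * sigma_s + table.rcut_mobile_max
    if reach >= 0.5 * L:
        raise BoxTooSmallError(
            f"box too small: sigma_c/2 + M*sigma + rcut = {reach:.2f} "
            f">= L/2 = {0.5 * L:.2f}"
        )
    center = 0.5 * np.asarray(box.lengths)
    layout = place_anchors(f, sigma_c, min_separation, seed, sigma_s=sigma_s)
    rigid = table.rigid_ligands or variant in ("M2", "M2a")

    positions = [center[None, :]]
    species = [np.array([CORE], dtype=np.int8)]
    mobile = [np.array([False])]
    bonds = []
    grown = np.zeros((0, 3))
    rng_seeds = np.random.default_rng(seed).integers(2**31, size=f)
    for k in range(f):
        chain = grow_chain(
            layout.anchor_directions[k],
            M,
            mode="rigid" if rigid else "flexible",
            seed=int(rng_seeds[k]),
            sigma_c=sigma_c,
            sigma_s=sigma_s,
            core_center=center,
            existing=grown,
        )
        grown = np.vstack([grown, chain])
        offset = 1 + k * M
        positions.append(chain)
        species.append(np.full(M, SEGMENT, dtype=np.int8))
        mob = np.ones(M, dtype=bool)
        mob[0] = False  # anchor frozen
        if rigid:
            mob[:] = False
        mobile.append(mob)
        bonds.append(_chain_bonds(offset, M))

    pos = np.vstack(positions)
    cfg = Configuration(
        positions=pos,
        velocities=np.zeros_like(pos),
        species=np.concatenate(species),
        mobile=np.concatenate(mobile),
        bonds=np.vstack(bonds) if bonds else np.zeros((0, 2), dtype=np.int64),
        box=box,
        spec={
            "geometry": "sphere",
            "sigma_c": sigma_c,
            "f": f,
            "M": M,
            "variant": variant,
            "rho_gr": layout.grafting_density,
            "seed": seed,
        },
    )
    _init_velocities(cfg, T_star=1.0, seed=seed)
    return cfg


def build_flat_brush(
    f: int,
    M: int,
    rho_gr: float = 0.398,
    Lz: float = 40.0,
    seed: int = 0,
    variant: str = "M1",
    table: InteractionTable | None = None,
    min_separation: float = 0.9,
    _force_rods: bool = False,
) -> Configuration:
    """Planar brush on the z=0 wall of a slab box; Lx = Ly = sqrt(f/rho_gr).

    ``f=0`` yields a valid bare-wall system.
    """
    if table is None:
        from .model import make_interaction_table

        table = make_interaction_table(variant)
    sigma_s = table.sigma_species[1]
    if f > 0:
        area = f / rho_gr
        Lx = Ly = float(np.sqrt(area))
    else:
        Lx = Ly = 10.0
    box = BoxSpec.slab(Lx, Ly, Lz)
    if M * sigma_s + table.rcut_mobile_max >= Lz:
        raise BoxTooSmallError("slab too short for stretched ligands")
    rigid = variant in ("M2", "M2a")

    rng = np.random.default_rng(seed)
    positions, species, mobile, bonds = [], [], [], []
    grown = np.zeros((0, 3))
    z0 = 0.5 * sigma_s
    force_rods = _force_rods
    for k in range(f):
        for _ in range(5000):
            xy = rng.uniform(0, Lx, size=2)
            anchor = np.array([xy[0], xy[1], z0])
            if len(grown) == 0:
                break
            d = grown[grown[:, 2] < z0 + 1.0] - anchor
            d[:, 0] -= Lx * np.round(d[:, 0] / Lx)
            d[:, 1] -= Ly * np.round(d[:, 1] / Ly)
            if len(d) == 0 or np.min(np.linalg.norm(d, axis=1)) >= min_separation:
                break
        else:
            raise PackingError("could not place flat-brush anchors")
        if rigid or force_rods:
            chain = anchor + np.array([0.0, 0.0, 1.0])[None, :] * (
                sigma_s * np.arange(M)[:, None]
            )
        else:
            chain = None
            for attempt in range(20):  # dead-end -> regrow with a sub-seed
                sub = np.random.default_rng((seed, k, attempt))
                try:
                    chain = _grow_flexible(
                        anchor,
                        np.array([0.0, 0.0, 1.0]),
                        M,
                        grown,
                        None,
                        0.0,
                        sub,
                        bond_length=sigma_s,
                        z_floor=0.5 * sigma_s,
                        box=box,
                    )
                    break
                except PackingError:
                    continue
            if chain is None:
                # dense brush: restart with every chain a vertical rod,
                # which is overlap-free at any anchor spacing (all beads
                # of a level share one z-plane, so pair distances equal
                # the anchor spacing); equilibration erases the bias
                return build_flat_brush(
                    f, M, rho_gr=rho_gr, Lz=Lz, seed=seed, variant=variant,
                    table=table, min_separation=min_separation,
                    _force_rods=True,
                )
        grown = np.vstack([grown, chain])
        offset = k * M
        positions.append(chain)
        species.append(np.full(M, SEGMENT, dtype=np.int8))
        mob = np.ones(M, dtype=bool)
        mob[0] = False
        if rigid:
            mob[:] = False
        mobile.append(mob)
        bonds.append(_chain_bonds(offset, M))

    if positions:
        pos = np.vstack(positions)
        spc = np.concatenate(species)
        mob = np.concatenate(mobile)
        bnd = np.vstack(bonds)
    else:
        pos = np.zeros((0, 3))
        spc = np.zeros(0, dtype=np.int8)
        mob = np.zeros(0, dtype=bool)
        bnd = np.zeros((0, 2), dtype=np.int64)
    cfg = Configuration(
        positions=pos,
        velocities=np.zeros_like(pos),
        species=spc,
        mobile=mob,
        bonds=bnd,
        box=box,
        spec={
            "geometry": "flat",
            "f": f,
            "M": M,
            "variant": variant,
            "rho_gr": rho_gr if f else 0.0,
            "seed": seed,
        },
    )
    _init_velocities(cfg, T_star=1.0, seed=seed)
    return cfg


def _min_image(d: np.ndarray, box: BoxSpec) -> np.ndarray:
    L = np.asarray(box.lengths)
    per = np.asarray(box.periodic)
    for a in range(3):
        if per[a]:
            d[..., a] -= L[a] * np.round(d[..., a] / L[a])
    return d


def insert_fluid(
    config: Configuration,
    rho_0: float,
    seed: int = 0,
    T_star: float = 1.0,
    table: InteractionTable | None = None,
    max_batch_failures: int = 500,
) -> Configuration:
    """Insert ``round(rho_0 * V)`` fluid particles without overlaps.

    Candidates are drawn uniformly in the box (respecting a half-diameter
    wall offset in slab geometry) and rejected if any existing bead lies
    closer than ``0.9 sigma_ij``.
    """
    if rho_0 < 0:
        raise ConfigurationError("rho_0 must be >= 0")
    n_target = int(round(rho_0 * config.box.volume))
    cfg = config.copy()
    if n_target == 0:
        return cfg
    if table is None:
        from .model import make_interaction_table

        table = make_interaction_table(
            cfg.spec.get("variant", "M1"), sigma_c=cfg.spec.get("sigma_c", 4.0)
        )
    sig = table.sigma_ij_matrix
    rng = np.random.default_rng(seed)
    L = np.asarray(cfg.box.lengths)
    slab = cfg.box.geometry == "slab"
    sigma_P = table.sigma_species[2]

    accepted: list[np.ndarray] = []
    existing = cfg.positions
    ex_species = cfg.species
    failures = 0
    # max needed exclusion radius for a fluid candidate
    rmax = MIN_DIST_FACTOR * max(sig[PARTICLE, s] for s in (CORE, SEGMENT, PARTICLE))
    while len(accepted) < n_target:
        cand = rng.uniform(0.0, 1.0, size=3) * L
        if slab:
            cand[2] = 0.5 * sigma_P + rng.uniform() * (L[2] - sigma_P)
        ok = True
        if len(existing):
            d = _min_image(existing - cand, cfg.box)
            r = np.linalg.norm(d, axis=1)
            near = r < rmax
            if np.any(near):
                lim = MIN_DIST_FACTOR * sig[PARTICLE, ex_species[near]]
                if np.any(r[near] < lim):
                    ok = False
        if ok and accepted:
            d = _min_image(np.asarray(accepted) - cand, cfg.box)
            if np.min(np.linalg.norm(d, axis=1)) < MIN_DIST_FACTOR * sig[PARTICLE, PARTICLE]:
                ok = False
        if ok:
            accepted.append(cand)
            failures = 0
        else:
            failures += 1
            if failures > max_batch_failures * (1 + n_target):
                raise PackingError(
                    f"fluid insertion stalled at {len(accepted)}/{n_target} "
                    "particles; consider lattice pre-placement or lower rho_0"
                )
    new_pos = np.asarray(accepted)
    vel = rng.normal(scale=np.sqrt(T_star), size=new_pos.shape)
    cfg.positions = np.vstack([cfg.positions, new_pos])
    cfg.velocities = np.vstack([cfg.velocities, vel])
    cfg.species = np.concatenate([cfg.species, np.full(n_target, PARTICLE, dtype=np.int8)])
    cfg.mobile = np.concatenate([cfg.mobile, np.ones(n_target, dtype=bool)])
    cfg.spec["rho_0"] = rho_0
    cfg.spec["N_P"] = n_target
    # remove net momentum of mobile beads (harmless with frozen beads,
    # required for clean NVE bookkeeping in fully mobile systems)
    mob = cfg.mobile
    if mob.any():
        cfg.velocities[mob] -= cfg.velocities[mob].mean(axis=0)
    return cfg


def _init_velocities(cfg: Configuration, T_star: float, seed: int) -> None:
    rng = np.random.default_rng((seed, 7919))
    v = rng.normal(scale=np.sqrt(T_star), size=cfg.positions.shape)
    v[~cfg.mobile] = 0.0
    cfg.velocities = v
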