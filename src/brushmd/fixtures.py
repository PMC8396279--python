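"""Synthetic configurations and analytic profiles for estimator validation.

Every observable in :mod:`brushmd.observables` can be exercised without
running dynamics: positions are sampled from prescribed analytic density
profiles by inverse-CDF sampling on the shell-weighted measure (exact
tails, no rejection), and small mechanical fixtures carry precomputed
energy/force oracles.  These fixtures validate estimators, not dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import quad

from .build import BoxSpec, Configuration
from .model import PARTICLE, SEGMENT, make_interaction_table

__all__ = [
    "AnalyticProfile",
    "constant_profile",
    "shell_profile",
    "bump_profile",
    "decay_profile",
    "sample_positions_from_profile",
    "make_mechanical_fixtures",
]


@dataclass
class AnalyticProfile:
    """A prescribed radial (or z) number-density profile.

    ``gamma_excess(rho_b)`` and ``thickness(Rc)`` hold closed forms where
    they exist (they match numerical quadrature to 1e-10 by construction).
    """

    form: str
    rho: Callable[[np.ndarray], np.ndarray]
    r_range: tuple[float, float]
    params: dict = field(default_factory=dict)
    gamma_excess: Callable[[float], float] | None = None
    thickness: Callable[[float], float] | None = None

    def gamma_numeric(self, rho_b: float, geometry: str = "spherical") -> float:
        """Quadrature reference for the excess (independent of binning)."""
        a, b = self.r_range
        if geometry == "spherical":
            val, _ = quad(lambda r: 4 * np.pi * r**2 * (self.rho(r) - rho_b), a, b,
                          limit=400)
        else:
            val, _ = quad(lambda z: self.rho(z) - rho_b, a, b, limit=400)
        return val

    def thickness_numeric(self, Rc: float, geometry: str = "spherical") -> float:
        a, b = self.r_range
        if geometry == "spherical":
            num, _ = quad(lambda r: r**3 * self.rho(r), a, b, limit=400)
            den, _ = quad(lambda r: r**2 * self.rho(r), a, b, limit=400)
            return 2.0 * (num / den - Rc)
        num, _ = quad(lambda z: z * self.rho(z), a, b, limit=400)
        den, _ = quad(lambda z: self.rho(z), a, b, limit=400)
        return 2.0 * num / den


def constant_profile(c: float, r_range: tuple[float, float]) -> AnalyticProfile:
    """Uniform density ``c`` on ``r_range``."""
    a, b = r_range

    def gamma(rho_b: float) -> float:
        return 4 * np.pi / 3 * (c - rho_b) * (b**3 - a**3)

    def thick(Rc: float) -> float:
        return 2.0 * (0.75 * (b**4 - a**4) / (b**3 - a**3) - Rc)

    return AnalyticProfile(
        "constant", lambda r: np.full_like(np.asarray(r, float), c), r_range,
        {"c": c}, gamma, thick,
    )


def shell_profile(
    base: float, excess: float, r1: float, r2: float, r_range: tuple[float, float]
) -> AnalyticProfile:
    """Top-hat: ``base`` everywhere, ``base + excess`` on [r1, r2]."""

    def rho(r):
        r = np.asarray(r, float)
        return base + np.where((r >= r1) & (r < r2), excess, 0.0)

    def gamma(rho_b: float) -> float:
        a, b = r_range
        return (
            4 * np.pi / 3 * ((base - rho_b) * (b**3 - a**3) + excess * (r2**3 - r1**3))
        )

    thick = None
    if base == 0.0:

        def thick(Rc: float) -> float:  # uniform shell closed-form moment ratio
            return 2.0 * (0.75 * (r2**4 - r1**4) / (r2**3 - r1**3) - Rc)

    return AnalyticProfile(
        "top-hat", rho, r_range, {"base": base, "excess": excess, "r1": r1, "r2": r2},
        gamma, thick,
    )


def bump_profile(
    centers: tuple[float, ...],
    heights: tuple[float, ...],
    width: float,
    r_range: tuple[float, float],
    base: float = 0.0,
) -> AnalyticProfile:
    """Sum of narrow Gaussian layers (for peak-detection tests)."""

    def rho(r):
        r = np.asarray(r, float)
        out = np.full_like(r, base)
        for c, h in zip(centers, heights):
            out = out + h * np.exp(-0.5 * ((r - c) / width) ** 2)
        return out

    return AnalyticProfile(
        "gaussian-bumps", rho, r_range,
        {"centers": centers, "heights": heights, "width": width, "base": base},
    )


def decay_profile(
    plateau: float, amplitude: float, decay_length: float, r0: float,
    r_range: tuple[float, float]
) -> AnalyticProfile:
    """Exponential decay onto a plateau: c + a exp(-(r-r0)/lambda)."""

    def rho(r):
        r = np.asarray(r, float)
        return plateau + amplitude * np.exp(-np.clip(r - r0, 0, None) / decay_length)

    lam = decay_length

    def gamma(rho_b: float) -> float:
        a, b = r_range

        def antider(R: float) -> float:  # -int r^2 exp(-(r-r0)/lam) from primitive
            return -lam * np.exp(-(R - r0) / lam) * (R**2 + 2 * lam * R + 2 * lam**2)

        tail = antider(b) - antider(max(a, r0))
        head = (max(a, r0) ** 3 - a**3) / 3.0  # clipped region: amplitude constant
        return 4 * np.pi * (
            (plateau - rho_b) * (b**3 - a**3) / 3.0 + amplitude * (tail + head)
        )

    return AnalyticProfile(
        "decay-to-plateau", rho, r_range,
        {"plateau": plateau, "amplitude": amplitude, "lambda": lam, "r0": r0}, gamma,
    )


def sample_positions_from_profile(
    profile: AnalyticProfile,
    N: int,
    geometry: str = "spherical",
    seed: int = 0,
    center: np.ndarray | None = None,
    grid_points: int = 20001,
) -> np.ndarray:
    """Draw ``N`` points with radial (or z) density proportional to the profile.

    Inverse-CDF sampling on the shell-weighted measure ``r^2 rho(r) dr``
    (or ``rho(z) dz``); angles are uniform on the sphere.  Deterministic
    for a given seed.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    a, b = profile.r_range
    grid = np.linspace(a, b, grid_points)
    w = profile.rho(grid)
    if np.any(w < -1e-12):
        raise ValueError("profile density must be non-negative")
    if geometry == "spherical":
        w = w * grid**2
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (w[1:] + w[:-1]) * np.diff(grid))])
    if cdf[-1] <= 0:
        raise ValueError("profile is not normalizable (zero total weight)")
    cdf /= cdf[-1]
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=N)
    r = np.interp(u, cdf, grid)
    if geometry == "spherical":
        v = rng.normal(size=(N, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pts = r[:, None] * v
        if center is not None:
            pts = pts + center
        return pts
    xy = rng.uniform(0.0, 1.0, size=(N, 2))
    return np.column_stack([xy[:, 0], xy[:, 1], r])


def _two_bead_config(r: float, species, L: float = 20.0) -> Configuration:
    box = BoxSpec.cubic(L)
    pos = np.array([[0.5 * L, 0.5 * L, 0.5 * L], [0.5 * L + r, 0.5 * L, 0.5 * L]])
    return Configuration(
        positions=pos,
        velocities=np.zeros_like(pos),
        species=np.array(species, dtype=np.int8),
        mobile=np.ones(2, dtype=bool),
        bonds=np.zeros((0, 2), dtype=np.int64),
        box=box,
        spec={"geometry": "bulk"},
    )


def make_mechanical_fixtures(seed: int = 1234) -> dict:
    """Named tiny configurations with independently computed oracles.

    Returns ``{name: (Configuration, oracle_dict)}``.  The 50-bead cell's
    oracle energy/forces come from the vectorized numpy O(N^2) reference
    path, independent of the numba kernels it is used to check.
    """
    from .build import build_hairy_particle
    from .engine import compute_forces

    table = make_interaction_table("M1", sigma_c=4.0)
    fixtures: dict = {}

    dimer = _two_bead_config(1.0, (SEGMENT, SEGMENT))
    dimer.bonds = np.array([[0, 1]], dtype=np.int64)
    fixtures["bonded_dimer"] = (dimer, {"force": 0.0, "energy": 0.0})

    rep = _two_bead_config(1.2, (SEGMENT, SEGMENT))  # beyond repulsive cutoff
    fixtures["repulsive_pair"] = (rep, {"force": 0.0, "energy": 0.0})

    att = _two_bead_config(2.5, (SEGMENT, PARTICLE))  # exactly at attractive cutoff
    fixtures["attractive_pair_at_cutoff"] = (att, {"force": 0.0, "energy": 0.0})

    rng = np.random.default_rng(seed)
    L = 10.0
    # overlap-free random cell: rejection at 0.85 sigma keeps forces finite
    pts: list[np.ndarray] = []
    while len(pts) < 50:
        cand = rng.uniform(0, L, size=3)
        if pts:
            d = np.asarray(pts) - cand
            d -= L * np.round(d / L)
            if np.min(np.linalg.norm(d, axis=1)) < 0.85:
                continue
        pts.append(cand)
    pos = np.asarray(pts)
    species = np.array([SEGMENT] * 25 + [PARTICLE] * 25, dtype=np.int8)
    bonds = np.array([[2 * k, 2 * k + 1] for k in range(5)], dtype=np.int64)
    cell = Configuration(
        positions=pos,
        velocities=np.zeros_like(pos),
        species=species,
        mobile=np.ones(50, dtype=bool),
        bonds=bonds,
        box=BoxSpec.cubic(L),
        spec={"geometry": "bulk"},
    )
    f_ref, e_ref = compute_forces(cell, table, method="reference")
    fixtures["random50"] = (cell, {"energy": e_ref, "forces": f_ref})

    hedgehog = build_hairy_particle(4.0, 20, 10, variant="M2", box=57.0, seed=seed)
    radii = np.linalg.norm(
        hedgehog.positions[hedgehog.species == SEGMENT]
        - 0.5 * np.asarray(hedgehog.box.lengths),
        axis=1,
    )
    H_exact = 2.0 * (radii.mean() - 2.0)  # delta shells: <r^3>/<r^2> = mean radius
    fixtures["hedgehog"] = (hedgehog, {"H": H_exact, "radii": radii})
    return fixtures
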