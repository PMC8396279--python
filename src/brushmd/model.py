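"""Reduced units, interaction tables, and the pair/bond potentials.

The model is a bead-spring description of a polymer-grafted (hairy)
nanoparticle immersed in a fluid of small spherical particles.  Three
species exist:

* ``c`` -- the spherical core (one bead, diameter ``sigma_c``),
* ``s`` -- chain (ligand) segments, diameter ``sigma`` (the length unit),
* ``P`` -- fluid particles, diameter ``sigma_P``.

All non-bonded interactions are shifted-force Lennard-Jones: the force is
made continuous at the cutoff by subtracting the cutoff force, and a
constant is added so the energy also vanishes continuously at the cutoff.
Attractive pairs are cut at ``2.5 sigma_ij``; "repulsive" pairs are cut at
``sigma_ij``, which leaves only the soft repulsive shoulder of the
potential.  Chain connectivity is a stiff harmonic spring
``u(r) = k_ss (r - sigma_s)^2``.

Everything is expressed in reduced units: lengths in the segment diameter
``sigma``, energies in the segment-segment well depth ``epsilon``, masses
in the segment mass ``m``, time in ``tau = sigma * sqrt(m / epsilon)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = [
    "CORE",
    "SEGMENT",
    "PARTICLE",
    "SPECIES_TAGS",
    "MODEL_VARIANTS",
    "Units",
    "SpeciesPair",
    "InteractionTable",
    "make_interaction_table",
    "pair_energy_force",
    "bond_energy_force",
]

# Integer species ids used throughout the package (positions/species arrays).
CORE = 0
SEGMENT = 1
PARTICLE = 2
SPECIES_TAGS = ("c", "s", "P")
_TAG_TO_ID = {"c": CORE, "s": SEGMENT, "P": PARTICLE}

#: The four model variants: flexible (M1) vs rigid hedgehog (M2) ligands,
#: with the plain interaction matrix or the "a" matrix in which
#: segment-segment and particle-particle attractions are switched on.
MODEL_VARIANTS = ("M1", "M1a", "M2", "M2a")


class ConfigurationError(ValueError):
    """Raised for invalid model / build specifications."""


@dataclass(frozen=True)
class Units:
    """Reduced-unit system of the bead-spring model.

    ``tau`` is derived as ``sigma * sqrt(mass / epsilon)``.
    """

    sigma: float = 1.0
    epsilon: float = 1.0
    mass: float = 1.0
    T_star: float = 1.0

    def __post_init__(self) -> None:
        for name in ("sigma", "epsilon", "mass", "T_star"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"unit {name!r} must be positive")

    @property
    def tau(self) -> float:
        return self.sigma * np.sqrt(self.mass / self.epsilon)


@dataclass(frozen=True)
class SpeciesPair:
    """LJ parameters for one unordered species pair.

    ``attractive`` pairs keep the full well (cutoff ``2.5 sigma_ij``);
    repulsive pairs are truncated at contact (cutoff ``sigma_ij``).
    """

    i: str
    j: str
    sigma_ij: float
    eps_ij: float
    rcut_ij: float
    attractive: bool

    def __post_init__(self) -> None:
        if self.i not in _TAG_TO_ID or self.j not in _TAG_TO_ID:
            raise ConfigurationError(f"unknown species tags ({self.i}, {self.j})")
        if self.sigma_ij <= 0 or self.eps_ij <= 0 or self.rcut_ij <= 0:
            raise ConfigurationError("pair parameters must be positive")


# pairs that are always repulsive regardless of variant
_ALWAYS_REPULSIVE = {("c", "c"), ("c", "s"), ("c", "P")}


@dataclass
class InteractionTable:
    """All six unordered species-pair potentials for one model variant.

    Lookup is symmetric: ``table.pair("s", "P") == table.pair("P", "s")``.
    Matrix views (``sigma_ij_matrix`` etc., indexed by the integer species
    ids) are what the force kernels consume.
    """

    model_variant: str
    eps_Ps: float
    kss: float
    sigma_species: tuple[float, float, float]  # (sigma_c, sigma_s, sigma_P)
    entries: dict = field(default_factory=dict)

    def pair(self, i: str, j: str) -> SpeciesPair:
        key = tuple(sorted((i, j)))
        return self.entries[key]

    def __iter__(self) -> Iterator[SpeciesPair]:
        return iter(self.entries.values())

    @property
    def rigid_ligands(self) -> bool:
        return self.model_variant in ("M2", "M2a")

    def _matrix(self, attr: str) -> np.ndarray:
        m = np.zeros((3, 3))
        for p in self:
            a, b = _TAG_TO_ID[p.i], _TAG_TO_ID[p.j]
            m[a, b] = m[b, a] = getattr(p, attr)
        return m

    @property
    def sigma_ij_matrix(self) -> np.ndarray:
        return self._matrix("sigma_ij")

    @property
    def eps_ij_matrix(self) -> np.ndarray:
        return self._matrix("eps_ij")

    @property
    def rcut_ij_matrix(self) -> np.ndarray:
        return self._matrix("rcut_ij")

    @property
    def rcut_max(self) -> float:
        return float(self.rcut_ij_matrix.max())

    @property
    def rcut_mobile_max(self) -> float:
        """Largest cutoff among pairs that can occur in a one-core system
        (the core-core pair never arises: there is a single frozen core)."""
        m = self.rcut_ij_matrix.copy()
        m[CORE, CORE] = 0.0
        return float(m.max())

    # -- serialization (flat key/value mapping, config-file friendly) ----
    def to_dict(self) -> dict:
        return {
            "model_variant": self.model_variant,
            "eps_Ps": self.eps_Ps,
            "kss": self.kss,
            "sigma_c": self.sigma_species[0],
            "sigma_s": self.sigma_species[1],
            "sigma_P": self.sigma_species[2],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InteractionTable":
        return make_interaction_table(
            d["model_variant"],
            eps_Ps=d["eps_Ps"],
            sigma_c=d["sigma_c"],
            sigma_P=d.get("sigma_P", 1.0),
            sigma_s=d.get("sigma_s", 1.0),
            kss=d.get("kss", 1000.0),
        )


def make_interaction_table(
    variant: str,
    eps_Ps: float = 1.5,
    sigma_c: float = 4.0,
    sigma_P: float = 1.0,
    sigma_s: float = 1.0,
    kss: float = 1000.0,
    repulsive_cut_factor: float = 1.0,
) -> InteractionTable:
    """Build the interaction table for one model variant.

    Parameters
    ----------
    variant:
        ``"M1"`` / ``"M2"`` (flexible / rigid ligands, only the
        particle-segment pair attractive) or ``"M1a"`` / ``"M2a"``
        (additionally segment-segment and particle-particle attractive).
    eps_Ps:
        Particle-segment well depth in units of epsilon (1.5 or 3.0 in the
        replication runs).
    repulsive_cut_factor:
        Cutoff of repulsive pairs in units of ``sigma_ij``.  The default 1.0
        truncates at contact; a WCA-style ``2**(1/6)`` can be requested.

    All other well depths are ``epsilon``; cross diameters follow the
    Lorentz rule ``sigma_ij = (sigma_i + sigma_j) / 2``.
    """
    if variant not in MODEL_VARIANTS:
        raise ConfigurationError(
            f"unknown model variant {variant!r}; expected one of {MODEL_VARIANTS}"
        )
    if sigma_c <= 0 or sigma_P <= 0 or sigma_s <= 0:
        raise ConfigurationError("species diameters must be positive")
    if eps_Ps <= 0 or kss <= 0:
        raise ConfigurationError("eps_Ps and kss must be positive")

    like_pairs_attractive = variant.endswith("a")
    diam = {"c": sigma_c, "s": sigma_s, "P": sigma_P}
    table = InteractionTable(
        model_variant=variant,
        eps_Ps=eps_Ps,
        kss=kss,
        sigma_species=(sigma_c, sigma_s, sigma_P),
    )
    for i, j in (("c", "c"), ("c", "s"), ("P", "c"), ("s", "s"), ("P", "s"), ("P", "P")):
        key = tuple(sorted((i, j)))
        if key in {tuple(sorted(p)) for p in _ALWAYS_REPULSIVE}:
            attractive = False
        elif key == ("P", "s"):
            attractive = True
        else:  # s-s and P-P
            attractive = like_pairs_attractive
        sigma_ij = 0.5 * (diam[i] + diam[j])
        eps_ij = eps_Ps if key == ("P", "s") else 1.0
        rcut = 2.5 * sigma_ij if attractive else repulsive_cut_factor * sigma_ij
        table.entries[key] = SpeciesPair(key[0], key[1], sigma_ij, eps_ij, rcut, attractive)
    return table


def _lj(r: float, sigma: float, eps: float) -> tuple[float, float]:
    """Plain LJ energy and force magnitude (-du/dr)."""
    sr6 = (sigma / r) ** 6
    u = 4.0 * eps * (sr6 * sr6 - sr6)
    f = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r
    return u, f


def pair_energy_force(r: float, pair: SpeciesPair) -> tuple[float, float]:
    """Shifted-force LJ energy and force magnitude at separation ``r``.

    Returns ``(u, F)`` with ``F = -du/dr`` (positive F pushes the beads
    apart).  Both ``u`` and ``F`` go to zero continuously at the cutoff;
    beyond the cutoff both are exactly zero.
    """
    if r <= 0:
        raise ValueError("pair separation must be positive (r=0 is singular)")
    rc = pair.rcut_ij
    if r >= rc:
        return 0.0, 0.0
    u_r, f_r = _lj(r, pair.sigma_ij, pair.eps_ij)
    u_c, f_c = _lj(rc, pair.sigma_ij, pair.eps_ij)
    # force shift: F(r) = F_LJ(r) - F_LJ(rc); energy integrates to
    # u_LJ(r) - u_LJ(rc) + (r - rc) * F_LJ(rc), zero at rc.
    return u_r - u_c + (r - rc) * f_c, f_r - f_c


def bond_energy_force(r: float, kss: float = 1000.0, sigma_s: float = 1.0) -> tuple[float, float]:
    """Harmonic tether ``u = kss (r - sigma_s)^2``; returns ``(u, -du/dr)``."""
    dr = r - sigma_s
    return kss * dr * dr, -2.0 * kss * dr
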