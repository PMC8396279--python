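"""Trajectory and topology writers: extended XYZ, LAMMPS data/dump, CSV."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .build import BoxSpec, Configuration
from .model import SPECIES_TAGS

__all__ = [
    "write_xyz",
    "read_xyz",
    "write_lammps_data",
    "write_lammps_dump",
    "write_scalars_csv",
]


def _lattice(box: BoxSpec) -> str:
    Lx, Ly, Lz = box.lengths
    return f'Lattice="{Lx} 0 0 0 {Ly} 0 0 0 {Lz}"'


def write_xyz(path, config: Configuration, comment: str = "") -> None:
    """Extended XYZ snapshot (species tag + coordinates)."""
    lines = [str(config.n_beads), f"{_lattice(config.box)} Properties=species:S:1:pos:R:3 {comment}".strip()]
    for tag, (x, y, z) in zip(
        (SPECIES_TAGS[s] for s in config.species), config.positions
    ):
        lines.append(f"{tag} {x:.8f} {y:.8f} {z:.8f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz(path) -> tuple[np.ndarray, np.ndarray]:
    """Read one extended-XYZ frame; returns (species tags, positions)."""
    lines = Path(path).read_text().splitlines()
    n = int(lines[0])
    tags, pos = [], []
    for ln in lines[2 : 2 + n]:
        parts = ln.split()
        tags.append(parts[0])
        pos.append([float(v) for v in parts[1:4]])
    return np.asarray(tags), np.asarray(pos)


def write_lammps_data(path, config: Configuration, masses=(1.0, 1.0, 1.0)) -> None:
    """LAMMPS data file (atom style *bond*) for external cross-validation."""
    n = config.n_beads
    nb = len(config.bonds)
    Lx, Ly, Lz = config.box.lengths
    out = [
        "# brushmd configuration",
        "",
        f"{n} atoms",
        f"{nb} bonds",
        "",
        "3 atom types",
        "1 bond types",
        "",
        f"0.0 {Lx} xlo xhi",
        f"0.0 {Ly} ylo yhi",
        f"0.0 {Lz} zlo zhi",
        "",
        "Masses",
        "",
    ]
    out += [f"{t + 1} {masses[t]}" for t in range(3)]
    out += ["", "Atoms # bond", ""]
    for i, (s, (x, y, z)) in enumerate(zip(config.species, config.positions), 1):
        out.append(f"{i} 1 {int(s) + 1} {x:.8f} {y:.8f} {z:.8f}")
    if nb:
        out += ["", "Bonds", ""]
        for b, (i, j) in enumerate(config.bonds, 1):
            out.append(f"{b} 1 {i + 1} {j + 1}")
    Path(path).write_text("\n".join(out) + "\n")


def write_lammps_dump(path, frames, species: np.ndarray, box: BoxSpec,
                      sample_interval: int = 1) -> None:
    """Minimal LAMMPS dump ('id type x y z'), one block per frame."""
    Lx, Ly, Lz = box.lengths
    out: list[str] = []
    for k, fr in enumerate(frames):
        out += [
            "ITEM: TIMESTEP",
            str(k * sample_interval),
            "ITEM: NUMBER OF ATOMS",
            str(len(fr)),
            "ITEM: BOX BOUNDS pp pp pp",
            f"0.0 {Lx}",
            f"0.0 {Ly}",
            f"0.0 {Lz}",
            "ITEM: ATOMS id type x y z",
        ]
        for i, (s, (x, y, z)) in enumerate(zip(species, fr), 1):
            out.append(f"{i} {int(s) + 1} {x:.6f} {y:.6f} {z:.6f}")
    Path(path).write_text("\n".join(out) + "\n")


def write_scalars_csv(path, scalars: pd.DataFrame) -> None:
    scalars.to_csv(path, index=False)
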