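"""Molecular configuration containers and multi-frame XYZ I/O.

Coordinates are Cartesian angstroms throughout; energies are kJ/mol.
Per-atom energies have no place in plain XYZ, so they travel in a sidecar
CSV (``frame_id, atom_index, atom_label, energy_kj_mol``) while the total
energy rides on the XYZ comment line as an ``energy=<float>`` token.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MolecularConfiguration",
    "Trajectory",
    "XYZParseError",
    "read_xyz",
    "write_xyz",
    "read_atomic_energies",
    "write_atomic_energies",
]

_ENERGY_TOKEN = re.compile(r"energy=([-+0-9.eEdD]+)")


class XYZParseError(ValueError):
    """Raised when an XYZ file violates the count/comment/atom-line layout."""


def _normalize_symbol(symbol: str) -> str:
    return symbol[:1].upper() + symbol[1:].lower()


@dataclass
class MolecularConfiguration:
    """One molecular frame: element symbols plus Cartesian coordinates.

    Parameters
    ----------
    elements
        Element symbols, one per atom.
    coordinates
        ``(natoms, 3)`` array of positions in angstroms.
    atomic_energies
        Optional per-atom energies (kJ/mol); when both energy fields are
        set they must be consistent: ``sum(atomic_energies) == total_energy``
        to 1e-9 relative.
    total_energy
        Optional total energy (kJ/mol).
    frame_id
        Index of the frame within its source trajectory.
    """

    elements: list[str]
    coordinates: np.ndarray
    atomic_energies: np.ndarray | None = None
    total_energy: float | None = None
    frame_id: int = 0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (len(self.elements), 3):
            raise ValueError(
                f"coordinates shape {self.coordinates.shape} does not match "
                f"{len(self.elements)} elements"
            )
        if self.atomic_energies is not None:
            self.atomic_energies = np.asarray(self.atomic_energies, dtype=float)
            if self.atomic_energies.shape != (len(self.elements),):
                raise ValueError("one atomic energy per atom required")
            if self.total_energy is not None:
                total = float(np.sum(self.atomic_energies))
                scale = max(abs(self.total_energy), 1.0)
                if abs(total - self.total_energy) > 1e-9 * scale:
                    raise ValueError(
                        "atomic energies do not sum to the total energy: "
                        f"{total} vs {self.total_energy}"
                    )

    @property
    def natoms(self) -> int:
        return len(self.elements)


@dataclass
class Trajectory:
    """Ordered frames sharing a single element list and atom ordering."""

    configurations: list[MolecularConfiguration] = field(default_factory=list)
    source_tag: str = ""

    def __post_init__(self) -> None:
        if self.configurations:
            ref = self.configurations[0].elements
            for cfg in self.configurations[1:]:
                if cfg.elements != ref:
                    raise ValueError("all frames must share one element list")

    def __len__(self) -> int:
        return len(self.configurations)

    def __iter__(self) -> Iterator[MolecularConfiguration]:
        return iter(self.configurations)

    def __getitem__(self, i: int) -> MolecularConfiguration:
        return self.configurations[i]

    @property
    def elements(self) -> list[str]:
        if not self.configurations:
            raise ValueError("empty trajectory has no element list")
        return self.configurations[0].elements

    def coordinates(self) -> np.ndarray:
        """Stack all frame coordinates into ``(nframes, natoms, 3)``."""
        return np.stack([c.coordinates for c in self.configurations])


def read_xyz(path: str | Path, source_tag: str = "") -> Trajectory:
    """Read a multi-frame XYZ file.

    The comment line of each frame is scanned for an ``energy=<float>``
    token; when present it is stored as the frame's total energy.

    Raises
    ------
    XYZParseError
        On an empty file, a malformed atom-count line (the error names the
        line number), or frames with inconsistent atom lists.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not any(line.strip() for line in lines):
        raise XYZParseError(f"{path}: empty XYZ file")

    frames: list[MolecularConfiguration] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():  # tolerate trailing blank lines
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError:
            raise XYZParseError(
                f"{path}: line {i + 1}: expected an atom count, got {lines[i]!r}"
            ) from None
        if i + 1 + natoms >= len(lines) + 1 or natoms <= 0:
            raise XYZParseError(
                f"{path}: line {i + 1}: frame of {natoms} atoms is truncated"
            )
        comment = lines[i + 1]
        total_energy = None
        m = _ENERGY_TOKEN.search(comment)
        if m:
            total_energy = float(m.group(1).replace("D", "E").replace("d", "e"))
        elements: list[str] = []
        coords = np.empty((natoms, 3))
        for j in range(natoms):
            parts = lines[i + 2 + j].split()
            if len(parts) < 4:
                raise XYZParseError(
                    f"{path}: line {i + 3 + j}: expected 'symbol x y z'"
                )
            elements.append(_normalize_symbol(parts[0]))
            coords[j] = [float(p) for p in parts[1:4]]
        frames.append(
            MolecularConfiguration(
                elements=elements,
                coordinates=coords,
                total_energy=total_energy,
                frame_id=len(frames),
            )
        )
        i += 2 + natoms

    try:
        return Trajectory(configurations=frames, source_tag=source_tag)
    except ValueError as exc:
        raise XYZParseError(f"{path}: {exc}") from None


def write_xyz(trajectory: Trajectory, path: str | Path) -> None:
    """Write a trajectory as multi-frame XYZ (re-readable by :func:`read_xyz`)."""
    if len(trajectory) == 0:
        raise ValueError("refusing to write an empty trajectory")
    path = Path(path)
    out: list[str] = []
    for cfg in trajectory:
        out.append(str(cfg.natoms))
        comment = f"frame {cfg.frame_id}"
        if cfg.total_energy is not None:
            comment += f" energy={cfg.total_energy:.12g}"
        out.append(comment)
        for sym, (x, y, z) in zip(cfg.elements, cfg.coordinates):
            out.append(f"{sym:<3s} {x:18.10f} {y:18.10f} {z:18.10f}")
    path.write_text("\n".join(out) + "\n")


def write_atomic_energies(trajectory: Trajectory, path: str | Path) -> None:
    """Write per-atom energies to the sidecar CSV format."""
    rows = []
    for cfg in trajectory:
        if cfg.atomic_energies is None:
            continue
        for a, (label, e) in enumerate(zip(cfg.elements, cfg.atomic_energies)):
            rows.append((cfg.frame_id, a, label, e))
    pd.DataFrame(
        rows, columns=["frame_id", "atom_index", "atom_label", "energy_kj_mol"]
    ).to_csv(path, index=False)


def read_atomic_energies(trajectory: Trajectory, path: str | Path) -> Trajectory:
    """Attach per-atom energies from a sidecar CSV onto matching frames."""
    df = pd.read_csv(path)
    by_frame = {fid: g for fid, g in df.groupby("frame_id")}
    for cfg in trajectory:
        g = by_frame.get(cfg.frame_id)
        if g is None:
            continue
        e = np.full(cfg.natoms, np.nan)
        e[g["atom_index"].to_numpy()] = g["energy_kj_mol"].to_numpy()
        cfg.atomic_energies = e
        if cfg.total_energy is None:
            cfg.total_energy = float(np.sum(e))
    return trajectory
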