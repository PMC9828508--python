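"""Synthetic configuration sampler and per-atom energy oracle.

This module plays the role that an ab initio MD engine, a wavefunction
code and a topological energy-partitioning program play in a production
pipeline: it (a) generates distorted molecular configurations at a
nominal temperature with a minimum-distance rejection rule, and (b)
returns per-atom energies that sum *exactly* to a smooth total molecular
energy, so every downstream stage (featurization, regression, active
learning, evaluation) can be exercised end to end at desk scale.

The potential is a transparent toy: harmonic bonds and angles plus
Lennard-Jones nonbonded pairs.  Each pair term is split half/half between
its two atoms and each angle term a third each, which makes the atomic
partition conserve the total by construction — the property the atomic
regression targets rely on.

"Temperature" is a monotone distortion control (spread grows like
sqrt(T)), not a thermodynamic Kelvin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import yaml

from .alf import bonding_graph, compute_alf, featurize_trajectory, ALFDefinition
from .molio import MolecularConfiguration, Trajectory

__all__ = [
    "SamplerConfig",
    "ToyPES",
    "ToyPESOracle",
    "PESConfigurationError",
    "sample_configurations",
    "atomic_energies",
    "label_trajectory",
    "default_systems",
    "suggest_cutoff",
]

logger = logging.getLogger(__name__)

# per-normal-mode displacement scale: std = AMPLITUDE_PER_SQRT_K * sqrt(T) angstrom
AMPLITUDE_PER_SQRT_K = 0.002


class PESConfigurationError(ValueError):
    """A PES term refers to atoms the configuration does not have."""


@dataclass
class SamplerConfig:
    seed_geometry: MolecularConfiguration
    temperature: float = 300.0
    n_frames: int = 1000
    min_dist_cutoff: float = 0.0
    seed: int = 0
    max_attempts_per_frame: int = 100

    def __post_init__(self) -> None:
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if self.min_dist_cutoff < 0:
            raise ValueError("min_dist_cutoff must be >= 0")


@dataclass
class ToyPES:
    """Harmonic bond/angle + Lennard-Jones toy potential with an exact
    per-atom partition.

    ``bonds``: (i, j, k_b, r0) with k_b in kJ/mol/A^2, r0 in angstrom.
    ``angles``: (i, j, k, k_theta, theta0) centered on j, k_theta in
    kJ/mol/rad^2, theta0 in radian.
    ``pairs``: (i, j, epsilon, sigma) Lennard-Jones, kJ/mol and angstrom.
    """

    bonds: list[tuple[int, int, float, float]] = field(default_factory=list)
    angles: list[tuple[int, int, int, float, float]] = field(default_factory=list)
    pairs: list[tuple[int, int, float, float]] = field(default_factory=list)

    def to_yaml(self, path) -> None:
        doc = {"bonds": [list(b) for b in self.bonds],
               "angles": [list(a) for a in self.angles],
               "pairs": [list(p) for p in self.pairs]}
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh)

    @classmethod
    def from_yaml(cls, path) -> "ToyPES":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(bonds=[tuple(b) for b in doc.get("bonds", [])],
                   angles=[tuple(a) for a in doc.get("angles", [])],
                   pairs=[tuple(p) for p in doc.get("pairs", [])])

    @classmethod
    def from_geometry(cls, config: MolecularConfiguration,
                      k_bond: float = 2500.0, k_angle: float = 300.0,
                      lj_epsilon: float = 0.5) -> "ToyPES":
        """Build a PES whose minimum sits exactly at ``config``.

        Equilibrium bond lengths, angles and Lennard-Jones minima are read
        off the supplied geometry, so every term has zero gradient there
        and the geometry is a stationary point of the total energy.
        """
        adj = bonding_graph(config)
        coords = config.coordinates
        bonds, angles, pairs = [], [], []
        bonded = set()
        for i in range(config.natoms):
            for j in sorted(adj[i]):
                if j > i:
                    r0 = float(np.linalg.norm(coords[j] - coords[i]))
                    bonds.append((i, j, k_bond, r0))
                    bonded.add((i, j))
        for j in range(config.natoms):
            nbs = sorted(adj[j])
            for a in range(len(nbs)):
                for b in range(a + 1, len(nbs)):
                    i, k = nbs[a], nbs[b]
                    theta0 = _angle(coords[i], coords[j], coords[k])
                    angles.append((i, j, k, k_angle, theta0))
        for i in range(config.natoms):
            for j in range(i + 1, config.natoms):
                if (i, j) in bonded:
                    continue
                r = float(np.linalg.norm(coords[j] - coords[i]))
                sigma = r / 2.0 ** (1.0 / 6.0)  # LJ minimum at r
                pairs.append((i, j, lj_epsilon, sigma))
        return cls(bonds=bonds, angles=angles, pairs=pairs)


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    u, v = a - b, c - b
    cos = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(cos, -1.0, 1.0)))


def atomic_energies(config: MolecularConfiguration, pes: ToyPES
                    ) -> tuple[np.ndarray, float]:
    """Per-atom energies and the total they sum to (exactly).

    Each pair term is split half/half, each angle term a third per
    participating atom, so ``sum(e_atom) == E_total`` to machine precision.
    """
    n = config.natoms
    coords = config.coordinates
    e = np.zeros(n)
    for i, j, kb, r0 in pes.bonds:
        if not (0 <= i < n and 0 <= j < n):
            raise PESConfigurationError(f"bond ({i},{j}) outside {n} atoms")
        r = np.linalg.norm(coords[j] - coords[i])
        term = 0.5 * kb * (r - r0) ** 2
        e[i] += term / 2.0
        e[j] += term / 2.0
    for i, j, k, ka, th0 in pes.angles:
        if not (0 <= i < n and 0 <= j < n and 0 <= k < n):
            raise PESConfigurationError(f"angle ({i},{j},{k}) outside {n} atoms")
        th = _angle(coords[i], coords[j], coords[k])
        term = 0.5 * ka * (th - th0) ** 2
        e[i] += term / 3.0
        e[j] += term / 3.0
        e[k] += term / 3.0
    for i, j, eps, sigma in pes.pairs:
        if not (0 <= i < n and 0 <= j < n):
            raise PESConfigurationError(f"pair ({i},{j}) outside {n} atoms")
        r = np.linalg.norm(coords[j] - coords[i])
        sr6 = (sigma / r) ** 6
        term = 4.0 * eps * (sr6 * sr6 - sr6)
        e[i] += term / 2.0
        e[j] += term / 2.0
    return e, float(np.sum(e))


def total_energy(config: MolecularConfiguration, pes: ToyPES) -> float:
    return atomic_energies(config, pes)[1]


def label_trajectory(trajectory: Trajectory, pes: ToyPES) -> Trajectory:
    """Attach per-atom and total energies to every frame, in place."""
    for cfg in trajectory:
        e, tot = atomic_energies(cfg, pes)
        cfg.atomic_energies = e
        cfg.total_energy = tot
    return trajectory


def _rigid_body_basis(coords: np.ndarray) -> np.ndarray:
    """Orthonormal basis (6 x 3N, or 5 x 3N for linear molecules) of net
    translations and rotations about the centroid."""
    n = len(coords)
    centered = coords - coords.mean(axis=0)
    rows = []
    for ax in range(3):
        t = np.zeros((n, 3))
        t[:, ax] = 1.0
        rows.append(t.ravel())
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = 1.0
        rows.append(np.cross(centered, e).ravel())
    B = np.array(rows)
    # orthonormalize, dropping null rotations (linear molecules)
    q, r = np.linalg.qr(B.T)
    keep = np.abs(np.diag(r)) > 1e-10
    return q[:, keep].T


def _mode_directions(coords: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random orthonormal displacement directions spanning the internal
    (non-rigid-body) subspace of Cartesian space."""
    n3 = coords.size
    rigid = _rigid_body_basis(coords)
    raw = rng.standard_normal((n3, n3))
    raw -= rigid.T @ (rigid @ raw)
    q, _ = np.linalg.qr(raw)
    # keep the first n3 - nrigid columns, re-projected for safety
    nmodes = n3 - rigid.shape[0]
    modes = q[:, :nmodes]
    modes -= rigid.T @ (rigid @ modes)
    q2, _ = np.linalg.qr(modes)
    return q2.T  # (nmodes, 3N)


def _feature_snapshot(config: MolecularConfiguration, alf: ALFDefinition
                      ) -> np.ndarray:
    from .alf import featurize
    return np.concatenate(
        [featurize(config, alf, a).values for a in range(config.natoms)])


def sample_configurations(config: SamplerConfig) -> Trajectory:
    """Generate distorted frames around the seed geometry.

    Gaussian displacements along randomized internal-coordinate-like
    directions, standard deviation proportional to sqrt(temperature); a
    candidate is rejected when its all-atom feature-space distance to any
    accepted frame is below ``min_dist_cutoff``.  Generation stops at
    ``n_frames`` accepted frames or at the attempt cap (with a warning).
    """
    seed_cfg = config.seed_geometry
    if seed_cfg.natoms < 3:
        raise ValueError("need at least 3 atoms to sample")
    rng = np.random.default_rng(config.seed)
    modes = _mode_directions(seed_cfg.coordinates, rng)
    std = AMPLITUDE_PER_SQRT_K * np.sqrt(config.temperature)
    alf = compute_alf(seed_cfg)

    accepted: list[MolecularConfiguration] = []
    accepted_feats: list[np.ndarray] = []
    attempts = 0
    cap = config.n_frames * config.max_attempts_per_frame
    while len(accepted) < config.n_frames and attempts < cap:
        attempts += 1
        amps = std * rng.standard_normal(modes.shape[0])
        disp = (amps @ modes).reshape(-1, 3)
        cand = MolecularConfiguration(
            elements=list(seed_cfg.elements),
            coordinates=seed_cfg.coordinates + disp,
            frame_id=len(accepted),
        )
        feats = _feature_snapshot(cand, alf)
        if config.min_dist_cutoff > 0 and accepted_feats:
            dmin = np.min(np.linalg.norm(
                np.array(accepted_feats) - feats, axis=1))
            if dmin < config.min_dist_cutoff:
                continue
        accepted.append(cand)
        accepted_feats.append(feats)
    if len(accepted) < config.n_frames:
        logger.warning(
            "attempt cap reached: %d of %d frames accepted",
            len(accepted), config.n_frames)
    return Trajectory(configurations=accepted,
                      source_tag=f"synthetic T={config.temperature}")


def suggest_cutoff(trajectory: Trajectory, fraction: float = 0.01) -> float:
    """Rejection-cutoff heuristic: ``fraction`` of the median
    nearest-neighbour all-atom feature distance of a seed trajectory."""
    alf = compute_alf(trajectory[0])
    feats = np.stack([_feature_snapshot(c, alf) for c in trajectory])
    d = np.linalg.norm(feats[:, None, :] - feats[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    return fraction * float(np.median(d.min(axis=1)))


class ToyPESOracle:
    """On-demand per-atom energy labels for frames of a trajectory.

    Mirrors the production contract in which each atomic model may request
    only its own atom's output for a chosen frame.
    """

    def __init__(self, trajectory: Trajectory, pes: ToyPES):
        self.trajectory = trajectory
        self.pes = pes
        self._cache: dict[int, np.ndarray] = {}

    def _energies(self, frame_id: int) -> np.ndarray:
        if frame_id not in self._cache:
            e, _ = atomic_energies(self.trajectory[frame_id], self.pes)
            self._cache[frame_id] = e
        return self._cache[frame_id]

    def atomic_energy(self, frame_id: int, atom: int) -> float:
        return float(self._energies(frame_id)[atom])

    def total_energy(self, frame_id: int) -> float:
        return float(np.sum(self._energies(frame_id)))


def _water_geometry() -> MolecularConfiguration:
    r, half = 0.9572, np.deg2rad(104.52) / 2
    return MolecularConfiguration(
        elements=["O", "H", "H"],
        coordinates=np.array([
            [0.0, 0.0, 0.0],
            [r * np.sin(half), r * np.cos(half), 0.0],
            [-r * np.sin(half), r * np.cos(half), 0.0],
        ]),
    )


def _ammonia_geometry() -> MolecularConfiguration:
    # pyramidal NH3: N-H 1.012 A, HNH 106.7 deg
    r, hnh = 1.012, np.deg2rad(106.7)
    # place H ring at polar angle beta from the z axis such that the
    # H-N-H angle equals hnh
    sin2_beta = (1.0 - np.cos(hnh)) / (1.0 - np.cos(2 * np.pi / 3))
    beta = float(np.arcsin(np.sqrt(sin2_beta)))
    coords = [[0.0, 0.0, 0.0]]
    for k in range(3):
        phi = 2 * np.pi * k / 3
        coords.append([r * np.sin(beta) * np.cos(phi),
                       r * np.sin(beta) * np.sin(phi),
                       r * np.cos(beta)])
    return MolecularConfiguration(elements=["N", "H", "H", "H"],
                                  coordinates=np.array(coords))


def _chain12_geometry() -> MolecularConfiguration:
    # 12-atom zig-zag carbon chain, C-C 1.53 A, CCC 111 deg, in a plane
    r, theta = 1.53, np.deg2rad(111.0)
    half = theta / 2
    coords = []
    for k in range(12):
        x = k * r * np.sin(half)
        y = (k % 2) * r * np.cos(half)
        coords.append([x, y, 0.0])
    return MolecularConfiguration(elements=["C"] * 12,
                                  coordinates=np.array(coords))


def default_systems() -> dict[str, tuple[MolecularConfiguration, ToyPES]]:
    """Built-in benchmark systems: water (3 atoms, 3 features), ammonia
    (4 atoms, 6 features), and a 12-atom carbon chain (30 features).

    Every geometry is a stationary point of its own PES by construction.
    """
    out = {}
    for name, geom in [("water", _water_geometry()),
                       ("ammonia", _ammonia_geometry()),
                       ("chain12", _chain12_geometry())]:
        out[name] = (geom, ToyPES.from_geometry(geom))
    return out


def get_system(name: str) -> tuple[MolecularConfiguration, ToyPES]:
    systems = default_systems()
    if name not in systems:
        raise KeyError(f"unknown system {name!r}; have {sorted(systems)}")
    return systems[name]
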