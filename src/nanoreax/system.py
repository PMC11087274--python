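"""Periodic atomic configurations and minimum-image geometry.

The containers here are deliberately small: an orthorhombic :class:`Cell`,
a :class:`Configuration` of atoms inside it, a :class:`Trajectory` of frames
on a strictly increasing time grid, and a :class:`LabeledSample` pairing a
configuration with reference energy/forces.  All geometry goes through the
minimum-image convention; neighbor searches offer both a brute-force scan
and a cell-linked-list implementation that must agree exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .units import ATOMIC_MASSES, AMU_IN_GRAMS, SUPPORTED_ELEMENTS


class GeometryError(ValueError):
    """Raised for invalid cells, cutoffs or non-finite coordinates."""


@dataclass(frozen=True)
class Cell:
    """Orthorhombic simulation cell.

    Parameters
    ----------
    edge_lengths
        The three box edge lengths in Å, all strictly positive.
    periodic_flags
        Per-axis periodicity.  Non-periodic axes use plain Euclidean
        displacements along that axis.
    """

    edge_lengths: tuple[float, float, float]
    periodic_flags: tuple[bool, bool, bool] = (True, True, True)

    def __post_init__(self) -> None:
        lengths = np.asarray(self.edge_lengths, dtype=float)
        if lengths.shape != (3,):
            raise GeometryError("cell needs exactly three edge lengths")
        if not np.all(np.isfinite(lengths)) or np.any(lengths <= 0):
            raise GeometryError(f"edge lengths must be positive and finite, got {self.edge_lengths}")
        object.__setattr__(self, "edge_lengths", tuple(float(x) for x in lengths))
        object.__setattr__(self, "periodic_flags", tuple(bool(p) for p in self.periodic_flags))

    @property
    def lengths(self) -> np.ndarray:
        return np.asarray(self.edge_lengths, dtype=float)

    @property
    def volume(self) -> float:
        """Cell volume in Å³."""
        return float(np.prod(self.lengths))

    @classmethod
    def cubic(cls, edge: float, periodic: bool = True) -> "Cell":
        return cls((edge, edge, edge), (periodic,) * 3)

    def min_periodic_edge(self) -> float:
        """Shortest edge among the periodic axes (inf if none are periodic)."""
        periodic = np.asarray(self.periodic_flags)
        if not periodic.any():
            return float("inf")
        return float(self.lengths[periodic].min())


def _as_positions(x: np.ndarray | Sequence) -> np.ndarray:
    pos = np.asarray(x, dtype=float)
    if pos.ndim == 1:
        pos = pos.reshape(1, 3)
    if pos.shape[-1] != 3:
        raise GeometryError(f"positions must have trailing dimension 3, got shape {pos.shape}")
    if not np.all(np.isfinite(pos)):
        raise GeometryError("non-finite position encountered")
    return pos


def minimum_image_displacement(
    a: np.ndarray, b: np.ndarray, cell: Cell
) -> tuple[np.ndarray, float]:
    """Minimum-image displacement ``b − a`` and its length.

    Returns the displacement vector pointing from ``a`` to the nearest
    periodic image of ``b``, and the corresponding distance in Å.  Axes with
    ``periodic_flags`` off are treated as open.
    """
    a = _as_positions(a).reshape(3)
    b = _as_positions(b).reshape(3)
    d = b - a
    lengths = cell.lengths
    periodic = np.asarray(cell.periodic_flags)
    d[periodic] -= lengths[periodic] * np.round(d[periodic] / lengths[periodic])
    return d, float(np.linalg.norm(d))


def mic_displacements(delta: np.ndarray, cell: Cell) -> np.ndarray:
    """Vectorised minimum-image reduction of raw displacement vectors."""
    delta = np.asarray(delta, dtype=float)
    lengths = cell.lengths
    periodic = np.asarray(cell.periodic_flags)
    out = delta.copy()
    for ax in range(3):
        if periodic[ax]:
            L = lengths[ax]
            out[..., ax] -= L * np.round(out[..., ax] / L)
    return out


@dataclass
class Configuration:
    """A set of atoms in an orthorhombic (possibly periodic) cell.

    ``species`` are element symbols from {H, C, N, O}; ``positions`` are
    Cartesian coordinates in Å.
    """

    species: tuple[str, ...]
    positions: np.ndarray
    cell: Cell

    def __post_init__(self) -> None:
        self.species = tuple(str(s) for s in self.species)
        unknown = set(self.species) - set(SUPPORTED_ELEMENTS)
        if unknown:
            raise GeometryError(f"unsupported elements: {sorted(unknown)}")
        self.positions = _as_positions(self.positions)
        if len(self.species) != len(self.positions):
            raise GeometryError(
                f"{len(self.species)} species vs {len(self.positions)} positions"
            )

    def __len__(self) -> int:
        return len(self.species)

    @property
    def n_atoms(self) -> int:
        return len(self.species)

    @property
    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_MASSES[s] for s in self.species])

    def wrapped(self) -> "Configuration":
        """Copy with fractional coordinates wrapped into [0, 1) on periodic axes."""
        pos = self.positions.copy()
        lengths = self.cell.lengths
        for ax in range(3):
            if self.cell.periodic_flags[ax]:
                pos[:, ax] = np.mod(pos[:, ax], lengths[ax])
        return Configuration(self.species, pos, self.cell)

    def with_positions(self, positions: np.ndarray) -> "Configuration":
        return Configuration(self.species, positions, self.cell)

    def copy(self) -> "Configuration":
        return Configuration(self.species, self.positions.copy(), self.cell)


def mass_density(config: Configuration) -> float:
    """Mass density of the configuration in g/cc.

    Uses standard atomic weights.  The cell volume must be non-zero (it is
    by :class:`Cell` construction) and all axes contribute regardless of
    periodicity.
    """
    if config.n_atoms == 0:
        raise GeometryError("density of an empty configuration is undefined")
    grams = config.masses.sum() * AMU_IN_GRAMS
    cc = config.cell.volume * 1e-24  # Å³ → cm³
    return grams / cc


def cell_edge_for_density(species: Iterable[str], density: float) -> float:
    """Cubic cell edge (Å) giving the requested density for these atoms."""
    if density <= 0:
        raise GeometryError("density must be positive")
    grams = sum(ATOMIC_MASSES[s] for s in species) * AMU_IN_GRAMS
    volume_cc = grams / density
    return (volume_cc * 1e24) ** (1.0 / 3.0)


# ---------------------------------------------------------------------------
# Neighbor search


def _check_cutoff(cell: Cell, cutoff: float, allow_multi_image: bool) -> None:
    if cutoff < 0:
        raise GeometryError("cutoff must be non-negative")
    half_edge = cell.min_periodic_edge() / 2.0
    if not allow_multi_image and cutoff > half_edge:
        raise GeometryError(
            f"cutoff {cutoff:.3f} Å exceeds half the shortest periodic edge "
            f"({half_edge:.3f} Å); enlarge the box or pass allow_multi_image=True "
            "to accept minimum-image-only neighbor lists"
        )


def brute_force_pairs(
    config: Configuration, cutoff: float, *, allow_multi_image: bool = False
) -> list[tuple[int, int, float]]:
    """All pairs (i < j) with minimum-image distance strictly below cutoff.

    O(N²) reference scan; authoritative for correctness tests and the
    default for small systems.
    """
    _check_cutoff(config.cell, cutoff, allow_multi_image)
    n = config.n_atoms
    if n < 2 or cutoff == 0:
        return []
    pos = config.positions
    delta = pos[None, :, :] - pos[:, None, :]
    delta = mic_displacements(delta, config.cell)
    dist = np.sqrt((delta**2).sum(axis=-1))
    iu, ju = np.triu_indices(n, k=1)
    mask = dist[iu, ju] < cutoff
    return [(int(i), int(j), float(dist[i, j])) for i, j in zip(iu[mask], ju[mask])]


def _cell_linked_pairs(
    config: Configuration, cutoff: float
) -> list[tuple[int, int, float]]:
    """Cell-linked-list neighbor search (periodic axes only bins with ≥3 cells)."""
    cell = config.cell
    lengths = cell.lengths
    pos = config.wrapped().positions
    n = config.n_atoms
    nbins = np.maximum(1, np.floor(lengths / cutoff).astype(int))
    # With fewer than 3 bins on a periodic axis the half-shell trick breaks;
    # fall back to brute force there.
    if np.any(nbins < 3):
        return brute_force_pairs(config, cutoff)
    bin_size = lengths / nbins
    bins = np.minimum((pos / bin_size).astype(int), nbins - 1)
    from collections import defaultdict

    members: dict[tuple[int, int, int], list[int]] = defaultdict(list)
    for idx, b in enumerate(map(tuple, bins)):
        members[b].append(idx)

    periodic = cell.periodic_flags
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
    ]
    candidates: set[tuple[int, int]] = set()
    for b, atoms in members.items():
        for off in offsets:
            nb = []
            valid = True
            for ax in range(3):
                v = b[ax] + off[ax]
                if periodic[ax]:
                    v %= nbins[ax]
                elif v < 0 or v >= nbins[ax]:
                    valid = False
                    break
                nb.append(v)
            if not valid:
                continue
            other = members.get(tuple(nb))
            if not other:
                continue
            for i in atoms:
                for j in other:
                    if i < j:
                        candidates.add((i, j))
    if not candidates:
        return []
    # distance pass with the exact arithmetic of the brute-force scan so
    # the two searches agree bitwise
    raw = config.positions
    idx = np.array(sorted(candidates))
    delta = mic_displacements(raw[idx[:, 1]] - raw[idx[:, 0]], cell)
    dist = np.sqrt((delta**2).sum(axis=-1))
    sel = dist < cutoff
    return [
        (int(i), int(j), float(d))
        for (i, j), d in zip(idx[sel], dist[sel])
    ]


#: Below this atom count the brute-force scan is used directly.
_BRUTE_FORCE_LIMIT = 200


def neighbor_pairs(
    config: Configuration, cutoff: float, *, allow_multi_image: bool = False
) -> list[tuple[int, int, float]]:
    """Pairs (i, j, distance) with i < j and minimum-image distance < cutoff.

    Dispatches to a cell-linked-list search for large systems and the
    brute-force scan otherwise; the two agree exactly by construction and
    by test.  Cutoffs beyond half the shortest periodic edge raise unless
    ``allow_multi_image`` is set (in which case only the nearest image is
    still considered, documented minimum-image-only behavior).
    """
    _check_cutoff(config.cell, cutoff, allow_multi_image)
    if cutoff == 0 or config.n_atoms < 2:
        return []
    if config.n_atoms < _BRUTE_FORCE_LIMIT:
        return brute_force_pairs(config, cutoff, allow_multi_image=allow_multi_image)
    return _cell_linked_pairs(config, cutoff)


def min_pairwise_distance(config: Configuration) -> float:
    """Smallest minimum-image distance over all atom pairs (Å)."""
    if config.n_atoms < 2:
        return float("inf")
    pos = config.positions
    delta = pos[None, :, :] - pos[:, None, :]
    delta = mic_displacements(delta, config.cell)
    dist = np.sqrt((delta**2).sum(axis=-1))
    iu, ju = np.triu_indices(config.n_atoms, k=1)
    return float(dist[iu, ju].min())


# ---------------------------------------------------------------------------
# Trajectories and labeled samples


@dataclass
class Trajectory:
    """Ordered frames on a strictly increasing time grid (fs).

    Optional per-frame scalars (temperature K, density g/cc, potential
    energy kcal/mol) ride along in ``scalars``; every frame must share the
    species ordering of the first.
    """

    frames: list[Configuration] = field(default_factory=list)
    times: list[float] = field(default_factory=list)
    scalars: dict[str, list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        if len(self.frames) != len(self.times):
            raise ValueError("frames and times length mismatch")
        if any(t2 <= t1 for t1, t2 in zip(self.times, self.times[1:])):
            raise ValueError("times must be strictly increasing")
        if self.frames:
            ref = self.frames[0].species
            for k, f in enumerate(self.frames):
                if f.species != ref:
                    raise ValueError(f"frame {k} species ordering differs from frame 0")
        for key, vals in self.scalars.items():
            if len(vals) != len(self.frames):
                raise ValueError(f"scalar series {key!r} length mismatch")

    def __len__(self) -> int:
        return len(self.frames)

    def append(self, frame: Configuration, time: float, **scalars: float) -> None:
        if self.times and time <= self.times[-1]:
            raise ValueError("times must be strictly increasing")
        if self.frames and frame.species != self.frames[0].species:
            raise ValueError("species ordering differs from frame 0")
        self.frames.append(frame)
        self.times.append(float(time))
        for key, value in scalars.items():
            self.scalars.setdefault(key, [float("nan")] * (len(self.frames) - 1)).append(
                float(value)
            )
        for key in self.scalars:
            if key not in scalars:
                self.scalars[key].append(float("nan"))


@dataclass
class LabeledSample:
    """Configuration with reference total energy (kcal/mol) and forces (kcal/mol/Å)."""

    configuration: Configuration
    energy: float
    forces: np.ndarray

    def __post_init__(self) -> None:
        self.forces = np.asarray(self.forces, dtype=float)
        if self.forces.shape != (self.configuration.n_atoms, 3):
            raise ValueError(
                f"forces shape {self.forces.shape} does not match "
                f"{self.configuration.n_atoms} atoms"
            )
        self.energy = float(self.energy)
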