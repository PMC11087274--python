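"""Constructed geometries with known ground truth, for tests and demos.

Everything here is exact by construction: the diamond lattice has
coordination number 4 with nearest-neighbor distance a·√3/4, a fused
hexagonal sheet of k rings has a ring census of exactly {6: k}, and the
scripted reaction trajectories realize a prescribed species event at a
prescribed frame.
"""

from __future__ import annotations

import math
import re

import numpy as np

from .builders import molecule_template, random_rotation_matrix
from .system import Cell, Configuration, Trajectory


def diamond_lattice(a: float = 3.567, replicas: tuple[int, int, int] = (1, 1, 1)) -> Configuration:
    """Periodic diamond-cubic carbon lattice.

    ``a`` is the conventional cubic cell parameter (Å, default the carbon
    diamond value); the conventional cell holds 8 atoms and the
    nearest-neighbor distance is a·√3/4.
    """
    if a <= 0 or any(r < 1 for r in replicas):
        raise ValueError("need a > 0 and replicas >= 1")
    basis = np.array(
        [
            [0.0, 0.0, 0.0],
            [0.0, 0.5, 0.5],
            [0.5, 0.0, 0.5],
            [0.5, 0.5, 0.0],
            [0.25, 0.25, 0.25],
            [0.25, 0.75, 0.75],
            [0.75, 0.25, 0.75],
            [0.75, 0.75, 0.25],
        ]
    )
    nx_, ny, nz = replicas
    frac = []
    for ix in range(nx_):
        for iy in range(ny):
            for iz in range(nz):
                frac.append(basis + np.array([ix, iy, iz]))
    frac = np.vstack(frac) / np.array(replicas)
    cell = Cell((a * nx_, a * ny, a * nz))
    positions = frac * cell.lengths
    return Configuration(("C",) * len(positions), positions, cell)


def hexagonal_sheet(n_rings: int, bond: float = 1.42, vacuum: float = 30.0) -> Configuration:
    """Linear chain of ``n_rings`` edge-fused carbon hexagons (acene-style).

    Constructed in a large non-periodic box; the minimum cycle basis of its
    bond graph is exactly ``n_rings`` six-cycles.
    """
    if n_rings < 1:
        raise ValueError("need at least one ring")
    # Two mirrored zigzag chains joined by vertical rungs at every even
    # position: bottom[k] = (k·(√3/2)b, −b/2 for odd k else 0), top is the
    # reflection about y = b/2.  Rung pairs at consecutive even k close one
    # hexagon each → exactly n_rings six-cycles, 2(2n+1) atoms.
    bottom = [
        (k * bond * math.sqrt(3) / 2.0, -bond / 2.0 if k % 2 else 0.0)
        for k in range(2 * n_rings + 1)
    ]
    top = [(x, bond - y) for (x, y) in bottom]
    coords = bottom + top
    xyz = np.zeros((len(coords), 3))
    xyz[:, 0] = [c[0] for c in coords]
    xyz[:, 1] = [c[1] for c in coords]
    xyz += vacuum / 2.0
    cell = Cell(
        (vacuum + float(np.ptp(xyz[:, 0])), vacuum, vacuum), (False, False, False)
    )
    return Configuration(("C",) * len(xyz), xyz, cell)


_EVENT_RE = re.compile(r"^\s*(.+?)\s*->\s*(.+?)\s*@\s*frame\s*(\d+)\s*$")
_TERM_RE = re.compile(r"^\s*(\d*)\s*([A-Za-z0-9]+)\s*$")


def _parse_side(side: str) -> list[str]:
    names: list[str] = []
    for term in side.split("+"):
        m = _TERM_RE.match(term)
        if not m:
            raise ValueError(f"cannot parse species term {term!r}")
        count = int(m.group(1) or 1)
        names.extend([m.group(2)] * count)
    return names


def reaction_toy_trajectory(
    script: str,
    n_frames: int = 6,
    spacing: float = 6.0,
    frame_dt: float = 50.0,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Scripted species-event trajectory, e.g. ``"2H2+O2->2H2O@frame3"``.

    Frames before the event frame contain the reactant molecules, frames
    from the event on contain the products; molecules sit on a cubic grid
    with ``spacing`` Å pitch (far beyond every bond cutoff), so the bond
    graph per frame is exactly the scripted species list.  Atom count need
    not be conserved by the script; the trajectory then reports what the
    script says, frame by frame (species ordering across frames is kept
    fixed by padding with the union system — reactants and products both
    present, displaced far apart, with the inactive side parked beyond the
    interaction range).

    For species-conservation-style tests use balanced scripts; this
    generator places reactant atoms and product atoms in two disjoint
    far-apart sub-boxes and swaps which sub-box is "assembled" at the event
    frame, so the per-frame species census changes while the global atom
    list stays identical across frames.
    """
    m = _EVENT_RE.match(script)
    if not m:
        raise ValueError(
            f"cannot parse script {script!r}; expected 'A+B->C@frameK'"
        )
    reactants = _parse_side(m.group(1))
    products = _parse_side(m.group(2))
    event_frame = int(m.group(3))
    if event_frame < 0 or event_frame >= n_frames:
        raise ValueError("event frame outside trajectory")
    rng = rng or np.random.default_rng(0)

    def assembled(names: list[str], origin: np.ndarray) -> tuple[list[str], np.ndarray]:
        species: list[str] = []
        pos: list[np.ndarray] = []
        side = max(1, math.ceil(len(names) ** (1.0 / 3.0)))
        for idx, name in enumerate(names):
            tmpl = molecule_template(name)
            rot = random_rotation_matrix(rng)
            center = origin + spacing * np.array(
                [idx % side, (idx // side) % side, idx // side**2], dtype=float
            )
            species.extend(tmpl.species)
            pos.append(tmpl.geometry @ rot.T + center)
        return species, np.vstack(pos)

    def exploded(names: list[str], origin: np.ndarray) -> tuple[list[str], np.ndarray]:
        # same atoms, but every atom isolated on its own grid site: the
        # parked side contributes only free atoms, never molecules
        species: list[str] = []
        for name in names:
            species.extend(molecule_template(name).species)
        n = len(species)
        side = max(1, math.ceil(n ** (1.0 / 3.0)))
        pos = origin + spacing * np.array(
            [[k % side, (k // side) % side, k // side**2] for k in range(n)],
            dtype=float,
        )
        return species, pos

    # geometry layout: reactant sub-box near origin, product sub-box far away
    r_species_a, r_pos_a = assembled(reactants, np.zeros(3))
    r_species_x, r_pos_x = exploded(reactants, np.zeros(3))
    p_species_a, p_pos_a = None, None
    offset = None
    extent = max(
        float(np.abs(r_pos_a).max()), float(np.abs(r_pos_x).max()), spacing
    )
    offset = np.array([extent + 5 * spacing, 0.0, 0.0])
    p_species_a, p_pos_a = assembled(products, offset)
    p_species_x, p_pos_x = exploded(products, offset)

    box = float(extent + 5 * spacing + max(
        float(np.abs(p_pos_a - offset).max()), float(np.abs(p_pos_x - offset).max())
    ) + 5 * spacing)
    cell = Cell.cubic(box, periodic=False)
    species = tuple(r_species_a + p_species_a)

    traj = Trajectory()
    for f in range(n_frames):
        if f < event_frame:
            pos = np.vstack([r_pos_a, p_pos_x])
        else:
            pos = np.vstack([r_pos_x, p_pos_a])
        traj.append(Configuration(species, pos + 2.0, cell), f * frame_dt)
    return traj
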