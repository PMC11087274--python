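"""Extended-XYZ reading and writing.

The canonical interchange format for configurations and trajectories:
per frame an atom count, a comment line with ``Lattice="ax ay az ..."``,
``Properties=species:S:1:pos:R:3[:forces:R:3]`` and optional scalar fields
(``energy``, ``time``, ``temperature``, ``density``, ``pbc``), then one row
per atom.  Only orthorhombic lattices are accepted.  Floats are written
with ``repr`` precision so a write→read round trip is exact to well below
1e-8 Å.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .system import Cell, Configuration, Trajectory


class ExtXYZError(ValueError):
    """Malformed extended-XYZ content; the message carries the line number."""


@dataclass
class Frame:
    """One parsed frame: configuration plus optional labels and scalars."""

    configuration: Configuration
    energy: float | None = None
    forces: np.ndarray | None = None
    scalars: dict[str, float] | None = None


def _format_comment(
    config: Configuration,
    energy: float | None,
    with_forces: bool,
    scalars: dict[str, float] | None,
) -> str:
    lx, ly, lz = (float(x) for x in config.cell.edge_lengths)
    lattice = f"{lx!r} 0.0 0.0 0.0 {ly!r} 0.0 0.0 0.0 {lz!r}"
    props = "species:S:1:pos:R:3" + (":forces:R:3" if with_forces else "")
    pbc = " ".join("T" if p else "F" for p in config.cell.periodic_flags)
    fields = [f'Lattice="{lattice}"', f"Properties={props}", f'pbc="{pbc}"']
    if energy is not None:
        fields.append(f"energy={float(energy)!r}")
    for key, value in (scalars or {}).items():
        fields.append(f"{key}={float(value)!r}")
    return " ".join(fields)


def write_extxyz(
    path,
    frames: Configuration | Trajectory | list,
    energies: list | None = None,
    forces: list | None = None,
) -> None:
    """Write configuration(s) to extended-XYZ.

    Accepts a single :class:`Configuration`, a list of them, or a
    :class:`Trajectory` (whose per-frame scalars, time included, ride along
    in the comment line).  ``energies``/``forces`` are optional per-frame
    labels.
    """
    scalars_per_frame: list[dict[str, float] | None]
    if isinstance(frames, Trajectory):
        configs = frames.frames
        scalars_per_frame = []
        for k in range(len(configs)):
            d = {"time": frames.times[k]}
            for key, series in frames.scalars.items():
                if not np.isnan(series[k]):
                    d[key] = series[k]
            scalars_per_frame.append(d)
    elif isinstance(frames, Configuration):
        configs = [frames]
        scalars_per_frame = [None]
    else:
        configs = list(frames)
        scalars_per_frame = [None] * len(configs)

    with open(path, "w") as fh:
        for k, config in enumerate(configs):
            energy = energies[k] if energies is not None else None
            frc = np.asarray(forces[k]) if forces is not None else None
            fh.write(f"{config.n_atoms}\n")
            fh.write(
                _format_comment(config, energy, frc is not None, scalars_per_frame[k])
                + "\n"
            )
            for i in range(config.n_atoms):
                x, y, z = (float(v) for v in config.positions[i])
                row = f"{config.species[i]} {x!r} {y!r} {z!r}"
                if frc is not None:
                    fx, fy, fz = (float(v) for v in frc[i])
                    row += f" {fx!r} {fy!r} {fz!r}"
                fh.write(row + "\n")


_KV_RE = re.compile(r'(\w+)=("(?:[^"]*)"|\S+)')


def _parse_comment(comment: str, lineno: int):
    kv = {}
    for m in _KV_RE.finditer(comment):
        value = m.group(2)
        if value.startswith('"'):
            value = value[1:-1]
        kv[m.group(1)] = value
    if "Lattice" not in kv:
        raise ExtXYZError(f"line {lineno}: missing Lattice")
    lat = [float(x) for x in kv["Lattice"].split()]
    if len(lat) != 9:
        raise ExtXYZError(f"line {lineno}: Lattice must have 9 entries")
    mat = np.array(lat).reshape(3, 3)
    if np.abs(mat - np.diag(np.diag(mat))).max() > 1e-10:
        raise ExtXYZError(f"line {lineno}: only orthorhombic lattices are supported")
    pbc = (True, True, True)
    if "pbc" in kv:
        flags = kv["pbc"].replace(",", " ").split()
        if len(flags) == 3:
            pbc = tuple(f.upper().startswith("T") for f in flags)
    cell = Cell(tuple(np.diag(mat)), pbc)
    props = kv.get("Properties", "species:S:1:pos:R:3")
    fields = props.split(":")
    columns = [
        (fields[i], int(fields[i + 2])) for i in range(0, len(fields), 3)
    ]
    energy = float(kv["energy"]) if "energy" in kv else None
    scalars = {}
    for key in ("time", "temperature", "density", "potential_energy"):
        if key in kv:
            scalars[key] = float(kv[key])
    return cell, columns, energy, scalars


def read_extxyz(path) -> list[Frame]:
    """Parse every frame of an extended-XYZ file.

    Raises :class:`ExtXYZError` naming the offending line on malformed
    headers, truncated frames or non-numeric rows.
    """
    frames: list[Frame] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    frame_index = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n_atoms = int(lines[pos].strip())
        except ValueError:
            raise ExtXYZError(
                f"line {pos + 1}: expected an atom count, got {lines[pos]!r}"
            ) from None
        if pos + 1 >= len(lines):
            raise ExtXYZError(f"frame {frame_index}: missing comment line")
        cell, columns, energy, scalars = _parse_comment(lines[pos + 1], pos + 2)
        body = lines[pos + 2 : pos + 2 + n_atoms]
        if len(body) < n_atoms:
            raise ExtXYZError(
                f"frame {frame_index}: truncated (expected {n_atoms} atom rows, "
                f"got {len(body)})"
            )
        species: list[str] = []
        positions = np.empty((n_atoms, 3))
        has_forces = any(name == "forces" for name, _ in columns)
        forces = np.empty((n_atoms, 3)) if has_forces else None
        for i, line in enumerate(body):
            parts = line.split()
            expected = sum(width for _, width in columns)
            if len(parts) < expected:
                raise ExtXYZError(
                    f"line {pos + 3 + i}: expected {expected} columns, got {len(parts)}"
                )
            col = 0
            try:
                for name, width in columns:
                    chunk = parts[col : col + width]
                    col += width
                    if name == "species":
                        species.append(chunk[0])
                    elif name == "pos":
                        positions[i] = [float(x) for x in chunk]
                    elif name == "forces":
                        forces[i] = [float(x) for x in chunk]
            except ValueError as exc:
                raise ExtXYZError(f"line {pos + 3 + i}: {exc}") from None
        config = Configuration(tuple(species), positions, cell)
        frames.append(
            Frame(config, energy=energy, forces=forces, scalars=scalars or None)
        )
        pos += 2 + n_atoms
        frame_index += 1
    return frames


def read_configuration(path) -> Configuration:
    """First frame of an extended-XYZ file as a bare configuration."""
    frames = read_extxyz(path)
    if not frames:
        raise ExtXYZError("file contains no frames")
    return frames[0].configuration


def frames_to_trajectory(frames: list[Frame]) -> Trajectory:
    """Assemble parsed frames into a Trajectory (times from the ``time``
    scalar when present, else the frame index)."""
    traj = Trajectory()
    for k, frame in enumerate(frames):
        scalars = dict(frame.scalars or {})
        time = scalars.pop("time", float(k))
        if frame.energy is not None:
            scalars.setdefault("potential_energy", frame.energy)
        traj.append(frame.configuration, time, **scalars)
    return traj


def read_trajectory(path) -> Trajectory:
    return frames_to_trajectory(read_extxyz(path))
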