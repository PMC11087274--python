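"""Calculator contract, the toy reactive potential, and batch labeling.

A *calculator* maps a :class:`~nanoreax.system.Configuration` to a total
potential energy (kcal/mol) and per-atom forces (kcal/mol/Å).  The built-in
:class:`ToyReactivePotential` is a smoothly cut pairwise Morse model with no
fixed topology — bonds form and break freely — and serves as the desk-scale
labeler throughout the active-learning loop.  An adapter specification for
external labelers (e.g. a plane-wave DFT engine) lives in
:mod:`nanoreax.labeler_adapter`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Protocol

import numpy as np

from .system import Configuration, mic_displacements
from .units import SUPPORTED_ELEMENTS


class CalculatorError(RuntimeError):
    """Raised when a calculator cannot evaluate a configuration."""


class Calculator(Protocol):
    """Contract every energy/force engine must satisfy.

    Energy must be invariant under rigid translation and permutation of
    like elements; forces must be the negative gradient of the energy with
    respect to Cartesian positions.
    """

    elements: tuple[str, ...]
    cutoff: float

    def evaluate(self, config: Configuration) -> tuple[float, np.ndarray]: ...


def _default_pair_params() -> dict[tuple[str, str], tuple[float, float, float]]:
    """(depth kcal/mol, equilibrium length Å, inverse width 1/Å) per element pair.

    Equilibrium lengths roughly match the seed-molecule bonds (H–H 0.74 Å,
    C–H ≈ 1.1 Å, O–H ≈ 1.0 Å, C–C/N–N/O–O near the diatomic seeds); depths
    are plausible bond-energy magnitudes.  These are fixture values for a
    desk-scale stand-in, not fitted claims.
    """
    r0_table = {
        ("H", "H"): 0.74,
        ("H", "C"): 1.09,
        ("H", "N"): 1.01,
        ("H", "O"): 0.96,
        ("C", "C"): 1.30,
        ("C", "N"): 1.25,
        ("C", "O"): 1.20,
        ("N", "N"): 1.10,
        ("N", "O"): 1.20,
        ("O", "O"): 1.21,
    }
    depth = {"H": 104.0, "C": 85.0, "N": 110.0, "O": 60.0}
    params = {}
    for i, a in enumerate(SUPPORTED_ELEMENTS):
        for b in SUPPORTED_ELEMENTS[i:]:
            d = math.sqrt(depth[a] * depth[b])
            r0 = r0_table.get((a, b), r0_table.get((b, a)))
            params[(a, b)] = (d, r0, 2.0)
    return params


@dataclass
class ToyReactivePotential:
    """Reactive pairwise Morse potential with a smooth cosine cutoff.

    For each minimum-image pair at distance r < ``cutoff``::

        E(r) = D [(1 - exp(-a (r - r0)))² - 1] · S(r)
        S(r) = ½ (cos(π r / r_c) + 1)

    ``S`` and its derivative vanish at the cutoff, so energy and forces are
    continuous everywhere; the Morse wall provides short-range repulsion.
    Distances below ``overlap_distance`` are rejected as unphysical.
    """

    pair_params: dict[tuple[str, str], tuple[float, float, float]] = field(
        default_factory=_default_pair_params
    )
    cutoff: float = 4.0
    overlap_distance: float = 0.1
    elements: tuple[str, ...] = SUPPORTED_ELEMENTS

    def _params(self, a: str, b: str) -> tuple[float, float, float]:
        key = (a, b) if (a, b) in self.pair_params else (b, a)
        try:
            return self.pair_params[key]
        except KeyError:
            raise CalculatorError(f"no pair parameters for elements {a}-{b}") from None

    def _param_tables(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        k = len(self.elements)
        D = np.zeros((k, k))
        R0 = np.zeros((k, k))
        A = np.zeros((k, k))
        for i, a in enumerate(self.elements):
            for j, b in enumerate(self.elements):
                d0, r0, a0 = self._params(a, b)
                D[i, j], R0[i, j], A[i, j] = d0, r0, a0
        return D, R0, A

    def evaluate(self, config: Configuration) -> tuple[float, np.ndarray]:
        unknown = set(config.species) - set(self.elements)
        if unknown:
            raise CalculatorError(f"unsupported elements: {sorted(unknown)}")
        n = config.n_atoms
        forces = np.zeros((n, 3))
        if n < 2:
            return 0.0, forces
        pos = config.positions
        delta = mic_displacements(pos[None, :, :] - pos[:, None, :], config.cell)
        dist2 = (delta**2).sum(axis=-1)
        iu, ju = np.triu_indices(n, k=1)
        rc = self.cutoff
        r2 = dist2[iu, ju]
        sel = r2 < rc * rc
        if not sel.any():
            return 0.0, forces
        i_idx, j_idx = iu[sel], ju[sel]
        r = np.sqrt(r2[sel])
        if r.min() < self.overlap_distance:
            k = int(np.argmin(r))
            raise CalculatorError(
                f"atoms {i_idx[k]} and {j_idx[k]} overlap (distance "
                f"{r[k]:.4f} Å < {self.overlap_distance} Å)"
            )
        codes = np.array([self.elements.index(s) for s in config.species])
        D, R0, A = self._param_tables()
        ci, cj = codes[i_idx], codes[j_idx]
        d0, r0, a0 = D[ci, cj], R0[ci, cj], A[ci, cj]
        x = 1.0 - np.exp(-a0 * (r - r0))
        morse = d0 * (x * x - 1.0)
        s = 0.5 * (np.cos(np.pi * r / rc) + 1.0)
        ds = -0.5 * np.pi / rc * np.sin(np.pi * r / rc)
        dmorse = 2.0 * d0 * x * a0 * np.exp(-a0 * (r - r0))
        energy = float((morse * s).sum())
        dEdr = dmorse * s + morse * ds
        u = delta[i_idx, j_idx] / r[:, None]
        np.add.at(forces, j_idx, -dEdr[:, None] * u)
        np.add.at(forces, i_idx, dEdr[:, None] * u)
        return energy, forces


def toy_energy_forces(
    config: Configuration, potential: ToyReactivePotential | None = None
) -> tuple[float, np.ndarray]:
    """Energy and forces of ``config`` under the (default) toy potential."""
    potential = potential or ToyReactivePotential()
    return potential.evaluate(config)


@dataclass
class RepulsivePrior:
    """Short-range repulsive baseline for delta-learned models.

    A fixed, element-pair-resolved inner wall::

        E(r) = A (r_in/r - 1)²   for r < r_in,   else 0
        r_in = inner_scale · (R_a + R_b)         (covalent radii)

    C¹-continuous at r_in.  Learned models ride on top of this baseline
    (delta learning), which keeps dynamics physical in regions no training
    data has reached yet; committee members all share it, so it cancels
    exactly out of query-by-committee disagreement.
    """

    covalent_radii: dict[str, float] = field(
        default_factory=lambda: {"H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66}
    )
    inner_scale: float = 0.8
    stiffness: float = 200.0  # kcal/mol

    def evaluate(self, config: Configuration) -> tuple[float, np.ndarray]:
        n = config.n_atoms
        forces = np.zeros((n, 3))
        if n < 2:
            return 0.0, forces
        pos = config.positions
        delta = mic_displacements(pos[None, :, :] - pos[:, None, :], config.cell)
        dist2 = (delta**2).sum(axis=-1)
        iu, ju = np.triu_indices(n, k=1)
        radii = np.array([self.covalent_radii[s] for s in config.species])
        r_in = self.inner_scale * (radii[iu] + radii[ju])
        r = np.sqrt(dist2[iu, ju])
        sel = r < r_in
        if not sel.any():
            return 0.0, forces
        i_idx, j_idx = iu[sel], ju[sel]
        rs, rin = r[sel], r_in[sel]
        rs = np.maximum(rs, 1e-6)
        x = rin / rs - 1.0
        energy = float((self.stiffness * x * x).sum())
        dEdr = -2.0 * self.stiffness * x * rin / rs**2
        u = delta[i_idx, j_idx] / rs[:, None]
        np.add.at(forces, j_idx, -dEdr[:, None] * u)
        np.add.at(forces, i_idx, dEdr[:, None] * u)
        return energy, forces

    def to_dict(self) -> dict:
        return {
            "covalent_radii": dict(self.covalent_radii),
            "inner_scale": self.inner_scale,
            "stiffness": self.stiffness,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RepulsivePrior":
        return cls(
            covalent_radii={k: float(v) for k, v in d["covalent_radii"].items()},
            inner_scale=float(d["inner_scale"]),
            stiffness=float(d["stiffness"]),
        )


@dataclass
class LabelResult:
    """Outcome of labeling one configuration: a sample or a recorded failure."""

    sample: "LabeledSample | None"
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.sample is not None


from .system import LabeledSample  # noqa: E402  (dataclass forward reference)


def label(configs: list[Configuration], calculator: Calculator) -> list[LabelResult]:
    """Label a batch of configurations, isolating per-item failures.

    One result per input, order preserved.  A failure on one configuration
    (e.g. overlapping atoms, unsupported element — the desk analogue of a
    non-converged reference calculation) is recorded in its slot and does
    not abort the batch.
    """
    results: list[LabelResult] = []
    for config in configs:
        try:
            energy, forces = calculator.evaluate(config)
            results.append(LabelResult(LabeledSample(config, energy, forces)))
        except (CalculatorError, ValueError) as exc:
            results.append(LabelResult(None, str(exc)))
    return results
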