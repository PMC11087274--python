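"""Behler–Parrinello-style atomic environment descriptors (ANI variant).

Each atom gets a fixed-length vector of element-pair-resolved radial terms
and element-triple-resolved angular terms, all built from smooth cosine
cutoffs so the vector is continuous as atoms cross the cutoff sphere.
Default cutoffs are 5.2 Å (radial) and 3.5 Å (angular).

The radial terms are

    G_rad[i; e, s] = Σ_{j ∈ e} exp(-η (r_ij - R_s)²) f_c(r_ij)

and the angular terms follow the ANI modification of the original
Behler–Parrinello form,

    G_ang[i; (e,e'), a] = 2^(1-ζ) Σ_{j<k ∈ (e,e')} (1 + cos(θ_ijk - θ_a))^ζ
                          · exp(-η ((r_ij + r_ik)/2 - R_a)²) f_c(r_ij) f_c(r_ik)

with θ_ijk = arccos(0.95·cosθ) — the 0.95 factor keeps the angle gradient
finite at 0 and π.  Periodic images are handled with the minimum-image
convention.  Analytic position-gradients of every term are available for
force evaluation through :class:`DescriptorEnvironment`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .system import Configuration, mic_displacements
from .units import SUPPORTED_ELEMENTS


def cutoff_fn(r, r_c: float):
    """Smooth cosine cutoff: 0.5·cos(π r/r_c) + 0.5 for r < r_c, else 0."""
    r = np.asarray(r, dtype=float)
    out = np.where(r < r_c, 0.5 * np.cos(np.pi * r / r_c) + 0.5, 0.0)
    return out if out.ndim else float(out)


def _cutoff_and_deriv(r: np.ndarray, r_c: float) -> tuple[np.ndarray, np.ndarray]:
    inside = r < r_c
    fc = np.where(inside, 0.5 * np.cos(np.pi * r / r_c) + 0.5, 0.0)
    dfc = np.where(inside, -0.5 * np.pi / r_c * np.sin(np.pi * r / r_c), 0.0)
    return fc, dfc


def _default_radial_shells() -> tuple[tuple[float, float], ...]:
    # Three-tier set below the 5.2 Å cutoff: a dense short-range tier
    # (η=32 Å⁻², 0.45–1.45 Å) resolving repulsive walls and stiff bonded
    # wells, a mid-range tier (η=12 Å⁻²) over 1.6–3.2 Å, and a broad tail
    # tier (η=6 Å⁻²) out to 4.8 Å.
    short = tuple((32.0, float(c)) for c in np.linspace(0.45, 1.45, 10))
    mid = tuple((12.0, float(c)) for c in np.linspace(1.6, 3.2, 6))
    tail = tuple((6.0, float(c)) for c in np.linspace(3.5, 4.8, 4))
    return short + mid + tail


def _default_angular_set() -> tuple[tuple[float, float, float, float], ...]:
    # (ζ, θ_s, η, R_s): 2 angular sections × 2 radial sections
    sections = []
    for theta_s in (math.pi / 4, 3 * math.pi / 4):
        for r_s in (1.0, 2.2):
            sections.append((8.0, theta_s, 3.0, r_s))
    return tuple(sections)


@dataclass(frozen=True)
class DescriptorParams:
    """Hyperparameters of the symmetry-function descriptor set.

    Shell sets are deliberately small (desk-scale training); fully
    configurable.  ``angular_cutoff`` may not exceed ``radial_cutoff``.
    """

    radial_cutoff: float = 5.2
    angular_cutoff: float = 3.5
    radial_shells: tuple[tuple[float, float], ...] = field(
        default_factory=_default_radial_shells
    )  # (η 1/Å², R_s Å)
    angular_set: tuple[tuple[float, float, float, float], ...] = field(
        default_factory=_default_angular_set
    )  # (ζ, θ_s rad, η 1/Å², R_s Å)
    elements: tuple[str, ...] = SUPPORTED_ELEMENTS

    def __post_init__(self) -> None:
        if self.radial_cutoff <= 0 or self.angular_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if self.angular_cutoff > self.radial_cutoff:
            raise ValueError("angular_cutoff must not exceed radial_cutoff")
        if not self.radial_shells or not self.angular_set:
            raise ValueError("at least one radial shell and one angular section")

    @property
    def element_pairs(self) -> list[tuple[str, str]]:
        return list(itertools.combinations_with_replacement(self.elements, 2))

    @property
    def n_radial(self) -> int:
        return len(self.elements) * len(self.radial_shells)

    @property
    def n_angular(self) -> int:
        return len(self.element_pairs) * len(self.angular_set)

    @property
    def n_features(self) -> int:
        return self.n_radial + self.n_angular

    def radial_col(self, neighbor_code: int, shell: int) -> int:
        return neighbor_code * len(self.radial_shells) + shell

    def pair_code(self, code_a: int, code_b: int) -> int:
        a, b = min(code_a, code_b), max(code_a, code_b)
        k = len(self.elements)
        # index of (a, b) in combinations_with_replacement order
        return a * k - a * (a - 1) // 2 + (b - a)

    def to_dict(self) -> dict:
        return {
            "radial_cutoff": self.radial_cutoff,
            "angular_cutoff": self.angular_cutoff,
            "radial_shells": [list(s) for s in self.radial_shells],
            "angular_set": [list(s) for s in self.angular_set],
            "elements": list(self.elements),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DescriptorParams":
        return cls(
            radial_cutoff=float(d["radial_cutoff"]),
            angular_cutoff=float(d["angular_cutoff"]),
            radial_shells=tuple(tuple(map(float, s)) for s in d["radial_shells"]),
            angular_set=tuple(tuple(map(float, s)) for s in d["angular_set"]),
            elements=tuple(d["elements"]),
        )


#: arccos safety factor from the ANI convention
_ANGLE_FACTOR = 0.95


@dataclass
class DescriptorEnvironment:
    """Descriptors of one configuration plus the chain-rule machinery for forces.

    ``G`` is the (N, D) descriptor matrix.  The contribution arrays record,
    for every (pair, shell) and (triple, section) term, which matrix entry
    it feeds and the gradient of the term with respect to the involved atom
    positions; :meth:`forces_from_weights` contracts them with per-atom
    sensitivity rows dE/dG to produce Cartesian forces.
    """

    G: np.ndarray
    rad_center: np.ndarray | None = None  # (K,)
    rad_neigh: np.ndarray | None = None
    rad_col: np.ndarray | None = None
    rad_grad: np.ndarray | None = None  # (K,3): d(term)/d r_neigh
    ang_i: np.ndarray | None = None  # (K,)
    ang_j: np.ndarray | None = None
    ang_k: np.ndarray | None = None
    ang_col: np.ndarray | None = None
    ang_grad_j: np.ndarray | None = None  # (K,3)
    ang_grad_k: np.ndarray | None = None

    @property
    def has_jacobian(self) -> bool:
        return self.rad_center is not None

    def forces_from_weights(self, W: np.ndarray) -> np.ndarray:
        """Forces for an energy E = Σ_i W[i]·G[i]; W is the (N, D) dE/dG."""
        if not self.has_jacobian:
            raise ValueError("environment was computed without a jacobian")
        n = self.G.shape[0]
        F = np.zeros((n, 3))
        if self.rad_center is not None and len(self.rad_center):
            coef = W[self.rad_center, self.rad_col][:, None]
            np.add.at(F, self.rad_neigh, -coef * self.rad_grad)
            np.add.at(F, self.rad_center, coef * self.rad_grad)
        if self.ang_i is not None and len(self.ang_i):
            coef = W[self.ang_i, self.ang_col][:, None]
            gj = coef * self.ang_grad_j
            gk = coef * self.ang_grad_k
            np.add.at(F, self.ang_j, -gj)
            np.add.at(F, self.ang_k, -gk)
            np.add.at(F, self.ang_i, gj + gk)
        return F


def compute_environment(
    config: Configuration, params: DescriptorParams, jacobian: bool = False
) -> DescriptorEnvironment:
    """Descriptor matrix (and optionally per-term gradients) for a configuration."""
    n = config.n_atoms
    D = params.n_features
    G = np.zeros((n, D))
    codes = np.array([params.elements.index(s) for s in config.species])
    env = DescriptorEnvironment(G=G)
    if n < 2:
        if jacobian:
            _attach_empty_jacobian(env)
        return env

    pos = config.positions
    delta = mic_displacements(pos[None, :, :] - pos[:, None, :], config.cell)
    dist = np.sqrt((delta**2).sum(axis=-1))
    np.fill_diagonal(dist, np.inf)

    # ---- radial block: directed pairs (center, neighbor)
    ctr, nbr = np.where(dist < params.radial_cutoff)
    r = dist[ctr, nbr]
    vec = delta[ctr, nbr]  # center -> neighbor
    fc, dfc = _cutoff_and_deriv(r, params.radial_cutoff)
    n_shells = len(params.radial_shells)
    rad_centers, rad_neighs, rad_cols, rad_vals, rad_grads = [], [], [], [], []
    for s_idx, (eta, r_s) in enumerate(params.radial_shells):
        gauss = np.exp(-eta * (r - r_s) ** 2)
        val = gauss * fc
        cols = codes[nbr] * n_shells + s_idx
        np.add.at(G, (ctr, cols), val)
        if jacobian:
            dval = gauss * (-2.0 * eta * (r - r_s) * fc + dfc)
            rad_centers.append(ctr)
            rad_neighs.append(nbr)
            rad_cols.append(cols)
            rad_grads.append(dval[:, None] * (vec / r[:, None]))
    if jacobian:
        env.rad_center = np.concatenate(rad_centers) if rad_centers else np.empty(0, int)
        env.rad_neigh = np.concatenate(rad_neighs) if rad_neighs else np.empty(0, int)
        env.rad_col = np.concatenate(rad_cols) if rad_cols else np.empty(0, int)
        env.rad_grad = (
            np.concatenate(rad_grads) if rad_grads else np.empty((0, 3))
        )

    # ---- angular block
    rc_a = params.angular_cutoff
    ai, aj, ak, avj, avk, arj, ark = _angular_triples(delta, dist, rc_a)
    if len(ai):
        _accumulate_angular(env, params, codes, ai, aj, ak, avj, avk, arj, ark, jacobian)
    elif jacobian:
        env.ang_i = np.empty(0, int)
        env.ang_j = np.empty(0, int)
        env.ang_k = np.empty(0, int)
        env.ang_col = np.empty(0, int)
        env.ang_grad_j = np.empty((0, 3))
        env.ang_grad_k = np.empty((0, 3))
    return env


def _attach_empty_jacobian(env: DescriptorEnvironment) -> None:
    env.rad_center = np.empty(0, int)
    env.rad_neigh = np.empty(0, int)
    env.rad_col = np.empty(0, int)
    env.rad_grad = np.empty((0, 3))
    env.ang_i = np.empty(0, int)
    env.ang_j = np.empty(0, int)
    env.ang_k = np.empty(0, int)
    env.ang_col = np.empty(0, int)
    env.ang_grad_j = np.empty((0, 3))
    env.ang_grad_k = np.empty((0, 3))


def _angular_triples(delta: np.ndarray, dist: np.ndarray, rc: float):
    """All (center i, neighbor j < k) triples with both legs inside rc."""
    n = dist.shape[0]
    ai, aj, ak = [], [], []
    vj, vk, rj, rk = [], [], [], []
    for i in range(n):
        neigh = np.where(dist[i] < rc)[0]
        c = len(neigh)
        if c < 2:
            continue
        pj, pk = np.triu_indices(c, k=1)
        ai.append(np.full(len(pj), i))
        aj.append(neigh[pj])
        ak.append(neigh[pk])
        vj.append(delta[i, neigh[pj]])
        vk.append(delta[i, neigh[pk]])
        rj.append(dist[i, neigh[pj]])
        rk.append(dist[i, neigh[pk]])
    if not ai:
        e = np.empty(0, int)
        return e, e, e, np.empty((0, 3)), np.empty((0, 3)), np.empty(0), np.empty(0)
    return (
        np.concatenate(ai),
        np.concatenate(aj),
        np.concatenate(ak),
        np.vstack(vj),
        np.vstack(vk),
        np.concatenate(rj),
        np.concatenate(rk),
    )


def _accumulate_angular(
    env: DescriptorEnvironment,
    params: DescriptorParams,
    codes: np.ndarray,
    ai, aj, ak, vj, vk, rj, rk,
    jacobian: bool,
) -> None:
    G = env.G
    rc = params.angular_cutoff
    n_sections = len(params.angular_set)
    fcj, dfcj = _cutoff_and_deriv(rj, rc)
    fck, dfck = _cutoff_and_deriv(rk, rc)
    uj = vj / rj[:, None]
    uk = vk / rk[:, None]
    cos_t = np.clip((vj * vk).sum(axis=1) / (rj * rk), -1.0, 1.0)
    theta = np.arccos(_ANGLE_FACTOR * cos_t)
    # d cosθ / d v_j = v_k/(r_j r_k) − cosθ·v_j/r_j²  (and j↔k)
    dcos_dvj = vk / (rj * rk)[:, None] - (cos_t / rj**2)[:, None] * vj
    dcos_dvk = vj / (rj * rk)[:, None] - (cos_t / rk**2)[:, None] * vk
    dtheta_dcos = -_ANGLE_FACTOR / np.sqrt(1.0 - (_ANGLE_FACTOR * cos_t) ** 2)
    pair_col0 = params.n_radial
    pair_codes = np.array(
        [params.pair_code(a, b) for a, b in zip(codes[aj], codes[ak])]
    )
    ang_cols_all, grads_j, grads_k, idx_i, idx_j, idx_k = [], [], [], [], [], []
    rmean = 0.5 * (rj + rk)
    for a_idx, (zeta, theta_s, eta, r_s) in enumerate(params.angular_set):
        base = 1.0 + np.cos(theta - theta_s)
        A = 2.0 ** (1.0 - zeta) * base**zeta
        R = np.exp(-eta * (rmean - r_s) ** 2)
        FF = fcj * fck
        val = A * R * FF
        cols = pair_col0 + pair_codes * n_sections + a_idx
        np.add.at(G, (ai, cols), val)
        if jacobian:
            dA_dtheta = 2.0 ** (1.0 - zeta) * zeta * base ** (zeta - 1.0) * (
                -np.sin(theta - theta_s)
            )
            dA_dcos = dA_dtheta * dtheta_dcos
            dR_dr = -eta * (rmean - r_s) * R  # per leg (d rmean/dr_leg = 1/2 → folded)
            gj = (
                (dA_dcos * R * FF)[:, None] * dcos_dvj
                + (A * dR_dr * FF)[:, None] * uj
                + (A * R * dfcj * fck)[:, None] * uj
            )
            gk = (
                (dA_dcos * R * FF)[:, None] * dcos_dvk
                + (A * dR_dr * FF)[:, None] * uk
                + (A * R * fcj * dfck)[:, None] * uk
            )
            ang_cols_all.append(cols)
            grads_j.append(gj)
            grads_k.append(gk)
            idx_i.append(ai)
            idx_j.append(aj)
            idx_k.append(ak)
    if jacobian:
        env.ang_i = np.concatenate(idx_i)
        env.ang_j = np.concatenate(idx_j)
        env.ang_k = np.concatenate(idx_k)
        env.ang_col = np.concatenate(ang_cols_all)
        env.ang_grad_j = np.vstack(grads_j)
        env.ang_grad_k = np.vstack(grads_k)


def environment_vector(
    config: Configuration, atom_index: int, params: DescriptorParams | None = None
) -> np.ndarray:
    """Symmetry-function vector of one atom (rotation/translation/permutation
    invariant by construction)."""
    params = params or DescriptorParams()
    if not (0 <= atom_index < config.n_atoms):
        raise IndexError(f"atom index {atom_index} out of range")
    env = compute_environment(config, params)
    return env.G[atom_index].copy()
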