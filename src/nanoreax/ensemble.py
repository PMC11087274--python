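"""Committee of per-element atomic-energy regressors with query-by-committee
uncertainty.

Each committee *member* maps an atom's symmetry-function vector G to an
atomic energy through a feature map φ — either the identity ("linear") or
random Fourier features ("rff", the default) — followed by per-element
linear weights:

    E = Σ_i  w[e_i] · φ_member(G_i) + b[e_i]

Because the model is linear in its trainable weights, forces are analytic:
the per-atom sensitivity dE/dG_i chains through the descriptor Jacobian.
Members differ in their random feature maps and in their training-data
blocks (the 16-block, 14/1/1 cross-validation split), which is what gives
the committee its disagreement in unexplored regions of configuration
space.  Training is full-batch Adam with learning-rate annealing on
validation plateau; a run is converged when the learning rate drops below
the stop value (1e-5 by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .descriptors import DescriptorEnvironment, DescriptorParams, compute_environment
from .system import Configuration, LabeledSample


# ---------------------------------------------------------------------------
# Query-by-committee uncertainty


def qbc_from_members(
    energies: np.ndarray,
    forces: np.ndarray,
    n_atoms: int,
    force_aggregation: str = "mean",
) -> tuple[float, float]:
    """Normalized committee disagreement (ε_E, ε_F).

    ε_E is the population standard deviation of member total energies
    divided by √N (kcal/mol·N^(−1/2)); ε_F aggregates, over atoms, the
    Euclidean norm of the per-component population standard deviation of
    member forces (kcal/mol/Å), averaged over atoms by default — the
    convention of ensemble-disagreement selection in the ANI family —
    with "max" available as a conservative alternative.
    """
    energies = np.asarray(energies, dtype=float)
    forces = np.asarray(forces, dtype=float)
    eps_e = float(energies.std(ddof=0) / math.sqrt(n_atoms))
    per_component = forces.std(axis=0, ddof=0)  # (N, 3)
    per_atom = np.linalg.norm(per_component, axis=1)
    if force_aggregation == "max":
        eps_f = float(per_atom.max()) if len(per_atom) else 0.0
    elif force_aggregation == "mean":
        eps_f = float(per_atom.mean()) if len(per_atom) else 0.0
    else:
        raise ValueError(f"unknown force aggregation {force_aggregation!r}")
    return eps_e, eps_f


def qbc_uncertainty(ensemble: "EnsembleModel", config: Configuration) -> tuple[float, float]:
    """(ε_E, ε_F) of the committee on one configuration."""
    energies, forces = ensemble.predict_members(config)
    return qbc_from_members(
        energies, forces, config.n_atoms, ensemble.force_aggregation
    )


@dataclass(frozen=True)
class SelectionThresholds:
    """Uncertainty thresholds for structure selection.

    Defaults are the final campaign values: 1.85 kcal/mol·N^(−1/2) on the
    normalized energy spread and 6.92 kcal/mol/Å on the force spread.
    A structure is selected iff either metric *strictly* exceeds its
    threshold (values exactly at threshold do not flag).
    """

    energy_threshold: float = 1.85
    force_threshold: float = 6.92

    def __post_init__(self) -> None:
        if self.energy_threshold <= 0 or self.force_threshold <= 0:
            raise ValueError("thresholds must be positive")

    def exceeded(self, eps_energy: float, eps_force: float) -> bool:
        return eps_energy > self.energy_threshold or eps_force > self.force_threshold

    def scaled(self, factor: float) -> "SelectionThresholds":
        return SelectionThresholds(
            self.energy_threshold * factor, self.force_threshold * factor
        )


def exceeds_thresholds(
    eps: tuple[float, float], thresholds: SelectionThresholds
) -> bool:
    return thresholds.exceeded(*eps)


def thresholds_for_generation(
    final: SelectionThresholds, generation: int, ramp_generations: int = 6
) -> SelectionThresholds:
    """Per-generation threshold schedule: linear ramp from 50% to 100% of the
    final values over ``ramp_generations`` (later generations get larger
    thresholds, trading exploration for exploitation)."""
    if generation >= ramp_generations - 1 or ramp_generations <= 1:
        return final
    frac = 0.5 + 0.5 * generation / (ramp_generations - 1)
    return final.scaled(frac)


# ---------------------------------------------------------------------------
# Members


@dataclass
class EnsembleMember:
    """One per-element linear regressor on top of a fixed feature map."""

    feature_mode: str  # "linear" | "rff"
    omega: np.ndarray | None  # (F, D) for rff
    phase: np.ndarray | None  # (F,) for rff
    weights: np.ndarray  # (n_elements, F)
    biases: np.ndarray  # (n_elements,) per-element atomic baselines
    g_scale: np.ndarray  # (D,) descriptor standardization scale
    history: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return self.weights.shape[1]

    def feature_map(self, G: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
        """φ(G) per atom and, for force chains, dφ/dG as the sin factor.

        Returns (phi (N,F), sin_term) where for rff
        dφ_m/dG_d = −√(2/F)·sin(ΩĜ+b)_m·Ω_{m,d}/g_scale_d.
        """
        Gs = G / self.g_scale
        if self.feature_mode == "linear":
            return Gs, None
        z = Gs @ self.omega.T + self.phase
        scale = math.sqrt(2.0 / self.omega.shape[0])
        return scale * np.cos(z), scale * np.sin(z)

    def sensitivity(self, G: np.ndarray, codes: np.ndarray) -> np.ndarray:
        """dE/dG rows (N, D) for the atoms' current descriptors."""
        w_rows = self.weights[codes]  # (N, F)
        if self.feature_mode == "linear":
            return w_rows / self.g_scale
        Gs = G / self.g_scale
        z = Gs @ self.omega.T + self.phase
        scale = math.sqrt(2.0 / self.omega.shape[0])
        return (-(scale * np.sin(z)) * w_rows) @ self.omega / self.g_scale

    def atomic_energies(self, G: np.ndarray, codes: np.ndarray) -> np.ndarray:
        phi, _ = self.feature_map(G)
        return (phi * self.weights[codes]).sum(axis=1) + self.biases[codes]


def predict_member(
    member: EnsembleMember,
    config: Configuration,
    params: DescriptorParams,
    env: DescriptorEnvironment | None = None,
) -> tuple[float, np.ndarray]:
    """Total energy and analytic forces of one member on a configuration."""
    unknown = set(config.species) - set(params.elements)
    if unknown:
        raise ValueError(f"elements not covered by the model: {sorted(unknown)}")
    if env is None or not env.has_jacobian:
        env = compute_environment(config, params, jacobian=True)
    codes = np.array([params.elements.index(s) for s in config.species])
    energy = float(member.atomic_energies(env.G, codes).sum())
    W = member.sensitivity(env.G, codes)
    forces = env.forces_from_weights(W)
    return energy, forces


# ---------------------------------------------------------------------------
# Ensemble


@dataclass
class EnsembleModel:
    """M committee members sharing descriptor parameters and element list."""

    members: list[EnsembleMember]
    descriptor_params: DescriptorParams
    force_aggregation: str = "mean"
    repulsive_prior: "object | None" = None  # shared delta-learning baseline
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("an ensemble needs at least 2 members")

    @property
    def n_members(self) -> int:
        return len(self.members)

    def predict_members(
        self, config: Configuration, env: DescriptorEnvironment | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """(member energies (M,), member forces (M, N, 3)); one shared
        descriptor evaluation."""
        if env is None:
            env = compute_environment(config, self.descriptor_params, jacobian=True)
        energies = np.empty(self.n_members)
        forces = np.empty((self.n_members, config.n_atoms, 3))
        for m, member in enumerate(self.members):
            energies[m], forces[m] = predict_member(
                member, config, self.descriptor_params, env
            )
        if self.repulsive_prior is not None:
            e_prior, f_prior = self.repulsive_prior.evaluate(config)
            energies += e_prior
            forces += f_prior[None, :, :]
        return energies, forces

    def predict(self, config: Configuration) -> tuple[float, np.ndarray]:
        """Committee-mean energy and forces."""
        energies, forces = self.predict_members(config)
        return float(energies.mean()), forces.mean(axis=0)


class CommitteeCalculator:
    """Calculator facade over an ensemble: committee-mean energy/forces.

    Caches the member-resolved predictions of the last evaluation so the
    nanoreactor driver can derive uncertainty without re-evaluating.
    """

    def __init__(self, ensemble: EnsembleModel):
        self.ensemble = ensemble
        self.elements = ensemble.descriptor_params.elements
        self.cutoff = ensemble.descriptor_params.radial_cutoff
        self.last_members: tuple[np.ndarray, np.ndarray] | None = None

    def evaluate(self, config: Configuration) -> tuple[float, np.ndarray]:
        energies, forces = self.ensemble.predict_members(config)
        self.last_members = (energies, forces)
        return float(energies.mean()), forces.mean(axis=0)


# ---------------------------------------------------------------------------
# Training


@dataclass
class TrainConfig:
    """Weights, learning-rate schedule and stopping rule for member training.

    The loss is ``energy_weight``·MSE(per-atom energy) +
    ``force_weight``·MSE(force components); training stops when the
    annealed learning rate drops below ``stop_lr`` (default 1e-5) or at
    ``max_epochs``.
    """

    energy_weight: float = 1.0
    force_weight: float = 0.2
    lr: float = 0.05
    anneal_factor: float = 0.5
    patience: int = 60
    warmup_epochs: int = 300
    stop_lr: float = 1.0e-5
    max_epochs: int = 3000
    anneal_every: int = 150
    grad_clip: float = 1000.0
    ridge: float = 1.0e-3
    #: training-set curation: structures whose largest force component
    #: exceeds this (kcal/mol/Å) are held out of the fits — the desk
    #: analogue of dropping non-converged reference calculations
    max_force: float = 300.0
    n_features: int = 64
    feature_mode: str = "linear"
    rff_z_scale: float = 2.0
    shared_features: bool = True
    use_repulsive_prior: bool = True
    n_blocks: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.energy_weight < 0 or self.force_weight < 0:
            raise ValueError("loss weights must be non-negative")
        if self.energy_weight == 0 and self.force_weight == 0:
            raise ValueError("at least one loss weight must be positive")
        if self.stop_lr <= 0:
            raise ValueError("stop_lr must be positive")


@dataclass
class _SampleDesign:
    """Per-sample design blocks for one member's linear-in-weights model."""

    energy_row: np.ndarray  # (P,) coefficients of concatenated (w, b)
    force_rows: np.ndarray  # (3N, P)
    energy_target: float
    force_targets: np.ndarray  # (3N,)
    n_atoms: int


@dataclass
class _SampleTerms:
    """Member-independent design machinery for one sample.

    Flattens every descriptor term's position-gradient into per-element
    sparse matrices M_e of shape (3N, T_e) so that, for any member, the
    force-design block for element e is just M_e @ rows_e where
    rows_e[t, m] = dφ_m/dG_col(t) evaluated at the term's center atom.
    """

    env: DescriptorEnvironment
    codes: np.ndarray
    mats: list  # per element: CSR (3N, T_e), sign-folded gradients
    centers: list[np.ndarray]
    cols: list[np.ndarray]
    n_atoms: int


def _sample_terms(sample: LabeledSample, params: DescriptorParams) -> _SampleTerms:
    env = compute_environment(sample.configuration, params, jacobian=True)
    codes = np.array(
        [params.elements.index(s) for s in sample.configuration.species]
    )
    movers, centers, cols, grads = [], [], [], []

    def add(mover, center, col, grad):
        movers.append(mover)
        centers.append(center)
        cols.append(col)
        grads.append(grad)

    # sign convention: F_{mover} += W[center, col] * grad_signed
    if env.rad_center is not None and len(env.rad_center):
        add(env.rad_neigh, env.rad_center, env.rad_col, -env.rad_grad)
        add(env.rad_center, env.rad_center, env.rad_col, env.rad_grad)
    if env.ang_i is not None and len(env.ang_i):
        add(env.ang_j, env.ang_i, env.ang_col, -env.ang_grad_j)
        add(env.ang_k, env.ang_i, env.ang_col, -env.ang_grad_k)
        add(env.ang_i, env.ang_i, env.ang_col, env.ang_grad_j + env.ang_grad_k)

    n = sample.configuration.n_atoms
    if movers:
        mover = np.concatenate(movers)
        center = np.concatenate(centers)
        col = np.concatenate(cols)
        grad = np.vstack(grads)
    else:
        mover = center = col = np.empty(0, dtype=int)
        grad = np.empty((0, 3))

    mats, centers_e, cols_e = [], [], []
    for e in range(len(params.elements)):
        sel = np.where(codes[center] == e)[0] if len(center) else np.empty(0, int)
        t_e = len(sel)
        rows_idx = (mover[sel][:, None] * 3 + np.arange(3)[None, :]).ravel()
        cols_idx = np.repeat(np.arange(t_e), 3)
        data = grad[sel].ravel()
        mats.append(
            sparse.csr_matrix((data, (rows_idx, cols_idx)), shape=(3 * n, t_e))
        )
        centers_e.append(center[sel])
        cols_e.append(col[sel])
    return _SampleTerms(env, codes, mats, centers_e, cols_e, n)


def _member_design(
    sample: LabeledSample,
    terms: _SampleTerms,
    member: EnsembleMember,
    n_elements: int,
) -> _SampleDesign:
    """Design blocks: E and F are linear in the concatenated (w, b) vector."""
    G = terms.env.G
    F_feat = member.n_features
    P = n_elements * F_feat + n_elements
    phi, _ = member.feature_map(G)
    energy_row = np.zeros(P)
    for e in range(n_elements):
        mask = terms.codes == e
        if mask.any():
            energy_row[e * F_feat : (e + 1) * F_feat] = phi[mask].sum(axis=0)
            energy_row[n_elements * F_feat + e] = mask.sum()

    if member.feature_mode == "rff":
        Gs = G / member.g_scale
        z = Gs @ member.omega.T + member.phase
        scale = math.sqrt(2.0 / member.omega.shape[0])
        sin_z = scale * np.sin(z)

    blocks = []
    for e in range(n_elements):
        ctr, cls = terms.centers[e], terms.cols[e]
        if len(ctr) == 0:
            blocks.append(np.zeros((3 * terms.n_atoms, F_feat)))
            continue
        if member.feature_mode == "linear":
            rows = np.zeros((len(ctr), F_feat))
            rows[np.arange(len(ctr)), cls] = 1.0 / member.g_scale[cls]
        else:
            rows = -sin_z[ctr] * member.omega[:, cls].T / member.g_scale[cls][:, None]
        blocks.append(terms.mats[e] @ rows)
    force_rows = np.concatenate(
        blocks + [np.zeros((3 * terms.n_atoms, n_elements))], axis=1
    )
    return _SampleDesign(
        energy_row=energy_row,
        force_rows=force_rows,
        energy_target=sample.energy,
        force_targets=sample.forces.reshape(-1),
        n_atoms=terms.n_atoms,
    )


def _assemble(designs: list[_SampleDesign]):
    E_rows = np.stack([d.energy_row / d.n_atoms for d in designs])
    E_t = np.array([d.energy_target / d.n_atoms for d in designs])
    F_rows = np.concatenate([d.force_rows for d in designs])
    F_t = np.concatenate([d.force_targets for d in designs])
    return E_rows, E_t, F_rows, F_t


def _adam_fit(
    E_rows, E_t, F_rows, F_t, Ev_rows, Ev_t, Fv_rows, Fv_t, cfg: TrainConfig,
    init_w: np.ndarray | None = None,
) -> tuple[np.ndarray, dict]:
    """Full-batch Adam with LR annealing on validation-plateau; returns the
    weight vector and a loss history."""
    P = E_rows.shape[1]
    # column whitening: equalizes curvature across parameters (the model is
    # linear in w, so this is an exact reparametrization)
    col = np.sqrt(
        cfg.energy_weight * (E_rows**2).mean(axis=0)
        + (cfg.force_weight * (F_rows**2).mean(axis=0) if len(F_t) else 0.0)
    )
    # floor scales of (nearly) inactive features: without it, un-whitening
    # amplifies their weights explosively on configurations that do
    # activate them
    floor = 1e-3 * float(col.max()) if col.max() > 0 else 1.0
    col = np.maximum(col, floor)
    E_rows = E_rows / col
    F_rows = F_rows / col
    Ev_rows = Ev_rows / col
    Fv_rows = Fv_rows / col
    w = np.zeros(P) if init_w is None else init_w * col
    m_t = np.zeros(P)
    v_t = np.zeros(P)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr = cfg.lr
    best_val = math.inf
    best_w = w.copy()
    stall = 0
    since_anneal = 0
    history = {"train": [], "val": [], "lr": []}
    n_E, n_F = len(E_t), max(len(F_t), 1)

    def loss(weights, Er, Et, Fr, Ft):
        le = float(((Er @ weights - Et) ** 2).mean()) if len(Et) else 0.0
        lf = float(((Fr @ weights - Ft) ** 2).mean()) if len(Ft) else 0.0
        return cfg.energy_weight * le + cfg.force_weight * lf

    step = 0
    for epoch in range(cfg.max_epochs):
        rE = E_rows @ w - E_t
        grad = cfg.energy_weight * 2.0 / n_E * (E_rows.T @ rE)
        if cfg.force_weight > 0 and len(F_t):
            rF = F_rows @ w - F_t
            grad += cfg.force_weight * 2.0 / n_F * (F_rows.T @ rF)
        grad += 2.0 * cfg.ridge * w  # ridge in whitened coordinates
        gnorm = float(np.linalg.norm(grad))
        if not math.isfinite(gnorm):
            # diverged: rewind to the best iterate at a smaller step size
            w = best_w.copy()
            m_t[:] = 0.0
            v_t[:] = 0.0
            lr *= cfg.anneal_factor
            if lr < cfg.stop_lr:
                break
            continue
        if gnorm > cfg.grad_clip:
            grad *= cfg.grad_clip / gnorm
        step += 1
        m_t = beta1 * m_t + (1 - beta1) * grad
        v_t = beta2 * v_t + (1 - beta2) * grad**2
        m_hat = m_t / (1 - beta1**step)
        v_hat = v_t / (1 - beta2**step)
        w -= lr * m_hat / (np.sqrt(v_hat) + eps)

        val = loss(w, Ev_rows, Ev_t, Fv_rows, Fv_t)
        if not math.isfinite(val) or (
            math.isfinite(best_val) and val > 1e4 * max(best_val, 1e-12)
        ):
            w = best_w.copy()
            m_t[:] = 0.0
            v_t[:] = 0.0
            lr *= cfg.anneal_factor
            if lr < cfg.stop_lr:
                break
            continue
        history["train"].append(loss(w, E_rows, E_t, F_rows, F_t))
        history["val"].append(val)
        history["lr"].append(lr)
        if val < best_val - 1e-12:
            best_val, best_w, stall = val, w.copy(), 0
        elif epoch >= cfg.warmup_epochs:
            stall += 1
        # anneal on validation plateau or on the fixed cadence, whichever
        # comes first; converged once the learning rate undercuts stop_lr
        since_anneal += 1
        if stall >= cfg.patience or since_anneal >= cfg.anneal_every:
            lr *= cfg.anneal_factor
            stall = 0
            since_anneal = 0
            if lr < cfg.stop_lr:
                break
    history["final_val"] = best_val
    return best_w / col, history


def train_ensemble(
    dataset: list[LabeledSample],
    config: TrainConfig | None = None,
    n_members: int = 8,
    rng: np.random.Generator | None = None,
    descriptor_params: DescriptorParams | None = None,
    init_members: list[EnsembleMember] | None = None,
) -> EnsembleModel:
    """Train an M-member committee on labeled samples.

    The dataset is shuffled into ``config.n_blocks`` blocks (16 by
    default); member m validates on block 2m, tests on block 2m+1 and
    trains on the remaining 14 — every member sees a distinct split.
    When ``init_members`` is given (warm start), each member reuses its
    predecessor's feature map and starts optimization from its weights;
    otherwise members train from scratch.
    """
    config = config or TrainConfig()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    params = descriptor_params or DescriptorParams()
    if not dataset:
        raise ValueError("dataset is empty")
    n_blocks = config.n_blocks
    if len(dataset) < n_blocks:
        raise ValueError(
            f"dataset of {len(dataset)} samples is too small for a {n_blocks}-block "
            f"split; reduce TrainConfig.n_blocks to at most {len(dataset)}"
        )
    if 2 * n_members > n_blocks:
        raise ValueError("need n_blocks >= 2 * n_members for distinct val/test blocks")

    if config.max_force > 0:
        kept = [s for s in dataset if np.abs(s.forces).max() <= config.max_force]
        if len(kept) >= n_blocks:
            dataset = kept

    order = rng.permutation(len(dataset))
    blocks = [list(order[b::n_blocks]) for b in range(n_blocks)]

    prior = None
    if config.use_repulsive_prior:
        from .potentials import RepulsivePrior

        prior = RepulsivePrior()
        residual = []
        for s in dataset:
            e_p, f_p = prior.evaluate(s.configuration)
            residual.append(
                LabeledSample(s.configuration, s.energy - e_p, s.forces - f_p)
            )
        dataset = residual

    terms_list = [_sample_terms(s, params) for s in dataset]

    # Per-element baseline atomic energies (least squares on compositions):
    # removing the large composition-dependent offset before gradient
    # training is the usual atomic-reference-energy trick.
    n_el = len(params.elements)
    comp = np.zeros((len(dataset), n_el))
    e_tot = np.array([s.energy for s in dataset])
    for i, t in enumerate(terms_list):
        for e in range(n_el):
            comp[i, e] = (t.codes == e).sum()
    weights_rows = 1.0 / comp.sum(axis=1)
    baseline, *_ = np.linalg.lstsq(
        comp * weights_rows[:, None], e_tot * weights_rows, rcond=None
    )
    centered = [
        LabeledSample(s.configuration, s.energy - comp[i] @ baseline, s.forces)
        for i, s in enumerate(dataset)
    ]

    # shared descriptor standardization from all atoms in the dataset
    all_G = np.concatenate([t.env.G for t in terms_list])
    g_scale = all_G.std(axis=0)
    g_scale[g_scale < 1e-8] = 1.0

    D = params.n_features
    n_elements = len(params.elements)
    members: list[EnsembleMember] = []
    shared_omega = shared_phase = None
    if config.feature_mode == "rff" and config.shared_features:
        srng = np.random.default_rng(rng.integers(2**31))
        shared_omega = srng.normal(size=(config.n_features, D))
        z_std = float((all_G / g_scale @ shared_omega.T).std())
        if z_std > 0:
            shared_omega *= config.rff_z_scale / z_std
        shared_phase = srng.uniform(0, 2 * math.pi, size=config.n_features)
    for m in range(n_members):
        mrng = np.random.default_rng(rng.integers(2**31))
        init_w = None
        if init_members is not None:
            prev = init_members[m % len(init_members)]
            if prev.feature_mode != config.feature_mode:
                raise ValueError("warm start requires matching feature modes")
            member = EnsembleMember(
                feature_mode=prev.feature_mode,
                omega=None if prev.omega is None else prev.omega.copy(),
                phase=None if prev.phase is None else prev.phase.copy(),
                weights=prev.weights.copy(),
                biases=prev.biases.copy(),
                g_scale=prev.g_scale.copy(),
            )
            F_feat = member.n_features
            init_w = np.concatenate(
                [prev.weights.ravel(), prev.biases - baseline]
            )
        else:
            if config.feature_mode == "rff":
                if shared_omega is not None:
                    omega, phase = shared_omega, shared_phase
                else:
                    omega = mrng.normal(size=(config.n_features, D))
                    # scale frequencies so the feature phases have the
                    # configured spread over the training atoms
                    z_std = float((all_G / g_scale @ omega.T).std())
                    if z_std > 0:
                        omega *= config.rff_z_scale / z_std
                    phase = mrng.uniform(0, 2 * math.pi, size=config.n_features)
                F_feat = config.n_features
            elif config.feature_mode == "linear":
                omega, phase = None, None
                F_feat = D
            else:
                raise ValueError(f"unknown feature mode {config.feature_mode!r}")
            member = EnsembleMember(
                feature_mode=config.feature_mode,
                omega=omega,
                phase=phase,
                weights=np.zeros((n_elements, F_feat)),
                biases=np.zeros(n_elements),
                g_scale=g_scale,
            )
        val_block = blocks[(2 * m) % n_blocks]
        test_block = blocks[(2 * m + 1) % n_blocks]
        held_out = set(val_block) | set(test_block)
        train_idx = [i for i in range(len(dataset)) if i not in held_out]

        designs = {
            i: _member_design(centered[i], terms_list[i], member, n_elements)
            for i in range(len(dataset))
        }
        E_rows, E_t, F_rows, F_t = _assemble([designs[i] for i in train_idx])
        Ev_rows, Ev_t, Fv_rows, Fv_t = _assemble([designs[i] for i in val_block]) if val_block else (
            E_rows, E_t, F_rows, F_t
        )
        w_vec, history = _adam_fit(
            E_rows, E_t, F_rows, F_t, Ev_rows, Ev_t, Fv_rows, Fv_t, config,
            init_w=init_w,
        )
        member.weights = w_vec[: n_elements * F_feat].reshape(n_elements, F_feat)
        member.biases = w_vec[n_elements * F_feat :] + baseline
        # held-out test metrics (per-atom energy RMSE, force RMSE)
        if test_block:
            Et_rows, Et_t, Ft_rows, Ft_t = _assemble([designs[i] for i in test_block])
            e_rmse = float(np.sqrt(((Et_rows @ w_vec - Et_t) ** 2).mean()))
            f_rmse = float(np.sqrt(((Ft_rows @ w_vec - Ft_t) ** 2).mean())) if len(Ft_t) else 0.0
        else:
            e_rmse = f_rmse = float("nan")
        member.history = {
            "final_val_loss": history["final_val"],
            "epochs": len(history["train"]),
            "test_energy_rmse_per_atom": e_rmse,
            "test_force_rmse": f_rmse,
            "val_block": sorted(val_block),
            "test_block": sorted(test_block),
        }
        members.append(member)

    return EnsembleModel(
        members=members,
        descriptor_params=params,
        repulsive_prior=prior,
        metadata={
            "n_samples": len(dataset),
            "n_blocks": n_blocks,
            "feature_mode": config.feature_mode,
        },
    )
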