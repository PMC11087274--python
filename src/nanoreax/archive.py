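"""Versioned JSON archives for labeled datasets and trained committees.

JSON keeps the artifacts human-readable and diff-able; floats are encoded
by ``repr`` through the standard library, which round-trips IEEE doubles
bit-exactly.  Readers refuse unknown format versions instead of guessing.
"""

from __future__ import annotations

import json
from typing import Any

import numpy as np

from .descriptors import DescriptorParams
from .ensemble import EnsembleMember, EnsembleModel
from .potentials import RepulsivePrior
from .system import Cell, Configuration, LabeledSample

DATASET_VERSION = 1
MODEL_VERSION = 1


class ArchiveError(ValueError):
    pass


def _config_to_dict(config: Configuration) -> dict:
    return {
        "species": list(config.species),
        "positions": config.positions.tolist(),
        "cell": {
            "edge_lengths": list(config.cell.edge_lengths),
            "periodic_flags": list(config.cell.periodic_flags),
        },
    }


def _config_from_dict(d: dict) -> Configuration:
    cell = Cell(
        tuple(float(x) for x in d["cell"]["edge_lengths"]),
        tuple(bool(p) for p in d["cell"]["periodic_flags"]),
    )
    return Configuration(tuple(d["species"]), np.array(d["positions"]), cell)


def save_dataset(
    path, samples: list[LabeledSample], provenance: dict[str, Any] | None = None
) -> None:
    """Write labeled samples (+ provenance: labeler id, generation, schedule
    parameters, ...) as a versioned JSON archive."""
    payload = {
        "format": "nanoreax-dataset",
        "version": DATASET_VERSION,
        "provenance": provenance or {},
        "samples": [
            {
                "configuration": _config_to_dict(s.configuration),
                "energy": s.energy,
                "forces": s.forces.tolist(),
            }
            for s in samples
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_dataset(path) -> tuple[list[LabeledSample], dict[str, Any]]:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "nanoreax-dataset":
        raise ArchiveError(f"{path}: not a dataset archive")
    if payload.get("version") != DATASET_VERSION:
        raise ArchiveError(
            f"{path}: unsupported dataset version {payload.get('version')!r} "
            f"(this release reads version {DATASET_VERSION})"
        )
    samples = [
        LabeledSample(
            _config_from_dict(rec["configuration"]),
            float(rec["energy"]),
            np.array(rec["forces"]),
        )
        for rec in payload["samples"]
    ]
    return samples, payload.get("provenance", {})


def _member_to_dict(member: EnsembleMember) -> dict:
    return {
        "feature_mode": member.feature_mode,
        "omega": None if member.omega is None else member.omega.tolist(),
        "phase": None if member.phase is None else member.phase.tolist(),
        "weights": member.weights.tolist(),
        "biases": member.biases.tolist(),
        "g_scale": member.g_scale.tolist(),
        "history": _jsonable(member.history),
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _member_from_dict(d: dict) -> EnsembleMember:
    return EnsembleMember(
        feature_mode=d["feature_mode"],
        omega=None if d["omega"] is None else np.array(d["omega"]),
        phase=None if d["phase"] is None else np.array(d["phase"]),
        weights=np.array(d["weights"]),
        biases=np.array(d["biases"]),
        g_scale=np.array(d["g_scale"]),
        history=d.get("history", {}),
    )


def save_model(path, ensemble: EnsembleModel) -> None:
    """Write a trained committee as a self-describing JSON archive
    (descriptor params + member weights + metadata + format version)."""
    payload = {
        "format": "nanoreax-ensemble",
        "version": MODEL_VERSION,
        "descriptor_params": ensemble.descriptor_params.to_dict(),
        "force_aggregation": ensemble.force_aggregation,
        "repulsive_prior": (
            None
            if ensemble.repulsive_prior is None
            else ensemble.repulsive_prior.to_dict()
        ),
        "members": [_member_to_dict(m) for m in ensemble.members],
        "metadata": _jsonable(ensemble.metadata),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> EnsembleModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "nanoreax-ensemble":
        raise ArchiveError(f"{path}: not an ensemble archive")
    if payload.get("version") != MODEL_VERSION:
        raise ArchiveError(
            f"{path}: unsupported model version {payload.get('version')!r} "
            f"(this release reads version {MODEL_VERSION})"
        )
    return EnsembleModel(
        members=[_member_from_dict(d) for d in payload["members"]],
        descriptor_params=DescriptorParams.from_dict(payload["descriptor_params"]),
        force_aggregation=payload.get("force_aggregation", "mean"),
        repulsive_prior=(
            None
            if payload.get("repulsive_prior") is None
            else RepulsivePrior.from_dict(payload["repulsive_prior"])
        ),
        metadata=payload.get("metadata", {}),
    )
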