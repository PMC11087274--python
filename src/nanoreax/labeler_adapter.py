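"""Directory-exchange adapter for external reference labelers.

The built-in toy potential is the default labeler; this adapter lets an
external quantum-chemistry engine stand in without any code coupling.  The
exchange protocol is file-based and bit-exact:

1. :meth:`ExternalLabelerAdapter.write_batch` writes one extended-XYZ file
   per configuration into ``<root>/inputs/`` named ``NNNN.extxyz``
   (zero-padded batch index, single frame, no labels).
2. The external engine computes a total energy (kcal/mol) and per-atom
   forces (kcal/mol/Å) for each input and writes
   ``<root>/outputs/NNNN.extxyz``: the same frame with an ``energy=...``
   comment field and a ``forces:R:3`` property block.  A failed
   calculation instead writes ``<root>/outputs/NNNN.failed`` containing a
   one-line reason.
3. :meth:`ExternalLabelerAdapter.read_batch` collects the results in batch
   order; failures are per-item, never batch-fatal.

Reference settings for reproducing the original dataset's labeler with a
plane-wave DFT engine (documented for adapter users; this package never
invokes it): unrestricted Kohn–Sham DFT, BLYP functional, TZV2P basis,
GTH pseudopotentials, Grimme D3 dispersion with zero damping, 600 Ry /
60 Ry plane-wave and Gaussian cutoffs, overall singlet spin multiplicity
for the periodic box.
"""

from __future__ import annotations

from pathlib import Path

from .extxyz import read_extxyz, write_extxyz
from .potentials import LabelResult
from .system import Configuration, LabeledSample


class ExternalLabelerAdapter:
    """File-exchange labeling against an out-of-process engine."""

    def __init__(self, root) -> None:
        self.root = Path(root)
        (self.root / "inputs").mkdir(parents=True, exist_ok=True)
        (self.root / "outputs").mkdir(parents=True, exist_ok=True)

    def input_path(self, index: int) -> Path:
        return self.root / "inputs" / f"{index:04d}.extxyz"

    def output_path(self, index: int) -> Path:
        return self.root / "outputs" / f"{index:04d}.extxyz"

    def failure_path(self, index: int) -> Path:
        return self.root / "outputs" / f"{index:04d}.failed"

    def write_batch(self, configs: list[Configuration]) -> list[Path]:
        paths = []
        for k, config in enumerate(configs):
            path = self.input_path(k)
            write_extxyz(path, config)
            paths.append(path)
        return paths

    def read_batch(self, n_items: int) -> list[LabelResult]:
        results: list[LabelResult] = []
        for k in range(n_items):
            out = self.output_path(k)
            failed = self.failure_path(k)
            if failed.exists():
                results.append(
                    LabelResult(None, failed.read_text().strip() or "labeler failure")
                )
                continue
            if not out.exists():
                results.append(LabelResult(None, f"missing output {out.name}"))
                continue
            frame = read_extxyz(out)[0]
            if frame.energy is None or frame.forces is None:
                results.append(
                    LabelResult(None, f"{out.name}: energy/forces missing")
                )
                continue
            results.append(
                LabelResult(
                    LabeledSample(frame.configuration, frame.energy, frame.forces)
                )
            )
        return results
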