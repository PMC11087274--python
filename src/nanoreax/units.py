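"""Internal unit system and physical constants.

Everything in the package works in a single fixed unit system:

================  ==========
quantity          unit
================  ==========
length            Å
time              fs
mass              amu
temperature       K
energy            kcal/mol
force             kcal/mol/Å
density           g/cc
================  ==========

Velocities are therefore Å/fs and accelerations Å/fs².  Energies expressed
in kcal/mol must be converted with :data:`KCAL_MOL_TO_MD` before they can be
combined with masses in amu and times in fs.
"""

from __future__ import annotations

#: Boltzmann constant, kcal/(mol K).
KB_KCAL_MOL_K = 0.0019872041

#: Avogadro constant, 1/mol.
AVOGADRO = 6.02214076e23

#: One atomic mass unit in grams.
AMU_IN_GRAMS = 1.0 / AVOGADRO

#: 1 kcal/mol expressed in the MD energy unit amu·Å²/fs².
#: 1 amu Å²/fs² = 1.66053906892e-27 kg · 1e10 m²/s² per particle
#: = 1.66053906892e-17 J → ×N_A J/mol; 1 kcal/mol = 4184 J/mol.
KCAL_MOL_TO_MD = 4184.0 / (1.66053906892e-17 * AVOGADRO)

#: Inverse conversion: amu·Å²/fs² → kcal/mol.
MD_TO_KCAL_MOL = 1.0 / KCAL_MOL_TO_MD

#: Standard atomic weights (amu) for the supported elements.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
}

#: Elements the toolkit supports, in canonical order.
SUPPORTED_ELEMENTS: tuple[str, ...] = ("H", "C", "N", "O")
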