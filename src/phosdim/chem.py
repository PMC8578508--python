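"""Shared chemistry helpers: residue masses and averagine isotope statistics.

Masses are delegated to :mod:`pyteomics.mass` (element-based, exactly
additive); this module only adds validation, the water constant, and the
averagine one-neutron rate used for natural isotopic envelopes.
"""

from __future__ import annotations

from functools import lru_cache

from pyteomics import mass as _pmass

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

WATER_AVERAGE = _pmass.calculate_mass(formula="H2O", average=True)
WATER_MONO = _pmass.calculate_mass(formula="H2O")

#: Expected number of +1 heavy-isotope substitutions per Da of peptide mass,
#: from the averagine composition (C 4.9384, H 7.7583, N 1.3577, O 1.4773,
#: S 0.0417 per 111.1254 Da) and the one-neutron isotope abundances
#: (13C 1.07%, 2H 0.0115%, 15N 0.366%, 17O 0.038%, 33S 0.75%).  Two-neutron
#: isotopes (18O, 34S) are not modelled.
AVERAGINE_NEUTRON_RATE = (
    4.9384 * 0.0107
    + 7.7583 * 0.000115
    + 1.3577 * 0.00366
    + 1.4773 * 0.00038
    + 0.0417 * 0.0075
) / 111.1254


class UnknownResidueError(ValueError):
    """A sequence contains a character outside the 20 standard residues."""

    def __init__(self, residue: str, position: int):
        self.residue = residue
        self.position = position
        super().__init__(
            f"unknown residue code {residue!r} at position {position}"
        )


def validate_sequence(sequence: str, offset: int = 1) -> None:
    """Raise :class:`UnknownResidueError` naming the first bad position.

    ``offset`` is the residue number of the first character, so the error
    reports coordinates in the caller's numbering.
    """
    for i, aa in enumerate(sequence):
        if aa not in STANDARD_RESIDUES:
            raise UnknownResidueError(aa, offset + i)


@lru_cache(maxsize=4096)
def peptide_mass(sequence: str, average: bool = True) -> float:
    """Neutral mass of a peptide (residues + one water), in Da."""
    validate_sequence(sequence)
    return _pmass.calculate_mass(sequence=sequence, average=average)


def residue_mass(aa: str, average: bool = True) -> float:
    """Residue (monomer-in-chain) mass of a single amino acid, in Da."""
    water = WATER_AVERAGE if average else WATER_MONO
    return peptide_mass(aa, average=average) - water
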