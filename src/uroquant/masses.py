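"""Monoisotopic mass constants for peptide m/z computation.

All values in unified atomic mass units (Da). Residue masses are the
monoisotopic masses of the amino-acid residues (i.e. the free amino acid
minus one water), as tabulated by IUPAC/Unimod from CODATA atomic masses.
MRM samples are label-free, so no isobaric-tag or other modification
masses appear here.
"""

from __future__ import annotations

#: Mass of a proton (Da); added once per charge on protonation.
PROTON: float = 1.00728

#: Monoisotopic mass of water (Da); terminal H + OH of an intact peptide
#: and of y-type fragments.
WATER: float = 18.01056

#: Monoisotopic residue masses (Da) for the 20 canonical amino acids.
MONOISOTOPIC_RESIDUE_MASS: dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

CANONICAL_RESIDUES = frozenset(MONOISOTOPIC_RESIDUE_MASS)


def residue_mass_sum(sequence: str) -> float:
    """Sum of monoisotopic residue masses for *sequence*.

    Raises
    ------
    ValueError
        If the sequence contains a non-canonical residue.
    """
    total = 0.0
    for aa in sequence:
        try:
            total += MONOISOTOPIC_RESIDUE_MASS[aa]
        except KeyError:
            raise ValueError(f"unknown residue {aa!r} in sequence {sequence!r}") from None
    return total
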