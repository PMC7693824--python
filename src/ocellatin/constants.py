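"""Physicochemical reference tables.

All scales are packaged as explicit constants so every derived quantity
(mass, charge, pI, GRAVY, hydrophobic moment) is reproducible from this
file alone, independent of library-internal tables.
"""

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: ExPASy ProtParam average (isotope-averaged) residue masses, Da.
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

WATER_MASS = 18.01524

#: Mass shift of C-terminal amidation (-OH replaced by -NH2), Da.
#: Amidated peptides are ~1 u lighter than the free acid.
AMIDATION_DELTA = -0.9847

#: Kyte-Doolittle hydropathy scale (used for GRAVY and the hydrophobic moment).
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Residues counted as hydrophobic for the integer percentage panel.
#: This set, with truncation toward zero, reproduces the printed family
#: values (e.g. 9/21 -> 42%, 11/21 -> 52%).
HYDROPHOBIC_SET = frozenset("ACFILMVW")

#: EMBOSS-style pKa values for the continuous charge / pI model.
PKA = {
    "Cterm": 3.6,
    "D": 3.9,
    "E": 4.1,
    "H": 6.0,
    "Nterm": 8.6,
    "K": 10.8,
    "R": 12.5,
    "Y": 10.1,
    "C": 8.5,
}

#: Angular step between consecutive residues on an ideal alpha-helix, degrees.
HELIX_ANGLE = 100.0


def validate_sequence(sequence: str, context: str = "sequence") -> str:
    """Uppercase and validate a one-letter residue string.

    Raises ``ValueError`` naming the first offending character.
    """
    if not sequence:
        raise ValueError(f"{context}: empty sequence")
    seq = sequence.upper()
    for i, ch in enumerate(seq):
        if ch not in VALID_RESIDUES:
            raise ValueError(
                f"{context}: invalid residue {ch!r} at position {i + 1}"
            )
    return seq
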