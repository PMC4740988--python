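"""Monoisotopic mass constants for peptide and PTM mass computation.

Residue masses are monoisotopic amino-acid *residue* masses (peptide-bond
form, i.e. free amino acid minus water), from the IUPAC 2021 atomic masses.
Modification deltas are the standard Unimod monoisotopic values.
"""

from __future__ import annotations

# Monoisotopic residue masses, Da (amino acid minus H2O).
RESIDUE_MASS: dict[str, float] = {
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

WATER_MASS = 18.010565  # H2O, monoisotopic
PROTON_MASS = 1.007276  # mass of H+, Da

# Modification mass deltas, Da (Unimod monoisotopic).
MOD_MASS: dict[str, float] = {
    "un": 0.0,
    "me1": 14.015650,   # methyl
    "me2": 28.031300,   # dimethyl
    "me3": 42.046950,   # trimethyl
    "ac": 42.010565,    # acetyl
    "pr": 56.026215,    # propionyl (derivatization)
}

# Modification codes a residue may carry in a library definition.
KNOWN_CODES = frozenset(MOD_MASS) - {"pr"}
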