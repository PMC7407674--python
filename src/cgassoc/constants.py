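"""Residue-level parameter tables and physical constants.

Charges live on the side-chain functional center (SC site); hydropathies are
the Kyte-Doolittle scale.  Energies throughout the package are in units of kT
at 298.15 K, lengths in Angstrom, times in ns.
"""

from __future__ import annotations

import numpy as np
from scipy import constants as _const

#: The 20 standard amino acids, alphabetical by three-letter code.  This order
#: fixes the row/column layout of every 20x20 table in the package.
AMINO_ACIDS: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Kyte-Doolittle hydropathy scores (dimensionless, in [-4.5, 4.5];
#: positive = hydrophobic).
KYTE_DOOLITTLE: dict[str, float] = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5,
    "MET": 1.9, "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8,
    "TRP": -0.9, "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5,
    "GLN": -3.5, "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}

#: Integer side-chain charges (elementary-charge units) at neutral pH,
#: assigned at the SC site.  Residues not listed are neutral.  HIS defaults
#: to 0 but can be overridden when building a protein.
RESIDUE_CHARGE: dict[str, float] = {
    "ASP": -1.0, "GLU": -1.0, "LYS": 1.0, "ARG": 1.0, "HIS": 0.0,
}

#: Common non-standard residue names mapped to their standard parent.
NONSTANDARD_ALIASES: dict[str, str] = {
    "MSE": "MET", "SEC": "CYS", "CSO": "CYS", "CME": "CYS",
    "SEP": "SER", "TPO": "THR", "PTR": "TYR",
    "HSD": "HIS", "HSE": "HIS", "HSP": "HIS",
    "MLY": "LYS", "KCX": "LYS", "LLP": "LYS",
    "HYP": "PRO", "CGU": "GLU", "PCA": "GLU",
}

#: Backbone heavy-atom names; everything else (non-hydrogen) belongs to the
#: side chain for the purposes of the functional-center centroid and the
#: 5.5 A interface-contact criterion.
BACKBONE_ATOMS: frozenset[str] = frozenset({"N", "CA", "C", "O", "OXT"})

#: Simulation reference temperature (K).
TEMPERATURE_K: float = 298.15

#: kT at the reference temperature, Joule.
KT_JOULES: float = _const.k * TEMPERATURE_K

#: e^2 / (4 pi eps0 kT) in Angstrom: the Coulomb energy of two unit charges
#: at distance r (A) in vacuum is COULOMB_KT_A / r, in kT units.
COULOMB_KT_A: float = _const.e**2 / (4.0 * np.pi * _const.epsilon_0 * KT_JOULES) * 1e10

#: Dynamic viscosity of water at 298 K, Pa s.
WATER_VISCOSITY_PA_S: float = 8.9e-4
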