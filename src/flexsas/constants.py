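"""Physical constants and consensus residue tables.

Masses are average (isotope-abundance weighted) residue masses, i.e. the
monomer mass minus one water of condensation.  Volumes are consensus
crystallographic residue volumes in A^3; partial specific volumes are in
ml/g.  The carbohydrate entries follow the same conventions (glycosidic
water already removed).
"""

from __future__ import annotations

#: molar mass of water, g/mol
WATER_MASS = 18.0153

#: electrostricted volume of one protein-bound water molecule, nm^3
BOUND_WATER_VOLUME = 0.0245

#: default hydration, g water per g glycoprotein
DEFAULT_HYDRATION = 0.3

#: Avogadro constant, 1/mol
AVOGADRO = 6.02214076e23

#: Boltzmann constant, erg/K (CGS, to pair with poise and cm)
BOLTZMANN_CGS = 1.380649e-16

# ---------------------------------------------------------------------------
# amino acids (one-letter code)
# ---------------------------------------------------------------------------

#: average residue masses, Da
RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

#: consensus crystallographic residue volumes, A^3
RESIDUE_VOLUME = {
    "A": 100.3, "R": 192.8, "N": 135.2, "D": 113.6, "C": 105.6,
    "Q": 161.1, "E": 140.2, "G": 71.7, "H": 167.3, "I": 168.8,
    "L": 167.9, "K": 170.0, "M": 170.8, "F": 203.4, "P": 122.3,
    "S": 100.7, "T": 127.6, "W": 237.6, "Y": 205.3, "V": 141.7,
}

#: residue partial specific volumes, ml/g
RESIDUE_VBAR = {
    "A": 0.748, "R": 0.666, "N": 0.619, "D": 0.579, "C": 0.631,
    "Q": 0.674, "E": 0.643, "G": 0.632, "H": 0.670, "I": 0.884,
    "L": 0.884, "K": 0.789, "M": 0.708, "F": 0.774, "P": 0.774,
    "S": 0.613, "T": 0.689, "W": 0.734, "Y": 0.712, "V": 0.847,
}

#: molar extinction coefficients at 280 nm, 1/(M cm)
EXTINCTION_280 = {"W": 5500.0, "Y": 1490.0, "cystine": 125.0}

# ---------------------------------------------------------------------------
# monosaccharides
# ---------------------------------------------------------------------------

#: average glycosyl residue masses, Da
SUGAR_MASS = {
    "Gal": 162.141, "Man": 162.141, "Glc": 162.141, "Fuc": 146.143,
    "GlcNAc": 203.195, "GalNAc": 203.195, "NeuNAc": 291.255,
}

#: glycosyl residue volumes, A^3
SUGAR_VOLUME = {
    "Gal": 166.8, "Man": 170.8, "Glc": 171.9, "Fuc": 160.8,
    "GlcNAc": 222.0, "GalNAc": 232.9, "NeuNAc": 326.3,
}

#: glycosyl partial specific volumes, ml/g
SUGAR_VBAR = {
    "Gal": 0.607, "Man": 0.607, "Glc": 0.607, "Fuc": 0.671,
    "GlcNAc": 0.666, "GalNAc": 0.666, "NeuNAc": 0.584,
}

# ---------------------------------------------------------------------------
# solvents (20 degC)
# ---------------------------------------------------------------------------

#: named solvent presets: density g/ml, viscosity poise
SOLVENTS = {
    # pure water at 20 degC -- the s0(20,w) standard state
    "water20": {"density": 0.99823, "viscosity": 0.010016},
    # phosphate-buffered saline in light water at 20 degC
    "pbs": {"density": 1.00543, "viscosity": 0.010190},
    # the same PBS prepared in heavy water
    "pbs_d2o": {"density": 1.11238, "viscosity": 0.010190},
}

# ---------------------------------------------------------------------------
# peptide backbone geometry (Engh-Huber style ideal values)
# ---------------------------------------------------------------------------

BOND_N_CA = 1.458   # A
BOND_CA_C = 1.525   # A
BOND_C_N = 1.329    # A
ANGLE_N_CA_C = 111.2    # deg
ANGLE_CA_C_N = 116.2    # deg
ANGLE_C_N_CA = 121.7    # deg
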