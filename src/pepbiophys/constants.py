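"""Physical constants and reference data shared across the package.

All thermodynamic quantities use the calorie convention (cal, kcal) common
in the peptide-folding literature; the gas constant is therefore in
cal mol^-1 K^-1.
"""

#: Gas constant, cal mol^-1 K^-1.
R_CAL = 1.9872

#: 1H gyromagnetic ratio, rad s^-1 T^-1.
GAMMA_H = 2.6752e8

#: Mean-residue ellipticity of a fully formed alpha-helix at 222 nm,
#: deg cm^2 dmol^-1.  Used as the 100%-helix reference.
THETA_HELIX_222 = -39500.0

#: Hydrodynamic radius of 1,4-dioxane, Å (internal DOSY reference).
DIOXANE_RH_A = 2.12

#: Default temperature for CD population calculations (5 °C), K.
T_CD_K = 278.15

#: Default ITC experiment temperature (25 °C), K.
T_ITC_K = 298.15

#: Average (isotope-weighted) residue masses, Da.  These are masses of the
#: amino-acid *residues* (monomer minus water); one water is added per chain.
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788,
    "R": 156.1875,
    "N": 114.1038,
    "D": 115.0886,
    "C": 103.1388,
    "E": 129.1155,
    "Q": 128.1307,
    "G": 57.0519,
    "H": 137.1411,
    "I": 113.1594,
    "L": 113.1594,
    "K": 128.1741,
    "M": 131.1926,
    "F": 147.1766,
    "P": 97.1167,
    "S": 87.0782,
    "T": 101.1051,
    "W": 186.2132,
    "Y": 163.1760,
    "V": 99.1326,
}

#: Average mass of water, Da.
WATER_AVG_MASS = 18.01524

#: Mass added by N-terminal acetylation (CH3CO- replacing H-), Da.
ACETYL_MASS_DELTA = 42.04

#: Mass change from C-terminal amidation (-NH2 replacing -OH), Da.
AMIDE_MASS_DELTA = -0.98

#: Molar extinction coefficients at 280 nm, M^-1 cm^-1.
EPS280_TRP = 5500.0
EPS280_TYR = 1490.0
EPS280_CYSTINE = 125.0

#: Empirical mass scaling law for the hydrodynamic radius of a disordered
#: chain: Rh[nm] = RH_SCALING_COEF * MW**RH_SCALING_EXP.
RH_SCALING_COEF_NM = 0.027
RH_SCALING_EXP = 0.50
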