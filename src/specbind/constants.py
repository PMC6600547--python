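"""Physical constants and serum-albumin defaults used across the pipeline.

Energies are kept in kcal mol^-1 throughout, concentrations in molar, and
temperatures in Kelvin; the gas constant below is in matching units.
"""

#: Gas constant, kcal mol^-1 K^-1.
R_KCAL: float = 1.9872e-3

#: Unquenched fluorescence lifetime of HSA (Trp214), seconds.
TAU0_HSA: float = 5.71e-9

#: Diffusion-controlled quenching limit, M^-1 s^-1. Bimolecular quenching
#: constants well above this indicate ground-state (static) complex formation.
DIFFUSION_LIMIT: float = 2e10

#: FRET orientation factor for isotropically averaged dipoles.
KAPPA2_DEFAULT: float = 2.0 / 3.0

#: Refractive index of aqueous buffer used in the Forster-radius expression.
N_REFRACTIVE_DEFAULT: float = 1.33

#: Fluorescence quantum yield of the HSA tryptophan donor.
PHI_DONOR_DEFAULT: float = 0.118

#: Prefactor of the Forster-radius relation R0^6 = C * kappa^2 * n^-4 * Phi * J
#: with J in M^-1 cm^3 and R0 emerging in cm.
FORSTER_PREFACTOR: float = 8.79e-25

#: Mean residue weight of HSA, g mol^-1 (66,437 Da over 585 residues).
MRW_HSA: float = 113.6

#: Molar mass of HSA, g mol^-1.
HSA_MOLAR_MASS: float = 66437.0

#: Chen-method constants for %alpha-helix from mean residue ellipticity at
#: 222 nm: helix% = 100 * (-MRE222 - CHEN_OFFSET) / CHEN_SCALE.
CHEN_OFFSET: float = 2340.0
CHEN_SCALE: float = 30300.0
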