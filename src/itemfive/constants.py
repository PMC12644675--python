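"""Physical constants and mass conventions used across the package.

All masses are in unified atomic mass units (u) unless noted; SI constants
follow the 2019 redefinition (exact values).
"""

# Mass of a proton charge carrier added on protonation, in u.
PROTON_MASS = 1.00728

# Monoisotopic mass of water (added on peptide-bond hydrolysis / condensation).
WATER_MONO = 18.010565

# Replacing the C-terminal OH by NH2 (carboxamide) shifts the monoisotopic
# mass by -0.98402 u.
AMIDE_SHIFT = -0.98402

# SI constants (exact, 2019 SI).
ELEMENTARY_CHARGE = 1.602176634e-19  # C
BOLTZMANN = 1.380649e-23             # J/K
PLANCK = 6.62607015e-34              # J s
GAS_CONSTANT = 8.314462618           # J/(mol K)
AVOGADRO = 6.02214076e23             # 1/mol

# Neutral gas masses in u.
GAS_MASSES = {
    "argon": 39.948,
    "nitrogen": 28.0134,
    "helium": 4.002602,
}
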