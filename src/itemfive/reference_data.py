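"""Published study inputs for the T4 fibritin trimerization-domain series.

The T4 phage fibritin C-terminal trimerization domain ("foldon", T4Ff) is a
27-residue miniprotein forming an obligate homo-trimer.  A published series
of chemically engineered variants probes trimer stability: variants 1-6
carry a C-terminal carboxamide and D-amino acids at positions 10 and 17
(lowercase), variants 2-6 have altered N-termini (variant 2: D-Tyr2;
variants 3-6: Gly1 removed), and variants 5/6 replace Tyr2 by non-natural
residues with enlarged aromatic side chains (Nal = 3-(2-naphthyl)alanine,
Dip = 3,3-diphenylalanine) enabling interchain pi-stacking.

These sequences, the published half-dissociation voltages, and the
ambient-temperature reference thermodynamics are study inputs of the
analysis pipeline, analogous to a mobility calibrant table: the sequences
define target ion positions, and the reference enthalpy/entropy pair of the
parent trimer anchors the instrument-dependent constants of the
voltage-to-temperature and rate normalizations (see
:func:`itemfive.thermo.calibrate_conditions`).
"""

from __future__ import annotations

#: Monomer sequences of the trimerizing peptide series.  Lowercase letters
#: are D-amino acids; brace tokens are non-natural residues.
SEQUENCES = {
    "T4Ff": "H-GYIPEAPRDGQAYVRKDGEWVLLSTFL-OH",
    "variant1": "H-GYIPEAPRDaQAYVRKfGEWVLLSTFL-NH2",
    "variant2": "H-GyIPEAPRDaQAYVRKfGEWVLLSTFL-NH2",
    "variant3": "H-YIPEAPRDaQAYVRKfGEWVLLSTFL-NH2",
    "variant4": "H-yIPEAPRDaQAYVRKfGEWVLLSTFL-NH2",
    "variant5": "H-{Nal}IPEAPRDaQAYVRKfGEWVLLSTFL-NH2",
    "variant6": "H-{Dip}IPEAPRDaQAYVRKfGEWVLLSTFL-NH2",
}

#: Published half-dissociation voltages (V) of the trimer 5+ precursor for
#: the variants whose midpoints are reported explicitly.
DCV50 = {
    "T4Ff": 13.5,
    "variant1": 11.0,
    "variant6": 13.4,
}

#: Ambient temperature (K) consistent with the published relation between
#: the extrapolated rate constant, equilibrium-type constant and free
#: energy of the reference trimer.
AMBIENT_TEMPERATURE = 295.0

#: Published ambient-extrapolated ("m0g") quantities per analyte:
#: (k#, KD#, dG# kJ/mol, dH# kJ/mol, T_amb dS# kJ/mol).
REFERENCE_THERMO = {
    "T4Ff": (3.61e8, 5.81e-5, 23.9, 63.9, 40.0),
    "variant1": (6.61e9, 1.06e-3, 16.5, 51.8, 35.3),
    "variant2": (3.60e9, 5.80e-4, 18.5, 56.3, 37.8),
    "variant3": (2.64e9, 4.25e-4, 19.1, 56.7, 37.6),
    "variant4": (1.17e9, 1.89e-4, 21.2, 60.0, 38.8),
    "variant5": (1.22e9, 1.97e-4, 21.1, 61.1, 40.0),
    "variant6": (3.47e8, 5.60e-5, 24.6, 66.8, 42.2),
}

#: Reference (dH#, T_amb dS#) pair of the parent trimer used to solve the
#: instrument constants.
CALIBRATION_REFERENCE = ("T4Ff", 63.9, 40.0)
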