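"""Physical constants and study-wide defaults.

All energies are in calorie units (cal or kcal per mole), matching the
conventions of peptide helix-coil and calorimetric analyses.
"""

#: Gas constant in cal mol^-1 K^-1 (helix-coil free energies).
R_CAL = 1.987

#: Gas constant in kcal mol^-1 K^-1 (calorimetric free energies).
R_KCAL = 1.987e-3

#: Mean residue ellipticity of a 100% helical peptide at 222 nm,
#: deg cm^2 dmol^-1 residue^-1.
MRE_FULL_HELIX = -31500.0

#: Mean Halpha conformational shift of a fully formed helix, ppm.
FULL_HELIX_SHIFT_PPM = -0.39

#: |Δδ| range (ppm) commonly accepted for random-coil peptides.
RANDOM_COIL_THRESHOLD_PPM = 0.1

#: CD / TFE-titration temperature (5 °C).
T_CD_K = 278.15

#: Binding-experiment temperature (fluorescence, stopped-flow, ITC; 15 °C).
T_BINDING_K = 288.15
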