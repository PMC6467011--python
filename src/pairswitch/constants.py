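"""Physical constants used throughout the package.

Energies are in kcal/mol, temperatures in Kelvin, entropies in
entropy units (eu, cal mol^-1 K^-1) at the user surface and in
kcal mol^-1 K^-1 internally.
"""

#: Boltzmann constant, kcal mol^-1 K^-1 (molar gas constant).
KB_KCAL_MOL_K: float = 1.987e-3

#: Euler–Mascheroni constant, appears in the transition-path-time formula.
EULER_GAMMA: float = 0.5772156649

#: Conversion factor: entropy units (cal mol^-1 K^-1) per kcal mol^-1 K^-1.
EU_PER_KCAL_MOL_K: float = 1000.0
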