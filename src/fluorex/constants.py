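"""Physical constants and experiment-wide defaults.

Values are the conventions used throughout the package: the gas constant in
kcal units (so free energies come out in kcal/mol, the unit conformational
NMR papers print) and the default sample temperature of 25 degC.
"""

#: Gas constant, kcal mol^-1 K^-1.
R_KCAL: float = 1.9872e-3

#: Default absolute temperature, K (25 degC).
T_DEFAULT: float = 298.15

#: Default CPMG constant-time relaxation delay, s.
T_CPMG_DEFAULT: float = 3.84e-3

#: Default 19F spectrometer frequencies, MHz (14.1 T and 16.4 T magnets).
FIELDS_DEFAULT: tuple[float, float] = (564.0, 659.0)
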