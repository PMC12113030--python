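"""Physical constants and package-wide defaults.

All kinetic quantities are handled internally in ns (time) and Å
(length); rate matrices are expressed in μs⁻¹ to match the conventional
reporting scale for peptide hydrogen-bond kinetics.
"""

# Gas constant, kcal mol^-1 K^-1
R_KCAL: float = 0.0019872

# Boltzmann constant, J K^-1
KB_J: float = 1.380649e-23

# Hydrogen-bond weight cutoffs on the O...N donor-acceptor distance, Å.
# A helical i -> i+4 bond counts fully formed below HB_FORMED_CUTOFF and
# fully broken above HB_BROKEN_CUTOFF; in between a cubic ramp applies.
HB_FORMED_CUTOFF: float = 3.2
HB_BROKEN_CUTOFF: float = 4.0

# Default simulation / analysis temperature, K
DEFAULT_TEMPERATURE: float = 300.0

# Temperature used for free-energy profiles of microstate populations, K
PROFILE_TEMPERATURE: float = 298.0

# Helix rise per residue, Å: the elementary step of the boundary-diffusion
# picture (one hydrogen bond gained ~ one residue of helix grown).
HELIX_RISE_ANGSTROM: float = 1.5

# Weight threshold separating a "formed" from a "broken" bond when
# continuous weights are collapsed to 0/1 pattern strings.
PATTERN_THRESHOLD: float = 0.5
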