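"""Physical and empirical constants used across the package.

Collected here so that every conversion coefficient is visible (and, where a
config supports it, overridable) in one place.
"""

#: Chlorophyll-a extract coefficient, ug chl a per mL of ethanol extract per
#: unit of (A665 - A750) absorbance difference, 1-cm path.
CHLA_COEF_UG_PER_ML = 11.904

#: Molar masses, g mol-1.
O2_MOLAR_MASS = 32.0
C_MOLAR_MASS = 12.0

#: PSS-78 practical-salinity validity range (psu).
PSS78_VALID_SALINITY = (2.0, 42.0)

#: Validity window enforced for the O2 solubility fits.
SOLUBILITY_VALID_T = (-2.0, 40.0)
SOLUBILITY_VALID_S = (0.0, 60.0)

#: Default reference depth of the continuous PAR logger (m).
DEFAULT_REFERENCE_DEPTH = 0.3

#: PAR threshold defining dawn/dusk in a reference-depth series
#: (umol photons m-2 s-1).
DEFAULT_LIGHT_THRESHOLD = 1.0

#: Default Schmidt-number exponent for gas-transfer scaling (unitless);
#: -0.5 is the standard choice for a wavy, unbroken surface.
DEFAULT_SCHMIDT_EXPONENT = -0.5

#: Default AWCD evaluation time for EcoPlate kinetics (h).
DEFAULT_AWCD_TIME_H = 96.0
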