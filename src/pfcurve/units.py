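"""Unit conversions between the package's working units and SI.

Working units throughout the package: pressure in mmHg, flow in ml/s,
length in mm, area in mm^2, viscosity in cP, density in kg/m^3.
All conversions to and from SI are centralized here so that the two
loss-coefficient integrals and the network solver share one definition
of the mmHg.
"""

MMHG_PER_PA = 1.0 / 133.322
PA_PER_MMHG = 133.322

CP_TO_PA_S = 1.0e-3     # 1 cP = 1 mPa.s
MM_TO_M = 1.0e-3
MM2_TO_M2 = 1.0e-6
ML_TO_M3 = 1.0e-6

# 1 mmHg.s/ml expressed in Pa.s/m^3
LINEAR_COEFF_SI_PER_WORKING = PA_PER_MMHG / ML_TO_M3        # 1.33322e8
# 1 mmHg.s^2/ml^2 expressed in Pa.s^2/m^6
QUAD_COEFF_SI_PER_WORKING = PA_PER_MMHG / ML_TO_M3 ** 2     # 1.33322e14


def linear_coeff_to_working(value_si: float) -> float:
    """Convert a linear resistance coefficient from Pa.s/m^3 to mmHg.s/ml."""
    return value_si / LINEAR_COEFF_SI_PER_WORKING


def quadratic_coeff_to_working(value_si: float) -> float:
    """Convert a quadratic loss coefficient from Pa.s^2/m^6 to mmHg.s^2/ml^2."""
    return value_si / QUAD_COEFF_SI_PER_WORKING
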