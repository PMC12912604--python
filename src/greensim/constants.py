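"""Physical constants and moist-air caloric reference used throughout.

Caloric dialect: ideal-gas mixture with constant per-species specific
heats, enthalpy reference at 0 °C for the sensible part, and the latent
heat of vaporisation attached to the vapour species at the reference.
"""

# Universal
SIGMA_SB = 5.67e-8        # Stefan-Boltzmann constant, W m-2 K-4
R_GAS = 8.314             # universal gas constant, J mol-1 K-1
GRAVITY = 9.81            # m s-2

# Molar masses, kg mol-1
M_DRY_AIR = 0.02897
M_WATER = 0.018015
M_CO2 = 0.04401

# Specific gas constants, J kg-1 K-1
R_DRY_AIR = R_GAS / M_DRY_AIR     # 287.0
R_WATER = R_GAS / M_WATER         # 461.5
R_CO2 = R_GAS / M_CO2

# Specific heats (constant-pressure), J kg-1 K-1
CP_DRY_AIR = 1005.0
CP_WATER_VAPOR = 1860.0
CP_CO2 = 846.0
CP_LIQUID_WATER = 4186.0

# Constant-volume specific heats (ideal gas: cv = cp - R_i)
CV_DRY_AIR = CP_DRY_AIR - R_DRY_AIR
CV_WATER_VAPOR = CP_WATER_VAPOR - R_WATER
CV_CO2 = CP_CO2 - R_CO2

# Latent heat of vaporisation at the 0 degC reference, J kg-1
LATENT_HEAT_VAPORIZATION = 2.501e6

# Enthalpy/energy reference
T_REF_K = 273.15          # 0 degC

# Lewis number for water vapour in air (used in the heat/mass analogy)
LEWIS_NUMBER = 0.87

# Ratio of molar masses water/dry air (psychrometric 0.622)
EPS_W = M_WATER / M_DRY_AIR

# Conventional PAR share of global solar irradiance
PAR_FRACTION = 0.5
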