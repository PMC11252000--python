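"""Physical constants, centralised so no module carries magic numbers.

Values follow CODATA to the precision needed for assay-scale arithmetic.
"""

#: Faraday constant, C·mol⁻¹ (charge per mole of elementary charges).
FARADAY = 96485.332

#: Molar gas constant, J·mol⁻¹·K⁻¹.
GAS_CONSTANT = 8.314462

#: Default recording temperature, K (room temperature, 20 °C).
ROOM_TEMPERATURE_K = 293.15

#: Monoisotopic mass of a proton, Da (for [M+H]+ adducts).
PROTON_MASS = 1.00727646688

#: Monoisotopic mass of water, Da (condensation of two residues).
WATER_MASS = 18.0105646863

#: Default calibration slope of the intracellular pH microelectrode, mV per
#: pH unit (Nernstian response of a H+-selective electrode at ~20 °C).
ELECTRODE_SLOPE_MV_PER_PH = -59.0

#: Reference-current validity threshold for the acidification/current ratio
#: statistic, nA: proportionality between acidification slope and proton
#: influx only holds above roughly this current magnitude.
CURRENT_THRESHOLD_NA = 100.0
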