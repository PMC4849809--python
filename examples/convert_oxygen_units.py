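"""Convert a literature Pcrit value between oxygen units.

Published critical-oxygen levels appear in five units; comparing them
requires the water temperature and salinity, because concentration <->
partial-pressure conversion runs through the O2 solubility coefficient.
"""

from respcrit import OxygenQuantity, WaterConditions, convert_o2, o2_solubility

cond = WaterConditions(temperature=15.0, salinity=35.0)
c_sat, beta = o2_solubility(cond)
print(f"Air-saturated O2 at 15 degC / 35 PSU: {c_sat:.2f} mg/L "
      f"(beta = {beta:.4f} mg/L per kPa)")

pcrit = OxygenQuantity(38.6, "mmHg")
as_kpa = convert_o2(pcrit, "kPa", cond)
as_mgl = convert_o2(pcrit, "mg_per_L", cond)
as_sat = convert_o2(pcrit, "percent_air_saturation", cond)
print(f"A Pcrit reported as {pcrit.value} mmHg is {as_kpa.value:.2f} kPa, "
      f"{as_mgl.value:.2f} mg/L, or {as_sat.value:.1f}% air saturation.")
print("The kPa figure is the common currency used throughout the database "
      "analyses; the mg/L figure additionally depends on salinity through "
      "the solubility, which is why partial-pressure and concentration "
      "comparisons can disagree.")
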