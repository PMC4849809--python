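"""How much CO2 builds up in a closed respirometer, and what controls it.

A fish depleting O2 from air saturation (~20.9 kPa) to a typical Pcrit of
~6 kPa excretes roughly 140 umol/kg of CO2 (respiratory quotient 0.85).
The final pCO2 this produces depends dramatically on the starting pH and
salinity of the water, because they set the total alkalinity available to
buffer the added CO2.
"""

from respcrit import (
    RespirometerCO2Scenario,
    WaterConditions,
    delta_dic_from_o2,
    respirometer_co2_model,
)

dd = delta_dic_from_o2(20.9, 6.0, 0.85, WaterConditions(15.0, 35.0))
print(f"DIC added by respiration 20.9 -> 6 kPa at RQ 0.85: {dd:.0f} umol/kg "
      "(the scenario's round figure is 140)")

res = respirometer_co2_model(RespirometerCO2Scenario())
sal = res.scenario.salinity
print("\nfinal pCO2 (uatm) by starting pH (rows) and salinity (columns)")
print("pH    " + "".join(f"S={s:<7.0f}" for s in sal))
for i, ph in enumerate(res.scenario.start_ph):
    print(f"{ph:4.2f}  " + "".join(f"{res.final_pco2[i, j]:<9.0f}" for j in range(len(sal))))

print("\nStarting from atmospheric equilibrium (395 uatm), the same respired "
      "CO2 drives pCO2 anywhere from ~640 to ~3550 uatm: low-pH, low-salinity "
      "water has the least alkalinity and buffers worst. Closed-respirometry "
      "Pcrit trials therefore expose fish to strongly water-dependent "
      "hypercapnia unless the chemistry is reported and controlled.")
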