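# Default model parameters.
#
# Pressures are CGS (dyn/cm^2) except where a key says mmHg; resistances are
# dyn*s/cm^5. Activity-state distal resistances must stay inside the
# achievable range 50,000-300,000 dyn*s/cm^5 and decrease from rest (R)
# through light (E1) to moderate (E2) exercise.

[hemodynamic]
viscosity_poise = 0.037
mean_aortic_pressure_dyn_cm2 = 133322.0   # 100 mmHg
cardiac_period_s = 0.8                    # 75 bpm
total_input_flow_cc_s = 8.33
material_area_compliance_mm2_mmhg = 0.0975
compliance_mode = "per_segment"

[chamber]
P0_mmHg = 760.0     # 1 atm trapped-air reference
V0_mm3 = 44000.0    # air-cup volume
Ps_mmHg = 120.0
Pd_mmHg = 80.0

[chamber.inherent_resistance_dyn_s_cm5]
LAD = 1671.0
LCX = 1820.0
RCA = 591.0

[activity.R]
LAD = 250000.0
LCX = 250000.0
RCA = 250000.0

[activity.E1]
LAD = 120000.0
LCX = 120000.0
RCA = 120000.0

[activity.E2]
LAD = 60000.0
LCX = 60000.0
RCA = 60000.0
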