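# Mouse whole-body physiology for the 8-compartment cell-kinetic model.
# Units: body_weight kg; volumes L; flows L/h. Tissue density 1 kg/L assumed.
#
# Provenance: organ volume fractions and regional flow fractions transcribed
# from the standard reference compilations for PBPK parameterisation
# (Brown et al. 1997, Toxicol Ind Health 13:407; Davies & Morris 1993,
# Pharm Res 10:1093). Vascular (residual-blood) fractions of organ volume
# from the rodent blood-content tables in the same compilations.
# The rest-of-body compartment closes the mass and flow balances.
species: mouse
body_weight: 0.025
# Free blood pools (exchangeable arterial/venous blood outside organ beds);
# total blood ~0.085 L/kg less the blood resident in organ vascular spaces.
arterial_blood_volume: 0.0005
venous_blood_volume: 0.0010
# Cardiac output ~14 mL/min for a 25 g mouse (Davies & Morris 1993).
cardiac_output: 0.84
organs:
  lung:
    # 0.73% of BW; vascular fraction 0.50; perfused by total cardiac output.
    total_volume: 1.825e-4
    vascular_volume: 9.125e-5
    blood_flow: 0.84
  liver:
    # 5.49% of BW; vascular fraction 0.31.
    # blood_flow is the hepatic-artery inflow (15% of CO); the splenic
    # outflow (1.1% of CO) joins it so total hepatic perfusion is 16.1% of CO.
    total_volume: 1.3725e-3
    vascular_volume: 4.25475e-4
    blood_flow: 0.1260
  spleen:
    # 0.35% of BW; vascular fraction 0.17; flow 1.1% of CO (splanchnic inlet).
    total_volume: 8.75e-5
    vascular_volume: 1.4875e-5
    blood_flow: 0.00924
  kidney:
    # 1.67% of BW; vascular fraction 0.24; flow 9.1% of CO.
    total_volume: 4.175e-4
    vascular_volume: 1.002e-4
    blood_flow: 0.07644
  heart:
    # 0.50% of BW; vascular fraction 0.26; flow 6.6% of CO.
    total_volume: 1.25e-4
    vascular_volume: 3.25e-5
    blood_flow: 0.05544
  rest_of_body:
    # Residual mass (carcass incl. muscle, skin, bone, gut, brain);
    # vascular fraction 0.02; residual flow closing the arterial balance.
    total_volume: 0.0213
    vascular_volume: 4.26e-4
    blood_flow: 0.57288
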