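# Human whole-body physiology for the 8-compartment cell-kinetic model.
# Units: body_weight kg; volumes L; flows L/h. Tissue density 1 kg/L assumed.
# Provenance: ICRP Publication 89 reference adult male (organ masses),
# Brown et al. 1997 (regional flow fractions), Davies & Morris 1993
# (blood volume, cardiac output).
species: human
body_weight: 70.0
arterial_blood_volume: 1.2
venous_blood_volume: 2.2
# Cardiac output 5.6 L/min at rest.
cardiac_output: 336.0
organs:
  lung:
    # 0.76% of BW; vascular fraction 0.50; perfused by total cardiac output.
    total_volume: 0.532
    vascular_volume: 0.266
    blood_flow: 336.0
  liver:
    # 1.8 kg; vascular fraction 0.31.
    # Hepatic-artery inflow 19.7% of CO; splenic outflow (3.0%) joins it,
    # giving 22.7% of CO total hepatic perfusion.
    total_volume: 1.82
    vascular_volume: 0.5642
    blood_flow: 66.192
  spleen:
    # 0.15 kg; vascular fraction 0.17; flow 3.0% of CO (splanchnic inlet).
    total_volume: 0.15
    vascular_volume: 0.0255
    blood_flow: 10.08
  kidney:
    # 0.31 kg (paired); vascular fraction 0.24; flow 17.5% of CO.
    total_volume: 0.31
    vascular_volume: 0.0744
    blood_flow: 58.8
  heart:
    # 0.33 kg; vascular fraction 0.26; flow 4.0% of CO (coronary).
    total_volume: 0.33
    vascular_volume: 0.0858
    blood_flow: 13.44
  rest_of_body:
    # Residual mass; vascular fraction 0.02; residual flow.
    total_volume: 63.458
    vascular_volume: 1.26916
    blood_flow: 187.488
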