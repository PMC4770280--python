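# Rat whole-body physiology for the 8-compartment cell-kinetic model.
# Units: body_weight kg; volumes L; flows L/h. Tissue density 1 kg/L assumed.
# Provenance: Brown et al. 1997 (organ volume and flow fractions) and
# Davies & Morris 1993 (blood volume, cardiac output), 250 g reference rat.
species: rat
body_weight: 0.25
arterial_blood_volume: 0.0046
venous_blood_volume: 0.0093
# Cardiac output ~80 mL/min.
cardiac_output: 4.8
organs:
  lung:
    # 0.50% of BW; vascular fraction 0.50; perfused by total cardiac output.
    total_volume: 1.25e-3
    vascular_volume: 6.25e-4
    blood_flow: 4.8
  liver:
    # 3.66% of BW; vascular fraction 0.31.
    # Hepatic-artery inflow 16.4% of CO; splenic outflow (1.0%) joins it.
    total_volume: 9.15e-3
    vascular_volume: 2.8365e-3
    blood_flow: 0.7872
  spleen:
    # 0.20% of BW; vascular fraction 0.17; flow 1.0% of CO.
    total_volume: 5.0e-4
    vascular_volume: 8.5e-5
    blood_flow: 0.048
  kidney:
    # 0.73% of BW; vascular fraction 0.24; flow 14.1% of CO.
    total_volume: 1.825e-3
    vascular_volume: 4.38e-4
    blood_flow: 0.6768
  heart:
    # 0.33% of BW; vascular fraction 0.26; flow 5.1% of CO.
    total_volume: 8.25e-4
    vascular_volume: 2.145e-4
    blood_flow: 0.2448
  rest_of_body:
    # Residual mass; vascular fraction 0.02; residual flow.
    total_volume: 0.2225
    vascular_volume: 4.45e-3
    blood_flow: 3.0432
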