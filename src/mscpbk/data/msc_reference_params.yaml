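# Reference MSC-specific kinetic parameters, estimated by curve fitting
# against mouse flow-cytometry biodistribution data (5e5 GFP-MSCs IV).
# Units: partition_coefficient unitless; rate constants h^-1.
# blood_k_depletion applies to the circulating arterial and venous pools.
name: reference
blood_k_depletion: 0.636
organs:
  lung:
    partition_coefficient: 742.733
    k_arrest: 5.434
    k_release: 0.108
    k_depletion: 0.0589
  liver:
    partition_coefficient: 262.699
    k_arrest: 1.395
    k_release: 0.066
    k_depletion: 0.060
  spleen:
    partition_coefficient: 1633.24
    k_arrest: 0.608
    k_release: 0.856
    k_depletion: 0.002
  kidney:
    partition_coefficient: 305.351
    k_arrest: 1.727
    k_release: 0.054
    k_depletion: 0.151
  heart:
    partition_coefficient: 3.097
    k_arrest: 1.251
    k_release: 0.016
    k_depletion: 0.039
  rest_of_body:
    partition_coefficient: 6.765
    k_arrest: 0.143
    k_release: 0.957
    k_depletion: 0.148
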