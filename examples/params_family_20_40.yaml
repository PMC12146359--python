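# Published base-model point estimates for gender-based family violence
# under the 20% aggressor / 40% susceptible scenario.
r_A: 0.054631
k_A: 30.325876
r_S: 0.054604
k_S: 61.712497
beta_F: 0.000028
beta_M: 0.000003
alpha_F: 0.350354
alpha_M: 0.561616
gamma_F: 0.0
delta_A: 0.0
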