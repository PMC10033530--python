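M: 20.0
Kcd: 0.01
G: 1.295
epsilon: 0.005
k_prime: 0.0856
k_rep: 0.0857
k_div: 0.0193
k_req: 0.934
theta_s: 9.89
h_s: 6
theta_d: 45.0
h_d: 8
alpha_q: 1.0
resection_fraction: 0.7
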