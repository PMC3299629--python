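# Published default parameter set, as printed (decimal strings).
tau_D: ".328"
tau_S: ".048"
tau_H: "1.620"
h_D: "-30"
h_S: "-1"
h_H: "0"
beta_D: "1.4"
beta_S: "6"
D0: "0"
S0: "0"
k_H: "7"
a: "11"
b: "4.5"
c: "1"
sigma_a: "4"
sigma_b: "7"
w_SD: "95"
beta_stim: ".07"
m: "50"
I0: "18"
n_nodes: 100
dt: "5"
threshold: ".8"
delay_exo: "70"
delay_endo: "120"
delay_motor: "80"
boundary: zero
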