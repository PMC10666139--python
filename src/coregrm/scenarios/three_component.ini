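[column]
eps_b = 0.4
eps_p = 0.5
core_fraction = 0.0
xi_inj = 1.0

[numerics]
n_x = 100
n_r = 80
order = 2
gamma_reg = 1e-10
cfl_safety = 0.5
t_end = 220.0
dxi_out = 0.05

[components.1]
pe = 1500.0
bi = 50.0
eta = 2.0
a1 = 10.0
a2 = 15.0
b1 = 0.5
b2 = 1.0
c_inj = 1.0

[components.2]
pe = 1500.0
bi = 50.0
eta = 2.0
a1 = 30.0
a2 = 35.0
b1 = 1.5
b2 = 2.0
c_inj = 1.0

[components.3]
pe = 1500.0
bi = 50.0
eta = 2.0
a1 = 70.0
a2 = 75.0
b1 = 3.0
b2 = 3.5
c_inj = 1.0

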