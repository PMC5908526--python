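backend = "fcm"
master_seed = 0

[physical]
a = 3.0
d = 70.1
Sp = 12.0
K_B = 1800.0
K0_l = 12.76
eta = 1.0
F_S_over_d = 47.12388980384689
sigma_ratio = 0.0
steps_per_period = 300
gamma_tip = 0.13

[grid]
n_inplane = 3072
n_z = 64
L_z = 19.4

[suspension]
N = 1
init_mode = "solitary"
delta_phi = 0.0
pair_offset = [0.0, 0.3]

[solver]
broyden_tol = 1e-08
broyden_maxit = 400
constraint_tol_factor = 1e-08

[output]
n_periods = 30.0
n_flag = 29
snapshot_every = 10
out_path = "trajectory.h5"
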