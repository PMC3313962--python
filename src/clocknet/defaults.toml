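# Default configuration: one clock neuron's kinetic constants plus the
# network, coupling and protocol settings.  Values not listed in a user
# config fall back to these.

[params]
vs = 0.50    # max transcription rate, nM/h
vm = 0.35    # max mRNA degradation rate, nM/h
Km = 0.20    # mRNA degradation Michaelis constant, nM
ks = 2.00    # translation rate constant, 1/h
V1 = 6.00    # max phosphorylation P0->P1, nM/h
K1 = 1.50    # its Michaelis constant, nM
V2 = 3.00    # max dephosphorylation P1->P0, nM/h
K2 = 2.00    # its Michaelis constant, nM
V3 = 6.00    # max phosphorylation P1->P2, nM/h
K3 = 1.50    # its Michaelis constant, nM
V4 = 3.00    # max dephosphorylation P2->P1, nM/h
K4 = 2.00    # its Michaelis constant, nM
k1 = 2.00    # nuclear entry rate constant, 1/h
k2 = 1.00    # nuclear exit rate constant, 1/h
vd = 2.85    # max non-photic degradation of P2, nM/h (scans cover [2.7, 3.0])
Kd = 0.10    # its Michaelis constant, nM
KI = 1.50    # repression threshold, nM
n = 4        # Hill exponent, dimensionless
dL = 4.00    # light-induced degradation of P2, 1/h (scans cover [0.2, 8.5])

[network]
N = 50             # neuron count
sigma = 0.05       # multiplicative noise amplitude (calibrated default)
dt = 0.0016666666666666668   # integrator step: 0.1 min in hours
seed = 0
ic_sd = 1.0        # initial phase dispersion, h
record_every = 0.1 # output sampling interval, h
burn_days = 10     # noise-free LD burn-in of the reference clock

[modulation]
targets = []       # subset of ["k1_up", "k2_down", "vd_up", "vd_down"]
gain_k1 = 2.0      # per nM
gain_k2 = 2.0      # per nM
gain_vd = 2.0      # per nM

[protocol]
ld_days = 9
dd_days = 7
photoperiod_on = 12.0  # h of light per LD day
day_length = 24.0      # h
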