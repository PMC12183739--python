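# Example experiment configuration for `spinpair run --config ...`
# Flat key = value; units are carried in the key names.

fixture = toy            # toy | fourteen, or system_file = path/to/system.txt
method = direct          # direct (Z <= 1000) | sse
noise = broadband        # none | mono | broadband | file

# broadband noise parameters
sigma_delta = 0.1        # fractional modulation SD
n_components = 1000
band_MHz = 0 200
seed = 1

# optional conditioning (applied to the generated/loaded trajectories)
# nu_cutoff_MHz = 200
# decimation_factor = 10

# propagation and scan
dt_ns = 0.5
T_us = 5.0
theta_points = 33
B_mT = 0.05
k_per_s = 1e6
# M = 96                 # SSE sample count (method = sse)
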