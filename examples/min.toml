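# Min oscillations on a rod-shaped cell, exact NSM solver.
#   rdme run -c examples/min.toml
# Switch to the approximate solver with:
#   rdme run -c examples/min.toml --solver dfsp
model = "min"
solver = "nsm"
seed = 1
output = "min_trajectory.h5"

[mesh]
kind = "capsule"
length = 4.5   # um
radius = 0.5   # um
h = 0.3        # target edge length, um

[tspan]
t_end = 300.0  # s
dt = 1.0       # s

[dfsp]          # used only with --solver dfsp
tau = 0.05      # macro time-step tau_D, s
max_jump = 10
tol = 1e-3
cache_path = ".dfsp_cache"
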