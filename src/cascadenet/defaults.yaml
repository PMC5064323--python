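# Published constants of the cascading-adaptation network model.
g: 1.8        # feedforward gain
tau_m: 30.0   # membrane time constant, ms
alpha: 200.0  # rate-function saturation, Hz
beta: 1.0     # rate-function slope
theta: 6.0    # rate-function threshold, potential units
tau_S: 200.0  # STD recovery time constant, ms
tau_r: 200.0  # retinal-adaptation recovery time constant, ms
f_S: 0.75     # STD utilization fraction
f_r: 0.75     # retinal-adaptation depression fraction
A: 60.0       # stimulus peak optical strength
sigma1: 1.5   # retina->LGN tuning width, position units
sigma2: 1.5   # LGN->V1 tuning width, position units
N: 1000       # neurons per layer
L: 10.0       # half-width of the position domain
# Implementation-owned values (not among the published constants):
sigma_O: 1.5  # stimulus Gaussian width; defaults to sigma1
w_sum: 0.8    # summed feedforward weight per neuron (row normalization)
dt: 0.1       # integration step, ms
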