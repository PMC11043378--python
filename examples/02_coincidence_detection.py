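"""The coincidence-detection primitive: lag sweep on a programmed network.

Channel 1 feeds four dendritic circuits with delays 21/35/48/58 ms; the
58 ms synapse carries a high weight, the rest are low.  Channel 2 passes
through a near-zero-delay reference synapse.  The output LIF neuron's peak
membrane is maximal — and only crosses threshold — when the channel-2 spike
arrives ~58 ms after channel 1, i.e. when it coincides with the delayed copy.
"""

import numpy as np

from dendelay import DelayBank, DendriticLayer, LIFParams, SpikeRaster, coincidence_detect

dt = 5e-3
delays = np.array([[0.021, 0.035, 0.048, 0.058], [1e-9] * 4])
weights = np.full((2, 4, 1), 0.05)
weights[0, 3, 0] = 1.0  # high weight on the 58 ms delay
weights[1, 0, 0] = 1.0  # reference branch
layer = DendriticLayer(weights, DelayBank(delays, dt=dt))
params = LIFParams(tau_mem=20e-3, v_threshold=1.8, dt=dt)

print(f"{'lag (ms)':>9} {'peak membrane':>14} {'detected':>9}")
for lag_ms in range(0, 85, 5):
    counts = np.zeros((2, 40), dtype=int)
    counts[0, 0] = 1
    counts[1, round(lag_ms / 5)] = 1
    out = coincidence_detect(SpikeRaster(counts, dt), layer, params)
    print(f"{lag_ms:>9} {out['peak_membrane']:>14.3f} {str(out['detected']):>9}")
print("\npeak membrane is maximized at the programmed 58 ms delay; only")
print("lags within a bin of it drive the neuron over threshold")
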