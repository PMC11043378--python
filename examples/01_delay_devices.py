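"""Delay-device statistics: sample a bank, fit it back, map to resistances.

The delay of each dendritic synapse comes from an RC circuit whose resistor
is an RRAM device in its pristine (never-formed) state.  Measured delays are
log-normal with mean 22 ms and sigma 0.5 on the underlying normal.
"""

import numpy as np

from dendelay import (
    DelayDistribution,
    RCDelayMap,
    delay_to_resistance,
    fit_lognormal,
    sample_delays,
)

dist = DelayDistribution.measured()
print(f"calibrated distribution: mu_log={dist.mu_log:.3f}, sigma_log={dist.sigma_log}")
print(f"implied mean delay: {dist.mean_ms:.1f} ms")

bank = sample_delays(dist, n_channels=2, n_synapses=8, seed=0)
print("\nsampled 2x8 delay bank (ms):")
print(np.round(bank.delays_s * 1e3, 1))
print("bin offsets at 5 ms resolution:")
print(bank.bin_offsets)

fit = fit_lognormal(sample_delays(dist, 100, 100, seed=1).delays_s.ravel() * 1e3)
print(f"\nrefit from 10,000 draws: mean={fit.mean_ms:.2f} ms, sigma={fit.sigma_log:.3f}")
print("(should recover ~22 ms and ~0.5)")

rc = RCDelayMap(capacitance=400e-15)
r = delay_to_resistance(22e-3, rc)
print(f"\na 22 ms delay across a 400 fF capacitor needs R = {r:.2e} ohm")
print("(tens of gigaohms: only pristine-state devices are this resistive)")
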