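"""Dendritic delay-network forward model.

Each input channel fans out through a bank of fixed delays and trainable
weights — one (delay, weight) pair per dendritic synapse circuit — into
leaky integrate-and-fire (LIF) output neurons.  The branch current into
output neuron ``o`` is

    S_o(t) = sum_{c,i} w[c,i,o] * x_c(t - Delta[c,i]),

i.e. a weighted superposition of delayed copies of the input spike trains.
Because delayed copies of spikes from different channels can be brought into
temporal alignment by the right (delay, weight) combination, a neuron can be
made to respond maximally to a specific inter-channel lag — coincidence
detection, the architecture's temporal-feature primitive.

Dynamics are simulated in discrete time with exponential-Euler leak
``alpha = exp(-dt / tau_mem)``, reset-to-value after a spike, membrane
recorded post-reset, and no refractory period.  Delays are quantized to bins
by round-half-up; spikes delayed past the simulation horizon are dropped
(causal hardware behavior), never wrapped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .devices import DelayBank, DelayDistribution, sample_delays
from .raster import SpikeRaster

__all__ = [
    "DelayBank",
    "DendriticLayer",
    "LIFParams",
    "NetworkOutput",
    "apply_delays",
    "branch_current",
    "run_lif",
    "run_leaky_integrator",
    "forward",
    "coincidence_detect",
]


@dataclass(frozen=True)
class LIFParams:
    """Discrete-time LIF / leaky-integrator parameters.

    ``v[t] = alpha * v[t-1] + I[t]`` with ``alpha = exp(-dt / tau_mem)``;
    a spike is emitted when ``v[t] >= v_threshold``, after which the membrane
    is reset to ``v_reset``.
    """

    tau_mem: float
    v_threshold: float = 1.0
    v_reset: float = 0.0
    dt: float = 5e-3

    def __post_init__(self) -> None:
        if not self.tau_mem > 0:
            raise ValueError("tau_mem must be positive")
        if not self.v_threshold > self.v_reset:
            raise ValueError("v_threshold must exceed v_reset")
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    @property
    def alpha(self) -> float:
        """Per-bin exponential decay factor of the membrane leak."""
        return float(np.exp(-self.dt / self.tau_mem))


class DendriticLayer:
    """Trainable weights ``(channels, synapses, outputs)`` over a frozen delay bank."""

    def __init__(self, weights: np.ndarray, bank: DelayBank):
        weights = np.asarray(weights, dtype=float)
        if weights.ndim != 3:
            raise ValueError("weights must be 3-D (channels x synapses x outputs)")
        if weights.shape[:2] != (bank.n_channels, bank.n_synapses):
            raise ValueError(
                f"weight shape {weights.shape[:2]} inconsistent with delay bank "
                f"({bank.n_channels}, {bank.n_synapses})"
            )
        self.weights = weights
        self.bank = bank

    @property
    def n_channels(self) -> int:
        return self.weights.shape[0]

    @property
    def n_synapses(self) -> int:
        return self.weights.shape[1]

    @property
    def n_outputs(self) -> int:
        return self.weights.shape[2]

    @classmethod
    def initialize(
        cls,
        n_channels: int,
        n_synapses: int,
        n_outputs: int,
        dist: DelayDistribution | None = None,
        dt: float = 5e-3,
        seed: int = 0,
        weight_scale: float | None = None,
    ) -> "DendriticLayer":
        """Sample a delay bank from ``dist`` and draw small random initial weights."""
        dist = dist or DelayDistribution.measured()
        bank = sample_delays(dist, n_channels, n_synapses, seed=seed, dt=dt)
        rng = np.random.default_rng(seed + 1)
        if weight_scale is None:
            weight_scale = 1.0 / np.sqrt(n_channels * n_synapses)
        weights = rng.normal(0.0, weight_scale, size=(n_channels, n_synapses, n_outputs))
        return cls(weights, bank)


@dataclass(frozen=True)
class NetworkOutput:
    """Spikes and (post-reset) membrane traces, each ``(outputs, time_bins)``."""

    spikes: np.ndarray
    membrane: np.ndarray

    @property
    def spike_counts(self) -> np.ndarray:
        return self.spikes.sum(axis=-1)

    @property
    def max_membrane(self) -> np.ndarray:
        return self.membrane.max(axis=-1)


def apply_delays(raster: SpikeRaster, bank: DelayBank) -> np.ndarray:
    """Expand a raster to ``(channels, synapses, time_bins)`` of delayed copies.

    ``expanded[c, i, t] = counts[c, t - offset[c, i]]`` for ``t >= offset``,
    zero before (causal shift, zero-padded); spikes shifted past the last bin
    are dropped.
    """
    if not np.isclose(raster.dt, bank.dt):
        raise ValueError(f"raster dt {raster.dt} != bank dt {bank.dt}")
    if raster.n_channels != bank.n_channels:
        raise ValueError(
            f"raster has {raster.n_channels} channels, bank expects {bank.n_channels}"
        )
    return _apply_delays_array(raster.counts, bank.bin_offsets)


def _apply_delays_array(counts: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Delay expansion on a bare array; ``counts`` may carry leading batch axes."""
    *lead, n_channels, n_bins = counts.shape
    n_synapses = offsets.shape[1]
    expanded = np.zeros((*lead, n_channels, n_synapses, n_bins), dtype=float)
    for c in range(n_channels):
        for i in range(n_synapses):
            k = int(offsets[c, i])
            if k < n_bins:
                expanded[..., c, i, k:] = counts[..., c, : n_bins - k]
    return expanded


def branch_current(expanded: np.ndarray, layer: DendriticLayer) -> np.ndarray:
    """Weighted branch current ``I[o, t] = sum_{c,i} w[c,i,o] * expanded[c,i,t]``."""
    if expanded.shape[-3:-1] != layer.weights.shape[:2]:
        raise ValueError(
            f"expanded raster shape {expanded.shape} inconsistent with weights "
            f"{layer.weights.shape}"
        )
    # (..., c, i, t) x (c, i, o) -> (..., o, t)
    return np.einsum("...cit,cio->...ot", expanded, layer.weights)


def run_lif(currents: np.ndarray, params: LIFParams) -> NetworkOutput:
    """Simulate LIF dynamics over ``(..., outputs, time_bins)`` input currents."""
    currents = np.asarray(currents, dtype=float)
    alpha = params.alpha
    n_bins = currents.shape[-1]
    v = np.full(currents.shape[:-1], params.v_reset, dtype=float)
    spikes = np.zeros_like(currents)
    membrane = np.zeros_like(currents)
    for t in range(n_bins):
        v = alpha * v + currents[..., t]
        fired = v >= params.v_threshold
        spikes[..., t] = fired
        v = np.where(fired, params.v_reset, v)
        membrane[..., t] = v  # post-reset, by convention
    return NetworkOutput(spikes=spikes, membrane=membrane)


def run_leaky_integrator(currents: np.ndarray, params: LIFParams) -> np.ndarray:
    """Leaky integration without threshold or reset; returns membrane traces."""
    currents = np.asarray(currents, dtype=float)
    alpha = params.alpha
    membrane = np.empty_like(currents)
    v = np.full(currents.shape[:-1], params.v_reset, dtype=float)
    for t in range(currents.shape[-1]):
        v = alpha * v + currents[..., t]
        membrane[..., t] = v
    return membrane


def forward(
    raster: SpikeRaster,
    layer: DendriticLayer,
    params: LIFParams,
    readout: Literal["spiking", "max_membrane"] = "spiking",
) -> NetworkOutput:
    """Full forward pass: delay expansion -> branch currents -> neuron dynamics.

    ``spiking`` runs the thresholded LIF (used for the binary anomaly
    detector, where high output spike count signals an anomaly);
    ``max_membrane`` runs the non-spiking leaky integrator whose per-class
    maximum membrane over time serves as the logit.
    """
    expanded = apply_delays(raster, layer.bank)
    currents = branch_current(expanded, layer)
    if readout == "spiking":
        return run_lif(currents, params)
    if readout == "max_membrane":
        membrane = run_leaky_integrator(currents, params)
        return NetworkOutput(spikes=np.zeros_like(membrane), membrane=membrane)
    raise ValueError(f"unknown readout {readout!r}")


def coincidence_detect(
    raster2: SpikeRaster, layer: DendriticLayer, params: LIFParams
) -> dict:
    """Run the coincidence-detection primitive on a 2-channel raster.

    Returns whether the (single) output neuron spiked, its peak free membrane
    potential and the peak time — the quantities swept in lag analyses.  With
    one synapse programmed to a high weight at delay ``Delta*`` and the rest
    low, detection occurs only when the inter-channel lag falls within one
    bin-rounding of ``Delta*``.
    """
    if raster2.n_channels != 2:
        raise ValueError("coincidence detection expects exactly 2 channels")
    expanded = apply_delays(raster2, layer.bank)
    currents = branch_current(expanded, layer)
    spiking = run_lif(currents, params)
    free_membrane = run_leaky_integrator(currents, params)
    peak_bin = int(np.unravel_index(np.argmax(free_membrane), free_membrane.shape)[-1])
    return {
        "detected": bool(spiking.spikes.sum() > 0),
        "peak_membrane": float(free_membrane.max()),
        "peak_time": peak_bin * raster2.dt,
        "output": spiking,
    }
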