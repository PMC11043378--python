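"""Spiking recurrent network (SRNN) baseline.

One hidden layer of LIF neurons with all-to-all recurrence and a layer of
leaky-integrator outputs.  The recurrence uses the previous step's hidden
spikes (explicit one-step delay), so the hidden drive at bin ``t`` is
``W_in @ x[t] + W_rec @ s[t-1]``.  No biases: every trainable parameter is a
weight, matching a two-devices-per-parameter differential RRAM mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import LIFParams, NetworkOutput
from .raster import SpikeRaster

__all__ = ["SRNNConfig", "SRNNWeights", "srnn_forward", "srnn_parameter_count"]


@dataclass(frozen=True)
class SRNNConfig:
    n_in: int
    n_hidden: int
    n_out: int
    hidden: LIFParams = field(default_factory=lambda: LIFParams(tau_mem=20e-3))
    output: LIFParams = field(default_factory=lambda: LIFParams(tau_mem=20e-3))

    def __post_init__(self) -> None:
        if min(self.n_in, self.n_hidden, self.n_out) < 1:
            raise ValueError("all layer sizes must be >= 1")


@dataclass
class SRNNWeights:
    """Weight triple (W_in: in x hidden, W_rec: hidden x hidden, W_out: hidden x out)."""

    w_in: np.ndarray
    w_rec: np.ndarray
    w_out: np.ndarray

    def validate(self, config: SRNNConfig) -> None:
        if self.w_in.shape != (config.n_in, config.n_hidden):
            raise ValueError(f"W_in shape {self.w_in.shape} != ({config.n_in}, {config.n_hidden})")
        if self.w_rec.shape != (config.n_hidden, config.n_hidden):
            raise ValueError(f"W_rec shape {self.w_rec.shape} is not square of n_hidden")
        if self.w_out.shape != (config.n_hidden, config.n_out):
            raise ValueError(f"W_out shape {self.w_out.shape} != ({config.n_hidden}, {config.n_out})")

    @classmethod
    def initialize(cls, config: SRNNConfig, seed: int = 0, scale: float | None = None) -> "SRNNWeights":
        rng = np.random.default_rng(seed)
        s_in = scale if scale is not None else 1.0 / np.sqrt(config.n_in)
        s_rec = scale if scale is not None else 1.0 / np.sqrt(config.n_hidden)
        return cls(
            w_in=rng.normal(0, s_in, (config.n_in, config.n_hidden)),
            w_rec=rng.normal(0, s_rec, (config.n_hidden, config.n_hidden)),
            w_out=rng.normal(0, s_rec, (config.n_hidden, config.n_out)),
        )


def srnn_forward(
    raster: SpikeRaster | np.ndarray, config: SRNNConfig, weights: SRNNWeights
) -> NetworkOutput:
    """Run the SRNN over a raster (or batched array ``(..., n_in, bins)``).

    The output layer is a non-spiking leaky integrator, so in the returned
    ``NetworkOutput`` the ``membrane`` field holds the output traces while
    ``spikes`` holds the hidden layer's spike trains.
    """
    weights.validate(config)
    x = raster.counts if isinstance(raster, SpikeRaster) else np.asarray(raster, dtype=float)
    if x.shape[-2] != config.n_in:
        raise ValueError(f"input has {x.shape[-2]} channels, config expects {config.n_in}")
    *lead, _, n_bins = x.shape
    alpha_h = config.hidden.alpha
    alpha_o = config.output.alpha
    v_h = np.full((*lead, config.n_hidden), config.hidden.v_reset, dtype=float)
    s_prev = np.zeros((*lead, config.n_hidden), dtype=float)
    u_o = np.full((*lead, config.n_out), config.output.v_reset, dtype=float)
    hidden_spikes = np.zeros((*lead, config.n_hidden, n_bins))
    out_membrane = np.zeros((*lead, config.n_out, n_bins))
    for t in range(n_bins):
        drive = x[..., :, t] @ weights.w_in + s_prev @ weights.w_rec
        v_h = alpha_h * v_h + drive
        fired = (v_h >= config.hidden.v_threshold).astype(float)
        v_h = np.where(fired > 0, config.hidden.v_reset, v_h)
        u_o = alpha_o * u_o + fired @ weights.w_out
        hidden_spikes[..., :, t] = fired
        out_membrane[..., :, t] = u_o
        s_prev = fired
    return NetworkOutput(spikes=hidden_spikes, membrane=out_membrane)


def srnn_parameter_count(config: SRNNConfig) -> int:
    """Trainable weight count: n_in*n_hidden + n_hidden^2 + n_hidden*n_out."""
    return (
        config.n_in * config.n_hidden
        + config.n_hidden * config.n_hidden
        + config.n_hidden * config.n_out
    )
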