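"""Closed-form parameter, device, footprint and energy accounting.

Trainable-parameter counts: the delay network has one weight per
(channel, synapse, output) triple — delays are frozen device properties, not
parameters — so parameters scale linearly with input size.  The SRNN's
recurrent block scales quadratically in its hidden size.  Each trainable
weight maps to two RRAM devices (differential positive/negative
conductances); each dendritic circuit additionally carries one Delay RRAM,
shared across the outputs of its tree.

Energy figures are constants-based estimates: a measured per-dendritic-event
energy (58.5 pJ from circuit-level simulation of one delayed, weighted
spike) multiplied by the event count, with a fixed per-block breakdown
(66.7% threshold block, <10% RC + weight path, remainder in the MUX
selectors).  They are order-of-magnitude estimates, not system simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .srnn import SRNNConfig, srnn_parameter_count

__all__ = [
    "EnergyConstants",
    "delay_net_parameter_count",
    "delay_net_device_count",
    "srnn_device_count",
    "estimate_energy",
    "memory_footprint_bytes",
    "cost_report",
]


@dataclass(frozen=True)
class EnergyConstants:
    """Per-event energy and its per-block split for the dendritic circuit."""

    per_event_energy: float = 58.5e-12  # joules per delayed+weighted spike event
    threshold_fraction: float = 0.667
    rc_and_weight_fraction: float = 0.095

    def __post_init__(self) -> None:
        fractions = (self.threshold_fraction, self.rc_and_weight_fraction)
        if any(not 0 <= f <= 1 for f in fractions) or sum(fractions) > 1:
            raise ValueError("block fractions must lie in [0,1] and sum to <= 1")
        if self.per_event_energy < 0:
            raise ValueError("per_event_energy must be >= 0")

    @property
    def mux_fraction(self) -> float:
        return 1.0 - self.threshold_fraction - self.rc_and_weight_fraction


def delay_net_parameter_count(n_channels: int, n_synapses: int, n_outputs: int) -> int:
    """Trainable weights of the delay network: channels x synapses x outputs."""
    if min(n_channels, n_synapses, n_outputs) < 1:
        raise ValueError("all counts must be >= 1")
    return n_channels * n_synapses * n_outputs


def delay_net_device_count(n_channels: int, n_synapses: int, n_outputs: int) -> int:
    """RRAM devices: 2 per weight plus one Delay RRAM per dendritic circuit.

    The delay device of a (channel, synapse) circuit is shared across the
    outputs of its dendritic tree, so the delay term does not multiply by
    ``n_outputs``.
    """
    params = delay_net_parameter_count(n_channels, n_synapses, n_outputs)
    return 2 * params + n_channels * n_synapses


def srnn_device_count(config: SRNNConfig) -> int:
    """RRAM devices of the SRNN: 2 per trainable weight (no delay devices)."""
    return 2 * srnn_parameter_count(config)


def estimate_energy(
    n_dendritic_events: int, constants: EnergyConstants = EnergyConstants()
) -> dict:
    """Constants-based energy estimate for ``n_dendritic_events`` spike events.

    Returns total joules and the per-block breakdown; flagged as an estimate
    in the output dict.
    """
    if n_dendritic_events < 0:
        raise ValueError("event count must be >= 0")
    total = n_dendritic_events * constants.per_event_energy
    return {
        "total_joules": total,
        "threshold_joules": total * constants.threshold_fraction,
        "rc_and_weight_joules": total * constants.rc_and_weight_fraction,
        "mux_joules": total * constants.mux_fraction,
        "kind": "constants-based estimate",
    }


def memory_footprint_bytes(n_parameters: int, bits_per_weight: int = 8) -> int:
    """Storage for the trainable weights at the stated precision."""
    if bits_per_weight < 1:
        raise ValueError("bits_per_weight must be >= 1")
    return (n_parameters * bits_per_weight + 7) // 8


def cost_report(
    architecture: str,
    n_channels: int,
    n_synapses: int | None = None,
    n_outputs: int | None = None,
    n_hidden: int | None = None,
    bits_per_weight: int = 8,
    n_events_per_inference: int = 0,
) -> dict:
    """Cost summary for a delay network (``"delaynet"``) or SRNN (``"srnn"``)."""
    if architecture == "delaynet":
        if n_synapses is None or n_outputs is None:
            raise ValueError("delay network costing needs n_synapses and n_outputs")
        params = delay_net_parameter_count(n_channels, n_synapses, n_outputs)
        devices = delay_net_device_count(n_channels, n_synapses, n_outputs)
    elif architecture == "srnn":
        if n_hidden is None or n_outputs is None:
            raise ValueError("srnn costing needs n_hidden and n_outputs")
        config = SRNNConfig(n_in=n_channels, n_hidden=n_hidden, n_out=n_outputs)
        params = srnn_parameter_count(config)
        devices = srnn_device_count(config)
    else:
        raise ValueError(f"unknown architecture {architecture!r}")
    report = {
        "architecture": architecture,
        "parameters": params,
        "devices": devices,
        "footprint_bytes": memory_footprint_bytes(params, bits_per_weight),
    }
    if n_events_per_inference:
        report["energy_per_inference"] = estimate_energy(n_events_per_inference)
    return report
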