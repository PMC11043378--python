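"""RRAM device models: delay statistics, RC mapping, programming noise.

The delay element of each dendritic synapse is a capacitor recharged through
a pristine-state RRAM device, giving an RC time constant ``tau = R_d * C``.
Measured delays across an array of such circuits follow a log-normal
distribution; :class:`DelayDistribution` holds the parameters of the
underlying normal (in log-milliseconds) and is the source from which
fixed per-synapse delay banks are sampled.  Weight devices are modelled by a
Gaussian programming-noise perturbation whose standard deviation is a fixed
fraction of the largest absolute weight in the layer, plus an optional
quantizer onto a discrete set of programmable conductance levels.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

__all__ = [
    "DelayDistribution",
    "RCDelayMap",
    "RRAMNoiseModel",
    "ConductanceLevels",
    "DelayBank",
    "fit_lognormal",
    "sample_delays",
    "delay_to_resistance",
    "resistance_to_delay",
    "perturb_weights",
    "quantize_to_levels",
    "load_delay_csv",
]

#: Default bin width (seconds) used when quantizing delays onto a raster grid.
DEFAULT_DT = 5e-3

#: Calibration of the measured pristine-state delay distribution: mean delay
#: 22 ms with sigma 0.5 on the underlying normal (log scale).
MEASURED_DELAY_MEAN_MS = 22.0
MEASURED_DELAY_SIGMA_LOG = 0.5


@dataclass(frozen=True)
class DelayDistribution:
    """Log-normal delay distribution, parameterized on the log-millisecond scale.

    ``mu_log`` and ``sigma_log`` are the mean and standard deviation of the
    underlying normal of ``ln(delay_ms)``.  The implied arithmetic mean in
    milliseconds is ``exp(mu_log + sigma_log**2 / 2)``.
    """

    mu_log: float
    sigma_log: float

    def __post_init__(self) -> None:
        if self.sigma_log < 0:
            raise ValueError(f"sigma_log must be >= 0, got {self.sigma_log}")
        if not np.isfinite(self.mu_log):
            raise ValueError("mu_log must be finite")

    @classmethod
    def from_mean(cls, mean_ms: float, sigma_log: float) -> "DelayDistribution":
        """Construct from the arithmetic mean delay (ms) and log-scale sigma.

        Inverts the log-normal moment relation:
        ``mu_log = ln(mean) - sigma_log**2 / 2``.
        """
        if mean_ms <= 0:
            raise ValueError("mean delay must be positive")
        return cls(mu_log=float(np.log(mean_ms) - sigma_log**2 / 2.0), sigma_log=sigma_log)

    @classmethod
    def measured(cls) -> "DelayDistribution":
        """The distribution calibrated to the pristine-state measurements
        (mean 22 ms, underlying-normal sigma 0.5)."""
        return cls.from_mean(MEASURED_DELAY_MEAN_MS, MEASURED_DELAY_SIGMA_LOG)

    @property
    def mean_ms(self) -> float:
        """Implied arithmetic mean delay in milliseconds."""
        return float(np.exp(self.mu_log + self.sigma_log**2 / 2.0))

    @property
    def median_ms(self) -> float:
        return float(np.exp(self.mu_log))


@dataclass(frozen=True)
class RCDelayMap:
    """Linear map between a delay and the resistance charging a fixed capacitor.

    The dendritic circuit produces its delay through ``tau = R_d * C`` with a
    gate-oxide capacitance of roughly 400 fF.
    """

    capacitance: float = 400e-15

    def __post_init__(self) -> None:
        if not self.capacitance > 0:
            raise ValueError("capacitance must be positive")


@dataclass(frozen=True)
class RRAMNoiseModel:
    """Gaussian programming/relaxation noise, sigma = ``relative_sigma`` x layer max |w|."""

    relative_sigma: float = 0.10

    def __post_init__(self) -> None:
        if self.relative_sigma < 0:
            raise ValueError("relative_sigma must be >= 0")


@dataclass(frozen=True)
class ConductanceLevels:
    """Discrete programmable conductance levels (siemens), ascending."""

    level_means: np.ndarray

    def __post_init__(self) -> None:
        levels = np.asarray(self.level_means, dtype=float)
        if levels.ndim != 1 or levels.size < 1:
            raise ValueError("level_means must be a non-empty 1-D array")
        if not (np.diff(levels) > 0).all():
            raise ValueError("level_means must be strictly increasing")
        object.__setattr__(self, "level_means", levels)

    @property
    def n_levels(self) -> int:
        return self.level_means.size

    @classmethod
    def uniform(cls, g_min: float, g_max: float, n_levels: int = 8) -> "ConductanceLevels":
        return cls(np.linspace(g_min, g_max, n_levels))


@dataclass(frozen=True)
class DelayBank:
    """Frozen per-(channel, synapse) delays and their integer bin offsets.

    Delays are sampled once from the device distribution and never updated by
    training; ``bin_offsets = round(delays_s / dt)`` (round-half-up).
    """

    delays_s: np.ndarray
    dt: float
    seed: int | None = None

    def __post_init__(self) -> None:
        delays = np.asarray(self.delays_s, dtype=float)
        if delays.ndim != 2:
            raise ValueError("delays_s must be 2-D (channels x synapses)")
        if (delays < 0).any():
            raise ValueError("delays must be non-negative")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        delays.setflags(write=False)  # frozen: training must never touch delays
        object.__setattr__(self, "delays_s", delays)

    @property
    def bin_offsets(self) -> np.ndarray:
        # round-half-up onto the bin grid
        return np.floor(self.delays_s / self.dt + 0.5).astype(np.int64)

    @property
    def n_channels(self) -> int:
        return self.delays_s.shape[0]

    @property
    def n_synapses(self) -> int:
        return self.delays_s.shape[1]

    def save(self, path: Union[str, os.PathLike]) -> None:
        np.savez_compressed(
            path,
            delays_s=self.delays_s,
            bin_offsets=self.bin_offsets,
            dt_s=np.float64(self.dt),
            seed=np.int64(-1 if self.seed is None else self.seed),
        )

    @classmethod
    def load(cls, path: Union[str, os.PathLike]) -> "DelayBank":
        with np.load(path) as archive:
            seed = int(archive["seed"])
            return cls(
                delays_s=archive["delays_s"],
                dt=float(archive["dt_s"]),
                seed=None if seed < 0 else seed,
            )


def fit_lognormal(delays_ms: Sequence[float] | np.ndarray) -> DelayDistribution:
    """Fit a log-normal to measured delays (ms) by log-space moments.

    ``mu_log`` is the mean of ``ln(delay)`` and ``sigma_log`` the (population)
    standard deviation of ``ln(delay)`` — the maximum-likelihood estimates for
    a log-normal sample.
    """
    delays = np.asarray(delays_ms, dtype=float)
    if delays.size < 2:
        raise ValueError(f"need at least 2 delay samples, got {delays.size}")
    if (delays <= 0).any() or not np.isfinite(delays).all():
        raise ValueError("all delays must be positive and finite")
    log_delays = np.log(delays)
    return DelayDistribution(
        mu_log=float(log_delays.mean()), sigma_log=float(log_delays.std())
    )


def sample_delays(
    dist: DelayDistribution,
    n_channels: int,
    n_synapses: int,
    seed: int,
    dt: float = DEFAULT_DT,
) -> DelayBank:
    """Draw a frozen ``n_channels x n_synapses`` delay bank from ``dist``.

    Samples are strictly positive (log-normal) and reproducible per seed.
    """
    if n_channels < 1 or n_synapses < 1:
        raise ValueError("n_channels and n_synapses must be >= 1")
    rng = np.random.default_rng(seed)
    delays_ms = rng.lognormal(
        mean=dist.mu_log, sigma=dist.sigma_log, size=(n_channels, n_synapses)
    )
    return DelayBank(delays_s=delays_ms * 1e-3, dt=dt, seed=seed)


def delay_to_resistance(delay_s: float | np.ndarray, rc_map: RCDelayMap = RCDelayMap()):
    """Resistance (ohms) producing ``delay_s`` through R = D / C."""
    delay = np.asarray(delay_s, dtype=float)
    if (delay < 0).any():
        raise ValueError("delay must be non-negative")
    result = delay / rc_map.capacitance
    return float(result) if result.ndim == 0 else result


def resistance_to_delay(resistance_ohm: float | np.ndarray, rc_map: RCDelayMap = RCDelayMap()):
    """Delay (seconds) produced by ``resistance_ohm`` through tau = R * C."""
    resistance = np.asarray(resistance_ohm, dtype=float)
    if (resistance < 0).any():
        raise ValueError("resistance must be non-negative")
    result = resistance * rc_map.capacitance
    return float(result) if result.ndim == 0 else result


def perturb_weights(
    weights: np.ndarray,
    noise: RRAMNoiseModel,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Return ``weights + eps`` with ``eps ~ N(0, (relative_sigma * max|w|)^2)``.

    The noise scale is tied to the largest absolute weight in the layer,
    mirroring conductance-relaxation spread measured as a fraction of the
    maximum programmed conductance.  The input array is left untouched.
    """
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise ValueError("weight array must be non-empty")
    if not np.isfinite(w).all():
        raise ValueError("weights must be finite")
    sigma = noise.relative_sigma * np.abs(w).max()
    if sigma == 0.0:
        return w.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return w + rng.normal(0.0, sigma, size=w.shape)


def quantize_to_levels(weights: np.ndarray, levels: ConductanceLevels) -> np.ndarray:
    """Snap each weight magnitude to the nearest programmable level, keeping sign.

    A magnitude exactly midway between two levels maps to the lower level.
    Idempotent by construction.
    """
    w = np.asarray(weights, dtype=float)
    mags = np.abs(w)
    centers = levels.level_means
    # midpoints between consecutive levels; searchsorted with side='right'
    # sends an exact midpoint to the lower level
    midpoints = (centers[:-1] + centers[1:]) / 2.0
    idx = np.searchsorted(midpoints, mags, side="left")
    # side='left' maps mag == midpoint to the *lower* bucket index
    snapped = centers[idx]
    return np.sign(w) * snapped


def load_delay_csv(path_or_buffer) -> np.ndarray:
    """Read measured delays (ms) from a one-column CSV, header optional."""
    if isinstance(path_or_buffer, (str, os.PathLike)):
        with open(path_or_buffer) as handle:
            text = handle.read()
    else:
        text = path_or_buffer.read()
    values = []
    for line in text.splitlines():
        token = line.strip().rstrip(",")
        if not token:
            continue
        try:
            values.append(float(token))
        except ValueError:
            if values:
                raise ValueError(f"non-numeric delay entry: {token!r}")
            # else: header line, skip
    if not values:
        raise ValueError("no delay values found")
    return np.asarray(values, dtype=float)
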