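"""Core in-memory containers: binned spike rasters and analog traces.

A :class:`SpikeRaster` is the discrete stand-in for a sum-of-Diracs spike
train ``x(t) = sum_k delta(t - t_k)``: an integer count array of shape
``(channels, time_bins)`` with a fixed bin width ``dt``.  Counts (rather
than binary occupancy) are kept because a bin several milliseconds wide can
hold more than one event; :meth:`SpikeRaster.binarize` collapses them when a
binary code is wanted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class SpikeRaster:
    """Binned spike counts, ``(n_channels, n_bins)``, with bin width ``dt`` seconds."""

    counts: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError(f"counts must be 2-D (channels x bins), got shape {counts.shape}")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("counts must be integer-valued")
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            raise ValueError("spike counts must be non-negative")
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        object.__setattr__(self, "counts", counts)

    @property
    def n_channels(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def duration(self) -> float:
        """Total covered time in seconds."""
        return self.n_bins * self.dt

    @property
    def total_spikes(self) -> int:
        return int(self.counts.sum())

    def binarize(self) -> "SpikeRaster":
        """Clip every bin to at most one spike."""
        return SpikeRaster(np.minimum(self.counts, 1), self.dt)

    def shift(self, n_bins: int) -> "SpikeRaster":
        """Causally delay the whole raster by ``n_bins`` bins (horizon-truncating)."""
        if n_bins < 0:
            raise ValueError("shift must be non-negative (causal)")
        out = np.zeros_like(self.counts)
        if n_bins < self.n_bins:
            out[:, n_bins:] = self.counts[:, : self.n_bins - n_bins]
        return SpikeRaster(out, self.dt)


@dataclass(frozen=True)
class AnalogTrace:
    """A uniformly sampled continuous signal (e.g. one ECG lead)."""

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise ValueError("samples must be 1-D")
        if not np.isfinite(samples).all():
            raise ValueError("samples must be finite")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate
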