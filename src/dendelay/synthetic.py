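"""Synthetic datasets with the spatio-temporal structure the architecture targets.

Three generators, all exactly reproducible from (spec, seed):

* a two-channel coincidence-detection (CD) task where the positive class
  carries a fixed inter-channel lag and negatives carry distractor lags
  (including negative lags, so channel order alone cannot solve the task);
* a quasi-periodic ECG-like waveform built from Gaussian bumps (P, QRS, T)
  with a controllable fraction of morphologically transformed anomalous
  beats (widened/attenuated QRS, inverted T, premature timing), standing in
  for a single-lead arrhythmia recording;
* multi-class spatio-temporal spike patterns defined by per-class
  (channel, time-offset) templates with Gaussian timing jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .codec import extract_beat_dataset, delta_modulate
from .raster import AnalogTrace, SpikeRaster

__all__ = [
    "CDTaskSpec",
    "SyntheticECGSpec",
    "LabeledRasterDataset",
    "gen_cd_dataset",
    "gen_synthetic_ecg",
    "make_ecg_beat_dataset",
    "gen_spatiotemporal_patterns",
]


@dataclass(frozen=True)
class LabeledRasterDataset:
    """A stack of equally shaped rasters with integer labels."""

    counts: np.ndarray  # (N, channels, bins)
    labels: np.ndarray  # (N,)
    dt: float

    def __post_init__(self) -> None:
        if self.counts.ndim != 3:
            raise ValueError("counts must be (samples, channels, bins)")
        if len(self.counts) != len(self.labels):
            raise ValueError("counts and labels must align")
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=np.int64))

    def __len__(self) -> int:
        return len(self.counts)

    def raster(self, k: int) -> SpikeRaster:
        return SpikeRaster(self.counts[k], self.dt)

    def split_chronological(self) -> tuple["LabeledRasterDataset", "LabeledRasterDataset"]:
        """Equal-size chronological split (first half train, second half test)."""
        half = len(self) // 2
        return (
            LabeledRasterDataset(self.counts[:half], self.labels[:half], self.dt),
            LabeledRasterDataset(self.counts[half:], self.labels[half:], self.dt),
        )


# ---------------------------------------------------------------------------
# coincidence-detection task
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CDTaskSpec:
    """Two-channel lag-detection task.

    Positives: a channel-1 spike and a channel-2 spike ``lag`` seconds later
    (plus Gaussian jitter).  Negatives: the lag is drawn uniformly from
    ``distractor_range``, rejecting draws within one bin of the target lag.
    Onsets are randomized so absolute timing carries no label information.
    """

    n_pairs: int = 200
    lag: float = 60e-3
    distractor_range: tuple[float, float] = (-80e-3, 80e-3)
    jitter: float = 0.0
    dt: float = 5e-3
    duration: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")
        lo, hi = self.distractor_range
        if lo >= hi:
            raise ValueError("distractor_range must be a non-empty interval")
        if lo >= self.lag - self.dt and hi <= self.lag + self.dt:
            raise ValueError("distractor range lies entirely inside the target window")
        if abs(self.lag) + self.dt >= self.duration:
            raise ValueError("lag must fit inside the simulation horizon")


def gen_cd_dataset(spec: CDTaskSpec) -> LabeledRasterDataset:
    """Generate a balanced, seeded CD dataset of 2-channel rasters."""
    rng = np.random.default_rng(spec.seed)
    n_bins = int(round(spec.duration / spec.dt))
    max_abs_lag = max(abs(spec.lag), abs(spec.distractor_range[0]), abs(spec.distractor_range[1]))
    margin = max_abs_lag + 4 * spec.jitter + spec.dt
    lo_bin = int(np.ceil(margin / spec.dt))
    hi_bin = n_bins - lo_bin - 1
    if hi_bin < lo_bin:
        raise ValueError("duration too short for the requested lags")
    counts = np.zeros((spec.n_pairs, 2, n_bins), dtype=np.int64)
    labels = np.zeros(spec.n_pairs, dtype=np.int64)
    target_bin = int(np.floor(spec.lag / spec.dt + 0.5))
    for k in range(spec.n_pairs):
        positive = k % 2 == 0
        if positive:
            lag = spec.lag
        else:
            # reject lags landing within one bin of the target after binning
            while True:
                lag = rng.uniform(*spec.distractor_range)
                if abs(int(np.floor(lag / spec.dt + 0.5)) - target_bin) > 1:
                    break
        lag = lag + rng.normal(0.0, spec.jitter) if spec.jitter else lag
        t1 = rng.integers(lo_bin, hi_bin + 1)
        t2 = t1 + int(np.floor(lag / spec.dt + 0.5))
        t2 = min(max(t2, 0), n_bins - 1)
        counts[k, 0, t1] += 1
        counts[k, 1, t2] += 1
        labels[k] = int(positive)
    order = rng.permutation(spec.n_pairs)
    return LabeledRasterDataset(counts[order], labels[order], spec.dt)


# ---------------------------------------------------------------------------
# synthetic ECG
# ---------------------------------------------------------------------------

def _gaussian_bump(t: np.ndarray, amp: float, center: float, width: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((t - center) / width) ** 2)


#: (amplitude, center offset from R peak [s], width [s]) per wave of a normal beat
NORMAL_MORPHOLOGY = (
    (0.12, -0.16, 0.025),   # P
    (-0.10, -0.020, 0.010),  # Q
    (1.00, 0.0, 0.012),      # R
    (-0.15, 0.020, 0.012),   # S
    (0.30, 0.22, 0.050),     # T
)


@dataclass(frozen=True)
class SyntheticECGSpec:
    """Gaussian-bump surrogate for a single-lead arrhythmia recording.

    Anomalous beats get a widened, attenuated QRS complex with an inverted T
    wave (ventricular-ectopic-like morphology) and arrive prematurely.  The
    generator returns ground-truth R-peak sample indices and beat symbols
    ('N' for normal, 'V' for anomalous), so the segmentation and labeling
    pathway is exercised exactly as on annotated clinical records.
    """

    n_beats: int = 200
    heart_rate_hz: float = 1.2
    anomaly_fraction: float = 0.4
    noise_std: float = 0.01
    sample_rate: float = 360.0
    premature_shift: float = 0.18  # fraction of the beat interval an ectopic arrives early
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.anomaly_fraction < 1:
            raise ValueError("anomaly_fraction must lie in [0, 1)")
        if self.heart_rate_hz <= 0 or self.sample_rate <= 0:
            raise ValueError("rates must be positive")
        if self.noise_std < 0:
            raise ValueError("noise_std must be >= 0")


def gen_synthetic_ecg(spec: SyntheticECGSpec) -> tuple[AnalogTrace, np.ndarray, list[str]]:
    """Generate the trace plus ground-truth (R-peak samples, beat symbols)."""
    rng = np.random.default_rng(spec.seed)
    interval = 1.0 / spec.heart_rate_hz
    is_anomaly = rng.random(spec.n_beats) < spec.anomaly_fraction
    # beat times: regular rhythm, ectopic beats arrive early
    beat_times = np.zeros(spec.n_beats)
    t_cursor = 0.5
    for k in range(spec.n_beats):
        gap = interval * (1.0 - spec.premature_shift * is_anomaly[k])
        t_cursor += gap
        beat_times[k] = t_cursor
    duration = beat_times[-1] + 0.6
    n_samples = int(np.ceil(duration * spec.sample_rate))
    t = np.arange(n_samples) / spec.sample_rate
    signal = np.zeros(n_samples)
    for k, t_beat in enumerate(beat_times):
        window = (t > t_beat - 0.45) & (t < t_beat + 0.45)
        tw = t[window]
        if is_anomaly[k]:
            # ventricular-like beat: no P wave, wide low R, deep slurred S, inverted T
            beat = (
                _gaussian_bump(tw, 0.65, t_beat, 0.045)
                + _gaussian_bump(tw, -0.35, t_beat + 0.07, 0.035)
                + _gaussian_bump(tw, -0.30, t_beat + 0.24, 0.060)
            )
        else:
            beat = sum(
                _gaussian_bump(tw, amp, t_beat + off, width)
                for amp, off, width in NORMAL_MORPHOLOGY
            )
        signal[window] += beat
    if spec.noise_std:
        signal = signal + rng.normal(0.0, spec.noise_std, size=n_samples)
    peaks = np.floor(beat_times * spec.sample_rate + 0.5).astype(np.int64)
    symbols = ["V" if a else "N" for a in is_anomaly]
    return AnalogTrace(signal, spec.sample_rate), peaks, symbols


def make_ecg_beat_dataset(
    spec: SyntheticECGSpec, delta: float = 0.06, window: int = 180
) -> LabeledRasterDataset:
    """Full encoder pathway: generate, delta-modulate, segment, label.

    Returns (n_kept, 2, window) UP/DOWN beat segments with 0=normal,
    1=anomaly labels, at the trace's sample resolution.
    """
    trace, peaks, symbols = gen_synthetic_ecg(spec)
    raster = delta_modulate(trace, delta)
    segments, labels = extract_beat_dataset(raster, peaks, symbols, window=window)
    return LabeledRasterDataset(segments, labels, raster.dt)


# ---------------------------------------------------------------------------
# multi-class spatio-temporal patterns
# ---------------------------------------------------------------------------

def gen_spatiotemporal_patterns(
    n_channels: int,
    n_classes: int,
    pattern_bins: int,
    jitter_bins: float = 0.0,
    seed: int = 0,
    n_per_class: int = 50,
    dt: float = 5e-3,
    templates: np.ndarray | None = None,
    onset_jitter_bins: int = 0,
) -> LabeledRasterDataset:
    """Jittered instantiations of per-class (channel, time-offset) templates.

    Each class is defined by one spike per channel at a class-specific
    offset within ``pattern_bins``; samples perturb every spike time by
    ``N(0, jitter_bins)`` (rounded, clipped) and optionally shift the whole
    pattern by a random onset.  Templates are drawn to be pairwise distinct;
    a ``(n_classes, n_channels)`` offset array can be supplied instead.
    """
    if min(n_channels, n_classes, pattern_bins, n_per_class) < 1:
        raise ValueError("all counts must be >= 1")
    if jitter_bins < 0:
        raise ValueError("jitter must be >= 0")
    rng = np.random.default_rng(seed)
    if templates is None:
        templates = np.zeros((n_classes, n_channels), dtype=np.int64)
        seen = set()
        for cls in range(n_classes):
            while True:
                offsets = tuple(rng.integers(0, pattern_bins, size=n_channels))
                if offsets not in seen:
                    seen.add(offsets)
                    break
            templates[cls] = offsets
    else:
        templates = np.asarray(templates, dtype=np.int64)
        if templates.shape != (n_classes, n_channels):
            raise ValueError("templates must be (n_classes, n_channels)")
    n_bins = pattern_bins + onset_jitter_bins + int(np.ceil(4 * jitter_bins)) + 1
    n_total = n_classes * n_per_class
    counts = np.zeros((n_total, n_channels, n_bins), dtype=np.int64)
    labels = np.repeat(np.arange(n_classes), n_per_class)
    for k in range(n_total):
        onset = rng.integers(0, onset_jitter_bins + 1)
        offsets = templates[labels[k]].astype(float)
        if jitter_bins:
            offsets = offsets + rng.normal(0.0, jitter_bins, size=n_channels)
        bins = np.clip(np.floor(offsets + 0.5).astype(np.int64) + onset, 0, n_bins - 1)
        for c in range(n_channels):
            counts[k, c, bins[c]] += 1
    order = rng.permutation(n_total)
    return LabeledRasterDataset(counts[order], labels[order], dt)
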