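"""Encoding of continuous biosignals and event datasets into spike rasters.

Covers the two input pathways of the simulator:

* **Delta modulation** of an analog trace (e.g. one ECG lead) into UP/DOWN
  spike channels marking each +delta / -delta excursion of the signal
  relative to a running staircase reference, followed by segmentation into
  fixed-length windows around annotated R peaks and grouping of beat
  annotation symbols into normal / anomaly classes.
* **Event binning** of (spike time, unit id) streams — the layout used by
  event-format HDF5 datasets such as Spiking Heidelberg Digits — into
  ``(channels, bins)`` count rasters, with truncation and strided channel
  subsampling for reduced-footprint networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import h5py
import numpy as np

from .raster import AnalogTrace, SpikeRaster

__all__ = [
    "BeatSegment",
    "delta_modulate",
    "bin_events",
    "truncate_raster",
    "subsample_channels",
    "segment_around_rpeaks",
    "group_labels",
    "extract_beat_dataset",
    "write_event_file",
    "read_event_file",
    "load_wfdb_record",
    "NORMAL_BEAT_SYMBOLS",
    "ANOMALY_BEAT_SYMBOLS",
]

logger = logging.getLogger(__name__)

#: Beat annotation symbols grouped as normal sinus-like beats.
NORMAL_BEAT_SYMBOLS = frozenset({"L", "R", "N"})
#: Beat annotation symbols grouped as arrhythmic / anomalous beats.
ANOMALY_BEAT_SYMBOLS = frozenset({"e", "j", "A", "a", "J", "S", "V", "E", "F", "/", "f", "Q"})

#: Fixed window length (bins) for beat segments centered on the R peak.
BEAT_WINDOW = 180


@dataclass(frozen=True)
class BeatSegment:
    """A 2-channel (UP/DOWN) raster window around one R peak, with its label."""

    raster: SpikeRaster
    label: str  # "normal" | "anomaly"

    def __post_init__(self) -> None:
        if self.raster.n_channels != 2:
            raise ValueError("beat segments carry exactly 2 channels (UP, DOWN)")
        if self.raster.n_bins != BEAT_WINDOW:
            raise ValueError(f"beat segments span exactly {BEAT_WINDOW} bins")
        if self.label not in ("normal", "anomaly"):
            raise ValueError(f"label must be 'normal' or 'anomaly', got {self.label!r}")


def delta_modulate(trace: AnalogTrace, delta: float) -> SpikeRaster:
    """Delta-modulate an analog trace into a 2-channel (UP, DOWN) spike raster.

    A staircase reference ``r`` starts at the first sample.  At each sample,
    while ``signal - r >= delta`` an UP spike is emitted and ``r`` steps up by
    ``delta``; while ``r - signal >= delta`` a DOWN spike is emitted and ``r``
    steps down.  One output bin per input sample; several spikes may land in
    one bin.  The reconstruction ``r`` tracks the signal to within ``delta``
    at every sample.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    signal = trace.samples
    if signal.size == 0:
        raise ValueError("trace is empty")
    counts = np.zeros((2, signal.size), dtype=np.int64)
    reference = signal[0]
    for n in range(signal.size):
        diff = signal[n] - reference
        if diff >= delta:
            n_up = int(diff // delta)
            counts[0, n] = n_up
            reference += n_up * delta
        elif -diff >= delta:
            n_down = int(-diff // delta)
            counts[1, n] = n_down
            reference -= n_down * delta
    return SpikeRaster(counts, dt=trace.dt)


def bin_events(
    spike_times: np.ndarray,
    unit_ids: np.ndarray,
    n_channels: int,
    dt: float,
    t_max: float,
) -> SpikeRaster:
    """Bin (time, unit) events into an ``n_channels x ceil(t_max/dt)`` raster.

    Each event increments ``counts[unit, floor(t/dt)]``.  Events at or beyond
    ``t_max`` are dropped (their count is logged); negative times or
    out-of-range unit ids raise.
    """
    times = np.asarray(spike_times, dtype=float)
    units = np.asarray(unit_ids, dtype=np.int64)
    if times.shape != units.shape:
        raise ValueError("spike_times and unit_ids must have the same length")
    if dt <= 0 or t_max <= 0:
        raise ValueError("dt and t_max must be positive")
    if times.size and times.min() < 0:
        raise ValueError("negative spike times are not allowed")
    if units.size and (units.min() < 0 or units.max() >= n_channels):
        raise ValueError("unit id out of range")
    n_bins = int(np.ceil(t_max / dt))
    keep = times < t_max
    dropped = int((~keep).sum())
    if dropped:
        logger.info("bin_events: dropped %d events at or beyond t_max=%.4g s", dropped, t_max)
    bins = np.floor(times[keep] / dt).astype(np.int64)
    counts = np.zeros((n_channels, n_bins), dtype=np.int64)
    np.add.at(counts, (units[keep], bins), 1)
    return SpikeRaster(counts, dt=dt)


def truncate_raster(raster: SpikeRaster, n_bins: int) -> SpikeRaster:
    """Keep only the first ``n_bins`` bins of a raster."""
    if n_bins > raster.n_bins:
        raise ValueError(f"cannot truncate to {n_bins} bins, raster has {raster.n_bins}")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    return SpikeRaster(raster.counts[:, :n_bins], raster.dt)


def subsample_channels(
    raster: SpikeRaster,
    n_out: int,
    n_augmentations: int = 3,
    scheme: str = "strided",
    seed: int = 0,
) -> list[SpikeRaster]:
    """Select ``n_out`` channels per augmentation by strided index sets.

    Augmentation ``a`` keeps channels ``a + stride * {0, .., n_out-1}`` with
    ``stride = floor(n_channels / n_out)``: distinct phase offsets give
    distinct (though partially overlapping) channel subsets, e.g. three
    256-channel views of a 700-channel raster.  Index sets are fully
    deterministic; ``seed`` is accepted for interface symmetry with the
    random schemes it could host.
    """
    if scheme != "strided":
        raise ValueError(f"unknown subsampling scheme {scheme!r}")
    if n_out > raster.n_channels:
        raise ValueError("n_out exceeds available channels")
    stride = max(1, raster.n_channels // n_out)
    out = []
    for phase in range(n_augmentations):
        idx = phase + stride * np.arange(n_out)
        if idx[-1] >= raster.n_channels:
            raise ValueError(
                f"augmentation phase {phase} overruns {raster.n_channels} channels"
            )
        out.append(SpikeRaster(raster.counts[idx], raster.dt))
    return out


def segment_around_rpeaks(
    raster: SpikeRaster, r_peak_bins: Sequence[int], window: int = BEAT_WINDOW
) -> list[SpikeRaster]:
    """Cut ``window``-bin segments centered on each R-peak bin.

    Each segment spans ``[peak - floor(window/2), peak + window - floor(window/2))``
    (half-open, 0-based).  Peaks whose window would cross a record edge are
    dropped.  No peaks yields an empty list.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    half = window // 2
    segments = []
    for peak in r_peak_bins:
        start = int(peak) - half
        stop = start + window
        if start < 0 or stop > raster.n_bins:
            continue
        segments.append(SpikeRaster(raster.counts[:, start:stop], raster.dt))
    return segments


def group_labels(annotation_symbols: Sequence[str]) -> list[str | None]:
    """Map beat annotation symbols to ``"normal"`` / ``"anomaly"`` classes.

    Normal: L, R, N.  Anomaly: e, j, A, a, J, S, V, E, F, /, f, Q.  Symbols
    outside both sets map to ``None`` (excluded; their count is logged) so the
    output stays aligned with the input.
    """
    out: list[str | None] = []
    n_unknown = 0
    for symbol in annotation_symbols:
        if symbol in NORMAL_BEAT_SYMBOLS:
            out.append("normal")
        elif symbol in ANOMALY_BEAT_SYMBOLS:
            out.append("anomaly")
        else:
            out.append(None)
            n_unknown += 1
    if n_unknown:
        logger.info("group_labels: excluded %d beats with unlisted symbols", n_unknown)
    return out


def extract_beat_dataset(
    raster: SpikeRaster,
    r_peak_bins: Sequence[int],
    annotation_symbols: Sequence[str],
    window: int = BEAT_WINDOW,
) -> tuple[np.ndarray, np.ndarray]:
    """Segment a 2-channel raster around R peaks and attach binary labels.

    Returns ``(segments, labels)`` where ``segments`` is
    ``(n_kept, 2, window)`` and ``labels`` is 0 for normal, 1 for anomaly.
    Beats with unlisted symbols or edge-clipped windows are dropped; the two
    outputs stay aligned.
    """
    if len(r_peak_bins) != len(annotation_symbols):
        raise ValueError("peaks and symbols must align")
    labels = group_labels(annotation_symbols)
    half = window // 2
    kept_segments, kept_labels = [], []
    for peak, label in zip(r_peak_bins, labels):
        if label is None:
            continue
        start = int(peak) - half
        stop = start + window
        if start < 0 or stop > raster.n_bins:
            continue
        kept_segments.append(raster.counts[:, start:stop])
        kept_labels.append(0 if label == "normal" else 1)
    if not kept_segments:
        return np.zeros((0, raster.n_channels, window), dtype=np.int64), np.zeros(0, dtype=np.int64)
    return np.stack(kept_segments), np.asarray(kept_labels, dtype=np.int64)


# ---------------------------------------------------------------------------
# event-format HDF5 I/O (public spiking-dataset layout: spikes/times,
# spikes/units as per-sample ragged arrays, plus an integer labels vector)
# ---------------------------------------------------------------------------

def write_event_file(
    path,
    times: Sequence[np.ndarray],
    units: Sequence[np.ndarray],
    labels: Sequence[int],
) -> None:
    """Write per-sample spike (times, units) lists and labels to HDF5."""
    if not (len(times) == len(units) == len(labels)):
        raise ValueError("times, units and labels must have equal length")
    vlen_f = h5py.special_dtype(vlen=np.dtype("float64"))
    vlen_i = h5py.special_dtype(vlen=np.dtype("int64"))
    with h5py.File(path, "w") as f:
        grp = f.create_group("spikes")
        ds_t = grp.create_dataset("times", (len(times),), dtype=vlen_f)
        ds_u = grp.create_dataset("units", (len(units),), dtype=vlen_i)
        for k, (t, u) in enumerate(zip(times, units)):
            ds_t[k] = np.asarray(t, dtype=np.float64)
            ds_u[k] = np.asarray(u, dtype=np.int64)
        f.create_dataset("labels", data=np.asarray(labels, dtype=np.int64))


def read_event_file(path) -> tuple[list[np.ndarray], list[np.ndarray], np.ndarray]:
    """Read an event-format HDF5 file; returns (times, units, labels)."""
    with h5py.File(path, "r") as f:
        times = [np.asarray(t, dtype=np.float64) for t in f["spikes/times"]]
        units = [np.asarray(u, dtype=np.int64) for u in f["spikes/units"]]
        labels = np.asarray(f["labels"], dtype=np.int64)
    return times, units, labels


def load_wfdb_record(record_path: str, annotation_ext: str = "atr"):
    """Load a WFDB record + beat annotations (signal, peak samples, symbols).

    Requires the optional ``wfdb`` package; everything else in this module
    works from plain arrays, so this loader is only needed when reading
    clinical archives directly.
    """
    try:
        import wfdb  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "loading WFDB records requires the optional 'wfdb' package; "
            "pass (signal, r_peak_samples, symbols) arrays directly instead"
        ) from exc
    record = wfdb.rdrecord(record_path)
    ann = wfdb.rdann(record_path, annotation_ext)
    signal = np.asarray(record.p_signal[:, 0], dtype=float)
    return AnalogTrace(signal, float(record.fs)), np.asarray(ann.sample), list(ann.symbol)
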