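# Methods

## Forward model

The network is purely feed-forward: input spike rasters (integer counts per
channel and per time bin; several spikes may share a 5 ms bin) are expanded
through a frozen delay bank, weighted, and integrated by output neurons.

* **Delay bank.** Per-(channel, synapse) delays are sampled once from a
  log-normal distribution parameterized by the mean and standard deviation
  of the underlying normal on the log-millisecond scale. The calibrated
  default is an arithmetic mean of 22 ms with σ = 0.5 on the underlying
  normal, which brackets measured pristine-state RC delays (8–58 ms);
  mean-based construction uses `μ = ln(mean) − σ²/2`. We read the measured
  "standard deviation of 0.5" as log-scale (dimensionless): with it, the
  printed extreme delays fall within ±2σ of the mean, which a 0.5 ms
  normal-scale deviation could not produce. Delays are quantized to bins by
  round-half-up; two delays mapping to the same bin are indistinguishable
  to the simulation. Spikes delayed past the simulation horizon are
  dropped, never wrapped (causal hardware behavior). Delays are never
  updated by training; the array is write-protected.
* **Neurons.** Discrete-time LIF with exponential-Euler leak
  `α = exp(−dt/τ)` (exact for the linear leak, stable for any dt),
  reset-to-value after a spike, membrane recorded post-reset, initial
  membrane = reset = 0 in normalized units, no refractory period. The
  non-spiking leaky integrator shares the recurrence without threshold or
  reset and serves as the multi-class readout: the logit of a class is the
  maximum of its membrane trace over time.
* **Coincidence detection.** Because the branch current is a weighted
  superposition of delayed spike copies, the peak membrane of an output
  neuron is maximized when copies from different channels align in time;
  with one high-weight synapse at delay Δ\* and a near-zero-delay reference
  branch, a two-spike input crosses threshold only when the inter-channel
  lag is within a bin of Δ\*.

## Device models

* **Delay ↔ resistance.** `R = D / C` with a 400 fF default capacitance.
  The exact capacitance of fabricated arrays is process-dependent, so
  resistance back-calculations are nominal.
* **Weight noise.** Additive Gaussian with σ = `relative_sigma` × max|w|
  over the layer (default 0.10), applied to the effective signed weight
  rather than to the two differential conductances separately, since one
  signed parameter per synapse is trained and the noise calibration is
  expressed as a fraction of the layer maximum. Whether physical noise
  scales with individual device conductance instead is an open calibration
  question; the layer-max convention is implemented.
* **Quantization.** Optional snapping of weight magnitudes to an ascending
  set of programmable conductance levels (8 by default); an exact midpoint
  maps to the lower level (deterministic tie-break); idempotent.
* RNG streams for delay sampling and weight noise are independent and
  separately seeded.

## Spike encoding

* **Delta modulation** converts an analog trace into UP/DOWN spike
  channels: a staircase reference starts at the first sample (avoiding a
  spurious burst at t = 0) and emits one spike per ±δ step needed to track
  the signal, guaranteeing |reconstruction − signal| < δ at every sample.
* **Event binning** floors event times onto the bin grid
  (`counts[u, ⌊t/dt⌋]`), dropping and logging events beyond the horizon;
  1.4 s at 5 ms bins gives 280 bins, truncation to 150 bins keeps 750 ms.
* **Channel subsampling** uses strided index sets with phase offsets
  0, 1, 2 and stride ⌊n_in/n_out⌋ (e.g. three 256-channel views of a
  700-channel raster). Three non-overlapping blocks of 256 cannot fit in
  700 channels, so partially overlapping strided views are the documented
  stand-in for "non-overlapping" augmentation.
* **Beat segmentation** cuts 180-bin windows with ⌊w/2⌋ bins before the R
  peak (half-open, 0-based), drops edge-clipped windows, and groups beat
  symbols {L, R, N} → normal, {e, j, A, a, J, S, V, E, F, /, f, Q} →
  anomaly; unlisted symbols are excluded with a logged count. Equal-size
  train/test splitting of beat sequences is chronological (first half
  train), which is deterministic and avoids leaking future beats.

## Training

Gradients are hand-derived BPTT in numpy. For leaky-integrator readouts
the membrane is linear in the weights, so the max-over-time cross-entropy
gradient is exact (up to the max subgradient). For spiking readouts the
threshold is backpropagated through a surrogate derivative — boxcar of
width 1 (gradient 1 inside |v − θ| < 0.5 θ) by default; a fast-sigmoid
surrogate `1/(1 + k|v − θ|)²` is used for the single-output spike-count
detector because it has no dead zone and keeps silent neurons trainable —
with the membrane gradient blocked at reset (standard detached-reset
treatment). Correctness is checked against central finite differences on
the non-spiking path and against scalar-loop oracles for the dynamics.

The optimizer is Adam with optional decoupled weight decay. Training runs
a noise-free pre-training phase (default 20 % of epochs) followed by
noise-injected training: each batch, weights are perturbed by the RRAM
noise model and the straight-through estimator applies the resulting
gradient to the clean weights; with zero noise this is bit-identical to
plain training. Validation selects the best epoch (accuracy for
multi-class; balanced accuracy for the binary detector, whose integer
spike-count decision threshold is calibrated on the validation split by
exhaustive sweep). Faulty-device retraining clamps masked weights to zero
before every forward pass and zeroes their gradients.

## Synthetic data

The generators produce the statistical structure the architecture assumes,
so the full pipeline is testable offline:

* **CD task** (default study conditions): 600 two-channel spike pairs,
  positive class at a 60 ms lag, negatives drawn uniformly from ±80 ms
  rejecting lags that quantize within one 5 ms bin of the target; negative
  (channel-2-first) lags are included so channel order alone cannot solve
  the task; onsets are randomized so absolute timing is uninformative. A
  spec whose distractor range lies entirely inside the one-bin exclusion
  window is rejected.
* **Synthetic ECG**: quasi-periodic Gaussian-bump beats (P, Q, R, S, T) at
  72 bpm, 360 Hz sampling, additive noise σ = 0.01; anomalous beats
  (default fraction 0.4, near the balance of the most class-balanced
  clinical subject) have a widened, attenuated QRS, no P wave, an inverted
  T wave, and arrive prematurely — a ventricular-ectopic-like morphology.
  It exercises the encoder/segmentation/classification pathway with
  realistic *relative-change* structure; it does not model cardiac
  electrophysiology, inter-patient variability, electrode artifacts or
  rhythm-level anomalies, so passing tests demonstrate the pipeline and
  the architecture's morphology sensitivity, not clinical performance.
* **Spatio-temporal patterns**: per-class (channel, offset) spike
  templates with Gaussian timing jitter and optional random onsets; used
  to show that lag-coded multi-class structure is separable by the delay
  network but not by a delay-free single-layer network of the same size.

## Experiment design choices

* **CD recovery experiment.** Solving a 60 ms lag task hinges on the bank
  containing a delay near the lag, which an 8-synapse draw from the
  calibrated distribution (mean 22 ms) contains only occasionally. The
  driver therefore draws four independent banks and tunes τ over
  {10, 15, 20, 30} ms, selecting on validation accuracy — the software
  analogue of selecting fabricated circuits with suitable delays and of
  per-task hyperparameter tuning. A small decoupled weight decay (0.02)
  favors the sparse coincidence solution and makes the dominant-weight
  recovery robust; recovery is asserted at bin-offset resolution.
* **ECG detector.** 2 × 8 × 1 spiking network (16 weights), τ = 30 ms,
  θ = 1, δ = 0.06 signal units, spike-count MSE loss with target count 4
  for anomalies, 60 epochs of Adam at 0.05. These defaults were tuned on
  the synthetic generator, as task hyperparameters always are.
* **Problem sizes** (600 CD pairs, 200 synthetic beats, 10,000 sampler
  draws) keep every experiment at seconds-scale on one CPU while leaving
  the statistical checks well-powered.

## Known limitations

* At this miniature scale, noise-injected training yields little
  measurable robustness benefit over clean training; the noise sweep
  reproduces the qualitative monotone degradation with σ, but the large
  noise resilience reported for large networks arises from averaging over
  many parameters and is not expected from 16–32-weight models.
* The energy model is a constants-based estimate (58.5 pJ per dendritic
  event; 66.7 % threshold block, <10 % RC + weight path, remainder MUX)
  and deliberately does not attempt system-level power figures, which
  depend on unmodeled activity statistics.
* The device-count rule (2 per weight + 1 delay device per dendritic
  circuit, shared across the outputs of a tree) is the self-consistent
  reading of the published accounting; published per-example device totals
  that contradict the rule are not reproduced.
* Recurrent-baseline training requires an initialization that spikes from
  the start (the boxcar surrogate is zero far from threshold); the
  baseline is provided for architecture comparison, not tuned for
  benchmark parity.
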