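# Methods

This note documents the models, the synthetic data, the numerical choices
and the open design decisions behind `emgforce`. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Signal model of the synthetic generator

A recording session emulates an isometric force-tracking protocol: the
subject follows a guided 6 s sinusoidal force profile
f(t) = A·(1 − cos 2πt/T)/2 at amplitudes A ∈ {0.2, 0.4, 0.6} of maximal
voluntary contraction, ten (by default) repetitions per level, while four
4×8 electrode grids record at 1 kHz. Ramp-and-hold and staircase profiles
are also available.

Each channel of grid g is amplitude-modulated band-limited noise:

    x_{g,c}(t) = w_{g,c} · a_g(t) · n_c(t) + σ ε_c(t)
    a_g(t)     = γ_g · clip(f(t)^{β_g} + δ_g · max(f^{β_g}) · s(t), 0, ·)

* `n_c` — unit-variance 20–500 Hz Gaussian carrier, independent per channel
  (an optional correlation parameter mixes in a grid-shared carrier; the
  default is 0 because inter-channel noise correlation of the target
  hardware is uncharacterized, so it is exposed rather than asserted).
* `w_{g,c}` — nonnegative spatial weights, a smooth Gaussian bump over the
  grid normalized to unit RMS. The normalization is deliberate: electrode
  coverage is comparable across muscle sites, so the *relative* intensity
  between grids is carried entirely by the gains γ_g, and the per-grid
  activation-level index is not confounded by where a random bump happens
  to sit.
* `γ_g` — grid gains, default (1.0, 0.45, 0.35, 0.25). Exactly one grid is
  dominant (ties are rejected). These emulate a task in which one muscle
  group leads and three co-activate at 25–45 % of its drive.
* `β_g` — per-grid nonlinearity exponents, default (1.0, 1.2, 1.0, 1.1):
  co-active muscles need not be proportional to force.
* `δ_g` — slow neural-drive fluctuation (white noise low-passed at 3 Hz,
  scaled relative to the activation peak), default (0.02, 0.12, 0.12,
  0.12). This is the feature that makes the benchmark informative: the
  dominant muscle tracks the target faithfully while co-active muscles
  drift, so their envelopes correlate less with force. Without it every
  grid's representative signal is a near-perfect copy of force and no
  method could justifiably prefer one input over another.
* `σ` — additive wide-band sensor noise, default 0.01 (recording units,
  versus O(0.1–1) signal amplitudes): baseline noise in a good surface
  recording sits well below the physiological signal.
* Bad channels (saturated constants with polarity spikes, or dead zeros)
  can be injected at stated (grid, channel) positions.

What the generator is **not**: it contains no motor-unit action-potential
trains, no inter-grid crosstalk, no electrode-shift or motion artifacts,
and its "measured" force equals the target plus optional low-pass tracking
jitter. Passing tests therefore demonstrate that the pipeline recovers
amplitude-and-fidelity structure from envelope-level signals; they do not
certify performance on physiological recordings.

Determinism: every cycle derives from an explicit seed via
`numpy.random.SeedSequence`; no random draw depends on parameter values, so
scaling a gain scales the affected channels exactly proportionally.

## Preprocessing

Repair → filter → envelope → normalize, per contraction cycle:

* **Bad-channel repair** precedes filtering (saturated channels would
  corrupt filter transients). A channel is flagged if its peak |amplitude|
  leaves [floor, ceiling] (defaults 1e-7, 1e3 recording units) or its
  variance exceeds the grid median by more than 5 median absolute
  deviations. Replacement is the sample-wise mean of valid 4-connected
  neighbors on the 4×8 grid (10 mm pitch makes physical adjacency the
  natural notion); a flagged channel with no valid neighbor falls back to
  the mean of all valid channels; a fully flagged grid is an error.
* **High-pass**: 81-tap Hann-window FIR, 20 Hz cutoff, built by spectral
  inversion of a unity-DC low-pass so DC is rejected exactly. Applied
  forward-backward (zero phase) to keep envelopes time-aligned with force;
  the effective magnitude response is the square of the design response.
  The filter is toggleable, since hardware that already band-passes 20–500
  Hz makes it partially redundant.
* **Envelope**: full-wave rectification, then a centered 100 ms moving
  average whose window shrinks at the edges (true mean of available
  samples — no zero-padding bias).
* **Normalization**: force by its cycle maximum; envelopes by the single
  maximum over all 128 channels of the cycle, preserving inter-grid
  amplitude relations (which the activation-level index depends on).

## PCA extraction

Covariance (not correlation) PCA of each grid's mean-removed envelope
matrix — channels share units, so per-channel standardization would be
wrong. Eigendecomposition via `numpy.linalg.eigh`; eigenvalues clipped at
zero (rank-deficient input is legal). Eigenvector sign is fixed so each
component correlates nonnegatively with the grid-mean envelope, giving
force-tracking components positive polarity.

Selection keeps the smallest N with cumulative variance ≥ 0.85. Across the
training cycles of a fold the count is harmonized to the *minimum*, and
held-out cycles use exactly that count with the threshold ignored, so the
model input width never varies between training and testing.

**Min–max scaling is sign-preserving.** The model inputs are scaled as
x′ = (x − min)/(max − min) with one global (min, max) pair over every
selected component of the training cycles. An alternative reading of the
scaling rule — rectify to |x| first — was rejected on structural grounds:
component scores are zero-mean, so rectification folds the rising and
falling phases of each contraction onto the same input value, making the
EMG→force map non-injective and unlearnable by construction. The bounds
are computed over the training set (per-cycle bounds are available via
config) and reapplied without clipping to held-out cycles.

## DBN regressor

Four layers (input, two sigmoid hidden, linear output); hidden width 80
for one-dimensional input, 100 for multi-grid input. Training:

1. **CD-1 pre-training**, layer by layer: RBM 1 has Gaussian visible units
   on standardized inputs (reconstruction is the linear mean); RBM 2 has
   Bernoulli visible units fed RBM 1's hidden probabilities. Probabilities
   (not samples) propagate between stacked RBMs by default — lower
   variance; sampling is available. Defaults: 10 epochs, learning rate
   0.05, momentum 0.9, batch 64. These are implementation choices, not
   reported facts, and are exposed in `DBNConfig`.
2. **Fine-tuning**: full backpropagation on MSE, mini-batch gradient
   descent with momentum (lr 0.01, momentum 0.9, batch 64, up to 200
   epochs), early-stopped when validation MSE fails to improve for 20
   epochs; the best-validation snapshot is restored, so the returned
   model's validation error never exceeds the final epoch's.

**Input standardization uses one shared mean and scale across features**,
not per-feature statistics. The joint min–max normalization exists to
encode which muscle is strongly activated in the relative amplitudes of
the inputs; per-feature standardization erases exactly that information
and, downstream, biases the impact-value analysis toward small-amplitude
inputs (a steep learned slope against a compressed input inflates its
apparent impact under multiplicative perturbation).

The mapping is per-sample (no temporal context window). Envelopes are
band-limited far below 50 Hz, so training samples are decimated from
1 kHz to 100 Hz by default to control training-set size.

Numerical notes: numerically stable sigmoid; divergence (non-finite loss
or weights) raises an explicit error naming the phase; full training under
a fixed seed is bit-reproducible; analytic gradients are verified against
central finite differences in the test suite.

## Mean impact value

For the trained model and a cycle's input matrix P (m × n), input k is
scaled by (1 ± 0.10) with all other rows fixed, and
MIV_k = mean over samples of the output difference. Signs are retained
internally (negative means the estimate falls as the input grows); ranking
uses |MIV|, ties broken by lower input index (ties are measure-zero). When
a grid contributes several inputs, the grid's priority is the maximum
|MIV| among them. The perturbation acts on the normalized model inputs —
the scale on which the sample matrix actually enters the network. Reports
are computed per cycle (pooled evaluation is available).

## Protocol and evaluation

Per force level: a fixed seeded draw of validation cycles (2 of 10 by
default) used only for early stopping, and leave-one-out cross-validation
over the remainder. Five conditions are compared — each single grid and
all four — with the architecture following the input width. One model per
force level (matching per-level reporting; a pooled mode exists). A master
seed fans out deterministically to the generator, the splitter and every
fold's trainer, and fold seeds also hash the condition and the test-cycle
index so folds are decorrelated.

Leakage rules (enforced by tests): harmonized component counts, min–max
bounds and model weights derive from training cycles only; corrupting a
held-out cycle must leave them bit-identical.

Metrics: RMSD = √(Σ(y−ŷ)²/N); R² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)², which may be
negative for poor fits (no flooring); Pearson r; activation level
I_j = Σ_{i=1}^{32} RMS_j(i)² on 128-channel-normalized envelopes. The R²
total sum of squares runs over all N samples — the alternative of dropping
the first term would be arbitrary and is treated as a typographical slip
in the formula this follows.

## Benchmark problem sizes

The recovery study (`run_recovery_benchmark`, also what the acceptance
script runs) uses 3 force levels × 5 cycles per session, ten sessions,
with training samples decimated to 100 Hz and LOO folds at the top force
level only — small enough to run in minutes on one CPU while still
exercising every pipeline stage, and sized so each fold trains on ~1 800
samples, comfortably above the capacity needed for these smooth
one-to-four-dimensional mappings.

## Known limitations

* Amplitude-modulated noise is not a motor-unit model: no recruitment or
  firing-rate structure, no crosstalk, no fatigue, no electrode shift.
* Conclusions about dominant-muscle sufficiency on synthetic sessions
  follow partly from the generator's own design (the dominant grid is both
  strongest and most faithful); the benchmark validates recovery, not the
  physiological claim itself.
* One hyperparameter set per experiment; no per-subject tuning, no
  transfer across sessions, no real-time path.
* CD-1 pre-training hyperparameters are conventional defaults; they were
  not tuned against any external reference.
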