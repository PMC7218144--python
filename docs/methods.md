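# Methods

This note documents the modelling choices, conventions, and defaults of
`ecogfm`, and what its synthetic validation does and does not establish.

## Task model and data layout

A mapping session is modelled as ten alternating fixed-length blocks —
control (broadband noise listening) first, then active (story listening),
five of each, a different story per active block — sampled at `fs` Hz
(default 1200, block duration 30 s). Sample indexing is 0-based and all
block intervals are half-open `[start, end)`, so window arithmetic is exact.
Annotations live in a JSON sidecar next to the signal container (CSV, HDF5,
or read-only EDF) rather than in embedded format events, which keeps plain
text fixtures first-class. Amplitudes are carried unscaled (nominally µV);
nothing in the pipeline rescales implicitly, because variance-sensitive
features (activity, AR innovation variance ρ) must see the data as stored.

## Segmentation

Trimming keeps exactly `[first block start, last block end)` and re-indexes
annotations; it is idempotent. Windows (default 600 samples / stride 100)
never straddle block boundaries and are dropped rather than padded at the
block end, so the count is exactly `floor((L − width)/stride) + 1` and every
window statistic is computed on real signal. No spectral filtering is
applied anywhere: the premise of the method is that discriminative structure
spans the full spectrum, and the generator produces band-limited effects
that the features must find on their own.

## Sub-blocks: the classification instance

The networks classify *sub-blocks*: contiguous segments of a block's
per-window feature sequence, default 20 windows long (≈ 2.1 s of signal)
advanced by 5 windows. A default active block therefore yields 68 sub-blocks
and a channel 5 × 68 = 340 — "hundreds of sub-blocks with reasonable
overlap", which gives the majority vote a deep pool of weakly dependent
calls. The segment length is a genuine design choice: one extreme (a single
segment spanning the whole block) leaves only five votes per channel; the
other (one window per segment) gives the sequence models nothing to model.
The default sits where the LSTM path sees a meaningful sequence while the
vote still aggregates hundreds of calls. Each sub-block inherits its
channel's label during training; control-block sub-blocks are used only by
the control-twin (CT) experiments.

## Time-domain features

Per window: mean, skewness, excess kurtosis, peak-to-peak, and the Hjorth
parameters. Fixed conventions (population 1/N moments; skew/kurtosis defined
as 0 on zero-variance windows; first differences as the derivative, no `fs`
scaling) are documented in `time_features` together with their invariances —
activity scales as gain², mobility/complexity are gain- and offset-invariant,
and a sinusoid at frequency f has mobility `2·sin(πf/fs)`. These identities
are the test oracles. Feature z-scoring is fitted on the training fold only
(inside `train_model`) and applied unchanged to validation and test data;
whether and how to normalize was an open choice, and fold-local z-scoring is
the conservative leakage-free option.

## Autoregressive features

Each block's AR model uses the minus-sign convention
`x[n] = −Σ a[k]x[n−k] + w[n]`; converters to the plus convention exist for
interop. Burg's method is implemented directly (forward/backward prediction
error minimization; reflection coefficients bounded by 1 in magnitude; the
Levinson–Durbin order update; ρ non-increasing in order), with Yule–Walker
and lagged least-squares fits serving as independent oracles in the tests.
AR features are computed per block, not per sub-block: a 20-coefficient fit
on 600 samples would be noise-dominated, and the fusion architecture pairs
one spectral vector with each of its block's sub-block sequences. The
default order p = 20 is configurable; AIC and final-prediction-error order
selection are provided (computed from the Burg error-power path), with the
caveat that AIC is not consistent — on long AR(2) realizations its *modal*
choice is 2 but individual draws overshoot.

## Network family and training

All variants share a small set of modules: a stack of same-padded 1-D
convolutions over the window axis (defaults 64/128/64 filters, kernels
8/5/3), an LSTM (64 units) whose final state joins the pooled convolutional
features, a one- or two-layer fully connected frequency module, and fusion
by concatenation — never stacking or element-wise products, so the two
domains may have different widths. Convolution-path fusion (`AT_AR2`) tiles
the frequency vector across time steps; FC-path fusion (`AT_AR3/4`)
concatenates it once. Layer sizes are deliberate defaults, not tuned
constants; every behavioural guarantee in the tests holds for the reduced
"small" preset (8/16 filters, 8 LSTM units) used in CI.

Training minimizes binary cross-entropy with Adam (lr 1e-3, batch 32),
dropout 0.3 before the head, and early stopping (patience 10) on a held-out
*channel-grouped* slice of the training channels, so the stopping rule never
sees test channels either. Runs are deterministic for a fixed seed: numpy
generators drive initialization, shuffling and dropout, and the engine is
pure float64 numpy. The sigmoid threshold is fixed at 0.5 (a probability of
exactly 0.5 is a negative call — positivity requires strict majority
evidence); class imbalance is handled by undersampling, never by threshold
tuning.

The autodiff engine (`ecogfm.nn`) implements exactly the required ops with
reverse-mode gradients, including full backpropagation through time for the
LSTM; correctness is established by central-difference gradient checks in
the test suite.

## Validation protocol

Each repeat: rebalance (keep all PRCs, undersample NRCs with a
repeat-derived seed), draw a class-stratified test set of channels (default
fraction 0.2, at least one channel per class on each side), train, predict
all test sub-blocks, vote, score. Grouping by channel is the load-bearing
constraint — sub-blocks of one channel are strongly dependent, and any
leakage across the split would inflate every metric. Abstentions (exact
vote ties) are counted and excluded from metric denominators; they are
vanishingly rare with hundreds of sub-blocks per channel. "Block accuracy"
denotes sub-block-level accuracy; the channel-level numbers are what matter
clinically.

## Synthetic cohorts

The generator emulates the statistical skeleton of a mapping session:

* baseline: a stationary AR process with a strong real pole (default 0.97),
  giving the 1/f-like spectrum of cortical recordings; innovation variance 1;
* PRC effect: an additive AR(2) resonance centred in 70–170 Hz whose
  innovation variance is set *analytically* from the baseline spectrum so
  active-block in-band power is `effect_gain` (default 4) times the control
  level — so band power, mobility, and the AR coefficients are all
  discriminative by construction, and `effect_gain=1` is an exact null;
* heterogeneity: per-channel gain (±20%) and pole jitter (±0.005), and
  per-story effect-amplitude jitter (±20%) so story-separated training has
  structure to exploit;
* cohort: default 10 PRC + 30 NRC, the 3:1 imbalance of clinical grids;
* `variance_neutral=True` rescales every block to the channel's nominal
  process variance, confining the class signal to spectral shape — the
  regime where a variance-only time-domain model must fail and domain
  fusion must win.

The effect size is a free knob of the simulation, not an estimate of any
clinical effect. Not emulated: within-block non-stationarity, evoked
transients, line noise, artifacts, and spatial correlation between
channels. Consequently, passing results demonstrate that the machinery is
correct and that the method recovers planted effects of plausible structure
— they say nothing quantitative about clinical accuracy.

## Problem sizes and numerical choices

The end-to-end checks run at the paradigm's native scale (1200 Hz, 30 s
blocks, 40–80 channels) but with the small model preset, 15 epochs, and 5–10
repeats, sizes chosen so the whole suite completes in a few minutes on one
core; unit tests of the generator and features use a reduced paradigm
(200 Hz, 2 s blocks, effect band 30–70 Hz) where closed forms are equally
valid. Degenerate inputs are explicit errors (zero-variance windows for
Hjorth, zero-variance signals for AR, single-class training sets); windows
with undefined features can be skipped or zero-filled by configuration.
Floating-point identities are asserted at 1e-12 where algebra is exact and
at 1e-9 relative where a rescaling intervenes.

## Known limitations

* EDF support is read-only (16-bit quantization applies); CSV/HDF5
  round-trip bit-exactly.
* The numpy engine is single-threaded and CPU-bound; it is sized for
  hundreds of channels, not for hyperparameter sweeps.
* Per-story training assumes all channels share the same number of stories
  and aligned block geometry.
* The published architecture family fixes topology classes, not layer
  sizes; the defaults here are standard time-series-classification choices
  and everything is configurable.
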