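# Methods

This note records the models, the synthetic-data design, the numerical
choices, and the limitations of `respigate`, in the spirit of a methods
appendix: enough detail that every number the package produces can be
traced to a stated decision.

## Problem setting

Respiration-gated radiotherapy switches the treatment beam on and off at
preselected respiratory phases. The gating decision is driven by a 1-D
surrogate signal (chest-surface distance, sampled at 20 Hz by devices of
the Anzai AZ-733VI class), but the beam-control chain has a latency of
roughly 300-800 ms between the gating decision and the actual beam
state. Compensating that latency requires forecasting the surrogate a
horizon `P_t` ahead from the most recent window of `T_s` milliseconds of
signal. The package trains and compares three sequence predictors for
this task and converts their residual error into millimetres of gating
error at the 30% and 70% respiratory phases.

## Synthetic respiration generator

Patient surrogate records are not public, so every stage is exercised on
synthetic traces built cycle by cycle from a Lujan-type `cos^2n` pulse
(default exponent `n = 2`), which reproduces the asymmetric waveform of
free breathing: a flat exhale dwell and a sharper inhale peak.

For cycle *i*, the period is `tau_i = tau0 + eps_tau` and the
peak-to-valley depth is `b_i = b0 + eps_b`, with independent zero-mean
Gaussian jitter truncated at `0.5*tau0` and `0.2*b0` so no cycle
degenerates. Cycles are valley-anchored: each starts and ends at the
exhale dwell with the peak mid-cycle, so concatenation is continuous
under period jitter and every cycle carries exactly one interior peak of
height `b_i` above its valleys (this is what makes the jitter knobs
directly measurable from detected extrema). Linear baseline drift and
white measurement noise are added on top.

Defaults, chosen once as typical of guided free breathing and then left
alone: period 4 s, unit amplitude, drift 0.002 per s, noise SD 0.01.
The four regularity classes used throughout are `regular` (residual
jitter 0.08 s / 0.03), `type1` (period jitter SD 0.6 s), `type2`
(amplitude jitter SD 0.30) and `type3` (both). Recording lengths are
drawn uniformly from 84.35-272.50 s (the clinical range) unless a caller
narrows it.

What the generator does *not* emulate: cardiac interference, coughing,
breath-holds, apnea, slow drifts of breathing frequency, or any coupling
between surrogate and internal target motion. Tests passing on this
cohort therefore demonstrate correctness of the pipeline and the
direction of its trends, not clinical accuracy on patient data.

## Preprocessing

* Per-signal Z-scoring (population SD) aligns baselines across records;
  the choice of divisor is irrelevant to rankings but is fixed for
  reproducibility.
* Sliding windows move with stride one sample; a record of `N` samples
  yields `N - L - H + 1` (window, target) pairs for input length `L` and
  horizon `H` samples. `T_s` and `P_t` must sit on the 50-ms grid;
  off-grid values are rejected rather than resampled.
* Whole signals are reserved for the test role; the remaining signals
  are split temporally 7:3 (first 70% of samples for training windows,
  the rest for validation) so no validation window contains samples seen
  in training. A random split would leak future samples in a
  forecasting task.
* A Savitzky-Golay filter (window 5 samples = 250 ms, polynomial order
  2, mirror padding) smooths *predicted* series as a postprocessing step
  before any metric; raw signals enter the networks unfiltered. A
  config flag can additionally filter training targets; it defaults to
  off.

## Irregularity taxonomy

A signal's irregularity value is `(STD(peaks) + STD(valleys)) / 2`
(population SDs), computed on extremum amplitudes (amplitude
irregularity) or on peak-to-peak and valley-to-valley periods (phase
irregularity). Peaks and valleys come from prominence-based detection
(minimum separation 1.5 s, prominence 0.2 of the signal's SD) with
strict alternation enforced by dropping the lesser of two same-kind
neighbours.

Signals are linearly detrended before profiling: a drifting baseline
shifts every extremum in proportion to the record length, so without
detrending the measured amplitude irregularity of a perfectly regular
breather grows with how long the recording ran — a confounder, not a
property of the breathing. A flag restores raw-signal profiling.

Cohort classification ranks after standardizing both axes within the
cohort (amplitude z-units and period seconds are incommensurable, so a
raw sum would be dominated by one axis). Four disjoint groups of equal
size are assigned with exclusion, in the order: highest combined score
type3, then highest phase score type1, then highest amplitude score
type2, then lowest combined score regular; ties break by signal id. A
`swap_type12` switch exchanges the roles of the two axes, since the two
conventions both appear in the gating literature.

## Predictors

All three models map a `T_s` window (20 samples at the standard
1000 ms) to one scalar.

**LSTM** — stacked standard LSTM cells (forget/input/candidate/output
gates) with an affine readout of the final hidden state. The default
stack is 3 layers of 15 hidden units. The deep-narrow transpose (15
layers of 3 units) is configurable but was found untrainable under the
study protocol at desk scale: with Adam at learning rate 1e-4 the
input signal dies across the narrow stack and the regular-group test
correlation plateaus near 0.93 regardless of initialization, whereas
the 3x15 configuration reaches the accuracy regime the comparison study
reports. A `tied_input_candidate` flag makes the input gate share the
candidate's parameters (the literal reading of the usual gate
equations, which reuse one weight matrix for both).

**Bi-LSTM** — a second, independent stack consumes the time-reversed
window; the final hidden states of the two directions are combined
affinely, `y = W_f h_fwd + W_b h_bwd + b`.

**Transformer** — the original encoder-decoder architecture: scalar
embedding to a 64-dim model width plus sinusoidal position encodings; 6
encoder and 6 decoder layers (4/4 configurable); 8-head scaled
dot-product attention (`d_k = 8`); position-wise feed-forward width 256
with ReLU; residual connections with post-layer-norm. The decoder input
is the window shifted by one position (zero start token) with look-ahead
masking, and the last decoder position is read out; this keeps the
one-step-offset teacher forcing of the original design while supervising
only the `P_t` target.

All parameters are drawn uniform with fan-in scaling from the model
seed; arithmetic is float32 by default (float64 configurable), on a
small in-package reverse-mode autodiff core with a fused
backpropagation-through-time primitive for the recurrent layers.

## Training protocol

Adam with learning rate 1e-4, L2 weight decay 2e-4 (added to the
gradient, not decoupled), beta1 = 0.9, beta2 = 0.999, mini-batches of
300 pairs, mean-squared-error loss. After every epoch the validation
loss is computed and the parameter snapshot with the smallest validation
loss so far is retained; the best snapshot is restored at the end of
training. Identical seeds give bit-identical runs.

## Accuracy metrics and comparisons

RMSE and Pearson correlation are computed per signal over its
latency-compensated, S-G-smoothed predicted series against the actual
series, then averaged across signals (pooled-over-windows is available
but per-signal averaging keeps long records from dominating). Model
differences are tested with a one-way ANOVA over the per-signal metric
values, one group per model.

## Gating feasibility in millimetres

The surrogate is assumed identical to tumor motion with a 10-mm
peak-to-peak excursion (5 mm selectable). The affine map that takes the
*actual* signal's global range to 10 mm (maximum at +5 mm) is applied to
both actual and predicted series, so a systematic amplitude error in the
forecast is preserved rather than rescaled away. Scaling is global per
record, not per cycle, so amplitude irregularity survives.

Each breathing cycle runs peak-to-peak (phase 0% at the inhale peak, the
4DCT convention) and phase grows linearly to 100% at the next peak. The
30% and 70% gates of cycle `[t_k, t_k+1]` sit at
`t_k + 0.3/0.7 (t_k+1 - t_k)`. Gates are located on the *predicted*
signal, and the error at each gate is the absolute difference between
the two series at that time, with linear interpolation between samples;
an alternative reading (gates from the actual signal) is available
behind a flag. Mean and maximum are aggregated over cycles, then over
the representative signals of each pattern.

## The scaled-down reference study

The clinical experiment (540 signals, 100 epochs) is reproduced in
structure at a size a single CPU completes in minutes; all sizes below
are the package's own choices and are fixed:

* cohort of 40 signals (30 regular, 4 type1, 3 type2, 3 type3),
  85-135 s each; stratified test split of 4 signals plus a held-out
  evaluation set of 6 signals per pattern;
* `T_s = 1000` ms; `P_t` in {300, 500, 700, 900} ms; epoch budgets are
  allocated by measured convergence need: the recurrent stacks run 30
  epochs at 300 and 500 ms (the 300 ms cell gets the full budget so the
  latency comparison reflects task difficulty rather than training
  budget) and shortened 15/12-epoch schedules at the harder 700/900 ms
  horizons; the transformer, which converges within ~100 optimizer
  steps, runs 30 epochs at 500 ms and 12 elsewhere;
* training windows: a 24000-window subsample for the recurrent models
  (they need the optimizer steps) and 1500 for the transformer (each of
  its steps costs two orders of magnitude more); validation-loss
  subsamples of 3000 and 600 windows respectively;
* scoring and gating use stride-1 series over the first 60 s of each
  scored signal (~15 breathing cycles).

`scripts/acceptance.py` runs exactly this study plus the 4x48 taxonomy
recovery check and writes every measured quantity as JSON.

## Numerical and degenerate-input conventions

* Constant signals cannot be z-scored or mm-scaled (degenerate-signal
  errors); fewer than two peaks or valleys is an insufficient-cycles
  error; windows that do not fit a record raise rather than truncate.
* The attention mask adds -1e9 before the softmax; softmax subtracts the
  row maximum.
* Ties in cohort ranking break lexicographically by signal id, making
  classification deterministic even for identical signals.
* Checkpoints and windowed datasets persist as zip-of-`.npy` archives
  written with fixed timestamps, so identical content is byte-identical
  and experiment manifests (SHA-256 per artifact) reproduce exactly
  under reruns; the run log (which contains wall-clock timings) is
  excluded from the manifest.
* Master seeds fan out to stages via `SeedSequence([master, stage])`;
  no stage reads a shared global random stream.

## Limitations

* Synthetic cohorts only; absolute RMSE/CC/mm values are not comparable
  to patient-data results, only the direction and ordering of effects.
* The desk-scale step budget under-trains all models relative to the
  clinical study, most visibly the recurrent ones at the reduced-epoch
  horizons.
* The 1-D surrogate is treated as identical to tumor motion; no
  surrogate-to-target model is included.
* Training is single-threaded CPU; there is no accelerator path.
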