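# Methods

`rovingnet` is a synthetic re-creation of a study design in which
group-level auditory-evoked fields (AEFs) recorded during a roving-oddball
paradigm are first characterised at the sensor level, then used as training
targets for a hierarchical recurrent network whose sign-partitioned
recurrent weights are perturbed post-training to probe the consequences of
reduced inhibition. No empirical recordings are involved anywhere: the
synthetic-data stage is a first-class, tested component whose defaults
define the study conditions.

## Stimuli

The roving-oddball stream presents runs of identical tones (250, 500 or
1000 Hz) whose frequency changes at run boundaries; run lengths are uniform
on [3, 12], the first tone of a non-initial run is the deviant (D), the
second the first repeat, the rest standards (S). Events are spaced 550 ms
apart. The network-input product is different: a 548 ms three-tone "triad"
waveform at 5000 Hz (50 ms unit-amplitude sinusoids, phase 0, separated by
two exact-zero 199 ms gaps). A triad is D iff its third frequency differs
from the first two, which are always equal. The two timing conventions
(550 ms SOA stream for the sensor side, 199 ms-gap triad for the network
side) are deliberately distinct products and never mixed. Tones carry no
amplitude ramps and are not loudness-equalised across frequencies — the
simplest defensible stimulus.

## Synthetic evoked fields

Time is trigger-relative; the tone starts 50 ms after the trigger (a fixed
presentation delay of the emulated acquisition setup), and all latencies
are quoted post-trigger.

A group AEF template is

    c(t) = p · A · [ (1 − β) · exp(−(t − L)² / 2σ²)
                     + β · ramp(t) · cos(2π (t − L) / T) ]

with polarity p = −1, peak amplitude A (181 fT control, 192 fT case), peak
latency L (144 ms control, 203 ms case; shifted per stimulus frequency by
tonotopic offsets so that control tones of 250/500/1000 Hz peak at
152/148/136 ms), Gaussian deflection width σ = 50 ms, and a sustained
evoked ringing component of relative weight β = 0.761 and period
T = 249 ms, ramped in smoothly between 60 ms and L (`smoothstep`), zero
before the trigger. For deviants the samples inside the deviant window
(150–180 ms post-trigger) are multiplied by the deviant gain (default 1.3).

Two template constants are calibrated rather than free:

* **β = 0.761** is solved so that the robust-scaled training target derived
  from the template peaks at 0.94 — the scale of the study's reported
  pre-perturbation predictions. Group-average evoked fields are not a lone
  deflection; the transient rides on slower evoked activity of comparable
  magnitude, and this share reproduces that ratio of peak to
  interquartile range. Without it the derived targets are ~2.6× too large
  relative to the fixed label noise, and the modelling stage runs at the
  wrong signal-to-noise ratio.
* **T = 249 ms** equals the triad's inter-tone onset interval (~4 Hz,
  theta band). A 249 ms-periodic target is invariant under tone-spaced time
  shifts, i.e. expressible as a superposition of identical per-tone
  responses. This is the regime in which a causal, weight-shared recurrent
  network can reproduce the target for tone prefixes never seen in
  training; with an aperiodic target the network must suppress later-tone
  responses through input-bin-specific weights, which cannot transfer to
  the held-out 1000 Hz prefix (verified empirically: such variants plateau
  at test losses ~2× the noise floor).

Sensor epochs span −400 to 550 ms at 1000 Hz. Each trial is
`gain_c × template(condition)` plus i.i.d. Gaussian sensor noise
(default 100 fT). Channel gains follow a dipolar pattern — two balanced
opposite-sign Gaussian lobes over the right half of a regular 8×8 sensor
sheet, normalised to unit peak gain — so gains sum to ~0 across the sheet.
The deviant enhancement is applied only at the 12 largest-|gain| channels
(the planted "cluster"), so the S–D contrast is confined in space and time.
Defaults: 150 trials per condition in the pipeline; the deviant gain 1.3
gives the downstream cluster test power near 1 at that size. What the
generator does **not** emulate: forward fields from dipole sources through
a head model, realistic (1/f, correlated) MEG noise, artefacts, or
inter-subject variability; trials are exchangeable draws around one
group-level truth, with deviants and standards in equal numbers.

## Sensor-space analysis

Preprocessing is order-stable: zero-phase low-pass (4th-order Butterworth,
30 Hz, applied forward–backward so peak latencies are undistorted) →
decimation to 250 Hz (anti-aliasing already guaranteed by the low-pass) →
per-channel baseline correction over −400..0 ms → trial rejection
(peak-to-peak > 4000 fT at any channel, or < 1 fT at every channel).
Evoked responses are arithmetic trial means per channel. Peak detection
returns the maximum-|value| sample in a search window (default 100–300 ms
post-trigger), ties broken toward the earliest time; across channels the
globally largest-|value| channel is selected first. Group peak metrics are
taken on the standard-evoked average: deviants are rare in the emulated
recordings but half the synthetic trials, so a pooled average would
over-weight the deviant enhancement.

The cluster-based permutation test computes per-(channel, time) Welch t
statistics between conditions (consistent with the fractional degrees of
freedom the study reports), groups suprathreshold points (|t| > 3.3) into
spatio-temporally connected clusters (channel adjacency = grid neighbours
within one step; temporal adjacency = consecutive samples; positive and
negative exceedances separate), and scores each cluster by its summed t.
The null distribution records the maximum |cluster mass| over 1000
label-only permutations of trials — permuting time points as well would
destroy autocorrelation and inflate sensitivity. p-values use the
(1 + exceedances)/(1 + permutations) estimator, which is never
anticonservative under the null; type-I error is verified by a
200-replicate null simulation in the test suite. The mismatch score is the
mean |D − S| over a channel set × time window (the mean absolute error
between the two evoked responses).

## Network model

Inputs are short-time Fourier magnitudes of the triad waveform: Hann
window of 125 samples, hop 20 (105-sample overlap), one-sided 125-point
transform → 63 bins of 40 Hz; the waveform is zero-padded at the tail to
2865 samples so exactly 138 frames result, one per 4 ms, aligned one-to-one
with the 250 Hz label grid. Magnitudes are linear, normalised by
sum(hann)/2 so a unit-amplitude tone has magnitude ~1 (inputs on an O(1)
scale; raw magnitudes ~31 let the untrained pathways of held-out bins
dominate the dynamics).

Targets: the S and D templates on the 138-sample post-trigger grid are
robust-scaled (median 0, IQR 1, fitted on the pooled S+D samples),
sign-flipped so the dominant deflection is positive, and replicated 1200×
per condition with i.i.d. Gaussian noise, σ = 0.6 (label-noise MSE floor
0.36). Tone combinations are split by design: standards of 250/500 Hz and
upward deviants train the network; the 1000 Hz standard and downward
deviants are held out for testing. Label replicates are split 70:15:15
into train/validation/test; train and validation instances draw uniformly
from the training combinations, test instances from the held-out ones.

Architecture: a 63-unit input layer (learned linear map with
rectification, no self-recurrence) → four 64-unit rectified recurrent
hidden layers, applied hierarchically (each layer's state sequence is the
next layer's input sequence, h₀ = 0) → a single recurrent output unit with
identity activation whose state is the prediction. Keeping the input layer
non-recurrent matters: with a recurrent input layer the network parks its
temporal structure there, and the perturbation experiments — which address
the hidden layers only — become inert.

Initialisation: Glorot-uniform feedforward weights, orthogonal recurrent
matrices (QR of a standard-normal matrix, sign-fixed; the output unit's
1×1 orthogonal recurrence is unity), zero biases. Training: Adam
(lr 2 × 10⁻⁴, β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁷), MSE over the 138 frames,
10 epochs, batch size 8. The published recipe fixes the learning rate,
epoch count and label count; the batch size is the remaining throughput
dial, and 8 (≈2100 updates) is the smallest-variance setting that reaches
the label-noise floor without overfitting the training combinations.
Dropout (rate 0.15) acts on each hidden layer's input transformation with
one mask per sequence, held fixed across timesteps — the convention of
standard recurrent-layer implementations. Besides regularising, the
per-sequence deletion of input units forces redundancy across spectral
channels, which is what lets tone-onset responses transfer across bins.
Training is float32 against float64 master weights; the time-step scans
are numba-compiled when numba is available (pure-numpy fallback otherwise).

## Perturbation experiments

After training, the recurrent weights of the four hidden layers are
partitioned by sign: positive entries are the excitatory connections,
negative the inhibitory ones (counts start ~1:1 from the orthogonal
initialisation and stay within a few percent of 1:1 after training). Three
experiments scale them multiplicatively at eight levels λ ∈ {0.5 %, …, 4 %},
each applied to the pristine trained model (never cumulatively):

* **negative**: w ← w(1 − λ) for every negative hidden recurrent weight
  (graded inhibition reduction; no sign flips since |1 − λ| < 1);
* **positive**: w ← w(1 + λ) for every positive hidden recurrent weight;
* **random**: a seeded random half of the hidden recurrent weights, with
  positives increased and negatives reduced.

Multiplicative scaling (rather than subtracting a constant) is scale-free
across heterogeneous weight magnitudes. Feedforward weights, biases, the
input layer and the output unit's self-recurrence are never touched.

Per level the battery evaluates test MSE, the mean S- and D-input
predictions (averaged over the test split's distinct stimulus types), their
peak amplitude and latency (100–300 ms search window, the same convention
as the sensor-space peaks), the prediction mismatch score (mean |D − S|),
relative amplitude increases versus the pre-perturbation baseline, and the
latent stability of the fourth hidden layer: its 64×138 activation matrix
(averaged over test inputs) is projected onto its top two principal
components (timepoints as observations, so the trajectory lives in
unit-space), and the start-to-end distance plus convex-hull area of the
2-D trajectory are reported. Degenerate (collinear) trajectories get hull
area 0.

## Numerical and reproducibility choices

Every stochastic step takes an explicit integer seed
(`numpy.random.default_rng`); the pipeline derives per-stage child seeds
from one global seed via `SeedSequence`. Peak ties break toward the
earliest sample. Filtering is zero-phase. Decimation assumes the target
rate divides the raw rate. The robust scaler raises on zero IQR; the PCA
projection raises on zero-variance input. Model parameters, epochs and
results serialise to flat `.npz`/CSV artefacts with a format version.

## Problem sizes

Default study sizes are desk-scale by design: 150 trials per condition,
64 channels, 1000 permutations for the sensor stage; 2400 labelled
instances over 9 distinct stimulus types and ~2100 Adam updates for the
model stage (about 25 s on one CPU per training run). The test suite's
calibration checks use reduced sensor studies (16–64 channels, 20–60
trials, 150 permutations, 200 null replicates, 20 recovery seeds) chosen
to keep the full suite under a few minutes of compute while leaving
Monte-Carlo error well inside the asserted tolerances.

## Known limitations

* The deviant enhancement sits just above the 144 ms response peak, so the
  MSE-optimal causal prediction — the posterior mean over conditions given
  an ambiguous tone prefix — peaks one to two frames late. Trained
  predictions accordingly peak near 148 ms rather than 140 ms; the
  alternative reading of the enhancement window (200–230 ms post-trigger)
  fixes the latency but makes the planted S–D contrast weak and
  mixed-sign, which is the worse emulation.
* Condition identity is only revealed by the third tone (frames 124–137),
  long after the response peak; any D-vs-S difference in the peak metrics
  therefore reflects the composition of the stimulus pools and the learned
  prefix-conditional mixture, not true deviance detection — a property of
  the study design itself, not of this implementation.
* Trained recurrent matrices stay near their orthogonal initialisation, so
  under rectification the effective dynamics remain contractive: the 4 %
  excitation increase degrades the fit several-fold rather than producing
  full runaway, and the balanced random perturbation responds gradedly
  rather than staying flat. The corresponding two property tests in the
  acceptance suite document this as an expected divergence.
* Hidden units are not separate excitatory/inhibitory populations (no
  Dale's law); perturbations are applied post-training only.
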