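# rovingnet

A fully synthetic, end-to-end reimplementation of a mechanistic modelling
study linking **reduced synaptic inhibition** to altered auditory-evoked
cortical responses. The package is aimed at computational neuroscientists
who want a testable, seedable desk-scale version of the entire chain:

1. **Stimuli** (`rovingnet.stimgen`) — roving-oddball tone streams
   (250/500/1000 Hz, 50 ms tones, 550 ms onset asynchrony, runs of 3–12
   repeats) and the three-tone 548 ms waveforms used as network inputs.
2. **Synthetic MEG** (`rovingnet.meg_synth`) — group-level auditory-evoked
   field (AEF) templates and multichannel sensor epochs with a dipolar
   topography, Gaussian sensor noise, and a deviant-response enhancement
   confined to a 12-channel cluster and time window. Control-like
   (144 ms / 181 fT) and case-like (203 ms / 192 fT) parameter sets ship as
   defaults.
3. **Sensor analysis** (`rovingnet.meg_analysis`) — zero-phase 30 Hz
   Butterworth low-pass, 250 Hz downsampling, baseline correction,
   peak-to-peak trial rejection (4000 fT / 1 fT), evoked averaging, peak
   metrics, spatio-temporal cluster-based permutation testing
   (cluster-forming threshold 3.3, α = 0.05), and the mismatch score
   (mean |deviant − standard|).
4. **Recurrent network** (`rovingnet.rnn_core`) — spectrogram encoding
   (Hann 125-sample windows, 105-sample overlap, 63 bins × 138 frames),
   robust-scaled noisy training targets (1200 per condition, σ = 0.6), and
   a hierarchical recurrent model trained to predict the group AEF:

   h_t = ReLU(W_hh h_{t−1} + W_xh x_t + b_h)   (four 64-unit hidden layers)

   y_t = W_hy h_t + w_oo y_{t−1} + b_y          (one recurrent output unit)

   optimised with Adam (lr 2 × 10⁻⁴, dropout 0.15, 10 epochs, MSE over the
   138 frames), with Glorot-uniform feedforward and orthogonal recurrent
   initialisation. Forward pass, backpropagation through time and the
   optimiser are implemented in numpy.
5. **Perturbation lab** (`rovingnet.perturb_lab`) — after training, the
   hidden layers' recurrent weights are split by sign into excitatory and
   inhibitory connections and scaled at eight graded levels (0.5 %–4 %):
   inhibition reduction, excitation increase, and a balanced random
   control; readouts are test loss, peak amplitude/latency of the mean
   standard- and deviant-input predictions, the prediction mismatch score,
   the excitation:inhibition weight-count ratio, and the stability of the
   fourth hidden layer's latent trajectory (top-2 PCA: start–end distance
   and convex-hull area).
6. **Pipeline** (`rovingnet.pipeline`, CLI `rovingnet`) — one seeded,
   resumable run of the whole study from a YAML config.

## Worked example

```bash
rovingnet all --seed 3 --out demo_run
rovingnet report --out demo_run
```

prints (about two minutes on one CPU):

```
rovingnet run report: demo_run
  control: peak 180 fT at 144 ms post-trigger, 2 significant cluster(s), mMMN 26.8 fT
  case: peak 193 fT at 204 ms post-trigger, 2 significant cluster(s), mMMN 20.9 fT
  model: test MSE 0.504, E:I ratio 0.981 (8115:8269)
  negative perturbation MSE over 8 levels: 0.48, 0.45, 0.43, 0.42, 0.41, 0.41, 0.42, 0.43
  positive perturbation MSE over 8 levels: 0.45, 0.42, 0.42, 0.49, 0.66, 0.99, 1.60, 2.48
  random perturbation MSE over 8 levels: 0.46, 0.42, 0.41, 0.44, 0.50, 0.64, 0.87, 1.26
```

Reading the report: the synthetic control group's standard-evoked field
peaks at 144 ms post-trigger (the trigger leads the tone by 50 ms) and the
case group ~60 ms later, recovering the planted latency separation; the
cluster test finds the planted deviant enhancement; the network's held-out
loss (0.50 here; ~0.37–0.43 when trained on clean generator templates
rather than pipeline-estimated ones) sits near the 0.36 label-noise floor;
and the three perturbation rows show the graded inhibition-reduction
response versus the runaway trend of pure excitation increase.

The same stages are available as library calls; see the module docstrings
and `docs/methods.md` for the model's assumptions, parameter meanings and
known limitations.

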