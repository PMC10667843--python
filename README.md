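# spindec

Signal processing, movement decoding, and neural-trajectory analysis for
chronic multichannel recordings from the spinal-cord **ventral horn**,
synchronized with hindlimb joint kinematics — plus a ground-truthed
synthetic-data generator so the whole chain can be exercised and verified
without access to animal recordings.

The package is aimed at researchers working with intraspinal (or other
penetrating) multi-site electrodes who want a tested, reproducible version
of the standard analysis chain for locomotion experiments:

1. **Channel QC** — keep sites whose 1 kHz impedance lies in [100 kΩ, 2 MΩ].
2. **Preprocessing** — common median reference (CMR), a 50 ms / 25 µV
   moving-window artifact mask, a zero-phase 50 Hz notch, and 4th-order
   zero-phase Butterworth band-passes: 300–6000 Hz for spikes, 1–300 Hz for
   LFP, and the seven canonical LFP bands
   (1–4, 4–8, 8–12, 12–30, 30–90, 90–200, 200–300 Hz).
3. **Spike detection** — per-channel threshold `T = mean − k·rms`
   (k = 4.5, or 3 for low-amplitude sessions); spike time = trough of each
   negative excursion; SNR = mean peak-to-peak / 2σ̂ with a robust
   (MAD-based) σ̂; single-unit calls from the fraction of inter-spike
   intervals under 3 ms (single iff ≤ 1%); multi-site footprint statistics
   such as the fraction of units captured entirely within 160 µm of their
   home site.
4. **Features** — for every 60 fps video frame, the preceding 300 ms of
   neural data summarized in 26 windows of 50 ms stepped by 10 ms:
   per-channel spike counts, or the windowed mean of a band-filtered LFP
   (the *local motor potential*); per-band Pearson correlation with joint
   coordinates.
5. **Decoding** — a two-layer LSTM with layer normalization and dropout
   (pure NumPy, hand-derived backpropagation) maps each frame's
   26 × channels tensor to the x/y coordinates of five hindlimb joints
   (toe, ankle, knee, hip, iliac), trained on a contiguous 0.8:0.1:0.1
   train/validation/test split with Bayesian (GP + expected improvement)
   hyperparameter search; a ridge baseline and the coefficient of
   determination `R² = 1 − SS_res/SS_tot` for evaluation.
6. **Trajectories** — firing rates from a 50 ms Gaussian kernel, PCA onto
   the first three PCs (LFP is first downsampled to 1000 Hz), phase-binned
   average loops over step cycles with a closure statistic, and a
   moving/stationary state-separation score.

The synthetic generator (`spindec.synthetic`) emulates the recordings this
chain expects: phase-tuned units (von Mises tuning to the gait phase,
inhomogeneous Poisson spiking with a refractory period, exponential spatial
footprints), a movement-locked field component at the ~3.5 Hz step
frequency, 1/f background, 50 Hz mains, and boxcar motion artifacts, all
synchronized to simulated swing/stance kinematics and fully determined by
one seed.

## Worked example

`examples/` contains one short script per capability. For instance:

```bash
$ python examples/02_preprocess_and_detect.py
masked sample fraction: 0.014
detected events across 32 channels: 9037
recall vs ground truth (±0.5 ms): 0.971
precision: 0.996
mean channel SNR: 13.0 (p2p amplitude / 2 x noise sigma)
```

The recall/precision compare detected threshold crossings with the
simulator's ground-truth spike times at ±0.5 ms; values near 1 mean the
mean−4.5·rms rule recovers essentially every inserted spike without false
alarms, and the SNR sits in the 10–30 range typical of chronic recordings.

```bash
$ python examples/04_decode_kinematics.py
session: 1000 frames, tensor 26 bins x 32 channels
     toe_x  R^2 = 0.952
     ...
ridge baseline toe_x R^2 = 0.828
```

Test-set R² ≈ 0.95 means the recurrent decoder reconstructs the hindlimb
trajectory almost perfectly from the 300 ms of neural history preceding
each frame, clearly beating the linear baseline.

```bash
$ python examples/05_neural_trajectories.py
top-3 PCs explain 57.6% of variance
step cycles: 124, average-loop closure: 0.085
phase-shuffle collapse ratio: 5.5
moving/stationary separation score: 1.94
```

A closure statistic ≤ 0.1 says the cycle-averaged population state forms a
closed loop once per step; phase shuffling collapses the loop (ratio ≫ 1),
and a separation score > 1 flags a clear neural state change between rest
and walking.

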