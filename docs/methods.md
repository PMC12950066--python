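# Methods

## Problem and data model

The unit of analysis is a continuous recording from one lower-back IMU:
a T×C matrix (C = 3 accelerometer axes in m/s², or 6 with the gyroscope
triad in deg/s appended), a per-sample activity label, and a participant
ID, nominally at 100 Hz. Axis convention: x anteroposterior,
y mediolateral, z vertical (gravity on +z when upright). The task is
binary window classification: any label in a configurable walking set
(default exactly `{"walking"}`) is positive; every other activity —
including near-gait activities such as shuffling or stair climbing — is
non-walking. Recordings at other sampling rates are linearly resampled
to 100 Hz before segmentation (labels carried from the nearest original
sample); no gravity removal or unit rescaling is applied anywhere.

## Preprocessing

**Segmentation.** Windows of `window_len` = 200 samples (2 s) advance by
`step = round(window_len · (1 − overlap))` samples, default overlap 0.5.
The window count is `floor((T − window_len)/step) + 1`; trailing samples
are discarded rather than padded (with 50% overlap at 100 Hz the loss is
under a second per recording). Each window's label is the majority of
its per-sample binary labels; an exact tie resolves to non-walking so
ambiguous windows can never inflate walking sensitivity.

**Normalization.** Per window and axis, the axis mean is subtracted —
nothing else. This happens after segmentation (a per-window operation);
normalizing an already-normalized set raises rather than silently
re-centering.

**Rotation augmentation.** A placement shift is modeled as a rigid
rotation of the sensor frame: the right-handed 3×3 quarter-turn matrix
about x, y or z applied sample-wise to the accelerometer triad and, when
present, identically to the gyroscope triad. The default augmentation
set is one +90° turn about each of the three axes, giving a 4× training
pool. Rotations are exact (matrix entries 0/±1), so triad norms are
preserved to machine precision and four turns reproduce the input
bit-exactly.

**Balancing.** Non-walking windows are down-sampled without replacement
(seeded) to the walking count. Balancing is applied to the training and
validation pools only; test pools keep their natural imbalance.
Augmentation precedes balancing, matching the pipeline stage order
(split → augment → segment → balance).

## Splitting

Splits are by participant: IDs are shuffled by seed and apportioned to
train/validation/test at (0.55, 0.25, 0.20) by largest remainder, ties
toward training — 20 participants yield (11, 5, 4). When largest
remainder would leave a role empty (possible at n = 3), one participant
moves from the largest role, since subject-wise evaluation needs all
three roles populated. Repeated hold-out re-splits with a fresh seed per
repeat; metrics are summarized as median (IQR) across repeats.

## Classifier

Topology: Conv1D(64 filters) → Dropout(0.5) → Conv1D(64) → Dropout(0.5)
→ MaxPool(2) → Dropout(0.5) → Flatten → Dense(64) → Dense(2) → Softmax,
for input batches of shape 32 × 200 × C. Filter count, dropout rate,
batch size, window length, channel counts and early-stopping patience
are fixed design constants of the method; the remaining knobs are package
defaults exposed in `ModelConfig`:

| parameter | default | rationale |
|---|---|---|
| kernel_len | 9 samples (~0.09 s) | sub-step-cycle feature scale |
| pool_len | 2 | halves the feature map, standard |
| dense_units | 64 | matches the filter width |
| optimizer / learning_rate | Adam, 1e-3 | mainstream default |
| max_epochs | 10 | see below |
| early_stop_patience | 3 epochs | fixed design constant |

The network is implemented directly in numpy: convolutions are lowered
to matrix products (im2col forward; the input gradient is accumulated
tap-by-tap), dropout is the inverted variant, training is mini-batch
Adam on cross-entropy, computation is float32. Early stopping monitors
validation loss — the reading consistent with its overfitting purpose —
with strict improvement and best-weights restoration; the restored
parameters never have worse validation loss than the best epoch
observed. All randomness (init, shuffling, dropout) derives from one
config seed, so a fixed (seed, data) pair reproduces training exactly.
Dropout after the fully connected layer is deliberately omitted: the
dropout placements follow each convolutional and pooling layer only.

On the synthetic task validation loss converges within about three
epochs and later fluctuations are noise, which patience-3 stopping
tracks only slowly; `max_epochs` = 10 caps that tail and keeps
full-scale training tractable on one CPU. Class order is fixed as
(non-walking, walking) everywhere to prevent silent metric
transposition.

## Evaluation

Walking is the positive class. From the window confusion matrix
(tp, fp, tn, fn): accuracy = (tp+tn)/n, precision = tp/(tp+fp),
sensitivity = tp/(tp+fn), specificity = tn/(tn+fp), F1 the harmonic
mean of precision and sensitivity. A zero denominator yields 0 with an
explicit flag instead of an exception, so degenerate all-one-class
predictions do not abort a repeat loop. Quantiles use the Hazen
convention (linear interpolation of order statistics at h = np + ½),
fixed so that median(IQR) summaries are reproducible across tools;
e.g. the IQR of [0.9, 0.92, 0.94, 0.96, 0.98] is 0.05. Best-model
selection maximizes validation — not test — sensitivity (ties: higher
F1, then earlier repeat), keeping the test pool honest.

`repeated_holdout` segments each participant once and reuses the cached
windows across repeats and grid cells, applying augmentation at window
level; this is exact because rotation is a per-sample linear map and
therefore commutes with window slicing (covered by a property test).

## Synthetic data generator

The simulator emulates the statistics of free-living activity in older
adults, not gait biomechanics. A participant's timeline alternates
walking bouts and non-walking segments:

* **Bouts**: durations are log-normal with μ = ln(median) and
  σ = asinh(IQR/(2·median))/z₇₅ — a two-parameter family pinned exactly
  by the target median 4.1 s and IQR 4.5 s.
* **Gaps**: log-normal (shape 0.6) with mean `mean_bout · (1−f)/f` so
  the expected walking fraction is f = 0.14. The realized fraction of a
  one-hour recording spreads about ±1.6 pp (s.d.) around 0.14; it is a
  stochastic quantity, calibrated in expectation, not forced per
  recording.
* **Walking signal**: per-axis quasi-periodic waveform at the
  participant's step frequency (drawn from 1.4–2.2 Hz): vertical axis
  gravity offset + fundamental + one harmonic, anteroposterior axis
  phase-shifted, mediolateral sway at half the step frequency (the
  stride rhythm), gyroscope channels oscillating at step frequency;
  plus white noise (s.d. 0.25 m/s²).
* **Non-walking**: four static postures (standing, sitting, lying,
  leaning) as constant specific-force vectors plus noise, interrupted by
  Poisson transition spikes (default 2/min, ~0.6 s Hanning bumps in a
  random direction) labeled "transition". The spikes ensure the task is
  not solvable by signal variance alone.

Per-participant step frequency and amplitudes are drawn independently;
everything is reproducible from one dataset seed. An optional
whole-recording sensor rotation in the config commutes with simulation
by construction.

What the simulator does **not** model: realistic gait spectra and
asymmetries, walking aids, stairs or shuffling as distinct signal
classes, sensor drift, or soft-tissue artifacts. Passing the end-to-end
tests therefore shows the pipeline's machinery is correct and that
rotation augmentation confers placement-shift robustness on separable
quasi-periodic signals — it does not certify performance on real
free-living data.

## Problem sizes used in tests and the acceptance script

The full-scale end-to-end check uses the study conditions — 20
participants × 1 h, 3-channel model, 5 hold-out repeats. The
rotation-robustness check uses 8 participants × 10 min over 5 seeds,
the smallest configuration at which both models train stably; the
augmentation effect there is large (non-augmented sensitivity collapses
on rotated test data). The acceptance script's end-to-end run uses 10
participants × 15 min with 3 repeats, chosen as a desktop-scale
configuration whose medians are stable to a few points.

## Known limitations

* The CNN is a compact numpy implementation: correct and reproducible,
  but not GPU-accelerated; full-scale training runs minutes per repeat
  on one CPU.
* The realized walking fraction of a single short recording can deviate
  several points from the configured target (renewal-process variance).
* The window container (`.npz`) is a binary artifact format intended
  for run-time exchange between CLI stages, not an archival format.
* Hold-out repeat counts, conv hyperparameters and the posture mix are
  deliberately open package choices rather than fixed constants; they
  are surfaced in `ModelConfig` / `SyntheticConfig` rather than fixed.
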