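# Methods

## Problem and scope

The package classifies fixed-length multi-lead ECG windows into a coarse
diagnosis — normal rhythm (N), arrhythmia (AR), myocardial infarction
(MI), ventricular hypertrophy (VH), atrial hypertrophy (AH) — and a fine
15-class diagnosis (N plus 14 disease subtypes), trained jointly.  The
label taxonomy is hierarchical and enforced everywhere: a record's coarse
label is always the parent of its fine label.

## Architecture

**Per-lead encoder.**  Each lead passes through its own convolutional
"group": a strided stem convolution, bottleneck residual blocks (1×1 →
1×3 → 1×1, each convolution followed by ReLU then batch normalization),
and a final expansion whose four parallel branches — a 1×3 convolution,
1×3 dilated convolutions at rates 2 and 3, and an average pool with a 1×1
projection — are concatenated along channels.  The ReLU-before-norm layer
order is deliberate; a switch restores the conventional norm-then-ReLU
order.  Groups share parameters across leads by default, which makes the
encoder equivariant under lead permutation and keeps the parameter count
independent of the lead count; per-lead parameters are one flag away.
The output length is the closed-form T' = ⌈L / (stem stride · block
strides)⌉, asserted in tests.

**Grouped recurrence.**  One *global* Bi-LSTM consumes the elementwise sum
of the per-lead feature sequences; its forget gate reads the previous cell
memory (a peephole realized through the dense weight block over the
concatenated gate input, not a diagonal vector).  At each time step the
freshly updated global hidden state is broadcast into the gates of all n
per-lead Bi-LSTMs of the same direction — the *global access* connection.
The candidate-memory equation is the standard tanh candidate; the
alternative readings (full peepholes on all gates; global state from the
previous step instead of the current one) are available behind
configuration flags but are not the default.  The backward direction
mirrors the forward wiring.  Initial states are zero; weights initialize
uniformly at ±1/√fan-in from a seeded generator.

**Attention pooling.**  Each of the n+1 Bi-LSTMs owns an attention
instance: h_t sums the two directions at time t, the final state F sums
each direction's own terminal step (time T'−1 forward, time 0 backward),
scores are the bilinear form h_tᵀUF, and the distribution is a softmax
computed with max-subtraction (mathematically identical, overflow-proof).
The pooled features concatenate into a single (n+1)·D_h representation
feeding both classification heads, each a single affine layer with
softmax.

**Loss.**  Per batch and per task, class k receives weight
c_k = 1 − n_k/M + ξ with ξ = 0.01; the weighted cross-entropy sums
−c_{y_j} log p_j(y_j) over the batch (probabilities clamped at 1e−12
before the log).  The two task losses combine as λL¹ + (1−λ)L² with
λ = 0.2 by default, and L2 regularization (0.01) over weight matrices —
biases and normalization parameters excluded — is added once on the joint
objective rather than inside each task loss (the two placements are
equivalent up to the convex combination summing to one).  Adam (lr 1e−3
default) optimizes the total.

## Numerical core

No autodiff framework is used: `groupecg.autodiff` is a tape-based
reverse-mode engine over numpy arrays implementing exactly the operations
the model needs (broadcast arithmetic, matmul, im2col-based 1-D
convolution with stride/dilation, average pooling, reductions, slicing,
concatenation, the standard activations).  Gradients of every primitive
and of composed model pieces are verified against central finite
differences (relative error < 1e−4 with an absolute floor of 1e−6
absorbing difference-quotient roundoff on near-zero derivatives).
Batch normalization uses batch statistics during training and running
moments in evaluation, so evaluation outputs are batch-independent;
zero-variance channels are protected by the ε in the denominator.

## Synthetic data generator

Real clinical corpora of this kind are not redistributable, so the
generator emulates their structure: 12-lead, 10 s records at 500 Hz with
two-level labels and strong imbalance (the clinical prior puts 61.10% of
records on N, 18.14% on SA, 7.72% on AA, and spreads the remaining 13.04%
over twelve classes).

Each beat is a sum of five Gaussian bumps (P, Q, R, S, T) with defaults in
the physiological ballpark (R at 1 mV, PR interval 0.14 s, RR 0.8 ± 0.03 s),
projected per lead through a stylized amplitude table (aVR inverted,
precordial R-progression).  Disease classes perturb the beat where the
textbook pattern shows: infarctions add a +0.25 mV ST shift and deepen Q
on their territory leads (anterior → V1–V4, inferior → II/III/aVF,
lateral → I/aVL/V5/V6); ventricular hypertrophy scales R by 1.9 (left →
I/V5/V6, right → V1/V2); atrial hypertrophy widens (left) or peaks
(right) the P wave; rhythm classes act on the RR sequence — sinus
arrhythmia raises RR sd to 0.18 s, heart block drops QRS complexes with
probability 0.3, atrial/ventricular arrhythmia inject ectopic beats,
junctional rhythm inverts P.  Effect sizes were chosen once so that class
effects are detectable above the noise floor (white noise 0.02 mV,
baseline wander 0.05 mV at 0.33 Hz; powerline off by default).

Determinism: a record is a pure function of (seed, parameters); dataset
record i derives its seed from `SeedSequence(master, spawn_key=(i,))`, so
datasets are reproducible and record i is identical regardless of how many
records are requested.

What the generator does **not** emulate: realistic inter-lead covariance
(leads are deterministic projections plus independent noise), beat-to-beat
morphology variability, electrode artefacts, co-morbid labels, or any
pathophysiological dynamics.  Passing tests therefore demonstrate that
the architecture, losses and training loop behave as specified and can
learn class-conditional morphology — not clinical-grade performance on
real ECGs.

## Windowing

Records are reduced to the model's fixed input length either by centered
cropping (zero-padded when short) or by polyphase resampling of the whole
record ("decimate", the default): cropping 10 s records to a short window
would discard beats the label depends on, while resampling preserves the
slow features (ST shifts, amplitude ratios, rhythm irregularity) that the
synthetic classes encode.  Both policies are deterministic.

## Desk-scale configuration

The reference input geometry (12 leads, 1900-sample windows, hidden size
64, batch 32) is the package default.  Tests and the worked example use a
compact configuration chosen for single-CPU turnaround: 128-sample
decimated windows, 4 base channels, hidden size 8, learning rate 3e−3,
tens of epochs on a few hundred generated records.  On these sizes the
separable two-class task trains to 100% accuracy in about a minute, and
on the imbalanced clinical-prior preset dynamic batch weighting improves
minority-class macro-F1 over uniform weighting (median ≈ 0.50 vs ≈ 0.35
across three seeded runs in our prototyping, re-verified by the test
suite at each run).

## Design choices where the design was open

- **Weight sharing** (encoder groups and intra-group cells): shared by
  default for permutation equivariance and parameter economy; switchable.
- **Global state timing**: per-lead cells read the global hidden state of
  the *current* time step, after the global update; the previous-step
  variant is a flag.
- **Backward final state** for attention: the backward pass's own terminal
  step, which sits at time index 0 of the time-aligned sequence.
- **Dynamic weights per task**: recomputed independently from each task's
  own labels (5-class and 15-class), every batch.
- **Aggregate metrics**: macro and support-weighted averages are both
  computed and reported; classes absent from both truth and prediction are
  excluded from macro averages.
- **Storage**: HDF5 (float32 signals) + CSV manifest; checkpoints are a
  single `.npz` archive of parameters, normalization moments and the JSON
  config.

## Known limitations

- Pure-numpy training is CPU-bound and loops over time steps in Python;
  it is meant for desk-scale experiments, not large corpora.
- The synthetic generator's separability makes absolute accuracy numbers
  incomparable to clinical results; only relative/behavioural claims are
  meaningful.
- WFDB import/export is not provided; the HDF5+CSV container is the only
  persistence format.
- Batch normalization statistics are shared across leads when encoder
  parameters are shared; per-lead normalization would require unshared
  groups.
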