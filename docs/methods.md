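# Methods

## Problem

A standard clinical ECG records twelve leads (I, II, III, aVR, aVL, aVF,
V1–V6) from ten electrodes. Wearable and ambulatory systems record far
fewer — typically a 3-lead subsystem: the orthogonal Frank leads
(VX, VY, VZ) or the EASI bipolar leads (VES = E−S, VAS = A−S, VAI = A−I
from four electrodes). Because the body-surface potentials are, to a good
approximation, linear projections of a rotating cardiac dipole, a reduced
lead set carries most of the information needed to reconstruct the full
montage. This package implements that reconstruction: classical affine
transforms as baselines, and a per-lead attention network as the primary
method, with the evaluation protocol (Pearson correlation Pr and mean
absolute error MAE per lead) used to compare them.

## Reconstruction models

### Affine baselines

The LSR baseline regresses each target lead on the three input leads plus
an intercept by ordinary least squares over all pooled training samples,
giving a 12×(3+1) matrix. Applying any externally supplied fixed matrix of
the same shape (a "universal transform" in the Dower tradition) is
supported through the same code path; the package does not ship published
universal coefficients, so the packaged default matrix is always a fitted
LSR matrix, labelled as such in its metadata.

### Per-lead attention network

One network is trained per target lead (twelve independent models), so no
lead's training interferes with another's. Each network has two streams:

**Multi-period 2-D encoder ("2D-ECGblock").** The 3-lead input is embedded
into `d_model` channels by a width-3 1-D convolution. The amplitude
spectrum of the embedded window (FFT magnitude averaged over channels, DC
excluded, frequencies restricted to 1..L/2 by conjugate symmetry) ranks
integer frequencies; the top `m` are kept. For each kept frequency `f`
with period `p = ceil(L/f)` the sequence is zero-padded to `p·f` and
folded into a `p × f` tensor whose columns are consecutive cycles —
within-cycle variation runs down a column, between-cycle variation along a
row. A shared bank of 2-D convolutions at scales 1×1, 3×3 and 5×5
(branches summed, GELU) mixes each folded tensor; the `m` unfolded results
are fused with softmax weights over their spectral amplitudes. A residual
connection to the embedding plus layer normalization closes the block.
Frequency selection and the fusion weights are computed from forward
values and treated as constants during backpropagation; gradients flow
through the folded signal path.

**Sparse-attention decoder ("ProbDecoder").** The decoder input is the one
input lead whose mean training-set correlation with the target lead has
the largest magnitude (magnitude, because leads such as aVR and V1–V4 view
the cardiac vector from the opposite side and correlate strongly
negatively; the signed value is kept as evidence, and ties break by fixed
input order). The lead is token-embedded by a width-3 convolution and
linearly mapped to Q, K, V. Each query is scored by a max-minus-mean
statistic of its dot products against `ceil(ln L)` uniformly sampled keys;
the statistic is computed over the sampled columns only — zero-filling the
unsampled entries would let the zeros dominate the mean, whereas the
sampled-column form recovers the dense score under full sampling. The
top `u = ceil(C·ln L)` queries (C = 5, clipped to [1, L]) receive full
softmax attention over all keys; all other output rows are filled with the
time-mean of V. ECG windows are mostly baseline with sparse
physiologically informative complexes, which is what makes this query
pruning appropriate. The attention output is added to the token embedding
and layer-normalized ("value correction"). Encoder–decoder attention then
derives queries and keys from the encoder output (convolution + linear
map) and attends densely over the corrected values; a position-wise
feed-forward block and a linear head produce the whole target lead in one
step (non-autoregressive).

Ablations share this scaffolding: `t_transformer` keeps the 2-D encoder
but uses dense decoder self-attention; `transformer` uses a vanilla
dense-attention encoder layer and dense decoder.

### Numerical and design choices

- Attention logits are scaled by `sqrt(d_head)` by default; the
  alternative `d_model` divisor is available behind `attn_scale_sqrt`
  because both conventions appear in the literature for this design.
- Head count `n_heads` defaults to 1 (the defining equations of this
  architecture are single-head); any divisor of `d_model` is accepted.
- The residual+normalization wrappers on the encoder block and around the
  decoder's cross-attention/feed-forward stages (`block_residual`,
  `decoder_residual`) are on by default; single-layer configurations train
  unstably without them.
- Fold geometry uses `p = ceil(L/f)` with zero padding, so unfold-then-
  truncate is an exact inverse for every `(L, f)`.
- Spectral ties break toward the lower frequency; top-u query ties break
  toward the lower index (stable sorts throughout).
- Training minimizes MSE on raw mV amplitudes with Adam, global gradient
  norm clipped to 1.0, dropout 0.1 (training only). The checkpoint with
  minimum validation loss is restored ("best epoch").
- All stochastic choices (init, dropout masks, key sampling, shuffling)
  derive from the config seed; a run is reproducible bit-for-bit from
  (data, config, seed). Network arithmetic runs in float32 by default
  (`ModelConfig.dtype`); the test oracles run the underlying operators in
  float64.
- Default full-scale settings: `d_model` 512, one encoder and one decoder
  layer, 100 epochs, learning rate 1e-4 (1e-5 for EASI-style cohorts),
  batch 200. Desk-scale runs in the tests and the acceptance script use
  `d_model` 32 or less, `m` ≤ 3, and tens of segments; these sizes are the
  package's documented test conditions, not the full protocol.

## Preprocessing

Per lead: a zero-phase second-order IIR notch at 50 Hz (Q = 30) applied
forward–backward over the whole record; baseline removal by subtracting a
degree-20 least-squares polynomial fitted per 8 s window on a normalized
time axis in [−1, 1] with a Chebyshev basis (a global degree-20 monomial
fit over minutes of signal is numerically singular); smoothing by local
linear regression in a centered 10-sample window (edges truncated);
segmentation into disjoint 8 s windows, trailing remainder dropped. The
degree-20 detrend annihilates any polynomial drift of degree ≤ 20 exactly
but also absorbs a predictable fraction of genuine low-frequency signal
(about 7% of a 10 Hz sine's energy over an 8 s window — the projection of
the sine onto the polynomial basis); the tests pin this leakage to its
least-squares value. An optional automated quality flag excludes windows
whose residual sub-0.5 Hz power exceeds half the total power — a
documented stand-in for manual artifact review, off by default.

## Synthetic data

The generator provides ground-truth-linked 3-lead/12-lead data with the
statistical structure the method relies on, and nothing more:

- Each beat is a sum of Gaussian waves (P, Q, R, S, T), each with a fixed
  direction in a 3-D dipole space; the three source channels are the
  projections of that loop. Defaults (fractions of the beat period):
  P 0.18 mV/σ 0.050, Q −0.12/0.013, R 1.10/0.025, S −0.25/0.014,
  T 0.45/0.100 — at 60 bpm roughly a 100 ms QRS, 150 ms P and 400 ms T.
  The prominent, wide T concentrates beat energy at the rhythm
  fundamental, which keeps the rhythm's spectral line dominant over QRS
  harmonics; that property is what the FFT period detector presupposes.
- Beat onsets jitter by 3% of the beat period (log of sinus arrhythmia);
  heart rate defaults to 60 bpm.
- The 12 leads are a fixed Dower-style 12×3 matrix applied per sample,
  optionally followed by a mild tanh saturation (off by default — the
  default map is exactly linear). Subject-level variation multiplies wave
  amplitudes/widths by ±15% and lead-field entries by ±10%, drawn once
  per subject, so subject-disjoint splits are meaningful. Setting
  `subject_leadfield_jitter = 0` yields one shared lead field, the
  condition under which held-out affine reconstruction is exact.
- Ectopy: a second beat train at its own rate, each beat a single broad
  PVC-like deflection (0.6× the R amplitude, 6× its width, slightly
  rotated direction) with 6% timing jitter. The composite spectrum then
  carries both rhythm fundamentals as its two dominant lines.
- Contaminants: 50 Hz powerline (0.05 mV), 0.3 Hz baseline wander
  (0.10 mV), white noise (0.01 mV), all seedable and individually
  switchable.

What the generator does **not** emulate: disease-specific morphologies
(ST shifts, conduction blocks), electrode motion artifacts, respiration
modulation, or any nonlinearity of real torso volume conduction beyond
the optional tanh term. Passing tests on this generator therefore
demonstrate that the implementation realizes the intended mechanism on
data satisfying its assumptions — not clinical-grade reconstruction
accuracy on real records.

## Evaluation protocol

Per segment and lead, Pr (product-moment correlation) and MAE (mV) between
reconstructed and recorded traces. Reports aggregate per lead (mean,
median, quartiles over segments); the "Total" column is the unweighted
mean of the twelve per-lead means, and totals are computed from
per-segment values (a per-record-first mode is available). A flat
(zero-variance) trace has no defined correlation: such segments are
excluded from Pr with a count in the report, never silently scored 0, but
are kept for MAE. The best-segment search slides a 10 s window at a 1 s
default stride and returns the window with the highest 12-lead mean Pr,
ties to the earliest window.

## Known limitations

- The WFDB support covers format-16 records with voltage units — enough
  for PTB-style layouts and the package's own files, not the full format
  zoo.
- Training at full scale (d_model 512 on 8 s, 1000 Hz windows for 12
  leads) is supported by the same code paths but is orders of magnitude
  slower on one CPU than the desk-scale configurations exercised here.
- The sparse attention saves compute only for long windows; at desk scale
  the dense cross-attention dominates runtime.
- Reported synthetic-data scores say nothing about diagnostic utility on
  clinical recordings.
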