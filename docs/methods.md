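# Methods

## Problem setting

Auditory EEG decoding maps multi-channel scalp EEG, recorded while a subject
listens to speech, onto a property of the stimulus: either the stimulus
mel-spectrogram (reconstruction) or a discrete stimulus category
(classification).  EEG is scarce, noisy and highly subject-specific, so data
augmentation is attractive — but individual augmentations can destroy exactly
the structure a given decoder relies on.  This package implements a training
framework that (a) aligns augmented and original representations with a
contrastive objective so augmentation does not distort the encoder's feature
space, and (b) searches over augmentation *integration policies* (subsets of
operators) instead of assuming all augmentations help.

Conventions: an epoch is a real matrix `[channels x time]`; the default
recording scale is 64 channels at 64 Hz with 30 s (1920-sample) epochs for
reconstruction and 1.2 s (77-sample) epochs for classification.

## Augmentation operators

Seven operators, each a pure function of `(segment, params, rng)`:

| operator | default parameters | notes |
|---|---|---|
| noise | sigma = 0.1 (relative) | iid Gaussian; sd scaled by each channel's sd so strength is gain-invariant.  The absolute noise level is otherwise unspecified, so the relative parameterization is this package's choice. |
| scale | gain ~ U[0.5, 2] | one global draw per segment, not per channel |
| horizontal_flip | — | time axis reversed; involution |
| vertical_flip | — | channel axis reversed; involution |
| temporal_dislocation | 10 blocks | uniform over all 10! block orders, identity included; conserves the value multiset exactly |
| time_warp | 10 blocks; stretch U[1.5, 2], compress U[0.5, 0.67] | a uniformly chosen half of blocks stretched, half compressed, via linear interpolation; the warped signal is linearly resampled back to length T so batches stack.  Non-divisible T: the last block absorbs the remainder. |
| mask | ratio = 0.30 | exactly `round(ratio * C * T)` scalar entries zeroed without replacement (36,864 of 122,880 at recording scale); mask tokens are literal zeros |

## Contrastive alignment

Each augmentation branch i produces an embedding `f_i` which is compared with
the embedding `f_a` of the unaugmented signal.  Similarity logits are
`f_a f_i^T * tau` with a trainable temperature parameterized as
`tau = exp(theta)` (initial tau = 1) so it stays positive.  The loss is
cross-entropy of each row's softmax against the diagonal (batch item j's
positive is augmented item j); a symmetric two-directional variant is
available behind a flag but off by default, matching the one-directional form
of the written objective.  Before the loss, the augmented embedding is passed
through single-head scaled dot-product cross-attention with queries from
`f_i` and keys/values from `f_a`, so each aligned row is a convex combination
of original-batch rows; the block is removable for ablations.

Composite objectives:

- reconstruction: `L = L_P + alpha * L_cont + beta * L_1` with `alpha = 0.01`,
  `beta = 0.001`; `L_P` is the negative mean Pearson correlation computed per
  mel bin across frames (the standard sample correlation, used consistently
  for both the loss and the evaluation metric), and `L_1` averages absolute
  error over all matrix entries.
- classification: `L = L_C + alpha * L_cont` with plain cross-entropy `L_C`
  (zero predicted probability clamped at 1e-12).

## Selective augmentation integration

Every augmentation carries a coefficient `w_i = sigmoid(theta_i)` initialized
at 0.5.  The written procedure does not define how `w` is updated; this
package's interpretation — its largest design decision — is that `theta` is
trained by backpropagation through the weighted contrastive loss
`sum_i w_i L_cont,i / sum_i w_i`, jointly with the model (the normalization
prevents a uniform shrink of all coefficients from trivially lowering the
loss).  Coefficients are snapshotted at validation time.

Stage 1 loops: train from scratch with the active set A (weights
re-initialized each iteration, seed = run seed + iteration), evaluate, drop
every branch with `w_i < t` (default t = 0.4), then drop the minimum
coefficient if it is a low outlier.  "Evenly distributed" is operationalized
leave-one-out: the minimum is an outlier when
`w_min < mean(others) - k * sd(others)` with population sd and k = 1.5
(configurable).  The loop ends when no outlier remains; each continuing
iteration removes at least one branch, so it terminates within |A| rounds.
Stage 2 trains each survivor alone.  The returned policy is the argmax over
all evaluated candidates — every stage-1 integration, every stage-2
singleton, and the no-augmentation baseline — with ties broken toward the
smaller policy, so the baseline is always a floor.

Training per candidate follows the framework protocol: AdamW, learning rate
5e-4, at most 100 epochs, early stopping with patience 6, 10% of the training
data held out for the augmentation stream (a fixed seeded split; per-epoch
resampling is available behind a flag), best-validation checkpoint retained.

## NeuroBrain

Encoder: squeeze-and-excitation attention along time, then along channels
(global average pool over the other axis, two fully connected layers, sigmoid
gates), a 1-D convolution (spatial structure), a unidirectional batch-first
GRU (temporal structure), a stack of residual transposed convolutions (three
for reconstruction, one for classification; stride 1 at desk scale so the
time axis stays exact, configurable for upsampling), and a
multi-receptive-field block: the mean of three residual convolution branches
with kernel sizes 3/5/7.  Decoder: exactly the final 1-D convolution, mapping
the feature map to `[mel_bins x frames]` or (after global time-averaging) to
class logits.  The embedding entering the contrastive loss is the time-mean
of the encoder feature map.  No layer widths are prescribed anywhere, so all
widths, kernel sizes, strides and the SE reduction are configuration; the
`tiny` preset (8 channels, 128 samples, hidden 16) is used for tests and
examples.  A linear baseline (one convolution + one fully connected layer)
serves as the cheap reference model.

All differentiable components run on a small reverse-mode autodiff engine
written for this package (`eegaug.autodiff`, float64 on numpy), with
convolution and transposed convolution as primitive ops; gradients of every
loss and layer are verified against central finite differences at 1e-4
relative tolerance.

## Metrics

- Pearson r (sample form); for spectrograms, computed per mel bin across
  frames and averaged over bins and batch (the axis is not prescribed; this
  is the package's recorded choice).
- Accuracy = correct / N.
- SSIM: sliding-window statistic with a 7x7 Gaussian window (sigma 1.5),
  `c1 = (0.01 L)^2`, `c2 = (0.03 L)^2`, L = data range — standard defaults,
  all configurable, since none are prescribed; a uniform window and a global
  single-window mode (`win_size="full"`) are available.  Cross-checked
  against scikit-image in the test-suite.
- CW-SSIM: complex Morlet CWT along the time axis at scales {2, 4, 8}, then
  the windowed statistic `(2 |sum c_x c_y*| + K) / (sum |c_x|^2 +
  sum |c_y|^2 + K)` with K = 0.01, averaged over windows and subbands.  A
  rigid time shift rotates coefficient phases coherently, so CW-SSIM degrades
  far more gracefully than SSIM (asserted on a shifted sinusoidal grating).
- Reported tables multiply all three by 100 (`scaled` flag / `--scale100`).

## Synthetic data

The reconstruction generator draws per-band Gaussian noise, smooths it with
an 8-sample moving average (so the envelope has roughly speech-envelope
bandwidth at 64 Hz), standardizes it, and mixes it into channels through a
random linear forward model with an optional integer lag (default 6 samples,
~94 ms) plus additive Gaussian sensor noise.  Defaults: 64 channels, 10 mel
bins, 30 s at 64 Hz.  The classification generator adds a Gaussian-shaped
evoked bump (amplitude proportional to the class index, fixed latency and
width, one random positive channel topography) to noise epochs with balanced
labels.  What these generators deliberately do not model: eye-blink and
line-noise artifacts, 1/f spectra, inter-subject variability, and nonlinear
stimulus-to-EEG coupling — so passing tests demonstrate that the machinery
recovers known structure, not that it reaches any particular score on real
recordings.

A scripted stub trainer (policy -> score and policy -> coefficient tables)
makes the selection engine exhaustively testable: over random score tables
the engine must return the exact planted argmax.

## Numerical choices and desk-scale sizes

Float64 throughout.  Constant channels are returned as zeros (with a
warning) by the z-score rather than dividing by zero; zero-variance mel bins
are skipped in the Pearson loss; ties in the policy argmax go to the smaller
candidate.  Test and acceptance runs use the tiny preset with 48 segments of
8 x 128 (2 s) synthetic data, 200 optimizer steps at learning rate 5e-3, and
the stub trainer for search-engine checks; these sizes are the package's
desk-scale defaults and reproduce in minutes on one CPU.

## Known limitations

The coefficient-update rule and the "evenly distributed" stopping test are
interpretations of an under-specified procedure (recorded above); results at
recording scale on real corpora require the original datasets and
multi-GPU budgets and are out of scope; the EDF/BDF acquisition formats are
not read — data enters through HDF5/NPZ bundles or the generators.
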