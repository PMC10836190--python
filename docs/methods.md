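# Methods

## The problem and the model

Speech-based depression screening models learn from small clinical corpora
in which every training speaker contributes many segments. Two things
follow: the learned segment embeddings carry enough speaker identity to
re-identify patients (a privacy failure), and the depression decision can
lean on speaker-specific traits rather than depression-specific ones (a
bias failure). This package implements speaker disentanglement for such
models: a shared sequence encoder feeds two heads, a depression head
(one sigmoid unit, probability `p` that the segment's speaker is
depressed) and a speaker-identification (SID) head (`M` raw logits over
the training speakers), and the training objective manipulates the SID
loss so the encoder stops encoding who is speaking.

With batch size `N`, depression labels `Y_n`, SID logits `x_n` and softmax
`σ`, the objective is `L_MDD ± λ·L_SID`, where
`L_MDD = −(1/N) Σ [Y_n log p_n + (1−Y_n) log(1−p_n)]` and the SID term is
one of:

* **ADV** — categorical cross-entropy at the true speaker,
  `−(1/N) Σ log σ(x_n)_{n̂}`, *subtracted* from the total so it is
  maximised (`total = L_MDD − λ·L_adv`). Implemented as loss negation,
  exactly as the objective is written; not as a gradient-reversal layer.
* **LEV** — squared L2 distance between `σ(x_n)` and the uniform vector
  `e = (1/M, …, 1/M)`, optionally with fresh elementwise `U(0,1)` noise
  (scaled, default 0.1, not re-normalised) added to `e` every batch to
  block the trivial solution where the SID head memorises `e`. A
  non-squared variant is available behind a flag.
* **LECE** — cross-entropy against an all-ones target, which simplifies
  to `−(1/N) Σ_n Σ_m log σ(x_n)_m`; minimised on the simplex exactly at
  the uniform distribution, with minimum `M·ln M`. The un-simplified
  all-ones form is kept as an independent oracle (`lece_loss_literal`)
  and agrees to 1e−12.
* **LEKLD** — `KL(e ‖ σ(x_n))` averaged over the batch; zero iff the
  softmax is uniform. Note the identity
  `KL(e‖σ) = LECE/M − ln M`, so LEKLD is LECE rescaled by `1/M`; its
  useful λ range is `M` times larger.

`λ = 0` recovers the baseline exactly (bit-for-bit identical training).

## Architectures

Three encoder families, all emitting a per-segment embedding shared by
both heads:

* **CNN-LSTM** — Conv1d → ReLU → max-pool(3) → dropout blocks, then
  unidirectional LSTM layers; the embedding is the last hidden state.
  Printed presets: mel-40 input, one conv (C=128, K=3, S=1), two LSTMs
  H=128; raw audio, convs (128, 1024, 512) + (128, 3, 1), H=128;
  130-dim prosodic input, conv (256, 3, 1), H=256.
* **ECAPA (reduced)** — input Conv1d (C=128; K=5 for mel-80, K=1024/S=512
  for raw audio), three SE-Res2 blocks (C=128, K=5, dilations 2, 3, 4,
  scale 4), multi-layer feature concatenation → 1×1 conv, attentive
  statistics pooling (attention dim 64) and a 128-dim embedding layer;
  the heads read the embedding, not an LSTM state.
* **LSTM-only** — an input LSTM (H=256) plus five hidden LSTM layers, for
  512/768-dim SSL-style frame features; embedding = last hidden state.

Max-pool stride equals its kernel (3) — the pooling placement is not
fully pinned down upstream, and non-overlapping pooling keeps sequence
lengths predictable. All LSTMs are unidirectional. Weights use fan-in
uniform initialisation from a recorded seed; LSTM forget-gate biases
start at 1.

The models are built on a small reverse-mode autodiff engine over NumPy
float64 arrays (`autodiff.py`, `layers.py`) written for this package:
convolution via im2col gather + matmul, exact gradients verified against
central differences in the test suite. On CPU at the study's scale this
is fast (a full training run takes under a second) and bit-reproducible.

## Features

Mel spectrograms use a Hann window of 1024 samples (64 ms at 16 kHz) and
hop 512 (32 ms). The frame count is `floor(len/hop)` with the signal
right-padded to fill the last window, so a 3.84 s clip (61 440 samples)
gives exactly 120 frames. Mel energies are log-compressed with a floor of
1e−10 (a power-scale switch exists; log is the default since the upstream
description does not say). Normalisation is global per-dimension
mean/variance over the *training* pool only (sd floored at 1e−8);
evaluation data reuse training statistics, so no evaluation information
leaks into the transform. Prosodic-130 and SSL features enter as
precomputed frame×dim arrays; their segment geometries (384, 200 or 193
frames per 3.84 s) are fixed constants. Class balance is restored by
sampling, without replacement, equal numbers of depressed and
non-depressed segments (optionally after random cropping to the shortest
utterance); a no-crop mode chops utterances deterministically from the
start.

## Training

Adam (β = 0.9/0.999, ε = 1e−8), default learning rate 5e−3 at study
scale, batch 64. The learning rate decays by 0.9 after every two
consecutive epochs without a new best validation loss (the stall counter
restarts after each decay). The retained checkpoint minimises the
*validation value of the training objective*, evaluated
deterministically (dropout off, LEV noise off): the equalization SID
terms are speaker-free, so they evaluate directly on validation
segments; ADV and the baseline reduce to the depression loss because
validation speakers are disjoint from the SID head's classes. This
matters: depression loss converges within ~8 epochs while the
equalization terms keep reshaping the embedding for another ~20, and a
depression-only criterion would snapshot the model before
disentanglement matured. For the λ=0 baseline the two criteria coincide,
so λ remains the only knob differing between baseline and disentangled
runs. Divergence (non-finite loss) aborts and returns the last good
checkpoint. Ensembles train one model per subset/seed; single-model mode
is the one-subset case.

## Synthetic corpus

The generator emulates the statistical skeleton of a clinical speech
corpus. Features live in `dims`-dimensional space (default 24). Each
speaker has an additive offset drawn in an `identity subspace`
(`dims//3` = 8 orthonormal directions) scaled by `identity_strength`,
plus a mild per-speaker diagonal scaling. Depressed speakers (prevalence
0.3, between the two clinical corpora's case/control ratios) get a mean
shift along a depression subspace (`dims//6` = 4 directions) scaled by
`mdd_strength`, and their smooth temporal contours are damped by
`1/(1+mdd_strength)` — flattened prosody. The depression subspace reuses
`round(0.25·rank)` identity directions (overlap 0.25): removing speaker
information then has a genuine cost for depression information, which is
the regime where disentanglement is a real trade-off rather than free.
White Gaussian noise (sd 0.5) covers everything. All outputs are pure
functions of (config, seed).

A waveform mode renders per-speaker harmonic sources (speaker-specific
f0 ∈ [90, 240] Hz and a resonance peak, 8 harmonics, slow pitch and
amplitude modulation; depressed speakers get both modulations compressed
by `1/(1+mdd_strength)`) as 16-bit PCM mono WAV at 16 kHz, to exercise
the mel front-end.

What the generator does **not** emulate: real spectro-temporal speech
structure, session/channel variability, linguistic content, label noise,
or severity gradations. Passing tests on this corpus show the method
moves identity and depression information the way the theory says under
controlled overlap; they do not certify clinical performance.

## Evaluation

Depression is scored at speaker level: segment probabilities are rounded
at 0.5, averaged into a per-model speaker score; ensembles are collapsed
by score averaging (AVG), majority vote (MV), or the sign of the summed
segment log-likelihood ratios `log(p/(1−p))` with probabilities clipped
to [1e−8, 1−1e−8] (LLR). All rounding thresholds are 0.5; a score exactly
at threshold rounds to 1 (depressed) — deterministic and
screening-conservative — and an LLR sum of exactly 0 likewise resolves
to 1. MV with an even ensemble falls back to AVG. Macro-F1 is the
unweighted mean of the depressed and non-depressed F1 scores computed
from the speaker-level confusion matrix.

Privacy uses two-covariance PLDA (`x = y + ε`, `y ~ N(μ, B)`,
`ε ~ N(0, W)`) fitted by EM on centred, length-normalised embeddings,
after a PCA projection to `min(d, K−1)` dimensions. The pairwise
verification LLR has the closed Gaussian form and is verified in tests
against direct multivariate-normal log-density computation. Similarity
matrices put `sigmoid(mean pairwise LLR)` between speaker i's and
speaker j's segments in entry (i, j); diagonal dominance is
|mean diagonal − mean off-diagonal|;
`GVD = 10·log10(D_pp/D_oo)` dB and `DeID = 100·(1 − D_op/D_oo)` %, where
`oo`, `pp`, `op` score original-vs-original, protected-vs-protected
(separately trained PLDAs) and original-vs-protected (one pooled PLDA).
The protocol samples disjoint PLDA-train / evaluation speaker sets
(defaults 25/10, scaled down with a logged warning when fewer speakers
exist), repeats over seeds and reports means. A linear SVC probe
(half/half per-speaker split) reports SID accuracy next to its 1/M
chance floor.

## The end-to-end study

`run_disentanglement_study` freezes one set of desk-scale conditions:
40 speakers × 20 segments (25 frames × 24 dims), identity and depression
strengths 1.0, noise 0.5, overlap 0.25; speaker-disjoint splits 40/15/45 %
per class; class-balanced training segments; a small CNN-LSTM
(conv 16×3, LSTM H=16); Adam 5e−3, 30 epochs; three member seeds whose
speaker scores are ensemble-averaged (AVG) and whose probe/privacy
metrics are member-paired means; probe and privacy computed on the 20
held-out evaluation speakers only — mirroring the clinical protocol,
where PLDA training and evaluation speakers both come from the corpus's
evaluation partition. λ grids per method span the gradient-scale
differences derived above: ADV {0.01–0.3}, LECE {1–10}, LEKLD {30–100},
LEV {300–3000}.

Two study-specific choices deserve justification:

* **LEV trains with a deterministic uniform target.** At λ ≈ 300+ the
  λ-scaled target noise becomes a large stochastic forcing term that
  destabilises the depression task, while monitoring the SID head's
  weight norm shows it does not collapse to the trivial solution within
  30 epochs — the failure mode the noise exists to prevent does not
  arise at this scale. The noise injection remains implemented, enabled
  by default in `LossSpec`, and unit-tested.
* **ADV does not reach the joint target at this scale, and the study
  reports that honestly.** Across wide λ ranges, optimizers and model
  sizes, maximising the SID cross-entropy drives the head/encoder pair
  to *confidently wrong* speaker predictions. Wrong-but-confident
  predictions still require speaker information, so identities are
  re-mapped rather than erased: DeID rises (original and adversarial
  embeddings become unlinkable) while speaker separability (GVD) and
  probe accuracy do not fall. The equalization losses behave
  differently because their log barriers penalise *every* confident
  speaker prediction, right or wrong, and therefore genuinely compress
  between-speaker variance. The same dissociation (positive GVD with
  high DeID under ADV) appears in the published experiments for some
  feature sets, along with the observation that the unbounded
  adversarial loss can harm convergence.

Under these conditions the equalization methods reproduce the joint
effect on every corpus seed tried during development: depression macro-F1
within tolerance of (usually above) baseline, probe accuracy down,
DeID ≈ +20–60 %, GVD ≈ −0.4 to −1.7 dB.

## Numerical choices

* Probabilities clipped at 1e−12 before logs; softmax computed via a
  max-shifted log-softmax; mel log floor 1e−10; normalisation sd floor
  1e−8; LLR segment clip 1e−8.
* PLDA covariances get a 1e−6 ridge only when near-singular, so EM
  log-likelihood stays non-decreasing (to float precision) in the
  well-conditioned case.
* Ties: max-pool backward splits gradient evenly across tied maxima;
  rounding threshold ties go to the depressed class (documented above).
* Degenerate inputs raise: < 2 speakers, single-class training sets,
  waves shorter than one window, empty segment lists, duplicate
  manifest ids.

## Known limitations

* The synthetic corpus is linear-Gaussian at heart; encoders never need
  more than mild nonlinearity, so architecture comparisons (CNN-LSTM vs
  ECAPA vs LSTM-only) are functional tests here, not performance
  benchmarks.
* GVD at desk scale has sampling noise of a few tenths of a dB; the
  study averages member-paired protocols over seeds, but single runs
  near 0 dB are sign-unstable.
* The ADV limitation discussed above: at this scale it is a masking
  method, not a distinctiveness-reduction method.
* Clinical headline numbers from restricted corpora are outside what a
  synthetic study can reproduce; the study checks directions and joint
  behaviour, and the table arithmetic checks the published evaluation
  pipeline exactly.
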