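# Methods

This note documents the models, parameter choices and numerical
conventions behind `neosleep`, and what the synthetic-data experiments
do and do not demonstrate.

## Problem setting

Five-state neonatal sleep staging assigns each 30-s EEG epoch one of
{W, AS1, QS1, QS2, AS2} (coded 1–5 in that order). The scientific
question the evaluation harness addresses is electrode economy: how
much staging accuracy individual 10–20 channels (F3/F4, C3/C4, P3/P4,
T3/T4) retain relative to four-channel hemispheric montages. Clinical
EEG of this kind is private in practice, so the pipeline is exercised
end-to-end on synthetic cohorts with planted, known structure; every
claim the test suite makes is about recovering that planted structure.

## Synthetic EEG generator

**Hypnogram.** A five-state Markov chain. The default transition matrix
is T = 0.75·I + 0.25·1·πᵀ with stationary distribution π =
(W 0.25, AS1 0.25, QS1 0.15, QS2 0.15, AS2 0.20); the 0.75 diagonal
gives a mean dwell of ~4 epochs (2 min), long enough for realistic
state runs without trivializing classification. The imbalance is a
plausible invention — cohort-specific class mixes vary and none is
assumed — and fully configurable.

**Epoch synthesis.** Each single-channel epoch is

    y = snr_ch · S + B,  then optional burst envelope, then RMS scaling

where S is a unit-RMS sum of band-limited Gaussian noises (δ, θ, α, β;
filtered with the same FIR design the preprocessing stage uses, so
generator and pipeline share one filtering convention) with power
proportional to the state's band weights, and B is a unit-RMS
state-independent background: half 1/f^β colored noise (β ≈ 2, steep
enough that its band-power ordering never overrides a state's weight
ordering), half band-limited noise with a random per-epoch band mixture
(lognormal weights, σ = 0.7). The final epoch is scaled to the state's
RMS amplitude times a lognormal per-epoch jitter (σ = 0.4).

Two design points matter:

* **The background is a genuine confound.** Its random band mixture
  perturbs exactly the band-power features the classifier uses, epoch
  by epoch. Because `channel_snr` scales S against B, it is a real
  discriminability dial: at snr 1 (default) single-channel accuracy
  sits near 0.7 on 600-epoch cohorts — difficulty comparable to what
  clinical five-state staging reports — and at snr 2 it rises to ~0.9.
  An early draft without the random mixture saturated near 0.98
  regardless of snr, which would have made channel comparisons
  meaningless; the confound was added during generator design, before
  the evaluation experiments were frozen.
* **QS1's tracé alternant** is emulated by a square-ish amplitude
  envelope (6-s cycle, depth 0.7, raised-cosine ramps), giving QS1 a
  burst/inter-burst signature that time-domain features pick up.

State profiles (band weights, amplitudes 30–40 µV, background
exponents 1.9–2.3) are qualitative stand-ins for neonatal EEG, not
estimates of any clinical cohort. The generator does **not** emulate:
artifacts (blinks, movement, electrode pops), inter-subject maturation
differences, topographic correlation between channels (channels are
independent draws), or non-stationarity within a state run. Passing
tests therefore show that the pipeline recovers planted spectral/
dynamical structure under realistic noise — not that it reaches any
particular accuracy on clinical data.

## Preprocessing

Band-pass 0.3–35 Hz, windowed-sinc FIR (Hamming), order from a 0.25 Hz
transition band (6,601 taps at 500 Hz). The symmetric kernel is applied
once with centered overlap-add convolution, which cancels the linear
phase exactly; stopband attenuation (~53 dB) far exceeds the ≥ 20 dB
the tests assert at 0.1 and 45 Hz. Trailing partial epochs are dropped
(whole 30-s epochs only); epochs containing non-finite samples are
rejected with a logged count — a simple stand-in for clinical artifact
rejection, whose criteria are site-specific.

## Features (94 per channel-epoch)

Conventions: population variance/std (divisor N), Fisher–Pearson
skewness, excess kurtosis; skewness/kurtosis of a zero-variance vector
are defined as 0 so flat epochs cannot poison a feature matrix.

* **Derivative statistics (27).** Nine summary statistics of the
  signal, of diff(x), and of diff²(x).
* **DFA α.** Profile Y = cumsum(x − x̄); non-overlapping windows of
  length n, per-window linear detrend; F(n) is the *RMS* residual (the
  square root is part of the estimator — it is what makes α = 0.5 hold
  for white noise and α = 1.5 for a random walk, both asserted in the
  tests). Window grid: 12 log-spaced sizes from 16 samples to len/4;
  α is the least-squares slope of log F(n) on log n.
* **Largest Lyapunov exponent.** Delay embedding (default m = 10,
  lag = 20 samples = fs/25, 300 follow steps); for ≤ 1,000 reference
  points the nearest neighbour outside a Theiler window (one mean
  period, estimated from the median spectral frequency) is found with a
  k-d tree; λ is the mean over pairs and steps of log d(n+1)/d(n).
  Efficiency choices that do not change the estimator: neighbour
  candidates are taken from every 2nd embedded point, the tree query
  accepts a (1+0.5) distance slack (a *near* neighbour suffices for
  divergence tracking), and squared distances along followed
  trajectories are computed as sums of shifted scalar squared
  differences (embedding coordinates are lagged samples of one series).
  The r = 4 logistic map recovers λ = ln 2 within 0.1 with m = 2,
  lag = 1 and 8 follow steps — few steps, because a map with ~2×10⁻⁴
  initial neighbour distances saturates its attractor after ~12
  doublings.
* **Multiscale fluctuation entropy.** At scale k (k = 1..5), segments
  of k × 250 samples; fluctuation = segment std / segment mean
  magnitude (this ratio makes the measure amplitude-scale invariant);
  H_k = Shannon entropy (nats, 0·log 0 ≡ 0) of the fluctuations in 10
  equal-width bins over their observed range; MFE = mean over k.
  Constant input ⇒ MFE = 0 exactly.
* **Spectral features (64).** Welch PSD with 2-s Hann windows, 50 %
  overlap — a standard resolution/variance balance at 500 Hz. Band
  intervals are closed; bins in the 3–4, 7–8, 12–13 Hz gaps belong to
  no band. The "mode" of continuous PSD values is defined as the
  midpoint of the most populated of 10 equal-width bins (ties → lowest
  bin). Band-power ratios guard the denominator with ε = 10⁻¹² and log
  a warning above 10⁶, keeping the pipeline total on degenerate inputs.
  The top-10 FFT features store *magnitudes* sorted descending:
  magnitudes are comparable across epochs and usable by PCA, whereas
  the frequencies of ranked bins are permutation-unstable.

## Projection, balancing, classifier

**PCA.** Global z-scoring (zero-variance columns get scale 1) then PCA
retaining the smallest component count with cumulative explained
variance ≥ 0.95. The retained count is a dataset property, not a
constraint (≈ 26 of 94 on default synthetic cohorts). By default the
projection is fitted inside each training fold — fitting before the
split leaks test-row statistics into the components; a
`paper_faithful_projection` switch exists for pipelines that accept
that leakage, and the leakage audit in the test suite verifies the
default is bitwise clean.

**SMOTE.** Exact-parity oversampling to the majority count; δ uniform
on [0, 1] (the canonical choice when no distribution is specified);
exact brute-force neighbour search (training folds are desk-scale);
minority classes of size ≤ k lower k to size−1 with a warning so small
fixtures run; a singleton class is an error. Balancing happens in the
classifier's input space (after projection); a pre-projection mode can
be composed manually from the module functions.

**LSTM.** Three stacked layers (batch normalization after the two
sequence-returning layers), two ReLU dense layers, softmax output;
L2 penalty on the LSTM weight matrices; Adam; categorical cross-entropy
(the natural loss for a five-way softmax); early stopping on the
validation loss of a stratified 10 % split with best-weight
restoration. Each epoch enters as a length-1 sequence of its projected
feature vector — labels are per-epoch and states are reset between
sequences — and multi-epoch windows are supported by passing 3-D input.
The full-size architecture (500/250/100 units, dense 100/50, lr 10⁻⁴,
batch 128, ≤ 50 epochs, patience 10) is dimensioned for training sets
of ~10⁴ epochs; on synthetic cohorts of a few hundred rows it would
perform only a few hundred Adam updates, far from convergence, so the
test suite and acceptance runs use `LSTMConfig.reduced()`:
64/32/16 units, dense 32/16, lr 3×10⁻³, batch 64, ≤ 60 epochs. This is
optimizer scaling for problem size, not tuning: learning-rate scale
must rise as update counts fall. The implementation is plain float64
numpy with hand-derived BPTT (verified against finite differences to
~10⁻⁶ relative error), so identical seeds give bit-identical training;
bit-exactness across BLAS builds is not promised.

## Evaluation

Shuffled epoch-level k-fold splits (near-equal test sets, remainder
spread over the first folds). Subject-level grouping is deliberately
not the default — epoch-level folds match the common design in this
literature — but the fold splitter takes any index partition, so
grouped CV can be composed. Metrics from the fold confusion matrix
(rows = true, columns = predicted):

* accuracy = trace/N;
* Cohen's κ = (p_o − p_e)/(1 − p_e) with p_e from the marginals — the
  multiclass form, which reduces exactly to
  2(TP·TN − FP·FN)/((TP+FP)(FP+TN) + (TP+FN)(FN+TN)) on 2×2 problems
  (a tested identity);
* recall, precision, F1 per class, combined support-weighted — chosen
  because support-weighted recall equals accuracy identically, the
  behaviour expected of this analysis (also tested); a class never
  predicted contributes precision 0 with a logged warning;
* MCC in the multiclass covariance form, reducing to
  (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)) on 2×2.

All metrics are kept as fractions in [−1, 1]; report layers may format
percentages. Fold aggregation is mean ± population SD. The channel
comparison runs every configuration on identical epochs and identical
fold splits (shared seed) so that ranking differences are attributable
to the channels, not to fold luck.

## Problem sizes used by the test suite and acceptance script

* Default cohort: 5 subjects × 120 epochs = 600 epochs, 8 channels;
  single-channel CV uses k = 5 and the reduced classifier.
* Planted-SNR ranking: 10 generator seeds, each 2 subjects × 75 epochs
  with 3 channels (C3 at snr 2.0 vs P4, T4 at 1.0), k = 3. Two
  subjects per seed keep every state above the ≥ 2-members-per-class
  floor that SMOTE interpolation requires; with one 120-epoch subject
  the sticky hypnogram occasionally leaves a state nearly empty.
* Metric equivalence: 1,000 random confusion matrices against a
  brute-force per-label-pair scorer at 10⁻¹² tolerance.

## Known limitations

* Synthetic channels are statistically independent given the state;
  real EEG montages are strongly cross-correlated, so multi-channel
  gains here are optimistic relative to clinical data.
* The Lyapunov and MFE estimators use fixed default parameters
  (embedding, scales, bins) chosen for 30-s/500-Hz epochs; they are
  features, not certified dynamical invariants of the underlying
  system.
* Epoch-level CV shares subjects between train and test folds; with
  only a handful of synthetic subjects, grouped CV would be
  high-variance, which is why it is compositional rather than default.
* The EDF writer covers the 16-bit single-rate subset of the format
  (sufficient for these recordings); annotations travel in a CSV
  sidecar rather than an EDF+ annotation channel.
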