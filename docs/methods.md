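# Methods

This package re-implements, as a tested offline pipeline, the analysis chain
of a hybrid visual brain-computer interface in which an oddball (P300)
stimulation is superimposed on flickering (SSVEP) panels. Because no public
EEG accompanies the design, every analysis is exercised on a synthetic EEG
generator that emulates the statistical structure the analyses assume. This
note documents the generative model, the decoding procedures, the numerical
choices, and what the synthetic setting can and cannot show.

## Stimulation paradigm

A *trial* is one cue-plus-stimulation cycle: a 2 s cue, a 1 s pause, flicker
onset, oddball onset 500 ms later, then 10 *flashing sequences* per panel in
which each of the panel's 6 icons is highlighted exactly once, in random
order, for a uniform 200-300 ms (randomised durations prevent the oddball
stream from itself entraining a steady-state response). Flashes are scheduled
back-to-back with no inter-stimulus gap. A 1 s pause closes the trial. A
*run* is 12 consecutive trials; every selectable icon is cued an equal number
of times in random order (twice with one panel of 6 icons, once with two
panels of 6). The expected flashing sequence lasts 6 x 0.250 = 1.5 s, a trial
2 + 1 + 0.5 + 10 x 1.5 + 1 = 19.5 s, and a run about 3.9 minutes.

Usable flicker frequencies on a 60 Hz display are 60/7 (= 8.57), 10, 12 and
15 Hz. The two-panel design flickers the panels at 12 and 15 Hz. The two
flash streams are scheduled independently per panel (independent orders and
durations); a config flag (`synchronize_panels`) forces shared flash timing
with independent orders, since onset synchrony across panels is a display
choice the design leaves open.

## Synthetic EEG

A recording has 32 scalp channels (10-20 layout) plus two mastoids, sampled
at 1024 Hz, in microvolts, and is the sum of:

* **Background noise.** Per-channel Gaussian noise with a 1/f^beta amplitude
  spectrum (beta = 1 by default, `noise_scale` = 8 uV per channel), mixed
  through a seeded random spatial smearing matrix with unit-norm rows so
  channel variances are preserved while channels become correlated. No
  dipole-level source model is attempted.
* **Target-locked ERPs.** Every flash of the cued icon adds a template: an
  early negativity (default 3 uV, 150 ms latency, 30 ms Gaussian SD,
  occipital topography) plus a P300 (default 8 uV, 350 ms, 60 ms SD,
  parieto-central topography peaking at Pz). Gaussian bumps are the simplest
  shapes satisfying the sign/latency constraints the components are defined
  by. Non-target flashes evoke nothing by default (`nontarget_erp_gain`
  exposes a small exogenous response).
* **Flicker responses.** Each panel with an active frequency f contributes
  sum_k A_k sin(2 pi k f t + phi), k = 1..3, gated from flicker onset to
  trial end, with occipital topography (Oz gain 1). The phase is drawn once
  per trial per panel. The attended panel's amplitudes are multiplied by
  `attention_gain` (>= 1, default 2); unattended panels stay at base
  amplitude - the attention effect, not the presence of flicker, is what
  distinguishes the panels. Default amplitudes (2.0, 1.2, 0.6) uV.
* Optional square-pulse frontal transients emulate ocular artifacts (off by
  default; they exist to exercise the amplitude-based rejection operator).

Generation is bit-reproducible given the seed, and the noiseless signal is
exactly linear in the profile amplitudes. `sample_profiles` draws a cohort
around these defaults with Dirichlet-distributed harmonic weights (the
fundamental is not always the strongest response, and some harmonics may be
nearly absent), moderate lognormal amplitude/noise variation, and uniform
latency jitter.

The defaults describe a clearly-above-threshold responder. What passing
tests show is therefore that the *pipeline* recovers the encoded structure
under realistic noise levels and topographies - not that any particular
human population would reach these accuracies. Real EEG additionally has
non-stationary noise, eye/muscle artifacts, trial-to-trial ERP latency
jitter, and imperfectly sinusoidal steady-state responses, none of which the
generator models.

## Preprocessing

Scalp channels are referenced to the mastoid mean (mastoids dropped).
Filters are zero-phase Butterworth designs applied forward and backward:
0.5-20 Hz order 3 for the ERP/P300 path, 0.2 Hz high-pass order 4 for the
SSVEP path. Edge handling uses odd-reflection padding of three low-edge
periods (3 fs / f_low samples, capped at the signal length): padding
proportional only to the filter order leaves multi-second transients for
sub-hertz cutoffs.

Epochs span a closed window [t_start, t_end] relative to flash onset, with
both endpoint samples included: the length is floor((t_end - t_start) fs) + 1,
so (-0.2, 0.8) s at 1024 Hz gives 1025 samples and (0, 0.6) s at 128 Hz
gives 77. Resampling is integer-factor decimation of band-limited data
(1024 -> 128 for the P300 path, 1024 -> 256 for the SSVEP path), keeping
sample 0.

Artifact rejection (ERP-averaging path only) removes, per run, the
ceil(0.10 n) epochs with the largest peak-to-peak amplitude (max over
channels), ties resolved by removing the earlier epoch. The classification
path uses all epochs. The order of operations is reference, filter, epoch,
reject, resample. Epochs are not baseline-corrected by default.

## ERP averaging and condition correlations

The target ERP of a condition (pure oddball, or hybrid at one of the four
flicker frequencies) is the sample-wise mean of its target epochs. Condition
similarity is the per-channel Pearson correlation across the full epoch
between two conditions' average waveforms, for all C(5,2) = 10 pairs, each
classed oddball-vs-hybrid (4 pairs) or hybrid-vs-hybrid (6). A constant
waveform makes r undefined and is reported as missing, never as 0. Group
inference on these correlations (mixed models, post-hoc contrasts) is out of
scope; the tidy table is the export surface for external statistics software.

## P300 decoding

Single-flash epochs (0-600 ms, 128 Hz, all 32 scalp channels) are flattened
to 32 x 77 = 2464-dimensional vectors. A linear support-vector machine
separates target from non-target flashes; the regularization strength C is
chosen by stratified 10-fold inner cross-validation maximizing accuracy over
a 15-point logarithmic grid, 10^-5..10^2. No class rebalancing is applied to
the 1:5 target/non-target ratio. The linear kernel matrix is precomputed
once and shared across the grid search, and the primal weight vector is
recovered from the support-vector dual coefficients; the SMO solver makes
training deterministic given the fold assignment seed.

At test time, each icon's epochs are averaged over the first N_r repetitions
(N_r = 1..10), the model's decision value ranks the 6 icons, and the argmax
is the detected target (ties break to the lowest icon id and are logged).
For a linear model, averaging epochs then scoring equals averaging the
scores, which is tested to 1e-9. Evaluation is blocked by run: 3-fold
cross-validation over 3 runs for the single-panel design (36 correctness
values per repetition count), or train-on-2/test-on-the-rest for the
two-panel design (72 values per repetition count with 8 runs). In the
two-panel design both training and scoring use the epochs of each trial's
cued panel, since the decoder is by construction applied to the attended
screen portion.

## SSVEP analysis

The narrowband power of a single-channel signal Y at frequency f is

    P(Y, f) = (mean_i y_i cos(2 pi i f / f_s))^2
            + (mean_i y_i sin(2 pi i f / f_s))^2 ,  i = 1..n_s,

which equals amplitude^2 / 4 for a sinusoid over an integer number of
cycles, and |DFT coefficient|^2 / n^2 at on-bin frequencies. The per-trial
power analysis reports P at harmonics 1-3 of the stimulation frequency at
Oz over the flicker-on interval, 12 values per run and harmonic.

Frequency detection uses the Minimum Energy Combination spatial filter,
fitted per analysis segment. The segment starts at oddball onset and spans
1.5 N_r seconds of the 256 Hz data. The sin/cos pairs of all candidate
frequencies (12 and 15 Hz) and their first three harmonics are projected out
by least squares; the residual channel covariance is eigendecomposed; the
filter keeps the eigenvectors whose cumulative eigenvalue share of the
residual energy is at most 0.10 (at least one), each scaled by
1/sqrt(eigenvalue). Eigenvalues below 1e-12 of the largest are treated as
rank deficiency and discarded.

The SNR of a filtered component at f is its narrowband power divided by the
mean power over the 8 nearest off-target frequencies at the segment's
resolution f_s/n_s, excluding all candidate harmonics; a zero noise estimate
is reported as +inf and flagged. This nearest-bin noise estimator replaces
the autoregressive noise model of the original MEC formulation: it is
simpler and directly testable (white noise gives SNR = 1 in expectation),
but anyone comparing against an AR-based implementation should expect
slightly different SNR scales. A candidate's score is the mean SNR over
components and harmonics; the candidate with the highest score is the winner
frequency (ties to the lower frequency, logged).

The trained variant keeps the per-harmonic SNRs as a 3-D feature vector
(component-averaged per harmonic) and fits a per-subject linear SVM on the
training runs - each (trial, candidate) pair is one sample labelled by
whether the candidate was attended - with leave-one-out cross-validation
over the same C grid. At test time the candidate with the highest SVM output
wins. This matters when subjects concentrate their response in one harmonic,
where the untrained average dilutes the informative SNR.

## Fusion and information transfer rate

The hybrid decision is correct only when the P300 decoder and the SSVEP
detector are simultaneously correct (logical AND), so fused accuracy is
bounded by both marginals; with independent errors it is close to their
product. The bitrate per symbol is B = log2 N + p log2 p +
(1-p) log2((1-p)/(N-1)) with N = 6 (P300; the decoder always sees the
attended panel), N = 2 (SSVEP) and N = 12 (hybrid), and the transfer rate is
I = B N_c / sum(t_i) x 60 bits per minute with t_i = 1.5 N_r seconds of
stimulation per trial (cue and pauses excluded; an `overhead` argument adds
them for realistic-rate reporting). The p -> 0 and p -> 1 limits of B are
evaluated by continuity. B is convex in p with a stationary minimum of
exactly 0 at p = 1/N, so it is never negative - below-chance accuracies map
to small positive bitrates, a known quirk of this definition worth keeping
in mind when reading ITR values near chance.

## Problem sizes and numerical choices

The test suite and the acceptance script run everything at desk scale as the
package's own choice of problem size: 3-4 simulated runs per evaluation
(train on 2), 12 trials per run, cohorts of 8 synthetic subjects, 20 seeds
for the paired harmonic-weighting comparison, and 100 schedules for timing
Monte Carlo. Statistical assertions use two-sided binomial tests or paired
Wilcoxon tests at alpha = 0.01, or 2-standard-error margins for paired
accuracy comparisons. Known limitations: no real-data ingestion is exercised
(BDF/EDF import is an optional interface), no online/adaptive operation, no
CCA-style SSVEP detectors, and no inferential statistics - those belong to
external statistical software operating on the exported tidy tables.
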