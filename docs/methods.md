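# Methods

This note documents the models and procedures behind `vocemo`, the choices
that were genuinely open, and what the synthetic experiments do and do not
demonstrate.

## The analysis being modelled

The package reimplements a cross-cultural vocal-emotion study design: child
speech expressing one of four emotional states (joy, neutral, sadness,
anger) is rated by panels of adult listeners from two language groups, and
the analysis asks (a) how well each panel recognizes each emotion
(confusion-matrix metrics), (b) how much listeners agree with each other
within and across groups (Cohen's kappa), and (c) which prosodic features of
the speech carry the emotion (rank tests and regressions on F0 and energy
statistics). No audio or raw votes from any real study ship with the
package; the published row-percentage confusion matrices are transcribed as
CSV fixtures, and everything upstream of them is simulated by first-class,
tested generator modules.

## Synthetic utterances (`vocemo.synth`)

Each utterance is additive harmonic synthesis: 6 harmonics with 1/k
amplitude roll-off riding a per-sample phase integral of the target F0
track. The F0 track is a single raised-cosine excursion,

    f0(t) = (f0_mean − exc/2) + (exc/2)·(1 − cos 2πt/T) + jitter,

so the noiseless contour has mean exactly `f0_mean`, range exactly
`f0_excursion`, minimum at the edges and maximum mid-utterance. The
amplitude envelope is a raised cosine in dB with depth `energy_tilt_db`
(0 dB mid-utterance, −tilt at the edges), which makes the energy at the
F0-maximum frame exceed the mean frame energy and the energy at the
F0-minimum frame fall below it — the structure the Emax/E0 and E0min/E0
ratios measure. Gaussian noise is added at a configurable SNR (default
30 dB re signal RMS) and the waveform is peak-normalized to 0.9.

Default presets (Hz, ms, dB):

| emotion | f0_mean | excursion | duration | tilt | jitter sd |
|---------|--------:|----------:|---------:|-----:|----------:|
| joy     | 280 | 140 | 900 ± 80 | 8  | 3 |
| neutral | 240 | 60  | 800 ± 80 | 2  | 2 |
| sadness | 210 | 40  | 800 ± 80 | 4  | 2 |
| anger   | 260 | 110 | 450 ± 50 | 10 | 3 |

These encode the qualitative contrasts reported for emotional child speech
— joy has the widest pitch excursion and longest duration, anger the
shortest duration, sadness the lowest pitch, neutral the flattest envelope —
and a +40 Hz per-language offset emulates a higher-pitched speaker group.
The absolute values are configuration, chosen once to sit inside the
100–600 Hz child-voice search band with comfortable margins; they are not
estimates of any real corpus. Per-utterance randomness (duration draw,
jitter, noise) is split from the corpus seed, so a corpus is byte-identical
under the same (spec, presets, seed).

What the generator deliberately omits: formants, phonemic segmentation,
voicing breaks, micro-prosody, amplitude shimmer, room acoustics. Passing
tests therefore show that the *pipeline* (tracking → features → statistics)
is correct and well-calibrated on signals whose ground truth is known; they
do not show that the feature extractor matches Praat or any other tool on
real child speech.

## Pitch and energy tracking (`vocemo.acoustics`)

Frames are 40 ms Hann windows at a 10 ms hop. Per frame, the estimator
computes the autocorrelation of the windowed, mean-removed frame and
divides it by the autocorrelation of the window itself; this lag
normalization removes the taper-induced tilt so that a perfectly periodic
frame peaks at exactly 1 at its period. Candidate peaks are searched in the
lag window for 100–600 Hz; among local maxima within 0.02 of the global
maximum the *shortest* lag wins (octave-down suppression for harmonic-rich
frames), and the winning lag is refined by parabolic interpolation. Frames
whose normalized peak falls below 0.30 are unvoiced. A running median
(width 5 over voiced frames, windows shrinking symmetrically at the edges
to avoid endpoint bias) removes isolated octave errors.

Frame energy is RMS in dB re full-scale 1.0, floored at −120 dB for silent
frames. Feature extraction takes F0 statistics over voiced frames only;
E0 is the mean dB level over voiced frames, and E0max/E0min are the levels
at the frames where F0 attains its maximum/minimum. Because quotients of
dB values depend on the dB reference, the energy "ratios" are computed as
linear-power ratios `10**((Ea−Eb)/10)`; the raw dB differences are carried
alongside. Duration is the full sample span; optional silence trimming
(−50 dB threshold) sits behind a flag and is off by default.

Measured on the default corpus (4 × 30 utterances, SNR 30 dB), the median
relative error of extracted F0 mean is below 1%, and the per-emotion
medians of F0max and F0 range preserve the neutral-below-joy and
sadness-below-joy orderings in 20/20 replicate corpora.

## Listener panels (`vocemo.raters`)

A panel is a row-stochastic 4×4 confusion kernel: P(response | true
emotion). Experts within a group share the kernel (no per-expert
parameters are published for the study design this mirrors); an optional
Dirichlet perturbation around the group rows is available but off by
default. Votes are independent across experts and stimuli — single-pass
listening justifies omitting order, fatigue and learning effects. Kernels
are built from per-class accuracies with the off-diagonal mass spread
uniformly or to adjacent categories.

## Recognition metrics (`vocemo.metrics`)

Confusion matrices are row percentages, rows = true emotion, columns =
response, canonical order joy–neutral–sadness–anger. Metrics treat the row
percentages as counts, giving every true class equal weight: recall_i =
cell(i,i)/100, precision_i = cell(i,i)/colsum(i), F1 the harmonic mean, UAR
the unweighted mean of the four recalls. This equal-row-weight convention
is the only one under which a row-percentage table determines precision,
and it reproduces every printed metric cell of the eight transcribed
matrices (415 of 416; one published F1 cell is internally inconsistent with
its own printed recall and precision and is flagged in the fixture rather
than matched). Display rounding is half-up to two decimals, implemented
with a two-step decimal quantization (1e−9, then 1e−2) so that float
representation noise cannot flip a value that sits exactly on the .xx5
boundary — two of the published UARs do.

Empty response columns make precision undefined (reported as NaN with a
warning, never silently 0); a true class with no stimuli leaves its row
undefined and UAR refuses to average unless explicitly told to skip.

## Agreement (`vocemo.agreement`)

Cohen's kappa uses the standard chance correction from marginal products.
Per-emotion kappa collapses labels one-vs-rest before computing kappa;
this handles naturally the degenerate case where a rater never uses an
emotion (kappa ≤ 0) and the fully degenerate case where neither rater does
(undefined, raised as an error — the same situation that blocks averaging
in sparse real panels). Group-level values are arithmetic means of
pairwise kappas — all unordered pairs within a group, all cross pairs
between groups — with undefined pairs skipped and counted, not imputed.
Strength bands use closed upper bounds: ≤0.20 slight, ≤0.40 fair, ≤0.60
moderate, ≤0.80 substantial, ≤1.00 almost perfect; negative kappa is
retained and banded slight with a below-zero flag. Weighted kappa, Fleiss'
multi-rater kappa and confidence intervals are out of scope.

## Rank tests and regressions (`vocemo.stats`)

Mann-Whitney U is computed from midranks. For combined n ≤ 12 the
two-sided p-value is exact, by enumeration of all C(n1+n2, n1) group
assignments (ties handled naturally through the midranks); above that, the
tie-corrected normal approximation is used, with a continuity correction
that is on by default and exposed as a flag. The degenerate all-tied case
returns U = n1·n2/2, Z = 0, p = 1.

Spearman correlation is Pearson on midranks (via scipy). Regressions are
OLS with intercept (via statsmodels); standardized β uses sample SDs with
the n−1 denominator, so β² = R² in simple regression and Σβ² = R² for
orthogonal predictors. Rank-deficient designs raise an error naming the
dependent columns (QR with column pivoting). The pairwise
feature-by-emotion contrast table reports two-sided Mann-Whitney p-values
with the direction taken from the median comparison (labels like "N<J");
p-values are raw by default, with Holm adjustment behind a flag.

Calibration note: the type-I-error check for the Mann-Whitney test uses
5000 null replicates at n = 30 per group. That size was chosen so the
asymptotic approximation is in its valid regime; at very small n the
continuity-corrected test on a discrete U statistic is intrinsically
conservative (empirical rate ≈0.038 at n = 15), which is a property of the
test, not an implementation defect.

## Pipeline (`vocemo.pipeline`, CLI `vocemo`)

A run is (config, seed): synthesize a corpus per language → extract
features → simulate each panel → confusion matrices and metrics →
agreement report → feature contrasts. Per-stage seeds are derived from the
master seed with CRC-tagged seed sequences, so partial stages are
individually reproducible and a full run is byte-identical under the same
config and seed. The pipeline refuses to overwrite a non-empty output
directory without `--force` and aborts on the first failing stage.

## Problem sizes used in the shipped experiments

The shipped tests and the acceptance script use: 4 × 30 utterances per
corpus with 20 replicate corpora for parameter recovery and orderings;
10-expert panels over 60 balanced stimuli with 100 replicates for the
in-group advantage; 10,000 trials for the kappa null; 5000 replicates for
rank-test calibration. These sizes put Monte-Carlo noise well inside the
asserted tolerances while keeping a full run in the tens of seconds.

## Known limitations

- The synthesizer's F0/energy structure is recoverable by design; real
  child speech with voicing breaks and formant interactions will degrade
  tracker accuracy in ways these experiments cannot measure.
- Absolute preset values (Hz, ms, dB) are qualitative stand-ins; only the
  orderings between emotions are meaningful.
- Numeric parity with Praat/Cool Edit feature values is not attempted; the
  published regression and Z-score tables depend on unpublished raw data
  and are reproduced as procedures and output formats only.
- Whether published between-group kappas pooled votes or averaged pairs is
  not documented; this package averages pairs, so those values are matched
  at the property level (orderings), not numerically.
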