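# Methods

## The interval spectrum

A band-passed EEG channel crosses its isoelectric (zero) line roughly
once per oscillation cycle.  The *interval spectrum* is the normalised
histogram of the times between successive crossings: a cheap, nonlinear
summary of the rhythmic content of a signal that — unlike the Fourier
spectrum — weights every cycle equally regardless of its amplitude.

Crossings are located by linear interpolation between the two samples
that bracket a sign change, giving sub-sample resolution.  Two
conventions are implemented:

* **rising** (default): crossings from negative to non-negative, one per
  cycle, so a rhythm at *f* Hz produces intervals of 1000/*f* ms and the
  8–13 Hz alpha band maps onto the 77–125 ms interval range.  This is the
  convention consistent with the band mapping used throughout the
  reports this package produces (the alpha peak of a ~10 Hz rhythm sits
  near 100 ms, not 50 ms).
* **all**: both crossing directions, i.e. half-period intervals.  Kept as
  an explicit mode because the definition "intervals between subsequent
  zero-crossings" is ambiguous on its own; the provenance of every
  spectrum records which convention produced it.

Exact-zero samples count as positive, so a run of zeros yields exactly
one crossing at its first sample.  Intervals are histogrammed into
half-open 4-ms bins spanning 0–4000 ms (bins labelled by their left
edge); intervals ≥ 4000 ms are tallied as overflow and excluded.
Intervals are never computed across a protocol-segment boundary: each
(channel, segment) stream is detected independently and only the *raw
histograms* are pooled — over symmetric channel pairs (Fp1+Fp2 … O1+O2,
midline singletons Fz/Cz/Pz), over protocol segments, or over everything
("whole-recording" analysis) — before normalisation.

## Filtering

Band-pass filters are linear-phase FIRs designed by frequency sampling
(`scipy.signal.firwin2`) on a 1-Hz grid of integer edge pairs, with unit
target gain in band, zero gain outside, and a 1-Hz linear transition.
The default order is 500 taps at 250 Hz (a 2-s impulse response), which
resolves 1-Hz transitions down to the lowest bands.  Filters are applied
forward and backward so the group delay is zero and the effective
magnitude response is the squared design response.  Edges use
point-symmetric (odd) reflection padding of one filter length — the
padding keeps signal and first derivative continuous through the segment
edge, so no spurious crossings are created there.  The forward-backward
pass is computed by FFT convolution with the kernel `taps*taps`; this is
numerically identical (to ~1e-14) to `scipy.signal.filtfilt` with the
same padding, and an order of magnitude faster when a ~100-band search
grid is scanned.  Edge transients of a fixed energy remain, as in any
zero-phase scheme; they are negligible for the multi-minute segments the
method is meant for.

## Markers

Three marker families reduce a spectrum to a scalar:

1. **single-bin relative counts** ("spectrometry"): the probability of an
   interval falling in one 4-ms bin;
2. **descriptive statistics** over bin centres: mean, median, mode,
   standard deviation, interquartile range (ms).  They are computed from
   the binned spectrum rather than raw interval lists so all families
   consume one data structure; the binning bias is at most half a bin
   width.  Quantiles interpolate the CDF across occupied bin centres, so
   a point-mass spectrum has zero IQR; mode ties break to the smallest
   bin;
3. **entropies**: Shannon entropy `Hs = −Σ p_i log2 p_i` and min-entropy
   `Hmin = −log2 max_i p_i`, in bits.  `Hmin ≤ Hs` always.  The log base
   is a pure rescaling, and every AUC computed from an entropy score is
   provably base-invariant, so base 2 is fixed by convention.

A Welch power-spectral-density score (4-s Hann window, 50% overlap —
the overlap and taper are the field-standard defaults) at the bin
nearest a chosen frequency serves as the Fourier comparator; comparison
curves index it by inverse frequency (1000/f ms) to overlay the interval
axis.  Power density is used rather than amplitude (an amplitude toggle
exists).

## Screening

Marker distributions within patient subgroups are not assumed normal or
homoscedastic; effects of diagnosis (TLE / FLE / PNES / headache) and of
antiepileptic drug load (nAED 0–3) are screened with one-way
Kruskal-Wallis tests, separately per factor.  Only histogram bins whose
raw count exceeds 100 in *every* subject are tested, which confines the
scan to well-populated parts of the spectrum; the Bonferroni divisor is
the number of tests actually performed (eligible bins + 7 non-bin
markers, per factor) rather than a fixed constant, and the report states
both the per-factor and the joint (×2) thresholds, since either
convention is defensible.  Post-hoc pairwise comparisons use the
Tukey-Kramer procedure on mean ranks with the studentized-range critical
value and unequal-n correction — the classical follow-up to a
significant Kruskal-Wallis test.

## Classification and cross-validation

AUC is estimated by pair counting (ties credit 0.5), i.e. the
probability that a random case outscores a random control; it equals the
scaled Wilcoxon rank-sum statistic and is verified in the tests against
a brute-force double loop.  Because a naive AUC maximised over free
parameters is optimistically biased, classifiers are evaluated by
**leave-pair-out cross-validation**: every case-control pair is held out
once, the parameters are refitted on the remainder, the held-out pair is
scored, and AUC* is the fraction of held-out pairs ranked correctly.

Objectives:

* `alpha_score` — minimise in-fold AUC of a single-bin marker over the
  alpha interval range (bins whose centre lies in 77–125 ms) × the
  passband grid, then invert the classifier;
* `theta_score` — maximise over the theta range (125–250 ms) × grid;
* `shannon_score` / `minentropy_score` — maximise the entropy marker's
  AUC over the passband grid alone.

Ties among equally good candidates break to the lexicographically
smallest (lo, hi, bin, channel group, segment) for cross-platform
determinism.  Held-out ties score 0.5, matching the estimator's tie
convention.  Two-step fitting re-maximises, after the whole-recording
fit, over singleton (symmetric channel group × protocol segment)
combinations; the per-fold ratio of second-step to first-step AUC,
averaged over folds, gives the channel/segment ratio map.  Ratios may
exceed 1 because the second step scores restricted data that the first
step pooled.

### Null behaviour of cross-validated selection

A subtlety worth documenting: at the null (no group difference), LPO-CV
AUC* is unbiased (mean 0.5) but its *spread across cohorts* grows with
the size of the candidate family being fitted.  When one candidate
happens to separate the groups by chance, it is selected in essentially
every fold, and AUC* approaches that single candidate's (extreme)
cohort AUC.  Pure-statistics simulation (iid Gaussian features, no EEG)
reproduces this: with one candidate the null SD matches the Mann-Whitney
value (0.080 at 25 cases/25 controls); with ~100 moderately correlated
candidates it roughly doubles.  Consequently the bin-count objectives
(hundreds of band × bin candidates) have a wide null AUC* distribution,
while the entropy objectives (a handful of strongly correlated passband
candidates) stay close to the theoretical null SD.  The null-calibration
test therefore uses the entropy objective at 50 cases / 50 controls,
where the [0.35, 0.65] band corresponds to ±2.6 null SDs; a separate
test asserts the weaker property that the alpha-score null distribution
is centred at 0.5.  For interpretation of real analyses this means: an
AUC* from a large parameter search is honest in expectation but noisy,
and its distance from 0.5 should be judged against the
selection-inflated null spread, not the plain Mann-Whitney one.

## The synthetic cohort generator

The generator exists to make every pipeline stage testable end to end;
it emulates the *statistical structure the markers respond to*, not
scalp EEG in full.  Per subject (19 channels, 250 Hz, protocol segments
pre-Fs / Fs / post-Fs / Hv / post-Hv, 20 min by default):

* a posterior-dominant **alpha oscillator** — centre frequency N(10, 0.3)
  Hz across subjects, instantaneous-frequency jitter as a smooth
  Ornstein-Uhlenbeck process (fractional SD 0.05, τ = 0.5 s, lognormal
  0.35 spread across subjects), slow lognormal amplitude envelope
  (σ = 0.15, τ = 2 s), 30 µV at O1/O2 falling to ~0.12–0.18 frontally.
  Jitter is the irregularity channel: interval-spectrum entropy responds
  to cycle-length variability, which amplitude modulation alone would
  not move;
* a fronto-central **theta oscillator** — N(6, 0.1) Hz, 10 µV baseline
  (lognormal 0.15 across subjects) plus 3 µV per antiepileptic drug.
  The baseline is essential: without it the theta interval range fails
  the >100-count eligibility rule at any realistic duration, because
  nothing in a clean recording produces theta-paced crossings;
* per-channel **pink (1/f) noise**, 10 µV RMS (lognormal 0.3 across
  subjects), and Poisson-placed **artifact transients** (half-sine,
  0.3–2 s, 100–300 µV, ocular topography, 2/min) drawn from a dedicated
  random stream so that changing the artifact rate perturbs nothing
  else;
* an analogue-like first-order 0.5-Hz high-pass.

Group effects: epilepsy multiplies alpha amplitude by 0.8 and the jitter
SD by 1.35; each antiepileptic drug adds 3 µV of theta.  These defaults
were calibrated — as the package's stated study condition — so that the
best alpha-bin separation between epilepsy-like and control-like groups
is ≈1 within-group SD and the alpha-score AUC* lands near 0.8, with the
Shannon-entropy score in the same region.  The calibration is a demo
operating point, not a claim of fidelity to any patient population.

Two generator parameters deviate from a first-guess design and deserve
their rationale.  The alpha centre-frequency spread uses 0.3 Hz rather
than 0.5 Hz, and the envelope σ 0.15 rather than 0.3: with wider
spreads the subjects' alpha peaks straddle more than three 4-ms bins and
single-bin markers lose the power race against the broadband
"slowing" flank, so the diagnosis/drug double dissociation of the
p-value curves becomes unrecoverable at desk-scale cohort sizes.
Normalised interval spectra are compositional — any change in alpha mass
must reappear elsewhere — so the planted effects are *not* local in the
strict sense: the epilepsy effect also raises theta-range counts (as the
clinical phenomenon itself does: rhythm slowing).  What the generator
guarantees, and the tests assert, is dominance and dissociation: each
factor's p-curve minimum falls in its home range (diagnosis → alpha,
drug load → theta) in the majority of cohorts.

What the generator does **not** model: epileptiform discharges (spikes),
photic driving, sleep architecture, eye-state changes, reference
contamination (an ideal common reference is assumed), volume-conduction
correlations between channels beyond shared oscillators, and non-
stationary medication effects.  Passing tests therefore demonstrate the
*pipeline's* correctness and calibration on signals with known structure
— they say nothing about diagnostic performance on real patients.

## Problem sizes

The seed-replicated experiments run at reduced sizes chosen to keep the
full test suite in the tens of minutes on one core: null calibration
uses 100-subject cohorts with a single 20-s segment and a 4-band entropy
grid over 200 seeds; effect-recovery uses 50-subject cohorts with a 60-s
segment and a 20-band grid over 5 seeds; the dissociation cohorts use a
300-s segment (theta-bin eligibility needs the counts); the artifact
contrast uses 6 subjects at 60 s.  The reference-cohort arithmetic and
the 20-minute default protocol are unchanged.

## Numerical choices and degenerate inputs

* Segment boundaries are half-open in seconds, mapped to samples by
  floor; adjacent segments can never overlap by construction.
* EDF output is 16-bit with physical range ±1000 µV against digital
  ±32767 (quantisation step ≈ 0.031 µV), record duration 1 s; the writer
  truncates to whole seconds and clips out-of-range samples.  Reading
  goes through `mne`; a per-channel sampling-rate mismatch raises rather
  than resampling.
* A constant (or all-positive) signal yields an empty crossing list; a
  spectrum with zero total raises rather than returning NaNs.
* A single-level factor in the screen (e.g. a cohort with no treated
  subjects) reports NaN p-values instead of failing.
* Completely tied Kruskal-Wallis data are defined as no evidence
  (H = 0, p = 1).
* `subsegment_experiment` at the full segment length returns exactly 1
  with zero SD (degenerate subsampling), and identical seeds give
  identical curves.

## Known limitations

* Descriptive markers inherit up to half-bin-width bias from binning.
* The averaged ROC curves are built from in-fold fitted scores and are
  optimistically biased; the function warns accordingly.
* The channel/segment ratio map requires the first fitting step to have
  found a sensible bin; when the planted signal is confined to one
  channel pair and segment, the whole-recording first step only sees its
  faint pooled trace, so the map is reliable only when some global
  effect exists (or subject heterogeneity is low).
* Edge transients of the zero-phase filter bias interval counts within
  ~2 s of segment boundaries; segments shorter than ~10 s are not
  meaningful inputs.
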