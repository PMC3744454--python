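# Methods

This note documents the models, parameter choices and numerical
conventions behind `larksong`, and what the synthetic data do and do
not establish about real recordings.

## Segmentation model

The operational syllable definition — a continuous spectrographic
trace, or traces separated by silent gaps of less than 25 ms — was
conceived for visual annotation.  The automated surrogate used here
thresholds a dB amplitude envelope: per-sample RMS power in a 2.5 ms
moving window, expressed relative to the song's maximum.  Voiced
regions above `threshold_db` (default −30 dB) are detected, regions
separated by gaps strictly shorter than `merge_gap_ms` (default 25 ms;
a gap of exactly 25 ms separates) are merged, and merged regions
shorter than `min_dur_ms` (default 10 ms) are discarded.  The threshold
and minimum duration have no counterpart in visual annotation and are
free, logged choices; no equivalence with human segmentation is
claimed.  The merge step is idempotent, lowering the threshold never
reduces total voiced time, and on jitter-free synthetic songs at
infinite SNR the segmenter recovers the generator's annotations exactly
(count) and within ~1 ms (boundaries; the raised-cosine onset ramps
bias onsets slightly inward, well under one analysis hop).

High-pass filtering is FFT masking (zero-phase): bins below the cutoff
(default 1600 Hz) are zeroed, with a 100 Hz raised-cosine transition to
limit ringing.  Spectrograms are magnitude STFTs with a 1024-point
Hamming window; the analysis overlap defaults to 0.75 (hop 256
samples).  The 100%-frame display convention of spectrogram software
corresponds here to `fft_length=1024` with a configurable overlap — a
display-versus-analysis distinction, since segmentation accuracy needs
finer hops than a zero-overlap display.

## Spectral measurements

All spectral parameters are read off the mean spectrum of a syllable:
squared STFT magnitudes averaged over the frames within the annotation
(energy weighting; an amplitude-weighted variant is available via
`weighting="amplitude"` since the convention is not fixed by the verbal
definition).  The peak frequency is the argmax bin.  The quartile
frequency qXX is the smallest frequency at which cumulative energy
reaches XX% of the total — the "upper limit" of the energy quartile
read as the threshold-crossing frequency.  Bandwidth needs a level
criterion to make "maximum minus minimum frequency" well defined; the
default floor is 24 dB below the spectral peak, configurable as
`floor_db`.  Quartile monotonicity (q25 ≤ q50 ≤ q75) holds by
construction.

Rhythm is the mean of per-syllable duration/gap ratios — the ratio is
defined per syllable, then averaged; the ratio-of-means variant is
reported alongside (`rhythm_ratio_of_means`) because the two differ
under timing jitter.  Syllables with a zero gap are excluded from the
rhythm mean and counted.  Tempo divides the syllable count by the span
from first onset to last offset of the analysed excerpt.

## Sequence analysis

Versatility windows are non-overlapping and consecutive from the
sequence start, with a trailing partial window dropped (a sliding mode
exists).  TrVer counts *distinct* ordered transitions between
different syllables — the variety reading; the raw count of differing
adjacent pairs is available as `trver_mode="count"`.  Both readings
agree at the printed extremes (9 for a fully alternating window, 0 for
a constant one).

The sequence catalog enumerates every contiguous sub-sequence of
length 3–10 containing at least three distinct syllable types
("at least three different consecutive syllable types" read as a
distinct-type count, not as all-adjacent-differing; a strict-adjacent
mode exists).  Overlapping occurrences are counted.  For the RS
coefficient in sequence mode, X and Y are the numbers of *distinct*
catalog keys, matching the repertoire-size convention of syllable mode;
sub-sequences of longer shared sequences are not collapsed.

## Statistical machinery

**pDFA.**  The discriminant core is a two-class Fisher axis
w = S_w⁻¹(m₁ − m₀) with nearest-centroid assignment along the axis and
standardized coefficients (axis × pooled within-class SD).  A ridge
term (1e-8 of the mean within-class variance) keeps near-singular
tables solvable.  The permutation scheme respects the crossed design:
phase labels are reshuffled independently within each individual,
preserving that individual's per-phase counts, and the full DFA is
re-run; p = (1 + #{permuted ≥ observed})/(1 + N).  Classification is
in-sample over all rows (the statistic is a whole-sample correct
count); with few rows relative to parameters the count saturates and
the test becomes conservative, so phase-comparison runs default to
10 individuals × 2 songs × 2 phases = 40 rows against 12 parameters.
A Shapiro–Wilk screen on cell-mean residuals flags non-normal
parameters; exclusion is an explicit configuration choice (the
phase-comparison pipeline excludes gap duration by default, which is
right-skewed by construction), and excluded parameters are recorded in
the result.

**Within-subject tests.**  The "GLM with subject as random factor" for
a balanced two-level within-subject design is computed as a randomized
block ANOVA: replicate observations are averaged within subject × level
cells, then F = MS_level / MS_level×subject with df (p−1, (p−1)(s−1)).
For two levels this equals the squared paired t.  Exact degeneracy
(zero effect and zero residual) returns F = 0, p = 1 via a relative
tolerance guard.

**Permutation and rank tests.**  Paired permutation tests flip the sign
of each pair's difference; exact mode enumerates all 2ⁿ patterns (cap
2²⁰), Monte-Carlo mode applies the add-one correction so p never
reaches 0 and has floor 1/(N+1).  The Wilcoxon signed-rank test drops
zero differences, assigns mid-ranks to ties, and for n ≤ 25 computes
the exact null distribution of the positive-rank sum by convolution
over doubled (integer) ranks — valid under ties, where the classical
tables are not; the two-tailed p uses the symmetry of the sign-flip
distribution.  Above n = 25 a tie-corrected normal approximation is
used.  Both statistics are reported on the rank-sum scale (W⁺), which
is the scale small-sample software traditionally prints.

**Playback scoring.**  De-duplication drops, in order: near-zero
variance measures, count measures whose total falls below a floor
(default 5 — a handful of calls across all playbacks carries no
usable signal), and the later member of any pair correlating at
|r| = 1 within 1e−12.  PCA is computed on the correlation matrix of
the remaining standardized measures; components with eigenvalue > 1
are retained, each loading vector (unit eigenvector) is sign-fixed so
its largest-magnitude entry is positive, and eigenvalues within 0.05
of 1 set an `unstable_retention` flag rather than an error.  Retained
scores are tested within subject against stimulus type and against
presentation order; measures with |loading| ≥ 0.5 (configurable; no
criterion is fixed by convention) on a significant component get
Wilcoxon follow-ups on the raw measure.

## Synthetic data model

The generator emulates the study conditions, not skylark physiology.

*Repertoires and sequences.*  Each group of individuals shares a label
pool and the group sequences drawn from it (length 3–10, ≥ 3 distinct
types), emulating micro-dialects; remaining labels are private.  Label
sequences are built window by window: each 10-syllable window uses
exactly k distinct types, with k randomized between ⌊target⌋ and
⌈target⌉ so the windowed SylVer mean equals the target (a degenerate
target of 1 yields a constant sequence).  Group sequences are embedded
verbatim — each at least once, then with probability 0.2 per window —
with the window's distinct-count bent minimally when needed to fit.

*Audio.*  A syllable is an FM burst: a carrier at the phase's peak
frequency (0.42), a label-specific sweep spanning the phase bandwidth
(0.42; direction and curvature fixed per label, so a label always has
the same shape), and two weak edge tones (0.08 each) that accentuate
the FM turning points so the band extent is sharply defined at any
analysis bin width.  The carrier makes the measured spectral peak land
on the set value within one bin; the sweep and edge tones make the
−24 dB bandwidth land on the set value within a few percent.  Onsets
and offsets carry 5 ms raised-cosine ramps.  Durations and gaps are
drawn around the phase means with relative jitter `jitter_cv`
(default 0.08 — a free choice, as no within-male spread is published;
clipped at 25% of the mean so gaps stay clear of the merge rule).
Optional white noise at a stated SNR is the only noise model.
Per-phase defaults are the published per-phase means (duration
137.9/158.9 ms, gap 48.33/54 ms, peak 4074/3954 Hz, bandwidth
1755/1859 Hz, SylVer target 8.309/6.778 for ascending/level).  In
`make_study`, each male additionally receives stable idiosyncratic
offsets (peak ±100 Hz SD, bandwidth ±120 Hz SD, duration ×7% CV, gap
×10% CV, versatility ±0.6 SD — the order of the between-male spread
implied by the published standard errors) applied identically to both
phases, so individuality inflates between-male variance without
biasing the paired phase contrast.

*Responses.*  Trials are driven by two latent standard-normal factors:
a locomotor factor loading (at 0.90) positively on the three movement
durations and negatively on the three latencies, and a vocal factor
loading positively on song duration and negatively on song latency.
The loading strength is chosen so the two retained components carry
roughly the dominant share of variance that the reference loading
structure implies (~80%).  `vocal_effect` shifts the vocal factor for
S1 trials, in latent-SD units.  The two time-in-zone measures duplicate
the corresponding movement durations exactly (the |r| = 1 pairs the
de-duplication step must catch), and calls are Poisson with mean 0.1
per trial (rare by design).  Values are clipped to [0, 160] s — the
observation span — with means placed ≥ ~1.8 SD from the bounds so
clipping stays mild.

*Feature-table simulator.*  Calibration simulations for the pDFA
(type-I error, power) need hundreds of replicates, so they run on a
feature-level simulator rather than rendered audio: parameter = phase
mean + male effect + within-male residual, with the between-male SD
recovered from the published standard errors (SE × √20) and the
within-male SD set equal to it (no within-male spread is published;
equality is a deliberate, conservative choice).  The audio path is
exercised end to end by the direction-recovery runs instead.

## What passing tests show — and do not

The synthetic songs have isolated FM syllables on silence, stationary
phase parameters and exactly known labels.  Passing the round-trip and
recovery tests shows the pipeline measures what the definitions say on
signals where ground truth exists; it does not show robustness to
overlapping wind noise, amplitude modulation from a moving bird,
syllable-type confusion, or annotation error — the segmentation
threshold in particular would need tuning per recording.  The
statistical calibration results (type-I error within binomial bounds of
nominal, permutation floors, oracle equivalence) are
distribution-level properties and carry over to real tables with the
same design.

## Problem sizes

Default analysis runs use 10 individuals × 2 songs × 2 phases with 50
syllables per song at 22.05 kHz (the band of interest ends below 6 kHz,
so half the field sampling rate loses nothing); calibration simulations
use 20 individuals × 2 songs × 2 phases (80 excerpts, mirroring the
reference design) with 200 permutations per test.  These sizes keep a
full test run in the low minutes on one core while leaving every
statistic in the regime where its calibration is informative.
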