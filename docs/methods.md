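# Methods

`canisleep` implements a quantitative analysis pipeline for canine sleep
polysomnography in a paired drug study design: each dog is recorded for
2 h at 400 Hz on four EEG channels (F3, F4, Fz, Cz referenced to Oz)
under a control and a trazodone condition, and the scored hypnogram plus
the EEG are analyzed along four axes — sleep architecture, spectral
content, nonlinear dynamics, and inter-channel connectivity. Because no
recordings of this kind are publicly deposited, the package carries a
synthetic-data generator that reproduces the study's shape and injects
known effects, so every stage can be validated end to end.

## Preprocessing

The continuous record is band-pass filtered to [1, 70] Hz with a 60 Hz
power-line notch, then cut into the scored 3-s epochs (1200 samples at
400 Hz; epoch *i* covers samples `[1200·i, 1200·(i+1))`, half-open; a
trailing partially-covered epoch is dropped, never padded). The filter
family is a 4th-order Butterworth applied forward-backward (8th-order
effective magnitude, zero net phase — phase preservation matters for the
connectivity stage) and a quality-factor-30 IIR notch, also
forward-backward. All epochs enter the hypnogram analyses; EEG-signal
metrics use 5 artifact-free epochs per behavioural state, drawn
uniformly without replacement from a generator seeded per
(seed, subject, condition). States with fewer than 5 clean epochs
contribute all they have (logged); states with none are absent and
downstream group comparisons degrade from paired to unpaired.

## Sleep architecture

Per session: percentage of epochs per state; latency to the first epoch
of each state in minutes, censored at the total recording duration
(120 min by default) when the state never occurs — the censoring rule
applies uniformly to every state, not only REM; the Lempel-Ziv
production complexity of the 4-symbol state sequence (see below); and
the first-order transition matrix `P(next state | current state)` from
all consecutive epoch pairs, row-normalized, with rows of unvisited
states left undefined (NaN) rather than imputed. Between conditions,
every architecture metric is compared with a paired two-sided Wilcoxon
signed-rank test; transition cells are compared cell-wise over subjects
for which the cell is defined in both conditions.

## Lempel-Ziv complexity

`lzc_sequence` returns the production complexity c(S) of the exhaustive
history: the sequence is parsed left to right, each phrase being the
shortest extension not reproducible as a substring of everything before
its final symbol, and c(S) is the phrase count. The implementation
parses with C-level substring search over a byte-mapped alphabet; the
test suite verifies it against an independent pointer-scanning counter
on all 8190 binary strings of length ≤ 12 and 10,000 random quaternary
strings. Hypnogram comparisons use the raw integer count (sequences
have near-equal length per session); EEG comparisons use the normalized
form `c·log2(n)/n` by default, with the raw count retained. For EEG the
signal is first binarized at its median — strictly above the median
maps to 1, ties to 0, so a constant signal yields the minimal-complexity
all-zero string with c = 2 for n ≥ 2.

## Permutation entropy

Bandt-Pompe ordinal patterns with embedding dimension D = 4 and delay
τ = 1 by default: each window of D samples is reduced to the
permutation that sorts it (ties broken by order of occurrence — a
stable sort, deterministic), and the Shannon entropy (bits) of the
pattern distribution is normalized by log2(D!), giving values in [0, 1].
PE is rank-based, hence exactly invariant under strictly monotone
transformations of the signal.

Both nonlinear metrics are computed on a low- and a high-frequency
component of each epoch — [1, 16] Hz and [17, 50] Hz by default (a
[16, 45] Hz high-band preset also ships; the two conventions circulate
and the split is configurable) — then averaged over the 5 epochs and 4
channels to one value per session × state × band × metric. Conditions
are compared per state (paired for wakefulness/drowsiness, unpaired for
NREM/REM); states are compared within a condition with Kruskal-Wallis
followed by Dunn's post-hoc z-tests on mean ranks (tie-corrected), with
Holm adjustment over the pairwise family by default (Bonferroni and
unadjusted available). Holm was chosen because it controls FWER
uniformly more powerfully than Bonferroni; the exact variant used by
comparable analyses is rarely stated.

## Spectral analysis

Welch spectra use an 800-ms Hann window at 50% overlap everywhere (the
same engine for power and coherence), giving 1.25 Hz resolution on 3-s
epochs. The relative PSD divides the epoch-averaged power at each
frequency by the total power over [1, 50] Hz per channel, removing
between-subject amplitude scale (skull thickness, electrode contact);
bins inside the normalization band sum to 1 by construction.
Channel-pair magnitude-squared coherence is computed per epoch and
averaged, reported on [1, 50] Hz. Group comparisons are per frequency
bin — paired Wilcoxon where pairing holds, Mann-Whitney otherwise — with
raw p-values thresholded at 0.01 (rPSD) or 0.05 (coherence) and no
correction across bins, reproducing the shading convention of the
analyses this pipeline mirrors; a Benjamini-Hochberg option exists, off
by default. Contiguous significant bins are reported as bands.

## Phase Lag Index and the surrogate threshold

PLI is computed in five 2-Hz bands (delta [2,4], theta [5,7], alpha
[9,11], beta [19,21], gamma [34,36] Hz). Implementation: the epoch's
spectrum is multiplied by the squared magnitude response of the
4th-order Butterworth band filter (identical in magnitude and phase to a
forward-backward application, with circular rather than reflective
boundary handling) and the analytic signal is obtained in the same step
by one-sided inverse FFT; 5% of samples at each epoch edge are then
discarded, which removes the circular wrap-around region along with
Hilbert edge effects. The PLI of a pair is `|⟨sign(Δφ(t))⟩|` with the
phase difference wrapped to (−π, π]; it is evaluated as
`sign(Im(z_i z̄_j))`, algebraically identical and exact for zero-lag
inputs. Per-epoch PLIs are averaged over the 5 epochs into one 4×4
matrix per band, state and session.

The condition contrast is `ΔPLI = ⟨PLI_control − PLI_trazodone⟩` over
dogs (pairwise-complete: dogs lacking the state in either condition are
excluded and logged). Its significance threshold comes from Ns = 100
phase-randomized surrogates per session: each channel's Fourier phases
are replaced independently by uniform draws, preserving every
per-channel amplitude spectrum (hence PSD) while destroying all
cross-channel phase relations; each surrogate then passes through
exactly the real PLI pipeline. The threshold is `Th = μ_s + σ_s` with
the mean and SD taken, by default, over the pooled collection of all
per-dog, per-surrogate difference matrices (`threshold_scope="pooled"`).
This places Th at the scale of a single dog's estimation noise, about
3–4 standard errors of the dog-averaged ΔPLI, so matched null cohorts
are essentially flag-free while an injected coupling difference exceeds
it several-fold. Two alternative scopes are provided — SD across the
ensemble of dog-averaged differences, and SD across animals of
ensemble-averaged differences — both of which place Th near 1 standard
error of ΔPLI and therefore flag roughly a third or more of null edges;
they are retained for comparison but not used by default. Edges with
`|ΔPLI| > Th` are flagged with the direction of change
(control-increase vs trazodone-increase) recorded explicitly, since the
sign convention of published ΔPLI figures is ambiguous. The surrogate
ensemble is computed in single precision (the PLI depends only on signs
of phase differences). All surrogate draws derive deterministically from
(seed, subject, condition).

## Group statistics

Paired Wilcoxon signed-rank (two-sided; zero differences dropped by
Wilcoxon's original rule; exact null for n ≤ 25, tie-corrected normal
approximation with continuity correction otherwise), Mann-Whitney U
(exact for group sizes ≤ 25), one-sample Kolmogorov-Smirnov against a
normal with the sample mean and SD (reported as a diagnostic, never used
to gate the nonparametric tests), and Kruskal-Wallis + Dunn as above.
Significance is 0.05 unless a stage states otherwise. For tied data the
exact Mann-Whitney p-value maps the statistic onto the tie-free null
(the standard behaviour of the underlying routines); oracle-equivalence
tests therefore use continuous, tie-free data.

## Synthetic data generator

The generator emulates the study, not canine neurophysiology: EEG is
Gaussian band-limited noise, stationary within states, with none of the
transients (spindles, K-complexes, movement artifacts) of real
recordings. Passing tests therefore demonstrate that the pipeline
recovers the structure it is designed to measure at realistic effect
sizes — not that it would behave identically on real, non-Gaussian,
nonstationary EEG.

Hypnograms are first-order Markov chains over the four states in 3-s
epochs (no semi-Markov bout durations). Default transition matrices
give a control stationary occupancy of roughly 19% wake / 22%
drowsiness / 55% NREM / 4% REM, and the trazodone-like variant raises
self-transitions (stickier states → lower hypnogram LZC), leaves NREM
occupancy essentially unchanged, increases drowsiness, and cuts
NREM→REM entry to 5·10⁻⁴ per epoch, so that ~60% of full-length (120-min)
trazodone sessions never reach REM — matching the study-reported REM
suppression (at the reduced 10-min length used in the acceptance runs
the absence fraction is higher, ~95%).

EEG per channel is a weighted sum of unit-RMS Gaussian band components
(delta [1,4], theta [4,8], alpha [8,13], beta [13,30], gamma [30,48] Hz,
synthesized spectrally under the same Butterworth magnitude response
used in analysis) plus a 1/f pink background (weight 0.15), scaled to
30 µV. Per-state weights follow classic profiles (delta-dominant NREM,
broadband wake/REM). Band amplitudes follow the scored state through
envelopes with 0.25-s crossfades, keeping epochs internally stationary.
Between-subject variability is a lognormal jitter on band weights
(σ = 0.05, i.e. 5% amplitude CV), shared by a subject's two sessions as
a subject trait. This value was fixed by a design-time power analysis:
with n = 12 per arm and a 1.5× high-band power effect, per-bin detection
at p < 0.01 requires the total per-bin coefficient of variation to stay
near 0.14, of which Welch estimation noise over 5 epochs × 4 channels
already contributes ~0.09. Artifact flags are drawn per state at the
retention rates the study reports (e.g. only 7.7% of control wakefulness
epochs clean, 100% of NREM); flagged epochs are excluded from EEG
metrics but their signals are not actually corrupted (an optional
corruption injector was considered out of scope).

Cross-channel coupling: a pair shares a common band-limited drive, one
copy phase-shifted by a fixed lag. The coupling fraction f is a linear
amplitude share (`(1−f)·private + f·drive`, renormalized), giving a
private-to-shared variance ratio `((1−f)/f)²`; amplitude mixing rather
than variance mixing is essential because a narrowband drive's Rayleigh
envelope fades would otherwise scramble phase whenever the drive is
weak. The trazodone-like preset injects f = 0.8 alpha-band Fz–Cz
coupling at lag π/4 during NREM; spectrally, it multiplies power above
13 Hz by 1.5 in drowsiness and NREM and reduces power below 13 Hz by
0.8× in wakefulness and drowsiness.

## Pipeline and reproducibility

`run_all` executes preprocess → hypnogram → spectral → complexity →
connectivity over a TSV manifest of EDF recordings and TSV hypnograms,
writing plain TSV tables keyed by (subject, condition, state, band) plus
a JSON run summary; each table carries a header line with the package
version, seed and configuration hash. Stages are idempotent and
individually runnable; a missing upstream stage is reported by name.
Given (inputs, configuration, seed), all outputs are byte-identical
across reruns. One master seed drives epoch sampling, surrogate
generation and data synthesis through per-stream seeds derived by
hashing (seed, purpose, subject, condition).

## Problem sizes for validation runs

The acceptance runs use scaled-down cohorts chosen to exercise the full
method chain at meaningful power: 20 seeded replicates of 12 paired
subjects with 10-minute sessions (200 epochs) for the end-to-end drug
signature and the matched-null false-positive checks, 10,000-epoch
chains for transition-matrix recovery, 120-s segments for coupling
recovery, and exhaustive or 500–10,000-case sweeps for the oracle
equivalences. Full-length (120-min) generation is the default outside
these runs.

## Known limitations

- The generator's Gaussianity means surrogate data are distributionally
  exchangeable with the originals; real EEG nonstationarity could widen
  surrogate thresholds.
- PLI floors are elevated for 3-s epochs in 2-Hz bands (few effective
  samples per epoch); absolute PLI values are therefore comparable only
  within a fixed epoch length and band width, which the paired design
  respects.
- Per-bin spectral tests are uncorrected by design (mirroring the
  analysis convention reproduced here); the Benjamini-Hochberg option
  should be preferred for confirmatory use.
- No automatic sleep staging, artifact detection, EOG/EMG/ECG handling,
  directed connectivity or source modelling.
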