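# Methods

This note documents the models and procedures implemented in `dfhm`, the
assumptions behind them, and the choices made where the design was open.

## The workload index

The package estimates mental workload from EEG using Dual Frequency Head
Maps (DFHM). The physiological premise is the classic spectral workload
signature: frontal midline theta power (4–8 Hz) rises and parietal alpha
power (8–12 Hz) falls as cognitive load increases. The processing chain is:

1. **Band-pass filtering**, 0.5–40 Hz, linear-phase FIR of order 100
   (Hamming window). The filter is applied in one forward pass with the
   group delay compensated by centred convolution; the first and last
   order/2 samples are edge transients and are flagged in provenance. The
   realization (FIR) is the package's choice — it keeps band-power tests
   clean because the passband is flat to within a few percent and 50 Hz
   mains is attenuated by ~50 dB.
2. **Infomax ICA** for ocular artifact rejection. Data are mean-centred and
   PCA-whitened (reduced-rank, so a flat acquisition-reference channel is
   harmless); classic (non-extended) Infomax unmixes the whitened sources.
   Components are canonicalized — ordered by explained variance, sign fixed
   so each mixing column's largest-magnitude weight is positive — so seeded
   runs are comparable. The rejection rule is automatic: a component whose
   time course correlates (|r| > 0.7) with the low-passed (< 4 Hz) mean of
   the frontal-most electrode pair (Fp1/Fp2) is removed. An optional
   frontal/other scalp-weight-ratio criterion exists but is off by default,
   because strongly frontal *rhythmic* components are legitimate workload
   signal. Whether rejection in the original analysis chain was manual or
   automatic is unknown; this rule is a documented, testable stand-in.
3. **Hjorth surface Laplacian**: each channel minus the mean of its
   neighbours, neighbours found by nearest-neighbour search in schematic
   2-D coordinates, capped at 8 and symmetrized by mutual agreement. Border
   electrodes keep fewer than 8 neighbours — the cap cannot hold at the
   montage border, so cap-and-symmetrize is the least surprising reading.
4. **Average reference** (idempotent, common-mode invariant).
5. **Segmentation** into 1-s windows stepping by 0.5 s; only windows fully
   inside the recording are used, so a T-second recording yields
   ⌊(T−1)/0.5⌋+1 segments.
6. **Band power** per electrode by plain FFT periodogram (rectangular
   taper by default; Hann behind a flag). Power is the *sum* of bins in the
   half-open band [low, high) — 8 Hz belongs to alpha only — normalized so
   a unit sinusoid carries amplitude²/2 (Parseval). Whether bin-sum or
   bin-mean was intended is unspecified; under a fixed grid the z-scoring
   step cancels the distinction, which a test asserts.
7. **Z-scoring** against per-subject baseline statistics (mean and SD of
   each electrode's band power) from the first 60 s of the session
   recording. The original baseline spans recordings that do not exist
   here (rest and familiar workplace tasks from a separate session); using
   the first minute of the session is the documented deviation, and the
   synthetic generator exposes a generic baseline segment rather than
   guessing that material's spectral content. SDs below 10⁻¹² µV² are
   floored and flagged so degenerate synthetic baselines cannot produce
   infinities.
8. **Classification** of each 14-dimensional DFHM vector (7 frontal theta
   z-scores + 7 parietal alpha z-scores) into low/moderate/high workload by
   an SVM (RBF kernel, one-vs-one multiclass, C chosen by stratified 5-fold
   CV over {0.1, 1, 10, 100}). The originally deployed classifier and its
   training corpus are unavailable, so the package trains a stand-in on
   synthetic calibration clusters; no attempt is made to reproduce the
   original decision boundaries.
9. **Index**: labels are mapped {low → 0, moderate → 50, high → 100} and
   averaged over a trailing (causal) 6-s window. This is the unique affine
   mapping hitting both stated endpoints (all-low → 0, all-high → 100) with
   the middle class centred; the exact "adjustment" used originally is
   unknown and this mapping is a documented modeling substitution. The
   window is defined from the first label on (a partially filled window
   averages what is available), which fixes an unstated boundary convention
   and permits online use. Changing a single label can move the index by at
   most 100/12 ≈ 8.3 points.

## Synthetic data

The EEG generator emulates only the structure the pipeline's assumptions
touch: 25 channels of a 10–20 montage at 500 Hz, with band-limited
(0.5–40 Hz) 1/f-shaped background noise (default SD 5 µV) plus sinusoidal
rhythms — 6 Hz on frontal channels with amplitude (2, 4, 6) µV for
(low, moderate, high) latent workload, 10 Hz on parietal channels with
amplitude (6, 4, 2) µV. Sinusoids make expected band powers analytically
checkable (amplitude²/2). The acquisition-reference channel (Cz) is flat.
Blink artifacts are biphasic ≤ 4 Hz pulses of 120 µV peak, 100–300 ms,
projected with exponential falloff from the forehead, Poisson-counted at a
configurable events/min rate, with a ground-truth log. Real EEG
microstructure — per-subject 1/f exponents, spindles, non-stationarity,
volume-conduction mixing of the rhythms themselves — is deliberately not
modelled, so passing tests demonstrate correctness of the *pipeline
machinery*, not field performance on human data.

The behavioral cohort generator draws 21 subjects with distinct integer
operation-span (AOSPAN) absolute scores centred near 43 (range 0–75), so
the strictly-below-median split yields groups of 10 and 11. Per-condition
workload-index means and SDs default to the study's descriptive values
(e.g. planning task 62.5 ± 7.4, memory task 57.5 ± 6.0 index points);
draws share a per-subject random effect with cross-condition correlation
ρ = 0.6, the standard repeated-measures structure — with independent draws
the paired task contrast would rarely reach significance at n = 21,
whereas the correlated structure makes the documented contrast typical.
Planning times are log-normal (matched to the natural-scale mean/SD per
condition and group), chosen so that the log transform used downstream is
exactly the right normalizing transform. Error counts are zero-inflated
Poisson (extra-zero probability 0.4), a right-skewed integer process for
which even log transforms fail normality — matching how they are treated
(nonparametrically) downstream.

## Task machinery

Tower of Hanoi is modelled as the 3ⁿ-state legal-move graph (discs encoded
by peg assignment; stacking order is forced). Minimal move counts are
breadth-first-search distances; trial generation draws uniformly (seeded)
among ordered state pairs at exactly the requested distance, excluding
start = goal. The restart protocol treats a move as an error iff it
strictly increases the remaining BFS distance relative to the best
available continuation — alternative optimal moves are allowed, which is
the weakest reading of "would result in a greater number of moves"; the
comparison is against the optimum from the *current* state, not the
original start (the ambiguity is noted, the current-state reading
implemented). Planning time is simulated log-normally, independent of move
execution. AOSPAN scoring is all-or-nothing per set (the absolute score),
and the per-subject math time limit is mean + 2.5 × sample SD of practice
response times.

## Statistics

The battery mirrors an SPSS-style repeated-measures analysis:

- **Shapiro–Wilk gating** at α = 0.05 selects parametric vs nonparametric
  branches; the decision and statistic are always logged, never silent.
- **Wilcoxon signed-rank**: zero differences dropped, ties mid-ranked with
  the variance correction; T is the smaller rank sum; z from the normal
  approximation without continuity correction; two-sided p; effect size
  r = |z|/√N with N = 2 × pairs. These conventions are the unique set
  consistent with reporting a (T, z, r) triple like (26, −3.11, 0.48) at
  n = 21.
- **Mixed ANOVA** (one within, one between factor) by the classical SS
  decomposition with complete crossing; no sphericity correction (the
  design's printed df are uncorrected), so error df are (N − g) between
  and (N − g)(k − 1) within/interaction; partial η² =
  SS_effect/(SS_effect + SS_error). Bonferroni post-hoc paired t-tests
  (adjusted p = min(1, p·m)) are reported regardless of the omnibus, as
  simple effects within each group where requested.
- **Friedman** χ² (tie-corrected, df = k − 1) with **Dunn–Bonferroni**
  rank-mean z post-hocs; an omnibus effect with no significant pairwise
  contrast is an expected outcome, not an error.

The normal/χ² approximations are validated in-tree against exact
enumeration (all 2⁸ sign assignments at n = 8; all (3!)⁵ within-row
permutations at n = 5), with max |Δp| < 0.05.

## Pipeline

`run_all` executes calibration → cohort → per-subject EEG →
conditioning → DFHM → classification → index → condition averages →
descriptive table → statistics, all derived from one seeded config whose
hash is stamped into the report. Per-subject sessions are laid out as a
60-s baseline, a memory-task interval, then the six planning trials, each
trial's interval length derived from the subject's behavioral record
(planning time plus executed moves at 1.5 s per move, restarts included)
and clipped to [5, 60] s. Latent per-segment workload labels inside an
interval are drawn i.i.d. with a fixed moderate share of 0.3 and
P(high) = clip((I − 15)/100, 0, 0.7), which makes the expected index equal
the condition's target I on the interior of the scale; how EEG was aligned
to tasks originally is not described, so this construction is the
package's own. If calibration separability is at chance (CV accuracy below
0.45), the report flags it and withholds statistical conclusions.

Default problem sizes: 21 subjects, 200 calibration points per class,
60-s baselines. The test suite exercises the same code at reduced sizes
(3–4 subjects, 10–20-s intervals, 40 calibration points per class), which
it states as its own choice of problem size; every algorithmic path is
identical.

## Known limitations

- The classifier is calibrated on synthetic clusters; its boundaries bear
  no relation to any deployed workload classifier.
- The EEG generator's rhythms are stationary sinusoids within a latent
  level; segment-level label noise at level transitions biases the
  EEG-derived index slightly toward 50 relative to the latent target.
- EDF files can be read (via mne) but not written in this environment;
  the canonical interchange formats are long-format CSV and JSON.
- The mixed ANOVA assumes complete crossing and reports uncorrected df;
  unbalanced *group* sizes are handled, missing cells are not.
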