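# Methods

## The scientific question

When people retell a long naturalistic experience — here, a ~50-minute
movie watched during fMRI, followed by unguided spoken recall in the
scanner — the retelling is temporally compressed: a single sentence may
cover seconds or minutes of movie time.  This package implements a chain
of analyses that (1) quantifies that compression from recall
transcripts, (2) measures classical within-subject reinstatement
(encoding-recall pattern similarity) as a function of compression, (3)
isolates *subject-consistent* encoding-to-recall pattern change with an
inter-subject statistic, and (4) asks whether scenes that people retell
more summarily undergo larger subject-consistent pattern change.

## Behavioural coding

Transcripts are segmented into utterances, each mapped to a span of
movie *micro-segments* (fine events of a few seconds, nested inside ~50
coarse *scenes*).  The temporal-precision rule: an utterance whose
described movie time (summed micro-segment durations of its span)
exceeds `threshold_s` (10 s) is a **Summary**; at most 10 s is
**Temporally Precise**; utterances without a span (inaccurate,
meta-cognitive) are **Other** and excluded from analysis.  A tie at
exactly 10 s is Precise by default (`boundary_rule`, configurable),
following the figure-caption convention "10 s or less is precise".

Derived quantities:

- **Temporal compression factor** `TCF = 1 − (content words / described
  seconds)`.  Content words are tokens after lowercasing, punctuation
  stripping, and removal of stop words and transcription fillers
  ("uh", "um", ...).  Higher TCF = fewer words per second of retold
  movie time.  TCF is naturally negative for short precise utterances
  and is only bounded above (by 1).  The stop-word list is a standard
  English function-word list, user-overridable in the configuration.
- **%Summary bias** per scene and subject: the proportion of that
  scene's recalled content words coming from Summary utterances, with
  Other words excluded from the denominator.  An utterance spanning
  several scenes credits its full word count to each scene it touches.
  Bias is defined only for recalled scenes (any non-Other utterance
  touching the scene).

## Within-subject reinstatement

For each retold micro-segment, the movie-run pattern (mean of TRs whose
onset falls inside the segment, optionally shifted by `lag_trs` to
compensate hemodynamic delay; synthetic data are generated without lag
so generator-driven runs use 0) is Pearson-correlated with the pattern
of the recall utterances describing it.  Multiple utterances of the same
condition covering a segment are averaged *before* correlating; a
segment retold both precisely and summarily receives one score per
condition.  Group inference per parcel: one-sample two-tailed t of
subject-mean r against zero per condition, a paired t for the
Precise−Summary contrast, and a one-tailed permutation p that shuffles,
within each subject, which recall pattern goes with which segment
(preserving each subject's pattern set while breaking correspondence).
BH-FDR runs across parcels at q = 0.05 for the condition maps and
q = 0.10 for the contrast map.  Subject means average raw r (a Fisher-z
switch exists for sensitivity analyses).

## Memory transformation

TRs are averaged within scenes — shared boundaries for the movie run,
per-subject retelling timestamps for the recall run (each utterance
assigned to the scene holding the majority of its described time).  For
subject i and scene k, with the *averaged recall pattern of the other
subjects who retold k* on the right-hand side:

- `MR(i,k)` = r(movie pattern of i, averaged others' recall)
- `RR(i,k)` = r(recall pattern of i, averaged others' recall)

Cells exist only where subject i retold scene k; scenes retold by fewer
than `min_recallers` (5) subjects are excluded.  Parcel MR/RR are cell
means.  A scene-label permutation test (labels of the averaged-others
patterns shuffled; one-tailed; 1000 iterations by default, literal
count/n p-values with an optional +1 smoothing) plus BH-FDR yields a
reliability mask of parcels where either MR or RR is reliable.  Within
the mask, the transformation score is `T = RR − MR`; `T > 0` means
recall patterns agree more with each other than with the original movie
patterns — an event-specific, subject-consistent change.  Per-scene
group transformation `T_k` averages (RR − MR) cell differences over
subjects with both cells defined.

The leave-one-out averaged-others construction is applied symmetrically
to MR and RR.  Permutations are drawn independently per parcel, with one
scene-label shuffle per iteration applied to every subject.

## Linking summarization to transformation

Within parcels showing positive transformation, each subject's
scene-level %Summary bias is Pearson-correlated with the group per-scene
`T_k` over scenes that subject recalled with a defined bias (at least
`min_scenes_per_subject` = 3; constant-bias subjects are dropped since
their correlation is undefined).  Subject correlations enter a
random-effects one-sample t-test (two-tailed) with BH-FDR across tested
parcels; negative-direction findings are reported with their sign.  A
control analysis repeats the subject-level correlation with scene
duration in place of `T_k`.

A structural caveat, verified by simulation: because every subject is
correlated against the *same* group `T_k` profile, a chance correlation
between `T_k` noise and the shared component of the bias profile is
inherited by all subjects, and the random-effects test is
anti-conservative when scene-mean bias variation dominates subject-level
variation.  The synthetic study's bias structure (below) keeps
subject-level variation dominant, under which the test's false-positive
rate respects the FDR level; with strongly shared bias profiles the
test should be interpreted with care.

## Text-similarity validation

Annotations and utterances are embedded and compared by cosine.  The
built-in embedder is a deterministic L2-normalised signed-hash
bag-of-content-words model (512 dimensions): identical text gives
identical vectors, disjoint vocabularies give near-orthogonal vectors,
no model download.  A production sentence encoder can be plugged in
behind the same three-field contract.  Matched similarity is the
composite (per-covered-segment averaged) cosine; the mismatched
baseline uses *all* non-covered segments (the least arbitrary choice;
a seeded subsample of fixed size is available for large corpora).
Group contrasts are paired t-tests of matched vs mismatched per recall
type and of matched(Precise) vs matched(Summary).

## Synthetic study generator

The generator emulates the study conditions end to end and exports
ground truth for parameter recovery.

**Timeline.**  Scene durations are drawn from a log-normal calibrated by
numerical moment-matching so that the `[11 s, 180 s]` truncation has
mean 57.7 s and SD 41.6 s.  Each scene is partitioned into contiguous
micro-segments (mean 3.95 s, gamma-weighted, each within
`[1 s, 9.5 s]`).  The segment cap sits just under the 10-s threshold so
that every single segment admits a Precise span, which makes the
automatic duration rule reproduce generated labels exactly.  A 50-scene
movie yields ~700 contiguous micro-segments.  Segment annotations draw
from disjoint per-scene vocabularies plus a small shared pool, so text
similarity is provably higher within than between scenes.

**Transcripts.**  Per subject and scene, a true summary-bias target
β is drawn: scene means from Beta(10.6, 12.2) (mean ≈ 0.46, SD ≈ 0.10)
with subject jitter of SD 0.30, clipped to [0, 1].  Most bias variation
is therefore idiosyncratic, matching the wide per-scene across-subject
spread seen in this kind of recall data (and required for calibrated
linking inference; see above).  Scenes too short to hold both span
types receive a mean-preserving Bernoulli(β) all-or-nothing target.
The scene's segments are tiled by utterance spans: Summary spans
accumulate segments until they exceed 10 s, Precise spans stay at or
under 10 s.  The span type is chosen with the probability that keeps the
expected summary word share equal to β (unbiased at every step), with a
last-chance rule when the scene tail is about to become too short for
any further Summary span.  Candidate spans are actually retold with
probability `p_describe` (0.55), reproducing ~200–250 utterances per
subject and a recall run roughly half the movie's length.  Word counts
are Poisson (mean 14; Summary inflated ×1.3), drawn from the covered
segments' vocabularies with an off-pool fraction (0.5 for Summary, 0.1
for Precise) that makes Summary text measurably diverge from its
sources.  Summary spans are followed with probability 0.3 by a brief
Precise re-description of one covered segment (~30% summary-precise
coverage overlap).  Other utterances are queued at scene tails with
probability 0.31 per content utterance (~24% of utterances).  Scenes
are skipped entirely with probability `1 − p_recall` (default recall
rate 0.9), leaving a noise-filled silent gap in the recall timeline.

**Neural model.**  For each parcel and scene k: a shared movie pattern
`m_k ~ N(0, I)` over features; subject i's movie TRs inside scene k are
`m_k + η_ik`, `η ~ N(0, σ_m²)`; recall TRs inside subject i's retelling
of scene k are `m_k + c_k·s_k + ε_ik`, with `s_k ~ N(0, I)` a shift
direction shared across subjects and `ε ~ N(0, σ_r²)`.  **Model 1** is
`c_k ≡ 0` (pattern change is noise / idiosyncratic); **Model 2** has
`c_k > 0` (an event-specific change shared across people).  In *linked*
parcels `c_k = a + b·β̄_k` with β̄_k the scene's group-mean bias
(defaults a = 0, b = 2); in unlinked parcels `c_k = a`.  Noise is drawn
once per subject × scene (and once per utterance for the optional
condition-specific utterance noise used in reinstatement experiments)
and held constant across the event's TRs: the analyses consume
event-averaged patterns, and TR-wise noise would simply be attenuated
by averaging in a way the closed forms below do not model.  TRs outside
retold-scene blocks (gaps, Other utterances, skipped scenes) are pure
TR-wise noise.  Defaults: σ_m = σ_r = 1, TR 1.5 s, 17 subjects.  The
`dtype` field allows float32 arrays for large runs; all correlations
accumulate in float64.

**Closed-form expectations** (large feature count, full recall), used as
independent oracles:

    MR  = 1 / sqrt((1 + σ_m²) (1 + c² + σ_r²/(n−1)))
    RR  = (1 + c²) / sqrt((1 + c² + σ_r²) (1 + c² + σ_r²/(n−1)))
    T   = RR − MR
    reinstatement r = 1 / sqrt((1 + σ_m²) (1 + c² + σ_r² + σ_u²))

With σ_m = σ_r = 1, c = 1, n = 17: MR ≈ 0.492, RR ≈ 0.804, T ≈ 0.31.
Under Model 1 with σ_m = σ_r, MR and RR have identical distributions, so
E[T] = 0 exactly; T > 0 in expectation iff c > 0.

**Determinism.**  All randomness flows through one seeded generator;
identical seeds reproduce everything bit-for-bit, and configurations
differing only in shift magnitudes consume the random stream
identically, so paired-seed comparisons across c are exact.

**Null modes.**  `null_recall=True` leaves the recall run as pure
TR-wise noise, which makes recall scene patterns exchangeable across
scenes (scene-label permutation calibration).  The utterance-shuffle
null additionally requires `single_segment_utterances=True`: utterances
spanning several segments would contribute the same pattern to all of
them, and shuffling would break that dependence rather than a true null.

A known residual: the realised %Summary bias keeps a weak positive
correlation with scene duration (group mean r ≈ 0.08) because very
short scenes admit only all-or-nothing Summary spans — an artifact of
the 10-s feasibility rule, not of the target biases, which are drawn
independently of duration.

## What the generator does not emulate

No hemodynamic convolution, head motion, physiological noise, spatial
autocorrelation between voxels or parcels, non-stationary recall order
(scenes are retold in movie order), semantic structure in the text
beyond vocabulary overlap, or inter-subject anatomical variability.
Passing tests therefore demonstrate that the *statistics* behave as
designed under the stated generative model — unbiasedness, calibration,
power, direction — not that the specific effect sizes would transfer to
real fMRI data.

## Numerical choices and edge cases

- Intervals are half-open `[onset, offset)` in seconds; a TR belongs to
  an interval if its onset does.  An interval covering no TR onset falls
  back to the single TR containing its midpoint (clamped to the run).
- Degenerate statistics are flagged, not raised: zero-variance t-tests
  report ±inf/0 with a `degenerate` flag so parcel-wide loops never
  abort; constant-input correlations return NaN and the caller drops
  the cell.
- Permutation p-values use the literal `count(null ≥ obs)/n_perm`
  (exact zeros possible); `(1+count)/(1+n_perm)` smoothing is available
  by configuration for FDR stability.
- BH-FDR is the standard step-up via statsmodels; NaN p-values are
  passed through unrejected.
- TSV round-trips write ≥12 significant digits; missing numeric values
  are empty fields.

## Problem sizes in the validation suite

The statistical tests run on synthetic studies at the default study
conditions (17 subjects, 50 scenes, TR 1.5 s) with parcel/feature counts
chosen per question: 2000 features for closed-form MR/RR recovery (50
replicates), 1000 for the Model-1 zero check (exact by symmetry at any
feature count), 12 parcels × 200 features for linking recovery (50
replicates), 100 features for reinstatement power (100 replicates), and
60 features for permutation calibration (50 replicates, 200
permutations).  `scripts/acceptance.py` re-runs the same chain at
smaller replicate counts and writes its numbers to JSON.
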