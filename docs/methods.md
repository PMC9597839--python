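# Methods

## Problem and pipeline

`equigait` quantifies unilateral fore- and hindlimb lameness of a horse
trotting on left (CL) and right (CR) lunging circles, from markerless
pose-estimation keypoint trajectories (per-frame `x, y, likelihood`
triplets at the image export resolution). The camera stands at the circle's
center, so each trial sees only the inner side of the horse: CL trials use
left-side landmarks, CR trials right-side ones, and left/right comparisons
are always *between circles*, never within a frame.

The pipeline is:

1. **Likelihood filter.** Frames whose detection confidence is strictly
   below 0.60 are marked missing (NaN), keeping frame indices aligned
   across bodyparts. The cut reflects the reliability point of the
   underlying tracker; it is configurable.
2. **Trimmed excursion statistics.** For a coordinate series, values are
   sorted and the value at 0-based sorted index *i* of *n* is assigned the
   rank-percentile `100·(i+0.5)/n`; a band `[lo, hi)` collects the values
   whose percentile falls inside it. The top and bottom 5% are treated as
   potential tracking errors: `Max̄` = mean of the 90–95 band, `Min̄` =
   mean of the 5–10 band, and the **span** `|Max̄ − Min̄|` is the robust
   excursion amplitude. The half-open membership rule and the `(i+0.5)/n`
   plotting position are package conventions, chosen to be unambiguous and
   checkable against a brute-force sort-and-slice oracle (no standard
   percentile estimator is implied by the span definition itself).
3. **Hindlimb scores.** Per circle, `DSSt` is the horizontal span of the
   circle-facing stifle and `DTTcox` the vertical span of the facing tuber
   coxae. The per-horse scores are `DSt = |DSSt(CL) − DSSt(CR)|` and
   `DTcox = |DTTcox(CL) − DTTcox(CR)|`. A shortened stride on the lame
   hindlimb shrinks the stifle span on that side, so the stifle statistic
   points at the **smaller**-span side; hip hike enlarges the tuber coxae
   span on the lame side, so that statistic points at the **larger**-span
   side. Scores and group means are reported rounded half-up to two
   decimals (with six guard digits so accumulated float noise cannot flip
   a printed tie).
4. **Forelimb head nod.** Stance onsets are the local maxima of the facing
   carpus' protraction coordinate (maximal protraction ≈ start of stance);
   the contralateral forelimb is assumed half a stride period out of
   phase, since it is not tracked from this viewpoint. The **nod index**
   is the mean poll height (negated image-y) over left-forelimb stance
   windows minus the mean over right-forelimb windows; a forelimb-lame
   horse carries its head higher during the lame limb's stance, so the
   sign encodes the side.
5. **Diagnostics.** Predictions are cross-tabulated against the clinical
   reference; SE/SP/ACC/PPV/NPV on 2×2 tables (percent, half-up to one
   decimal), Cohen's κ and overall accuracy on the 3×3 table over
   {forelimb lame, hindlimb lame (stifle-based), sound}. Undefined metrics
   (zero denominator) are flagged `None`, never raised.

## Decision thresholds

- **Stifle, `DSt > 1.2 px` → hindlimb-lame.** No threshold is published;
  1.2 px sits in the gap between the sound reference group's ordinary
  score range (≤ 0.87, one outlier at 1.24) and the smallest score flagged
  lame (1.23). One reference-cohort horse (moderately lame, DSt = 1.67,
  reported not-lame) contradicts any single-threshold rule; the package
  reproduces 16 of the 17 published verdicts and treats that row as a
  documented exception rather than fitting it.
- **Tuber coxae.** The evaluation deliberately mirrors the asymmetric
  per-group rule of the reference analysis: a clinically lame horse counts
  correct iff the larger-span side matches the clinical side; a control
  counts correct iff `DTcox ≤ 1.0 px` (the gap between 0.69 and 1.14 in the
  control scores). A conventional unified classifier (sound iff below
  threshold, else side call) is provided separately as an extension.
- **Head nod, `|nod| > 0.35 px` → forelimb-lame** per circle; a horse is
  lame if either circle triggers, the side given by agreement or, on
  disagreement, by the circle with the larger |nod|. The original analysis
  was visual and states no numeric criterion, so this threshold is a
  calibration choice: five standard deviations of the nod index over a
  20-horse simulated sound cohort (seed 20220, default gait and noise),
  recomputable with `calibrate_nod_threshold()` or `equigait calibrate`.
  Five sigma rather than a conventional two: verdicts aggregate two
  circles per horse, so a 2σ cut already mislabels ~9% of sound horses,
  while the smallest simulated lame effect lies ≈50σ above the sound
  noise floor — the wide margin buys specificity at no sensitivity cost.
  Against real data the margin would need recalibration on a real sound
  cohort.

## Numerical choices

- **Stance windows by fractional phase.** Stride period is estimated from
  the first and last detected onset, `(last − first)/(n−1)`, averaging away
  the ±1-frame quantisation of individual peaks (a median of integer gaps
  stays quantised to whole frames). Stance-window poll means are computed
  at 12 midpoint samples of the half-period window with linear
  interpolation across missing frames. This matters: at 74 strides/min and
  30 fps the stride period is 24.32 frames, and integer-frame windows leave
  a systematic ≈0.1 px residual of the sound double-bounce in the nod
  index — comparable to the noise floor — whereas phase-accurate windows
  cancel it exactly (a sinusoid integrates to zero over its full period
  regardless of phase).
- **Peak picking.** Onsets require both a minimum separation of half the
  expected stride period and a prominence of at least 25% of the trimmed
  (5–95 percentile) signal range. Separation alone admits spurious noise
  peaks midway between true protraction maxima, which silently corrupts
  the stride count and period.
- **Ties and boundaries.** The likelihood filter drops frames strictly
  below threshold; classification thresholds are strict (`score >
  threshold` → lame, a score exactly at threshold is sound). Equal spans
  give score 0 and side `none`.
- **Degenerate inputs.** Fewer than 20 usable frames (each 5% band must be
  non-empty), an empty percentile band, or fewer than 2 (stance) / 5
  (head-nod) strides raise typed errors naming the offending bodypart and
  trial; the cohort runner logs and excludes such horses with reasons.
- **Detrending** (moving median, off by default) is available for footage
  where the camera pans instead of rotating in place.

## Synthetic gait generator

No trajectory data are deposited with the reference study, so the
generator stands in for its videos. It emulates a centre-camera lunge
trial at the study's conditions: 30 fps, 60 s per circle, 74 strides/min
(Warmblood default; 84 for ponies), 768×432 px export resolution, subject
held near frame centre. The trot is an ideal two-beat diagonal gait at
stride frequency `f`: distal limb markers oscillate horizontally at `f`
(diagonal pairs in phase, contralateral limbs offset half a period), the
poll bobs vertically at `2f`, the tuber coxae at `2f`.

Amplitudes are chosen so the downstream statistics land in the ranges the
reference cohort reports: stifle half-amplitude 21 px (spans ≈ 41 px,
published range 30–55), tuber coxae 7 px (spans ≈ 14 px, published range
8–21), poll 15 px, distal limb protraction 40 px. A dense sinusoid's
trimmed span is `2A·0.9714` (the mean of the sine quantile over the 5%
band), which fixes the amplitude↔span conversion.

Lameness enters as three asymmetries with a single severity fraction
δ ∈ [0, 1): forelimb lameness adds a poll component at `f` with amplitude
`4·δ·head_amp`, phased to peak mid-stance of the lame forelimb; hindlimb
lameness scales the lame-side stifle amplitude by `(1−δ)` and the
lame-side tuber coxae amplitude by `(1+δ)`. The default clinical mapping
is δ = 0.05 for subtle (AAEP grade 1–2) and δ = 0.15 for moderate (3–4)
lameness — a modelling choice, since no published amplitude-per-grade
relation exists. The head-nod gain of 4 makes moderate grades visually
obvious in plotted traces.

Noise: shared per-frame body-position jitter plus independent per-keypoint
jitter (both Gaussian, σ = 1 px default), and confidence dropouts with
probability 0.05 per frame — dropped frames draw likelihood
Uniform(0, 0.6), kept frames Uniform(0.8, 1.0), so only the 0.60 cut is
meaningful. Everything is deterministic given a seed; cohorts derive
per-horse, per-circle seeds from one master seed.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: soft-tissue and coat-dependent tracking error
(non-Gaussian, autocorrelated, landmark-specific), circle-position drift
and perspective change over the lap, stride-to-stride timing variability,
compensatory multi-limb kinematics, and any systematic difference between
CL and CR locomotion in a sound horse. The synthetic study's perfect
recovery (SE = SP = 100% at δ ≥ 0.05) therefore validates the *pipeline
arithmetic and its thresholds under the stated noise model*, not clinical
performance; the published cohort's own verdict columns are reproduced
separately from the printed span values.

## Study re-enactment sizes

The synthetic acceptance study mirrors the reference design: 13
forelimb-lame (7 left / 6 right), 9 hindlimb-lame (5 left / 4 right), and
8 sound horses, with the subtle/moderate δ split following the published
grade distribution; each horse contributes one 60 s CL and one 60 s CR
trial (1800 frames each). A full 30-horse run takes well under a second
per cohort on one core.

## Known limitations

- The tuber coxae statistic is implemented faithfully and evaluated
  faithfully — and, as in the reference analysis, it performs poorly
  (SE 33.3% on the published verdicts): single-side viewing cannot capture
  the left–right hip asymmetry the sign is based on. It is retained for
  completeness, not recommended for classification.
- The contralateral forelimb's stance is inferred, not observed; systematic
  asymmetry in a real horse's protraction timing would bias the nod index.
- Scores are in pixels at export resolution and are not normalised for
  horse size or camera distance; comparisons across recordings assume a
  consistent setup.
- Only unilateral, single-limb lameness is modelled; multi-limb cases were
  excluded from the reference cohort and are out of scope.
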