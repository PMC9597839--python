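# equigait

Pose-estimation gait analysis for equine lameness detection on the lunge.

Lameness is among the most common problems in equine practice, yet its
detection is usually subjective, and even experienced clinicians disagree
on subtle cases. Markerless pose estimation makes kinematic gait analysis
possible from a plain phone video: a tracker emits per-frame keypoint
trajectories (`x, y, likelihood` per bodypart), and the asymmetries that
clinicians look for — the head nod of a forelimb-lame trot, the shortened
stride and hip hike of a hindlimb-lame one — become measurable numbers.

`equigait` is the analysis layer for such data, aimed at researchers in
veterinary biomechanics. From keypoint trajectory tables of a horse
trotting on left (CL) and right (CR) lunging circles it computes:

- **Trimmed excursion spans.** With values at sorted rank-percentiles
  `100·(i+0.5)/n`, the top and bottom 5% are discarded as tracking error;
  `Max̄` (mean of the 90–95 band) and `Min̄` (mean of the 5–10 band) give
  the span `|Max̄ − Min̄|` of a landmark's motion. Frames with detection
  confidence below 0.60 are excluded first.
- **Hindlimb scores.** Per circle, `DSSt` = horizontal stifle span and
  `DTTcox` = vertical tuber coxae span of the camera-facing side; per
  horse, `DSt = |DSSt(CL) − DSSt(CR)|` and `DTcox = |DTTcox(CL) −
  DTTcox(CR)|`. `DSt` above threshold flags hindlimb lameness on the
  smaller-span side (shortened stride); `DTcox` points at the larger-span
  side (hip hike).
- **Forelimb head nod.** Stance onsets from protraction maxima of the
  facing carpus; the nod index is the mean poll height during left-fore
  stance minus that during right-fore stance — positive when the head
  rides higher on the left stance, i.e. left forelimb lame.
- **Diagnostic evaluation.** SE / SP / ACC / PPV / NPV against clinical
  ground truth, Cohen's κ and overall accuracy on the three-way
  {forelimb-lame, hindlimb-lame, sound} classification.

Because no trajectory data are deposited with the reference study, the
package ships a synthetic trot generator (`equigait.synthetic_gait`) that
emulates the study's recording conditions — 30 fps, 60 s per circle,
74 strides/min, tunable lameness severity and pose-estimation noise — so
the entire pipeline is testable end to end. See `docs/methods.md` for the
model, conventions and limitations.

## Worked example

Simulate a moderately left-hindlimb-lame horse (asymmetry fraction 0.15)
on both circles and score it:

```sh
equigait simulate --group hindlimb --side L --grade-effect 0.15 --circle CL --seed 4 --out sim/
equigait simulate --group hindlimb --side L --grade-effect 0.15 --circle CR --seed 5 --out sim/
equigait analyze hindlimb --cl sim/sim4_CL.csv --cr sim/sim5_CR.csv --statistic stifle
```

```json
{
  "score": 6.15,
  "side": "left",
  "span_cl": 34.51327979999991,
  "span_cr": 40.66565819999997,
  "statistic": "stifle",
  "status": "hindlimb_lame"
}
```

The left circle (which sees the lame left side) shows a stifle span of
34.5 px against 40.7 px on the right circle — the shortened stride of the
lame limb. The difference `DSt = 6.15 px` is far above the 1.2 px decision
threshold, so the horse is classified hindlimb-lame on the left.

The same works from Python, including a whole-cohort run mirroring the
reference study design (13 forelimb-lame / 9 hindlimb-lame / 8 sound):

```python
from equigait import simulate_cohort, study_cohort_specs, run_study, format_report_text

cohort = simulate_cohort(study_cohort_specs(), seed=3)
print(format_report_text(run_study(cohort)))
```

```
Cohort of 30 horses

Test                    TP  FP  FN  TN    SE%    SP%   ACC%   PPV%   NPV%
forelimb                13   0   0   8  100.0  100.0  100.0  100.0  100.0
stifle                   9   0   0   8  100.0  100.0  100.0  100.0  100.0
tuber_coxae              9   0   0   8  100.0  100.0  100.0  100.0  100.0

3x3 agreement: kappa = 1.0, overall accuracy = 100.0%
```

Under the generator's idealised kinematics every lame horse is recovered
with its correct side; on real footage, tracking artefacts and biological
variability reduce this (see `docs/methods.md`).

## Data formats

- Trajectories: three-header-row CSV (`scorer` / `bodyparts` / `coords`,
  one `x, y, likelihood` triplet per bodypart, one row per frame, leading
  frame-index column), the dialect emitted by common pose-estimation
  tools.
- Trial metadata: YAML sidecar (`horse_id`, `circle`, `gait`, `fps`,
  `resolution`, clinical annotations).
- Bodypart map: YAML list binding landmark indices of the 58-point scheme
  to names; the 13 analysis-critical landmarks are required, the rest
  optional.
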