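"""Published per-horse measurements of the reference lunging cohort.

Span values (pixels at export resolution) of the stifle and tuber coxae
excursion analyses for the reference clinical cohort — nine hindlimb-lame
horses and eight sound controls — together with the clinical annotations
and the verdicts reported for each horse, plus the published forelimb
classification counts (13 forelimb-lame, 8 sound, all correctly called).

These numbers serve as regression fixtures: the package's score
arithmetic, group means and diagnostic metrics are checked against the
values the original analysis reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional


@dataclass(frozen=True)
class StifleRow:
    horse: int
    clinical_side: Optional[str]  # None for controls
    grade_band: Optional[str]  # "1-2" or "3-4" for lame horses
    span_cl: float
    span_cr: float
    reported_score: float
    reported_verdict_correct: bool  # "Yes"/"No" column of the source table


@dataclass(frozen=True)
class TcoxRow:
    horse: int
    clinical_side: Optional[str]
    grade_band: Optional[str]
    span_cl: float
    span_cr: float
    reported_score: float
    reported_verdict_correct: bool


#: Stifle analysis, hindlimb-lame horses (DSSt(CL), DSSt(CR), DSt).
STIFLE_LAME: tuple[StifleRow, ...] = (
    StifleRow(1, "left", "3-4", 42.50, 44.17, 1.67, False),
    StifleRow(2, "right", "3-4", 42.17, 34.32, 7.85, True),
    StifleRow(3, "right", "1-2", 31.16, 29.69, 1.47, True),
    StifleRow(4, "left", "3-4", 47.68, 54.61, 6.93, True),
    StifleRow(5, "right", "1-2", 43.32, 42.09, 1.23, True),
    StifleRow(6, "left", "1-2", 36.20, 38.21, 2.01, True),
    StifleRow(7, "left", "3-4", 48.03, 51.12, 3.09, True),
    StifleRow(8, "left", "1-2", 47.36, 49.60, 2.24, True),
    StifleRow(9, "right", "3-4", 49.90, 38.55, 11.35, True),
)

#: Stifle analysis, sound controls ("Yes" = correctly classified sound).
STIFLE_SOUND: tuple[StifleRow, ...] = (
    StifleRow(1, None, None, 38.27, 37.76, 0.51, True),
    StifleRow(2, None, None, 35.82, 34.95, 0.87, True),
    StifleRow(3, None, None, 40.44, 39.75, 0.69, True),
    StifleRow(4, None, None, 46.58, 46.51, 0.07, True),
    StifleRow(5, None, None, 46.09, 45.93, 0.16, True),
    StifleRow(6, None, None, 42.35, 41.53, 0.82, True),
    StifleRow(7, None, None, 37.43, 36.19, 1.24, False),
    StifleRow(8, None, None, 40.18, 40.18, 0.00, True),
)

#: Hindlimb-lame horse whose reported stifle verdict ("No") is not
#: reproducible under any single score threshold given the other rows.
STIFLE_KNOWN_EXCEPTION = 1

#: Tuber coxae analysis, hindlimb-lame horses (DTTcox(CL), DTTcox(CR), DTcox).
TCOX_LAME: tuple[TcoxRow, ...] = (
    TcoxRow(1, "left", "3-4", 11.29, 19.21, 7.92, False),
    TcoxRow(2, "right", "3-4", 13.18, 12.17, 1.01, False),
    TcoxRow(3, "right", "1-2", 11.81, 14.62, 2.81, True),
    TcoxRow(4, "left", "3-4", 15.68, 20.89, 5.21, False),
    TcoxRow(5, "right", "1-2", 9.22, 9.95, 0.73, True),
    TcoxRow(6, "left", "1-2", 11.53, 12.13, 0.60, False),
    TcoxRow(7, "left", "3-4", 13.69, 15.02, 1.33, False),
    TcoxRow(8, "left", "1-2", 7.98, 10.36, 2.38, False),
    TcoxRow(9, "right", "3-4", 11.18, 11.27, 0.09, True),
)

#: Tuber coxae analysis, sound controls.
TCOX_SOUND: tuple[TcoxRow, ...] = (
    TcoxRow(1, None, None, 11.13, 11.82, 0.69, True),
    TcoxRow(2, None, None, 12.06, 11.55, 0.51, True),
    TcoxRow(3, None, None, 14.28, 19.06, 4.78, False),
    TcoxRow(4, None, None, 13.99, 14.49, 0.50, True),
    TcoxRow(5, None, None, 11.38, 11.81, 0.43, True),
    TcoxRow(6, None, None, 9.96, 10.64, 0.68, True),
    TcoxRow(7, None, None, 8.45, 9.59, 1.14, False),
    TcoxRow(8, None, None, 8.15, 9.79, 1.64, False),
)

#: Reported forelimb test counts: every forelimb-lame horse and every
#: control was correctly classified from the head-nod charts.
FORELIMB_COUNTS = {"tp": 13, "fp": 0, "fn": 0, "tn": 8}

#: Reported 2x2 counts and diagnostic characteristics per test.
REPORTED_METRICS = {
    "forelimb": {"SE": 100.0, "SP": 100.0, "ACC": 100.0, "PPV": 100.0, "NPV": 100.0},
    "stifle": {"SE": 88.9, "SP": 87.5, "ACC": 88.2, "PPV": 88.9, "NPV": 87.5},
    "tuber_coxae": {"SE": 33.3, "SP": 62.5, "ACC": 47.1, "PPV": 50.0, "NPV": 45.4},
}

#: Reported group means of the circle-difference scores.
REPORTED_GROUP_MEANS = {
    "dst_sound": 0.55,
    "dtcox_non_lame": 1.30,
    "dtcox_detected_lame": 1.21,
    "dtcox_non_detected_lame": 3.08,
}
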