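"""Hindlimb lameness scores from stifle and tuber coxae excursions.

Two kinematic signs of hindlimb lameness are quantified per horse by
comparing the left-circle (CL) and right-circle (CR) trials:

* **Stifle** — a lame hindlimb takes a shorter stride, so the horizontal
  excursion span of the stifle marker shrinks on the lame side.  With
  ``DSSt(circle) = |Max̄St - Min̄St|`` per circle, the score is
  ``DSt = |DSSt(CL) - DSSt(CR)|`` and the suspected side is the side with
  the *smaller* span (CL exposes the left side, CR the right).
* **Tuber coxae** — the point of the hip shows increased vertical
  displacement ("hip hike") on the lame side, so with
  ``DTTcox(circle) = |Max̄Tcox - Min̄Tcox|`` the score is
  ``DTcox = |DTTcox(CL) - DTTcox(CR)|`` and the suspected side is the side
  with the *larger* span.

Scores and group means are reported rounded half-up to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from ._rounding import round_half_up
from .errors import ValidationError
from .io_trajectories import TrialRecording
from .preprocess import LIKELIHOOD_THRESHOLD, excursion_stats, filter_by_likelihood

#: Decision threshold (px) on DSt separating sound from hindlimb-lame:
#: placed in the gap between the sound group's ordinary score range and
#: the smallest score flagged as lame in the reference cohort.
DEFAULT_STIFLE_THRESHOLD = 1.2

#: Threshold (px) on DTcox below which a control horse is called sound.
DEFAULT_TCOX_SOUND_THRESHOLD = 1.0

STATISTICS = ("stifle", "tuber_coxae")


@dataclass(frozen=True)
class LamenessScore:
    """Per-horse circle-difference score for one statistic."""

    statistic: str
    span_cl: float
    span_cr: float
    score: float
    predicted_side: str
    predicted_status: Optional[str] = None

    @property
    def score_2dp(self) -> float:
        """Score rounded half-up to two decimals, as reported."""
        return round_half_up(self.score, 2)


@dataclass(frozen=True)
class TcoxAssessment:
    """Paper-style per-group evaluation of a tuber coxae score.

    For clinically lame horses the test is counted positive (and correct)
    iff the larger-span side matches the clinical side; for controls the
    test is positive iff the score exceeds the sound threshold, and
    correct iff it does not.
    """

    score: LamenessScore
    group: str  # "lame" or "control"
    predicted_positive: bool
    correct: bool


@dataclass(frozen=True)
class GroupSummary:
    """Scores of one group of horses and their mean."""

    label: str
    values: tuple[float, ...]

    @property
    def mean(self) -> float:
        return group_mean(self.values)

    @property
    def mean_2dp(self) -> float:
        return round_half_up(self.mean, 2)


def circle_span(
    trial: TrialRecording,
    statistic: str,
    likelihood_threshold: float = LIKELIHOOD_THRESHOLD,
    detrend_window: Optional[int] = None,
) -> float:
    """Trimmed excursion span (px) of the circle-facing landmark.

    Stifle spans are horizontal (axis x), tuber coxae spans vertical
    (axis y); the landmark side follows the circle (CL -> left, CR ->
    right) because the center camera only sees the inner side.
    """
    if statistic not in STATISTICS:
        raise ValidationError(f"unknown statistic {statistic!r}")
    facing = "left" if trial.circle == "CL" else "right"
    role = ("stifle_" if statistic == "stifle" else "tuber_coxae_") + facing
    axis = "x" if statistic == "stifle" else "y"
    series = filter_by_likelihood(trial.get(role), likelihood_threshold)
    stats = excursion_stats(
        series,
        axis,
        detrend_window=detrend_window,
        label=f"{role} of {trial.horse_id}/{trial.circle}",
    )
    return stats.span


def compute_score(span_cl: float, span_cr: float, statistic: str) -> LamenessScore:
    """Circle-difference score and suspected side from the two spans.

    The suspected side is the side of the smaller span for the stifle
    statistic (shortened stride) and of the larger span for the tuber
    coxae statistic (hip hike); equal spans give side ``"none"``.
    """
    if statistic not in STATISTICS:
        raise ValidationError(f"unknown statistic {statistic!r}")
    if span_cl < 0 or span_cr < 0:
        raise ValidationError("spans must be >= 0")
    score = abs(span_cl - span_cr)
    if span_cl == span_cr:
        side = "none"
    elif statistic == "stifle":
        side = "left" if span_cl < span_cr else "right"
    else:
        side = "left" if span_cl > span_cr else "right"
    return LamenessScore(
        statistic=statistic,
        span_cl=span_cl,
        span_cr=span_cr,
        score=score,
        predicted_side=side,
    )


def score_from_trials(
    cl: TrialRecording, cr: TrialRecording, statistic: str, **span_kwargs
) -> LamenessScore:
    """Compute a lameness score directly from a horse's CL+CR trials."""
    if cl.circle != "CL" or cr.circle != "CR":
        raise ValidationError("score_from_trials needs one CL and one CR trial")
    return compute_score(
        circle_span(cl, statistic, **span_kwargs),
        circle_span(cr, statistic, **span_kwargs),
        statistic,
    )


def classify_stifle(
    score: LamenessScore, threshold: float = DEFAULT_STIFLE_THRESHOLD
) -> LamenessScore:
    """Hindlimb-lame iff the stifle score strictly exceeds the threshold.

    Returns a copy of the score with ``predicted_status`` filled in; a
    horse at or below the threshold is called sound and its suspected
    side is cleared.
    """
    if score.statistic != "stifle":
        raise ValidationError("classify_stifle needs a stifle score")
    if score.score > threshold:
        return replace(score, predicted_status="hindlimb_lame")
    return replace(score, predicted_status="sound", predicted_side="none")


def classify_tuber_coxae(
    score: LamenessScore,
    clinical_side: Optional[str] = None,
    sound_threshold: float = DEFAULT_TCOX_SOUND_THRESHOLD,
) -> TcoxAssessment:
    """Per-group evaluation of a tuber coxae score.

    A clinically lame horse (``clinical_side`` given) is counted a true
    positive iff the larger-span side matches the clinical side; a
    control (``clinical_side`` None) is counted sound iff its score does
    not exceed ``sound_threshold``.
    """
    if score.statistic != "tuber_coxae":
        raise ValidationError("classify_tuber_coxae needs a tuber_coxae score")
    if clinical_side is not None:
        if clinical_side not in ("left", "right"):
            raise ValidationError(f"clinical_side must be left/right, got {clinical_side!r}")
        match = score.predicted_side == clinical_side
        return TcoxAssessment(score, "lame", predicted_positive=match, correct=match)
    flagged = score.score > sound_threshold
    return TcoxAssessment(score, "control", predicted_positive=flagged, correct=not flagged)


def classify_tuber_coxae_unified(
    score: LamenessScore, threshold: float = DEFAULT_TCOX_SOUND_THRESHOLD
) -> LamenessScore:
    """Unified tuber coxae classifier (extension, not the default rule).

    Sound iff the score is at or below the threshold, otherwise lame on
    the larger-span side.
    """
    if score.statistic != "tuber_coxae":
        raise ValidationError("needs a tuber_coxae score")
    if score.score > threshold:
        return replace(score, predicted_status="hindlimb_lame")
    return replace(score, predicted_status="sound", predicted_side="none")


def group_mean(scores: Sequence[float]) -> float:
    """Arithmetic mean of a non-empty list of scores (unrounded)."""
    if len(scores) == 0:
        raise ValidationError("group mean of an empty list")
    return float(np.mean(scores))
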