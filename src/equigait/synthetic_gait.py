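"""Synthetic trot keypoint trajectories for pipeline testing.

Emulates what a center-of-circle camera records of a horse trotting on the
lunge: a roughly frame-centred subject whose limb keypoints oscillate
horizontally with protraction/retraction at stride frequency, a poll that
bobs vertically twice per stride in a sound horse, and pose-estimation
artefacts (per-frame coordinate jitter and low-confidence dropout frames).

Lameness is injected as the three kinematic asymmetries the analysis is
built to detect:

* **forelimb lameness** — an extra once-per-stride component in poll height,
  phased so the head is highest while the lame forelimb is in stance
  (the classic "head nod");
* **hindlimb lameness, stride length** — the lame-side stifle's horizontal
  excursion amplitude is reduced by the factor ``(1 - delta)``;
* **hindlimb lameness, hip hike** — the lame-side tuber coxae's vertical
  excursion amplitude is increased by the factor ``(1 + delta)``.

The trot is modelled as an ideal two-beat diagonal gait: diagonal limb
pairs move in phase, contralateral limbs half a period apart.  The camera
follows the horse, so there is no net drift.  Given the same seed the
generator is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError
from .io_trajectories import (
    ANALYSIS_ROLES,
    KeypointSeries,
    TrialRecording,
    default_bodypart_map,
)

#: Ratio of the lameness head-nod amplitude to ``head_amp`` per unit of
#: asymmetry fraction.  Chosen so moderate grades give a visually obvious
#: nod relative to the baseline double-bounce.
HEAD_NOD_GAIN = 4.0

# limb protraction phases of an ideal trot (radians); diagonal pairs
# (left fore + right hind, right fore + left hind) move together
_LIMB_PHASE = {
    "left_fore": 0.0,
    "right_fore": np.pi,
    "left_hind": np.pi,
    "right_hind": 0.0,
}

# resting image positions (px) of each landmark for a left-facing,
# frame-centred horse at the 768x432 export resolution
_BASE_POS = {
    "poll": (540.0, 90.0),
    "elbow_left": (470.0, 250.0),
    "elbow_right": (470.0, 250.0),
    "os_carpi_accessorium_left": (475.0, 300.0),
    "os_carpi_accessorium_right": (475.0, 300.0),
    "carpus_left": (480.0, 295.0),
    "carpus_right": (480.0, 295.0),
    "tuber_coxae_left": (230.0, 150.0),
    "tuber_coxae_right": (230.0, 150.0),
    "stifle_left": (260.0, 240.0),
    "stifle_right": (260.0, 240.0),
    "tarsus_left": (250.0, 300.0),
    "tarsus_right": (250.0, 300.0),
}


@dataclass(frozen=True)
class GaitParams:
    """Kinematic parameters of the simulated trot.

    Defaults emulate a Warmblood lunged for one minute per circle at
    30 fps: 74 strides/min, stifle spans in the 30-55 px range and tuber
    coxae spans in the 8-21 px range at the 768x432 export resolution.
    """

    stride_rate: float = 74.0
    fps: float = 30.0
    duration: float = 60.0
    limb_protraction_amp: float = 40.0
    stifle_amp: float = 21.0
    tcox_amp: float = 7.0
    head_amp: float = 15.0

    def __post_init__(self) -> None:
        for name in ("limb_protraction_amp", "stifle_amp", "tcox_amp", "head_amp"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.fps * self.duration < 2 * 60.0 * self.fps / self.stride_rate:
            raise ValidationError("recording must cover at least two strides")

    @property
    def stride_freq(self) -> float:
        """Stride frequency in Hz."""
        return self.stride_rate / 60.0

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.duration))


@dataclass(frozen=True)
class LamenessSpec:
    """Ground-truth lameness of a simulated horse.

    ``grade_effect`` is the unitless asymmetry fraction delta; 0 is sound.
    The default mapping from clinical grades is 0.05 for subtle (AAEP 1-2)
    and 0.15 for moderate (AAEP 3-4) lameness.
    """

    status: str = "sound"
    side: Optional[str] = None
    grade_effect: float = 0.0

    def __post_init__(self) -> None:
        if self.status not in ("sound", "forelimb_lame", "hindlimb_lame"):
            raise ValidationError(f"unknown status {self.status!r}")
        if self.status == "sound":
            if self.side is not None or self.grade_effect != 0.0:
                raise ValidationError("a sound horse has no side or asymmetry")
        else:
            if self.side not in ("left", "right"):
                raise ValidationError("lame status requires side 'left' or 'right'")
        if not 0 <= self.grade_effect < 1:
            raise ValidationError("grade_effect must be in [0, 1)")


def grade_effect_for_aaep(grade: int) -> float:
    """Default asymmetry fraction for an AAEP 1-5 lameness grade."""
    if not 1 <= grade <= 5:
        raise ValidationError(f"AAEP grade must be 1-5, got {grade}")
    return 0.05 if grade <= 2 else 0.15


@dataclass(frozen=True)
class NoiseSpec:
    """Pose-estimation noise model.

    ``coord_sd`` is the per-frame Gaussian jitter in pixels (applied once
    as shared body-position jitter and once independently per keypoint);
    ``dropout_p`` is the probability that a frame's detection confidence
    falls below the 0.60 exclusion threshold.  Confidences are drawn
    Uniform(0, 0.6) on dropout frames and Uniform(0.8, 1.0) otherwise.
    """

    coord_sd: float = 1.0
    dropout_p: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coord_sd < 0:
            raise ValidationError("coord_sd must be >= 0")
        if not 0 <= self.dropout_p < 1:
            raise ValidationError("dropout_p must be in [0, 1)")


#: Noise switched off entirely: exact kinematics, full confidence.
NOISELESS = NoiseSpec(coord_sd=0.0, dropout_p=0.0, seed=0)


def _limb_of_role(role: str) -> Optional[str]:
    if "elbow" in role or "carpus" in role or "carpi" in role:
        return "left_fore" if role.endswith("left") else "right_fore"
    if "tarsus" in role or "stifle" in role:
        return "left_hind" if role.endswith("left") else "right_hind"
    return None


def simulate_trial(
    gait: GaitParams = GaitParams(),
    lameness: LamenessSpec = LamenessSpec(),
    circle: str = "CL",
    noise: NoiseSpec = NoiseSpec(),
    horse_id: str = "synthetic",
) -> TrialRecording:
    """Generate one trot trial (one horse, one circle direction).

    All analysis-critical landmarks are generated; the circle direction is
    recorded in the metadata and determines which body side the downstream
    analysis reads, but does not alter the kinematics — so a sound horse
    produces bit-identical trajectories on CL and CR for the same seed.
    """
    f = gait.stride_freq
    n = gait.n_frames
    t = np.arange(n) / gait.fps
    omega = 2 * np.pi * f

    rng = np.random.default_rng(noise.seed)
    body_jx = rng.normal(0.0, noise.coord_sd, n) if noise.coord_sd else np.zeros(n)
    body_jy = rng.normal(0.0, noise.coord_sd, n) if noise.coord_sd else np.zeros(n)

    fore_lame = lameness.status == "forelimb_lame"
    hind_lame = lameness.status == "hindlimb_lame"
    delta = lameness.grade_effect

    series: dict[int, KeypointSeries] = {}
    for role, idx in ANALYSIS_ROLES.items():
        x0, y0 = _BASE_POS[role]
        limb = _limb_of_role(role)

        if role == "poll":
            # sound double-bounce at 2f; lameness adds a once-per-stride
            # component peaking mid-stance of the lame forelimb
            height = gait.head_amp * np.sin(2 * omega * t)
            if fore_lame:
                phase = _LIMB_PHASE[f"{lameness.side}_fore"]
                height += (
                    -delta * HEAD_NOD_GAIN * gait.head_amp * np.cos(omega * t + phase)
                )
            x = x0 + 0.15 * gait.limb_protraction_amp * np.sin(omega * t)
            y = y0 - height
        elif "tuber_coxae" in role:
            amp = gait.tcox_amp
            if hind_lame and role.endswith(lameness.side):
                amp *= 1.0 + delta
            x = x0 + 0.1 * gait.limb_protraction_amp * np.sin(omega * t)
            y = y0 + amp * np.sin(2 * omega * t)
        elif "stifle" in role:
            amp = gait.stifle_amp
            if hind_lame and role.endswith(lameness.side):
                amp *= 1.0 - delta
            x = x0 + amp * np.sin(omega * t + _LIMB_PHASE[limb])
            y = y0 + 0.1 * gait.tcox_amp * np.sin(2 * omega * t)
        else:  # distal limb markers: protraction/retraction at stride rate
            amp = gait.limb_protraction_amp
            if "elbow" in role:
                amp *= 0.4
            x = x0 + amp * np.sin(omega * t + _LIMB_PHASE[limb])
            y = y0 + 0.1 * amp * np.sin(2 * (omega * t + _LIMB_PHASE[limb]))

        x = x + body_jx
        y = y + body_jy
        if noise.coord_sd:
            x = x + rng.normal(0.0, noise.coord_sd, n)
            y = y + rng.normal(0.0, noise.coord_sd, n)

        if noise.dropout_p > 0:
            dropped = rng.random(n) < noise.dropout_p
        else:
            dropped = np.zeros(n, dtype=bool)
        likelihood = rng.uniform(0.8, 1.0, n)
        likelihood[dropped] = rng.uniform(0.0, 0.6, n)[dropped]

        series[idx] = KeypointSeries(x, y, likelihood)

    return TrialRecording(
        horse_id=horse_id,
        circle=circle,
        fps=gait.fps,
        resolution=(768, 432),
        series=series,
        clinical_status=lameness.status,
        clinical_side=lameness.side,
        bodypart_map=default_bodypart_map(),
    )


@dataclass
class SimulatedHorse:
    """A simulated horse's CL+CR trial pair with its ground truth."""

    horse_id: str
    lameness: LamenessSpec
    trials: dict[str, TrialRecording] = field(default_factory=dict)

    @property
    def clinical_status(self) -> str:
        return self.lameness.status

    @property
    def clinical_side(self) -> Optional[str]:
        return self.lameness.side


def study_cohort_specs() -> list[LamenessSpec]:
    """Cohort mirroring the reference study design: 30 horses.

    13 forelimb-lame (7 left / 6 right; ten subtle, three moderate),
    9 hindlimb-lame (5 left / 4 right; four subtle, five moderate) and
    8 sound controls.
    """
    specs: list[LamenessSpec] = []
    fore_sides = ["left"] * 7 + ["right"] * 6
    fore_deltas = [0.05] * 10 + [0.15] * 3
    for side, d in zip(fore_sides, fore_deltas):
        specs.append(LamenessSpec("forelimb_lame", side, d))
    hind_sides = ["left"] * 5 + ["right"] * 4
    hind_deltas = [0.05] * 4 + [0.15] * 5
    for side, d in zip(hind_sides, hind_deltas):
        specs.append(LamenessSpec("hindlimb_lame", side, d))
    specs.extend(LamenessSpec() for _ in range(8))
    return specs


def simulate_cohort(
    specs: Sequence[LamenessSpec],
    gait: GaitParams = GaitParams(),
    noise: NoiseSpec = NoiseSpec(),
    seed: int = 0,
) -> list[SimulatedHorse]:
    """Simulate CL+CR trial pairs for a cohort of horses.

    Per-horse, per-circle noise seeds are derived from the master seed, so
    the whole cohort is reproducible from one integer; the kinematic
    asymmetry of each horse is identical on both circles.
    """
    if not specs:
        raise ValidationError("cohort needs at least one horse")
    ss = np.random.SeedSequence(seed)
    horses: list[SimulatedHorse] = []
    for i, (spec, child) in enumerate(zip(specs, ss.spawn(len(specs)))):
        horse_id = f"synth{i + 1:03d}"
        cl_seed, cr_seed = (int(s) % 2**31 for s in child.generate_state(2))
        horse = SimulatedHorse(horse_id=horse_id, lameness=spec)
        for circle, s in (("CL", cl_seed), ("CR", cr_seed)):
            trial_noise = NoiseSpec(noise.coord_sd, noise.dropout_p, s)
            horse.trials[circle] = simulate_trial(
                gait, spec, circle, trial_noise, horse_id=horse_id
            )
        horses.append(horse)
    return horses
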