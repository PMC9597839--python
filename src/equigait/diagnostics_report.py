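"""Diagnostic test evaluation and whole-cohort orchestration.

Cross-tabulates predicted against clinical lameness status and computes
the standard diagnostic test characteristics — sensitivity (SE),
specificity (SP), accuracy (ACC), positive and negative predictive values
(PPV, NPV) on 2x2 tables, plus Cohen's kappa and overall accuracy (OA) on
a 3x3 table over {forelimb lame, hindlimb lame, sound}.  ``run_study``
drives the full per-horse pipeline over a cohort of CL+CR trial pairs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from ._rounding import round_half_up
from .errors import EquigaitError, ValidationError
from .forelimb_analysis import (
    DEFAULT_NOD_THRESHOLD,
    analyze_circle,
    classify_forelimb,
)
from .hindlimb_analysis import (
    DEFAULT_STIFLE_THRESHOLD,
    DEFAULT_TCOX_SOUND_THRESHOLD,
    classify_stifle,
    classify_tuber_coxae,
    score_from_trials,
)

logger = logging.getLogger(__name__)

CATEGORIES_3X3 = ("forelimb_lame", "hindlimb_lame", "sound")


@dataclass(frozen=True)
class ConfusionTable:
    """Clinical-truth (rows) vs prediction (columns) cross-tabulation."""

    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        k = len(self.labels)
        if counts.shape != (k, k):
            raise ValidationError(f"counts must be {k}x{k}")
        if (counts < 0).any():
            raise ValidationError("counts must be >= 0")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def _binary(self) -> tuple[int, int, int, int]:
        if len(self.labels) != 2:
            raise ValidationError("TP/FP/FN/TN require a 2x2 table")
        c = self.counts
        return int(c[0, 0]), int(c[1, 0]), int(c[0, 1]), int(c[1, 1])

    @property
    def tp(self) -> int:
        return self._binary()[0]

    @property
    def fp(self) -> int:
        return self._binary()[1]

    @property
    def fn(self) -> int:
        return self._binary()[2]

    @property
    def tn(self) -> int:
        return self._binary()[3]


def tabulate(
    records: Iterable[tuple[str, str]], labels: Optional[Sequence[str]] = None
) -> ConfusionTable:
    """Cross-tabulate (clinical, predicted) label pairs.

    For 2x2 use the lame-positive label first so TP sits at [0, 0].  When
    ``labels`` is omitted they are taken in order of first appearance with
    ``"sound"`` moved last.
    """
    records = list(records)
    if labels is None:
        seen: list[str] = []
        for pair in records:
            for lab in pair:
                if lab not in seen:
                    seen.append(lab)
        if "sound" in seen:
            seen.remove("sound")
            seen.append("sound")
        labels = seen or ["lame", "sound"]
    labels = tuple(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for clinical, predicted in records:
        counts[index[clinical], index[predicted]] += 1
    return ConfusionTable(labels=labels, counts=counts)


def make_2x2(tp: int, fp: int, fn: int, tn: int) -> ConfusionTable:
    """Build a lame/sound 2x2 table directly from its four counts."""
    return ConfusionTable(("lame", "sound"), np.array([[tp, fn], [fp, tn]]))


def test_characteristics(t: ConfusionTable) -> dict[str, Optional[float]]:
    """SE, SP, ACC, PPV and NPV of a 2x2 table, in percent.

    Each value is rounded half-up to one decimal; a metric whose
    denominator is zero is returned as None rather than raising.
    """
    tp, fp, fn, tn = t._binary()

    def pct(num: int, den: int) -> Optional[float]:
        if den == 0:
            return None
        return round_half_up(100.0 * num / den, 1)

    return {
        "SE": pct(tp, tp + fn),
        "SP": pct(tn, tn + fp),
        "ACC": pct(tp + tn, tp + fp + fn + tn),
        "PPV": pct(tp, tp + fp),
        "NPV": pct(tn, tn + fn),
    }


def cohen_kappa(t: ConfusionTable) -> Optional[float]:
    """Chance-corrected agreement kappa = (Po - Pe) / (1 - Pe).

    Po is the observed agreement (trace / total) and Pe the agreement
    expected from the row/column margins.  Returns None when Pe = 1
    (agreement by chance is certain, kappa undefined).
    """
    n = t.total
    if n == 0:
        raise ValidationError("kappa of an empty table")
    po = np.trace(t.counts) / n
    pe = float(np.sum(t.counts.sum(axis=0) * t.counts.sum(axis=1))) / n**2
    if pe == 1.0:
        return None
    return float((po - pe) / (1.0 - pe))


def overall_accuracy(t: ConfusionTable) -> float:
    """Percentage of all correctly classified subjects (trace / total)."""
    if t.total == 0:
        raise ValidationError("overall accuracy of an empty table")
    return round_half_up(100.0 * np.trace(t.counts) / t.total, 1)


@dataclass
class StudyConfig:
    """Decision thresholds and stride-rate assumption for a cohort run."""

    nod_threshold: float = DEFAULT_NOD_THRESHOLD
    stifle_threshold: float = DEFAULT_STIFLE_THRESHOLD
    tcox_sound_threshold: float = DEFAULT_TCOX_SOUND_THRESHOLD
    expected_stride_rate: float = 74.0


def _round4(x: Optional[float]) -> Optional[float]:
    return None if x is None else round_half_up(float(x), 4)


def run_study(cohort: Sequence, config: Optional[StudyConfig] = None) -> dict:
    """Analyse a cohort of CL+CR trial pairs end to end.

    ``cohort`` items must expose ``horse_id``, ``clinical_status``,
    ``clinical_side`` and a ``trials`` mapping with ``"CL"`` and ``"CR"``
    recordings (``synthetic_gait.SimulatedHorse`` fits).  Returns a
    JSON-ready report: per-horse scores, group summaries, confusion
    tables, diagnostic metrics, kappa and overall accuracy.  Horses whose
    analysis fails are excluded with the reason recorded, never silently
    dropped.
    """
    config = config or StudyConfig()
    horses_out: list[dict] = []
    excluded: list[dict] = []
    fore_records: list[tuple[str, str]] = []
    stifle_records: list[tuple[str, str]] = []
    tcox_records: list[tuple[str, str]] = []
    records_3x3: list[tuple[str, str]] = []
    dst_by_group: dict[str, list[float]] = {"hindlimb_lame": [], "sound": []}
    dtcox_groups: dict[str, list[float]] = {
        "non_lame": [],
        "detected_lame": [],
        "non_detected_lame": [],
    }

    for horse in cohort:
        try:
            cl, cr = horse.trials["CL"], horse.trials["CR"]
            nod_cl = analyze_circle(
                cl, expected_rate=config.expected_stride_rate,
                threshold=config.nod_threshold,
            )
            nod_cr = analyze_circle(
                cr, expected_rate=config.expected_stride_rate,
                threshold=config.nod_threshold,
            )
            fore = classify_forelimb(nod_cl, nod_cr)
            stifle = classify_stifle(
                score_from_trials(cl, cr, "stifle"), config.stifle_threshold
            )
            tcox_score = score_from_trials(cl, cr, "tuber_coxae")
            clinical_side = (
                horse.clinical_side
                if horse.clinical_status == "hindlimb_lame"
                else None
            )
            tcox = classify_tuber_coxae(
                tcox_score, clinical_side, config.tcox_sound_threshold
            )
        except (EquigaitError, KeyError) as exc:
            logger.warning("excluding horse %s: %s", horse.horse_id, exc)
            excluded.append({"horse_id": horse.horse_id, "reason": str(exc)})
            continue

        truth = horse.clinical_status or "sound"
        if truth in ("forelimb_lame", "sound"):
            fore_records.append(
                (
                    "lame" if truth == "forelimb_lame" else "sound",
                    "lame" if fore.status == "forelimb_lame" else "sound",
                )
            )
        if truth in ("hindlimb_lame", "sound"):
            stifle_records.append(
                (
                    "lame" if truth == "hindlimb_lame" else "sound",
                    "lame" if stifle.predicted_status == "hindlimb_lame" else "sound",
                )
            )
            tcox_records.append(
                (
                    "lame" if truth == "hindlimb_lame" else "sound",
                    "lame" if tcox.predicted_positive else "sound",
                )
            )
        if fore.status == "forelimb_lame":
            combined = "forelimb_lame"
        elif stifle.predicted_status == "hindlimb_lame":
            combined = "hindlimb_lame"
        else:
            combined = "sound"
        records_3x3.append((truth, combined))

        if truth in dst_by_group:
            dst_by_group[truth].append(stifle.score)
        if truth == "sound":
            dtcox_groups["non_lame"].append(tcox_score.score)
        elif truth == "hindlimb_lame":
            key = "detected_lame" if tcox.correct else "non_detected_lame"
            dtcox_groups[key].append(tcox_score.score)

        horses_out.append(
            {
                "horse_id": horse.horse_id,
                "clinical_status": truth,
                "clinical_side": horse.clinical_side,
                "forelimb": {
                    "nod_index_cl": _round4(nod_cl.nod_index),
                    "nod_index_cr": _round4(nod_cr.nod_index),
                    "status": fore.status,
                    "side": fore.side,
                },
                "stifle": {
                    "span_cl": _round4(stifle.span_cl),
                    "span_cr": _round4(stifle.span_cr),
                    "score": stifle.score_2dp,
                    "status": stifle.predicted_status,
                    "side": stifle.predicted_side,
                },
                "tuber_coxae": {
                    "span_cl": _round4(tcox_score.span_cl),
                    "span_cr": _round4(tcox_score.span_cr),
                    "score": tcox_score.score_2dp,
                    "side": tcox_score.predicted_side,
                    "group": tcox.group,
                    "correct": tcox.correct,
                },
            }
        )

    tables = {
        "forelimb": tabulate(fore_records, ("lame", "sound")),
        "stifle": tabulate(stifle_records, ("lame", "sound")),
        "tuber_coxae": tabulate(tcox_records, ("lame", "sound")),
    }
    t3 = tabulate(records_3x3, CATEGORIES_3X3)
    report = {
        "config": {
            "nod_threshold": _round4(config.nod_threshold),
            "stifle_threshold": config.stifle_threshold,
            "tcox_sound_threshold": config.tcox_sound_threshold,
            "expected_stride_rate": config.expected_stride_rate,
        },
        "n_horses": len(horses_out),
        "horses": horses_out,
        "excluded": excluded,
        "group_means": {
            "dst_sound": (
                round_half_up(float(np.mean(dst_by_group["sound"])), 2)
                if dst_by_group["sound"]
                else None
            ),
            "dtcox": {
                k: (round_half_up(float(np.mean(v)), 2) if v else None)
                for k, v in dtcox_groups.items()
            },
        },
        "tables": {
            name: {
                "labels": list(t.labels),
                "counts": t.counts.tolist(),
                "tp": t.tp,
                "fp": t.fp,
                "fn": t.fn,
                "tn": t.tn,
            }
            for name, t in tables.items()
        },
        "metrics": {name: test_characteristics(t) for name, t in tables.items()},
        "table_3x3": {"labels": list(t3.labels), "counts": t3.counts.tolist()},
        "kappa": _round4(cohen_kappa(t3)),
        "overall_accuracy": overall_accuracy(t3),
    }
    return report


def report_json(report: Mapping) -> str:
    """Serialise a study report deterministically (sorted keys)."""
    return json.dumps(report, indent=2, sort_keys=True)


def format_report_text(report: Mapping) -> str:
    """Human-readable summary with one row per test, like a results table."""
    lines = [
        f"Cohort of {report['n_horses']} horses"
        + (f" ({len(report['excluded'])} excluded)" if report["excluded"] else ""),
        "",
        f"{'Test':<22}{'TP':>4}{'FP':>4}{'FN':>4}{'TN':>4}"
        f"{'SE%':>7}{'SP%':>7}{'ACC%':>7}{'PPV%':>7}{'NPV%':>7}",
    ]
    for name in ("forelimb", "stifle", "tuber_coxae"):
        t = report["tables"][name]
        m = report["metrics"][name]

        def fmt(v):
            return "  n/a" if v is None else f"{v:7.1f}"

        lines.append(
            f"{name:<22}{t['tp']:>4}{t['fp']:>4}{t['fn']:>4}{t['tn']:>4}"
            + "".join(fmt(m[k]) for k in ("SE", "SP", "ACC", "PPV", "NPV"))
        )
    kappa = report["kappa"]
    lines += [
        "",
        f"3x3 agreement: kappa = {kappa if kappa is not None else 'n/a'}, "
        f"overall accuracy = {report['overall_accuracy']}%",
    ]
    return "\n".join(lines)
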