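"""Keypoint trajectory I/O.

Reads and writes per-frame keypoint tables in the three-header-row CSV
dialect emitted by markerless pose-estimation software (scorer / bodyparts /
coords rows, one ``x, y, likelihood`` column triplet per bodypart, one data
row per video frame), and binds them to trial metadata and a configurable
bodypart naming map.

Coordinates follow the image convention: x grows rightward, y grows
*downward*.  Missing coordinates (e.g. frames removed by the likelihood
filter) are carried as NaN so frame indices stay aligned across bodyparts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, FormatError, ParseError, ValidationError

logger = logging.getLogger(__name__)

SIDES = ("left", "right", "midline")
REGIONS = ("head", "neck_trunk", "forelimb", "hindlimb")
CIRCLES = ("CL", "CR")
STATUSES = ("sound", "forelimb_lame", "hindlimb_lame")

#: Canonical analysis roles and the landmark indices they occupy in the
#: 58-point scheme.  Tuber coxae indices are not fixed by the published
#: point list available to us; 41/42 is this package's default assignment
#: and can be overridden in the YAML map.
ANALYSIS_ROLES: dict[str, int] = {
    "poll": 4,
    "elbow_left": 17,
    "elbow_right": 18,
    "os_carpi_accessorium_left": 19,
    "os_carpi_accessorium_right": 20,
    "carpus_left": 21,
    "carpus_right": 22,
    "tuber_coxae_left": 41,
    "tuber_coxae_right": 42,
    "stifle_left": 43,
    "stifle_right": 44,
    "tarsus_left": 45,
    "tarsus_right": 46,
}


@dataclass(frozen=True)
class BodypartEntry:
    index: int
    name: str
    side: str
    region: str

    def __post_init__(self) -> None:
        if not 1 <= self.index <= 58:
            raise ValidationError(f"bodypart index {self.index} outside 1-58")
        if self.side not in SIDES:
            raise ValidationError(f"unknown side {self.side!r}")
        if self.region not in REGIONS:
            raise ValidationError(f"unknown region {self.region!r}")


@dataclass(frozen=True)
class BodypartMap:
    """Ordered mapping of landmark indices to bodypart names.

    The analysis-critical landmarks (poll, elbows, accessory carpal bones,
    carpi, stifles, tubera coxarum, tarsi) must all be present; the
    remaining points of the 58-point scheme are optional.
    """

    entries: tuple[BodypartEntry, ...]

    def __post_init__(self) -> None:
        indices = [e.index for e in self.entries]
        names = [e.name for e in self.entries]
        if len(set(indices)) != len(indices):
            raise ValidationError("bodypart indices must be unique")
        if len(set(names)) != len(names):
            raise ValidationError("bodypart names must be unique")
        missing = [r for r, i in ANALYSIS_ROLES.items() if i not in indices]
        if missing:
            raise ValidationError(
                "analysis-critical bodyparts missing from map: " + ", ".join(missing)
            )

    def index_of(self, name: str) -> int:
        for e in self.entries:
            if e.name == name:
                return e.index
        raise ConfigurationError(f"bodypart {name!r} not in map")

    def name_of(self, index: int) -> str:
        for e in self.entries:
            if e.index == index:
                return e.name
        raise ConfigurationError(f"bodypart index {index} not in map")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.entries)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BodypartMap":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        entries = tuple(
            BodypartEntry(int(e["index"]), str(e["name"]), e["side"], e["region"])
            for e in doc["bodyparts"]
        )
        return cls(entries)

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "bodyparts": [
                {"index": e.index, "name": e.name, "side": e.side, "region": e.region}
                for e in self.entries
            ]
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def _role_side(name: str) -> str:
    if name.endswith("_left"):
        return "left"
    if name.endswith("_right"):
        return "right"
    return "midline"


def _role_region(name: str) -> str:
    if name == "poll":
        return "head"
    if "tuber_coxae" in name or "stifle" in name or "tarsus" in name:
        return "hindlimb"
    return "forelimb"


def default_bodypart_map() -> BodypartMap:
    """Map containing exactly the analysis-critical landmarks."""
    entries = tuple(
        BodypartEntry(idx, name, _role_side(name), _role_region(name))
        for name, idx in sorted(ANALYSIS_ROLES.items(), key=lambda kv: kv[1])
    )
    return BodypartMap(entries)


@dataclass
class KeypointSeries:
    """One bodypart's per-frame (x, y, likelihood) track."""

    x: np.ndarray
    y: np.ndarray
    likelihood: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.likelihood = np.asarray(self.likelihood, dtype=float)
        if not (len(self.x) == len(self.y) == len(self.likelihood)):
            raise ValidationError("x, y and likelihood must have equal length")
        finite = self.likelihood[np.isfinite(self.likelihood)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValidationError("likelihood values must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return len(self.x)

    def coord(self, axis: str) -> np.ndarray:
        if axis == "x":
            return self.x
        if axis == "y":
            return self.y
        raise ValueError(f"axis must be 'x' or 'y', got {axis!r}")

    def __eq__(self, other: object) -> bool:  # NaN-aware equality
        if not isinstance(other, KeypointSeries):
            return NotImplemented
        return all(
            np.array_equal(getattr(self, f), getattr(other, f), equal_nan=True)
            for f in ("x", "y", "likelihood")
        )


@dataclass
class TrialRecording:
    """All tracked bodyparts for one horse on one circle direction, in trot."""

    horse_id: str
    circle: str
    fps: float
    series: dict[int, KeypointSeries]
    resolution: tuple[int, int] = (768, 432)
    gait: str = "trot"
    clinical_status: Optional[str] = None
    clinical_side: Optional[str] = None
    aaep_grade: Optional[int] = None
    bodypart_map: BodypartMap = field(default_factory=default_bodypart_map)

    def __post_init__(self) -> None:
        if self.circle not in CIRCLES:
            raise ValidationError(f"circle must be CL or CR, got {self.circle!r}")
        if self.fps <= 0:
            raise ValidationError("fps must be positive")
        lengths = {s.n_frames for s in self.series.values()}
        if len(lengths) > 1:
            raise ValidationError("all series must share the same frame count")
        if self.clinical_status is not None and self.clinical_status not in STATUSES:
            raise ValidationError(f"unknown clinical status {self.clinical_status!r}")
        if self.clinical_status == "sound" and self.clinical_side is not None:
            raise ValidationError("a sound horse carries no clinical side")

    @property
    def n_frames(self) -> int:
        if not self.series:
            return 0
        return next(iter(self.series.values())).n_frames

    def get(self, role: str) -> KeypointSeries:
        """Series for an analysis role, e.g. ``'stifle_left'``."""
        idx = self.bodypart_map.index_of(role)
        if idx not in self.series:
            raise ConfigurationError(
                f"trial {self.horse_id}/{self.circle} has no series for "
                f"{role!r} (index {idx})"
            )
        return self.series[idx]


def read_dlc_csv(
    path: str | Path,
    bodypart_map: Optional[BodypartMap] = None,
    meta: Optional[Mapping] = None,
) -> TrialRecording:
    """Read a pose-estimation CSV export into a :class:`TrialRecording`.

    The file must carry the three header rows ``scorer`` / ``bodyparts`` /
    ``coords``; a leading frame-index column is accepted.  Bodyparts not in
    the map are ignored with a warning so that 58-point exports can be read
    with the 13-point analysis map.
    """
    path = Path(path)
    bodypart_map = bodypart_map or default_bodypart_map()
    meta = dict(meta or {})

    with open(path, encoding="utf-8") as fh:
        header = [fh.readline().rstrip("\n") for _ in range(3)]
    expected = ("scorer", "bodyparts", "coords")
    for row_no, (line, label) in enumerate(zip(header, expected), start=1):
        first = line.split(",")[0].strip()
        if first != label:
            raise FormatError(
                f"{path}: header row {row_no} must start with {label!r}, got {first!r}"
            )

    bp_row = header[1].split(",")[1:]
    coord_row = header[2].split(",")[1:]
    if len(bp_row) != len(coord_row):
        raise FormatError(f"{path}: bodyparts and coords rows differ in width")

    # tolerate an explicit leading frame-index column in the header rows
    # (empty bodypart label over an "index"/"frame"/empty coords cell)
    if bp_row and bp_row[0] == "" and coord_row[0] in ("", "index", "frame"):
        bp_row, coord_row = bp_row[1:], coord_row[1:]
    cols = list(zip(bp_row, coord_row))
    if len(cols) % 3 != 0:
        raise FormatError(f"{path}: columns do not form (x, y, likelihood) triplets")
    for i in range(0, len(cols), 3):
        triplet = [c for _, c in cols[i : i + 3]]
        names = {b for b, _ in cols[i : i + 3]}
        if triplet != ["x", "y", "likelihood"] or len(names) != 1:
            raise FormatError(
                f"{path}: header row 3 malformed near column {i + 1}: "
                f"expected x,y,likelihood for a single bodypart, got {triplet}"
            )

    try:
        raw = pd.read_csv(path, skiprows=3, header=None, dtype=str)
    except pd.errors.EmptyDataError:
        raw = pd.DataFrame()
    if raw.empty:
        data = np.empty((0, len(cols)))
    else:
        # data rows carry the frame index under the header-label column
        offset = raw.shape[1] - len(cols)
        if offset not in (0, 1):
            raise FormatError(
                f"{path}: {raw.shape[1]} data columns for {len(cols)} declared"
            )
        block = raw.iloc[:, offset : offset + len(cols)]
        try:
            data = block.astype(float).to_numpy()
        except ValueError:
            bad = block.apply(pd.to_numeric, errors="coerce")
            r, c = np.argwhere(bad.isna().to_numpy() & block.notna().to_numpy())[0]
            raise ParseError(
                f"{path}: non-numeric cell at frame {r}, column {c + offset + 1}"
            ) from None

    series: dict[int, KeypointSeries] = {}
    for i in range(0, len(cols), 3):
        name = cols[i][0]
        try:
            idx = bodypart_map.index_of(name)
        except ConfigurationError:
            logger.warning("ignoring unmapped bodypart %r in %s", name, path)
            continue
        x, y, lk = (data[:, i + j] for j in range(3))
        finite_lk = lk[np.isfinite(lk)]
        if finite_lk.size and (finite_lk.min() < 0 or finite_lk.max() > 1):
            raise ValidationError(f"{path}: likelihood outside [0, 1] for {name!r}")
        series[idx] = KeypointSeries(x, y, lk)

    return TrialRecording(
        horse_id=str(meta.get("horse_id", path.stem)),
        circle=meta.get("circle", "CL"),
        fps=float(meta.get("fps", 30.0)),
        resolution=tuple(meta.get("resolution", (768, 432))),
        gait=meta.get("gait", "trot"),
        clinical_status=meta.get("clinical_status"),
        clinical_side=meta.get("clinical_side"),
        aaep_grade=meta.get("aaep_grade"),
        series=series,
        bodypart_map=bodypart_map,
    )


def write_dlc_csv(trial: TrialRecording, path: str | Path, scorer: str = "equigait") -> None:
    """Write a trial back out in the three-header-row CSV dialect.

    Coordinates are written at fixed 6-decimal precision; a leading frame
    index column is regenerated.
    """
    path = Path(path)
    indices = sorted(trial.series)
    names = [trial.bodypart_map.name_of(i) for i in indices]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        ncols = 3 * len(indices)
        fh.write("scorer," + ",".join([scorer] * ncols) + "\n")
        fh.write("bodyparts," + ",".join(n for n in names for _ in range(3)) + "\n")
        fh.write("coords," + ",".join(["x", "y", "likelihood"] * len(indices)) + "\n")
        if not indices:
            return
        mat = np.column_stack(
            [
                col
                for i in indices
                for col in (
                    trial.series[i].x,
                    trial.series[i].y,
                    trial.series[i].likelihood,
                )
            ]
        )
        for f in range(trial.n_frames):
            cells = ",".join("" if np.isnan(v) else f"{v:.6f}" for v in mat[f])
            fh.write(f"{f},{cells}\n")


def read_trial(
    csv_path: str | Path,
    meta_path: Optional[str | Path] = None,
    bodypart_map: Optional[BodypartMap] = None,
) -> TrialRecording:
    """Read a trajectory CSV together with its YAML metadata sidecar."""
    meta = {}
    if meta_path is None:
        candidate = Path(csv_path).with_suffix(".yaml")
        meta_path = candidate if candidate.exists() else None
    if meta_path is not None:
        with open(meta_path, encoding="utf-8") as fh:
            meta = yaml.safe_load(fh) or {}
    return read_dlc_csv(csv_path, bodypart_map=bodypart_map, meta=meta)


def write_trial(trial: TrialRecording, csv_path: str | Path) -> None:
    """Write a trajectory CSV plus its YAML metadata sidecar."""
    write_dlc_csv(trial, csv_path)
    meta = {
        "horse_id": trial.horse_id,
        "circle": trial.circle,
        "gait": trial.gait,
        "fps": trial.fps,
        "resolution": list(trial.resolution),
        "clinical_status": trial.clinical_status,
        "clinical_side": trial.clinical_side,
        "aaep_grade": trial.aaep_grade,
    }
    with open(Path(csv_path).with_suffix(".yaml"), "w", encoding="utf-8") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
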