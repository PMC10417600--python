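"""Detection streams and the experimental design.

The unit of raw data is a *detection stream*: per-frame, per-compartment
bounding boxes produced by an object detector watching one ceiling camera
per compartment of a three-compartment environmental preference chamber
(EPC).  Streams are carried in memory as a :class:`pandas.DataFrame` in a
fixed column layout (one row per bounding box, one row with empty box
fields per frame in which nothing was detected), with light dataclasses
(:class:`BoundingBox`, :class:`FrameDetections`, :class:`Scene`) for the
typed views the downstream operations consume.

The experimental design is a Latin-square rotation of three light colors
(white, green, red) over the three compartments, crossed with three thermal
conditions (hot 35 degC, thermoneutral 24 degC, cold 17 degC), each
treatment lasting two days and repeated three times.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FRAME_WIDTH",
    "FRAME_HEIGHT",
    "COMPARTMENTS",
    "LIGHTS",
    "THERMAL_CELSIUS",
    "DETECTION_COLUMNS",
    "BOX_COLUMNS",
    "BoundingBox",
    "FrameDetections",
    "Scene",
    "ObservationWindow",
    "Experiment",
    "ExperimentDesign",
    "MalformedRowError",
    "centroid",
    "default_windows",
    "read_detection_csv",
    "write_detection_csv",
    "frames_from_dataframe",
    "downsample",
    "select_windows",
    "schedule_hours",
    "total_days",
    "expected_frame_count",
]

#: Default camera frame size in pixels (low-cost CCD cameras, 702 x 480).
FRAME_WIDTH = 702
FRAME_HEIGHT = 480

COMPARTMENTS = ("A", "B", "C")
LIGHTS = ("white", "green", "red")

#: Chamber setpoints, degrees Celsius.
THERMAL_CELSIUS = {"hot": 35.0, "neutral": 24.0, "cold": 17.0}

#: Canonical detection-CSV column order.  One row per box; a frame with no
#: detections contributes one row whose four box fields are empty.
DETECTION_COLUMNS = [
    "experiment_id",
    "replicate",
    "day",
    "session",
    "compartment",
    "frame_index",
    "timestamp_s",
    "x_min",
    "y_min",
    "x_max",
    "y_max",
]
BOX_COLUMNS = ["x_min", "y_min", "x_max", "y_max"]

META_COLUMNS = ["experiment_id", "replicate", "day", "session"]

#: Boxes with area below this (px^2) are rejected as degenerate.
MIN_BOX_AREA = 1e-3


class MalformedRowError(ValueError):
    """A detection-CSV row that cannot be parsed; carries the line number."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in continuous pixel coordinates.

    Origin is the image top-left corner, x grows rightward, y downward.
    Boxes are closed on their min edges and open on their max edges.
    """

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(
                f"degenerate box: ({self.x_min}, {self.y_min}, "
                f"{self.x_max}, {self.y_max})"
            )
        if self.x_min < 0 or self.y_min < 0:
            raise ValueError("box coordinates must be non-negative")
        if self.area < MIN_BOX_AREA:
            raise ValueError(f"box area {self.area} below minimum {MIN_BOX_AREA}")

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    @property
    def centroid(self) -> tuple[float, float]:
        return centroid(self)


def centroid(box: BoundingBox) -> tuple[float, float]:
    """Arithmetic midpoint of a bounding box, in pixels."""
    return ((box.x_min + box.x_max) / 2.0, (box.y_min + box.y_max) / 2.0)


@dataclass
class FrameDetections:
    """All bounding boxes seen by one camera at one frame instant."""

    frame_index: int
    timestamp: float
    compartment: str
    boxes: list[BoundingBox] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError("frame_index must be non-negative")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")

    @property
    def count(self) -> int:
        return len(self.boxes)

    def centroids(self) -> np.ndarray:
        """(n, 2) array of box centroids; empty array for an empty frame."""
        if not self.boxes:
            return np.empty((0, 2))
        return np.array([centroid(b) for b in self.boxes])


@dataclass
class Scene:
    """A synchronized triple of frames, one per compartment.

    The unit of the manual count-validation protocol: one video frame from
    each chamber compartment captured at the same instant.
    """

    scene_index: int
    frames: dict[str, FrameDetections]

    def __post_init__(self) -> None:
        if set(self.frames) != set(COMPARTMENTS):
            raise ValueError("a scene needs exactly one frame per compartment A, B, C")
        stamps = {f.timestamp for f in self.frames.values()}
        if len(stamps) != 1:
            raise ValueError(f"scene frames must share one timestamp, got {stamps}")

    @property
    def total_count(self) -> int:
        return sum(f.count for f in self.frames.values())


@dataclass(frozen=True)
class ObservationWindow:
    """A daily monitoring window, as time-of-day seconds, half-open [start, end)."""

    session: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError("window end must be after start")

    @property
    def hours(self) -> float:
        return (self.end - self.start) / 3600.0

    def contains(self, seconds_of_day: float) -> bool:
        return self.start <= seconds_of_day < self.end


def default_windows() -> list[ObservationWindow]:
    """The two 2-h daily monitoring windows: 09:30-11:30 and 15:00-17:00."""
    return [
        ObservationWindow("morning", 9.5 * 3600, 11.5 * 3600),
        ObservationWindow("afternoon", 15.0 * 3600, 17.0 * 3600),
    ]


@dataclass(frozen=True)
class Experiment:
    """One row of the treatment table: a thermal condition plus a light rotation."""

    experiment_id: int
    thermal: str
    light_map: Mapping[str, str]  # compartment -> light color

    def __post_init__(self) -> None:
        if self.thermal not in THERMAL_CELSIUS:
            raise ValueError(f"unknown thermal condition {self.thermal!r}")
        if set(self.light_map) != set(COMPARTMENTS):
            raise ValueError("light_map must cover compartments A, B, C")
        if sorted(self.light_map.values()) != sorted(LIGHTS):
            raise ValueError("light_map must use each of white/green/red once")


@dataclass
class ExperimentDesign:
    """The rotation of light colors over compartments x thermal conditions.

    Within each thermal condition the three experiments form a Latin square:
    every light color appears in every compartment exactly once.  Each
    experiment runs ``days_per_treatment`` days and the whole table is
    repeated ``replicates`` times.
    """

    experiments: list[Experiment]
    days_per_treatment: int = 2
    replicates: int = 3
    flock_size: int = 6

    def __post_init__(self) -> None:
        ids = [e.experiment_id for e in self.experiments]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate experiment ids")
        by_thermal: dict[str, list[Experiment]] = {}
        for e in self.experiments:
            by_thermal.setdefault(e.thermal, []).append(e)
        for thermal, exps in by_thermal.items():
            for comp in COMPARTMENTS:
                lights = sorted(e.light_map[comp] for e in exps)
                if lights != sorted(LIGHTS):
                    raise ValueError(
                        f"thermal {thermal!r}: compartment {comp} does not see "
                        "every light exactly once (not a Latin square)"
                    )

    @classmethod
    def default(cls) -> "ExperimentDesign":
        """The study's nine-experiment table: WGR/RWG/GRW per thermal condition."""
        rotations = [("W", "G", "R"), ("R", "W", "G"), ("G", "R", "W")]
        expand = {"W": "white", "G": "green", "R": "red"}
        experiments = []
        eid = 1
        for thermal in ("hot", "neutral", "cold"):
            for rot in rotations:
                light_map = {c: expand[s] for c, s in zip(COMPARTMENTS, rot)}
                experiments.append(Experiment(eid, thermal, light_map))
                eid += 1
        return cls(experiments=experiments)

    def experiment(self, experiment_id: int) -> Experiment:
        for e in self.experiments:
            if e.experiment_id == experiment_id:
                return e
        raise KeyError(f"no experiment {experiment_id}")

    def light_of(self, experiment_id: int, compartment: str) -> str:
        return self.experiment(experiment_id).light_map[compartment]

    def thermal_of(self, experiment_id: int) -> str:
        return self.experiment(experiment_id).thermal

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "days_per_treatment": self.days_per_treatment,
            "replicates": self.replicates,
            "flock_size": self.flock_size,
            "experiments": [
                {
                    "experiment_id": e.experiment_id,
                    "thermal": e.thermal,
                    "light_map": dict(e.light_map),
                }
                for e in self.experiments
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExperimentDesign":
        return cls(
            experiments=[
                Experiment(e["experiment_id"], e["thermal"], e["light_map"])
                for e in d["experiments"]
            ],
            days_per_treatment=int(d.get("days_per_treatment", 2)),
            replicates=int(d.get("replicates", 3)),
            flock_size=int(d.get("flock_size", 6)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentDesign":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def _empty_stream() -> pd.DataFrame:
    df = pd.DataFrame(columns=DETECTION_COLUMNS)
    for c in ("experiment_id", "replicate", "day", "frame_index"):
        df[c] = df[c].astype(int)
    for c in ("timestamp_s", *BOX_COLUMNS):
        df[c] = df[c].astype(float)
    return df


def read_detection_csv(path) -> pd.DataFrame:
    """Read a detection CSV into the canonical stream layout.

    Returns a DataFrame with :data:`DETECTION_COLUMNS`; empty frames are
    kept as rows with NaN box fields.  Boxes violating the box invariants
    (``x_min >= x_max`` etc.) are dropped; the number dropped is recorded in
    ``df.attrs["n_rejected_boxes"]`` and the remainder of the frame record
    is preserved (as an empty frame if it was the only box).

    Raises
    ------
    MalformedRowError
        If a row cannot be parsed; the message names the 1-based line number.
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise MalformedRowError(f"{path}: empty file, header required") from exc
    missing = [c for c in DETECTION_COLUMNS if c not in df.columns]
    if missing:
        raise MalformedRowError(f"{path}: header missing columns {missing}")
    df = df[DETECTION_COLUMNS].copy()

    def _conv(col: str, kind: str) -> pd.Series:
        # float() is correctly rounded, so written streams read back exactly
        vals = np.empty(len(df), dtype=float)
        for i, v in enumerate(df[col]):
            if v == "":
                vals[i] = np.nan
                continue
            try:
                vals[i] = float(v)
            except ValueError:
                raise MalformedRowError(
                    f"{path}: line {i + 2}: cannot parse {col!r}={v!r}"
                ) from None
        out = pd.Series(vals, index=df.index)
        if kind == "int":
            nan = out.isna()
            if nan.any():
                line = int(np.flatnonzero(nan.to_numpy())[0]) + 2
                raise MalformedRowError(f"{path}: line {line}: missing {col!r}")
            return out.astype(int)
        return out

    for col in ("experiment_id", "replicate", "day", "frame_index"):
        df[col] = _conv(col, "int")
    df["timestamp_s"] = _conv("timestamp_s", "float")
    if df["timestamp_s"].isna().any():
        line = int(np.flatnonzero(df["timestamp_s"].isna().to_numpy())[0]) + 2
        raise MalformedRowError(f"{path}: line {line}: missing 'timestamp_s'")
    for col in BOX_COLUMNS:
        df[col] = _conv(col, "float")

    box_fields = df[BOX_COLUMNS].notna()
    partial = box_fields.any(axis=1) & ~box_fields.all(axis=1)
    if partial.any():
        line = int(np.flatnonzero(partial.to_numpy())[0]) + 2
        raise MalformedRowError(
            f"{path}: line {line}: box fields must be all present or all empty"
        )
    bad_comp = ~df["compartment"].isin(COMPARTMENTS)
    if bad_comp.any():
        line = int(np.flatnonzero(bad_comp.to_numpy())[0]) + 2
        raise MalformedRowError(
            f"{path}: line {line}: unknown compartment {df['compartment'].iloc[line - 2]!r}"
        )

    has_box = box_fields.all(axis=1)
    valid = (
        (df["x_min"] < df["x_max"])
        & (df["y_min"] < df["y_max"])
        & (df["x_min"] >= 0)
        & (df["y_min"] >= 0)
        & ((df["x_max"] - df["x_min"]) * (df["y_max"] - df["y_min"]) >= MIN_BOX_AREA)
    )
    rejected = has_box & ~valid
    n_rejected = int(rejected.sum())
    if n_rejected:
        # keep the frame record: demote sole-box frames to empty frames
        keys = ["compartment", "frame_index"]
        drop = df.loc[rejected]
        keep = df.loc[~rejected]
        lost = drop.merge(keep[keys].drop_duplicates(), on=keys, how="left", indicator=True)
        lost = drop[ (lost["_merge"] == "left_only").to_numpy() ].copy()
        lost[BOX_COLUMNS] = np.nan
        df = pd.concat([keep, lost.drop_duplicates(subset=keys)], ignore_index=True)

    df = df.sort_values(
        ["experiment_id", "replicate", "day", "session", "compartment", "frame_index"],
        kind="stable",
    ).reset_index(drop=True)
    df.attrs["n_rejected_boxes"] = n_rejected
    df.attrs.setdefault("fps", None)
    return df


def write_detection_csv(stream: pd.DataFrame, path) -> None:
    """Write a stream in the canonical CSV dialect (one row per box)."""
    out = stream[DETECTION_COLUMNS].copy()
    out = out.sort_values(
        ["experiment_id", "replicate", "day", "session", "compartment", "frame_index"],
        kind="stable",
    )
    out.to_csv(path, index=False)


def frames_from_dataframe(stream: pd.DataFrame) -> Iterator[FrameDetections]:
    """Yield one :class:`FrameDetections` per (metadata, compartment, frame)."""
    keys = META_COLUMNS + ["compartment", "frame_index"]
    for key, grp in stream.groupby(keys, sort=True, dropna=False):
        eid, rep, day, session, comp, fidx = key
        boxes = [
            BoundingBox(r.x_min, r.y_min, r.x_max, r.y_max)
            for r in grp.itertuples()
            if not math.isnan(r.x_min)
        ]
        yield FrameDetections(
            frame_index=int(fidx),
            timestamp=float(grp["timestamp_s"].iloc[0]),
            compartment=comp,
            boxes=boxes,
            meta={"experiment_id": eid, "replicate": rep, "day": day, "session": session},
        )


# ---------------------------------------------------------------------------
# temporal operations
# ---------------------------------------------------------------------------


def downsample(stream: pd.DataFrame, factor: int) -> pd.DataFrame:
    """Keep frames whose index is a multiple of ``factor``.

    Emulates reducing 30 fps footage to 30/factor fps.  The resulting
    stream's ``attrs`` carry the effective fps (when known) and the frame
    step between retained frames.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError(f"downsampling factor must be a positive integer, got {factor}")
    factor = int(factor)
    step = int(stream.attrs.get("frame_step", 1) or 1)
    out = stream[stream["frame_index"] % (factor * step) == 0].reset_index(drop=True)
    out.attrs = dict(stream.attrs)
    fps = stream.attrs.get("fps")
    if fps is not None:
        out.attrs["fps"] = fps / factor
    out.attrs["frame_step"] = step * factor
    return out


def select_windows(
    stream: pd.DataFrame, windows: Sequence[ObservationWindow]
) -> pd.DataFrame:
    """Keep frames whose time of day falls in one of the monitoring windows.

    ``timestamp_s`` is interpreted as seconds since the start of the
    stream's first day; membership uses the half-open convention
    ``start <= t_of_day < end``.  A ``window`` column annotates each kept
    frame with the matching session name.
    """
    wins = sorted(windows, key=lambda w: w.start)
    for a, b in itertools.pairwise(wins):
        if b.start < a.end:
            raise ValueError(f"overlapping windows: {a} and {b}")
    out = stream.copy()
    if not wins:
        out = out.iloc[0:0].copy()
        out["window"] = pd.Series(dtype=str)
        out.attrs = dict(stream.attrs)
        return out
    tod = out["timestamp_s"].to_numpy() % 86400.0
    label = np.full(len(out), None, dtype=object)
    for w in wins:
        hit = (tod >= w.start) & (tod < w.end)
        label[hit] = w.session
    out["window"] = label
    out = out[pd.notna(out["window"])].reset_index(drop=True)
    out.attrs = dict(stream.attrs)
    return out


def schedule_hours(
    design: ExperimentDesign,
    windows: Sequence[ObservationWindow] | None = None,
    n_compartments: int = len(COMPARTMENTS),
) -> float:
    """Total monitored video hours: days x window-hours/day x compartments."""
    if windows is None:
        windows = default_windows()
    hours_per_day = sum(w.hours for w in windows)
    return total_days(design) * hours_per_day * n_compartments


def total_days(design: ExperimentDesign) -> int:
    """Experiment days in the full design: experiments x days x replicates."""
    return len(design.experiments) * design.days_per_treatment * design.replicates


def expected_frame_count(
    design: ExperimentDesign,
    fps: float = 15.0,
    windows: Sequence[ObservationWindow] | None = None,
) -> int:
    """Number of frames in the evaluation dataset at the effective frame rate."""
    return round(schedule_hours(design, windows) * 3600 * fps)
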