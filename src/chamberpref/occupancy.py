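"""Bird counts, doorway duplicate resolution, and permanence time.

Permanence time attributes cumulative bird-time to each light treatment:
with no individual identities available, the dwell time of the flock in a
compartment is the sum of per-frame bird counts divided by the effective
frame rate of the analysed stream,

    T_L = (sum of counts over all frames of cell L) / fps   [bird-seconds].

Dividing by the *effective* fps (15 after 2x down-sampling of 30 fps
footage) makes T_L invariant to down-sampling of a static scene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .streams import BOX_COLUMNS, COMPARTMENTS, FRAME_HEIGHT, FRAME_WIDTH, ExperimentDesign, Scene

__all__ = [
    "EdgePolicy",
    "DEFAULT_DOOR_EDGES",
    "frame_counts",
    "resolve_duplicates",
    "permanence_time",
    "occupancy_fractions",
]

#: Which image edge of each compartment abuts each neighbour.  The chamber
#: is a row of three compartments with doors between all pairs; geometry is
#: declared, never guessed from pixels.
DEFAULT_DOOR_EDGES: dict[tuple[str, str], str] = {
    ("A", "B"): "right", ("B", "A"): "left",
    ("B", "C"): "right", ("C", "B"): "left",
    ("A", "C"): "bottom", ("C", "A"): "bottom",
}


@dataclass(frozen=True)
class EdgePolicy:
    """Doorway duplicate suppression policy.

    mode ``"off"`` leaves scenes unchanged (the automatic pipeline, which
    over-counted a small fraction of scenes); ``"suppress"`` pairs boxes
    lying within ``margin`` pixels of a shared door edge in two adjacent
    compartments and removes the smaller-area member of each pair — a proxy
    for manual head-location adjudication, which the detector cannot see.
    """

    margin: float = 20.0
    mode: str = "off"

    def __post_init__(self) -> None:
        if self.margin < 0:
            raise ValueError("margin must be non-negative")
        if self.mode not in ("off", "suppress"):
            raise ValueError("mode must be 'off' or 'suppress'")


def frame_counts(stream: pd.DataFrame) -> pd.DataFrame:
    """Per-frame bird counts: one row per (metadata, compartment, frame).

    The count is the number of boxes in the frame record; empty-frame rows
    (NaN box fields) yield count 0.
    """
    df = stream.copy()
    df["_has_box"] = df[BOX_COLUMNS].notna().all(axis=1).astype(int)
    keys = [
        c for c in
        ("experiment_id", "replicate", "day", "session", "window", "compartment", "frame_index")
        if c in df.columns
    ]
    counts = (
        df.groupby(keys, sort=True, dropna=False)
        .agg(count=("_has_box", "sum"), timestamp_s=("timestamp_s", "first"))
        .reset_index()
    )
    counts["count"] = counts["count"].astype(int)
    counts.attrs = dict(stream.attrs)
    return counts


def _edge_distance(box: np.ndarray, edge: str, width: float, height: float) -> float:
    """Distance (px) from a box to an image edge; 0 if the box touches it."""
    x0, y0, x1, y1 = box
    if edge == "left":
        return x0
    if edge == "right":
        return width - x1
    if edge == "top":
        return y0
    if edge == "bottom":
        return height - y1
    raise ValueError(f"unknown edge {edge!r}")


def resolve_duplicates(
    scene: Scene,
    policy: EdgePolicy | None = None,
    door_edges: Mapping[tuple[str, str], str] = DEFAULT_DOOR_EDGES,
    frame_size: tuple[float, float] = (FRAME_WIDTH, FRAME_HEIGHT),
) -> Scene:
    """Suppress doorway double-detections in a synchronized scene.

    A bird straddling an automatic door may be detected in both adjacent
    compartments.  With ``mode="suppress"``, boxes within ``policy.margin``
    of a shared door edge on both sides are greedily paired (smallest
    combined edge distance first) and the smaller-area member of each pair
    is removed — at most one removal per pair, so counts never increase.
    With ``mode="off"`` the scene is returned unchanged.
    """
    policy = policy or EdgePolicy()
    if policy.mode == "off":
        return scene
    width, height = frame_size
    boxes = {
        comp: [np.array([b.x_min, b.y_min, b.x_max, b.y_max]) for b in fr.boxes]
        for comp, fr in scene.frames.items()
    }
    removed: dict[str, set[int]] = {c: set() for c in boxes}
    pairs_done: set[frozenset[str]] = set()
    for (ca, cb), edge_a in door_edges.items():
        key = frozenset((ca, cb))
        if key in pairs_done or (cb, ca) not in door_edges:
            continue
        pairs_done.add(key)
        edge_b = door_edges[(cb, ca)]
        cand_a = [
            (i, _edge_distance(b, edge_a, width, height))
            for i, b in enumerate(boxes.get(ca, []))
            if _edge_distance(b, edge_a, width, height) <= policy.margin
        ]
        cand_b = [
            (j, _edge_distance(b, edge_b, width, height))
            for j, b in enumerate(boxes.get(cb, []))
            if _edge_distance(b, edge_b, width, height) <= policy.margin
        ]
        # greedy pairing: nearest-to-the-door pairs first
        options = sorted(
            ((da + db, i, j) for i, da in cand_a for j, db in cand_b),
            key=lambda t: t[0],
        )
        used_a: set[int] = set()
        used_b: set[int] = set()
        for _, i, j in options:
            if i in used_a or j in used_b or i in removed[ca] or j in removed[cb]:
                continue
            used_a.add(i)
            used_b.add(j)
            area_a = np.prod(boxes[ca][i][2:] - boxes[ca][i][:2])
            area_b = np.prod(boxes[cb][j][2:] - boxes[cb][j][:2])
            # the smaller box is taken to be the body remnant across the door
            if area_a <= area_b:
                removed[ca].add(i)
            else:
                removed[cb].add(j)
    new_frames = {}
    for comp, fr in scene.frames.items():
        kept = [b for i, b in enumerate(fr.boxes) if i not in removed[comp]]
        new_frames[comp] = type(fr)(
            frame_index=fr.frame_index,
            timestamp=fr.timestamp,
            compartment=fr.compartment,
            boxes=kept,
            meta=dict(fr.meta),
        )
    return Scene(scene_index=scene.scene_index, frames=new_frames)


def permanence_time(
    counts: pd.DataFrame,
    fps: float,
    design: ExperimentDesign,
    per_bird_denominator: str = "flock",
) -> pd.DataFrame:
    """Permanence time per (light, temperature) treatment cell.

    T_L = (sum of per-frame counts in the cell) / fps, in bird-seconds;
    also reported in minutes and hours, plus ``minutes_per_bird`` with a
    configurable denominator: ``"flock"`` divides by flock size only,
    ``"flock_days"`` additionally by the number of replicate-days observed
    in the cell.  ``m`` is the number of bird-observations contributing.
    """
    if not fps > 0:
        raise ValueError(f"fps must be positive, got {fps}")
    if per_bird_denominator not in ("flock", "flock_days"):
        raise ValueError("per_bird_denominator must be 'flock' or 'flock_days'")
    df = counts.copy()
    df["light"] = [
        design.light_of(e, c) for e, c in zip(df["experiment_id"], df["compartment"])
    ]
    df["temperature"] = [design.thermal_of(e) for e in df["experiment_id"]]
    grouped = df.groupby(["light", "temperature"])
    rows = []
    for (light, temp), grp in grouped:
        m = int(grp["count"].sum())
        t_seconds = m / fps
        if per_bird_denominator == "flock_days":
            n_days = grp.drop_duplicates(subset=[k for k in ("replicate", "day") if k in grp])
            denom = design.flock_size * max(len(n_days), 1)
        else:
            denom = design.flock_size
        rows.append(
            {
                "light": light,
                "temperature": temp,
                "T_bird_seconds": t_seconds,
                "T_bird_minutes": t_seconds / 60.0,
                "T_bird_hours": t_seconds / 3600.0,
                "minutes_per_bird": t_seconds / 60.0 / denom,
                "m": m,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["fps"] = fps
    return out


def permanence_by_replicate(
    counts: pd.DataFrame, fps: float, design: ExperimentDesign
) -> pd.DataFrame:
    """Per-replicate permanence totals: the unit of the statistical tests."""
    if not fps > 0:
        raise ValueError(f"fps must be positive, got {fps}")
    df = counts.copy()
    df["light"] = [
        design.light_of(e, c) for e, c in zip(df["experiment_id"], df["compartment"])
    ]
    df["temperature"] = [design.thermal_of(e) for e in df["experiment_id"]]
    out = (
        df.groupby(["light", "temperature", "replicate"])["count"]
        .sum()
        .reset_index()
    )
    out["T_bird_seconds"] = out["count"] / fps
    return out.drop(columns="count")


def occupancy_fractions(permanence: pd.DataFrame) -> pd.DataFrame:
    """Fraction of bird-time per light within each temperature.

    Adds a ``fraction`` column; fractions sum to 1 within a temperature.
    A temperature whose totals are all zero gets NaN fractions (undefined,
    flagged rather than silently zero).
    """
    out = permanence.copy()
    totals = out.groupby("temperature")["T_bird_seconds"].transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        out["fraction"] = np.where(
            totals > 0, out["T_bird_seconds"] / totals, np.nan
        )
    return out
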