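"""Unrest index: identity-free activity from consecutive detection frames.

The unrest index of a frame pair is

    UI(i, i-1) = k * max( d(F_i, F_{i-1}), d(F_{i-1}, F_i) )

where ``F_i`` is the set of detection centroids at frame ``i``, ``d`` is the
directed Hausdorff distance between centroid sets (max over one set of the
Euclidean distance to the nearest point of the other), and ``k`` is a
camera proportionality factor (1.0 for a 90-degree field of view).  The
outer max makes the value the symmetric Hausdorff distance, so the index
needs no individual-bird identities: it measures how far the configuration
of birds moved between consecutive frames, in pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .streams import FrameDetections, ExperimentDesign

__all__ = [
    "UnrestParams",
    "directed_set_distance",
    "symmetric_hausdorff",
    "unrest_index",
    "unrest_series",
    "aggregate_unrest",
]


@dataclass(frozen=True)
class UnrestParams:
    """Parameters of the unrest computation.

    k: dimensionless camera proportionality factor (>0).
    empty_frame_policy: what a pair with an empty side yields —
        ``"missing"`` (NaN, excluded from aggregation; absence is not
        stillness) or ``"zero"``.
    """

    k: float = 1.0
    empty_frame_policy: str = "missing"

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError("k must be positive")
        if self.empty_frame_policy not in ("missing", "zero"):
            raise ValueError("empty_frame_policy must be 'missing' or 'zero'")


def directed_set_distance(A: np.ndarray, B: np.ndarray) -> float:
    """Directed Hausdorff distance d(A, B) = max_a min_b ||a - b||, pixels.

    ``A`` and ``B`` are (n, 2) arrays of centroids; both must be non-empty
    (the caller applies the empty-frame policy).  Asymmetric: every point of
    ``A`` must be near some point of ``B``, not conversely.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.size == 0 or B.size == 0:
        raise ValueError("directed set distance of an empty centroid set is undefined")
    return float(cdist(A, B).min(axis=1).max())


def symmetric_hausdorff(A: np.ndarray, B: np.ndarray) -> float:
    """max(d(A,B), d(B,A)): the (symmetric) Hausdorff distance."""
    return max(directed_set_distance(A, B), directed_set_distance(B, A))


def unrest_index(
    F_i: FrameDetections, F_prev: FrameDetections, params: UnrestParams | None = None
) -> float:
    """Unrest index of a consecutive frame pair, in k-scaled pixels.

    Returns NaN when a side is empty and the policy is ``"missing"``.
    """
    params = params or UnrestParams()
    if F_i.compartment != F_prev.compartment:
        raise ValueError(
            f"frames from different compartments: {F_i.compartment} vs {F_prev.compartment}"
        )
    A, B = F_i.centroids(), F_prev.centroids()
    if len(A) == 0 or len(B) == 0:
        return 0.0 if params.empty_frame_policy == "zero" else float("nan")
    return params.k * symmetric_hausdorff(A, B)


_SEGMENT_KEYS = ["experiment_id", "replicate", "day", "session", "compartment"]


def unrest_series(stream: pd.DataFrame, params: UnrestParams | None = None) -> pd.DataFrame:
    """Per-pair unrest values along a detection stream.

    One value per consecutive frame pair within each contiguous segment; a
    segment is one (experiment, replicate, day, session/window, compartment)
    block, and a jump in frame index larger than the stream's frame step
    (``stream.attrs["frame_step"]``, default: the smallest observed
    increment) additionally breaks the segment, so no pair spans a gap
    between observation windows.

    Returns a DataFrame with the segment keys plus ``pair_index`` (frame
    index of the later frame), ``unrest_px``, ``n_boxes``, ``n_boxes_prev``.
    """
    params = params or UnrestParams()
    keys = [k for k in _SEGMENT_KEYS if k in stream.columns]
    if "window" in stream.columns:
        keys = keys + ["window"]
    rows: list[dict] = []
    for seg_key, grp in stream.groupby(keys, sort=True, dropna=False):
        if not isinstance(seg_key, tuple):
            seg_key = (seg_key,)
        meta = dict(zip(keys, seg_key))
        frames = _frames_of_segment(grp)
        if len(frames) < 2:
            continue
        idx = np.array([f[0] for f in frames])
        steps = np.diff(idx)
        step = stream.attrs.get("frame_step") or (int(steps.min()) if len(steps) else 1)
        for (i0, c0), (i1, c1), d in zip(frames[:-1], frames[1:], steps):
            if d != step:
                continue  # gap: not consecutive after down-sampling
            if len(c0) == 0 or len(c1) == 0:
                val = 0.0 if params.empty_frame_policy == "zero" else np.nan
            else:
                val = params.k * symmetric_hausdorff(c1, c0)
            rows.append(
                {**meta, "pair_index": int(i1), "unrest_px": val,
                 "n_boxes": len(c1), "n_boxes_prev": len(c0)}
            )
    out = pd.DataFrame(rows, columns=keys + ["pair_index", "unrest_px", "n_boxes", "n_boxes_prev"])
    out.attrs["k"] = params.k
    return out


def _frames_of_segment(grp: pd.DataFrame) -> list[tuple[int, np.ndarray]]:
    """(frame_index, centroid array) per frame, sorted, empty frames kept."""
    out = []
    for fidx, rows in grp.groupby("frame_index", sort=True):
        box = rows[["x_min", "y_min", "x_max", "y_max"]].to_numpy(dtype=float)
        box = box[~np.isnan(box).any(axis=1)]
        cent = np.column_stack(((box[:, 0] + box[:, 2]) / 2, (box[:, 1] + box[:, 3]) / 2)) \
            if len(box) else np.empty((0, 2))
        out.append((int(fidx), cent))
    return out


def aggregate_unrest(
    series: pd.DataFrame,
    design: ExperimentDesign,
    unit: str = "window",
) -> pd.DataFrame:
    """Aggregate per-pair unrest to (light, temperature) treatment cells.

    The statistical unit is the mean unrest over one observation window
    (``unit="window"``: one value per experiment x replicate x day x
    session x compartment block), which gives balanced replicate counts per
    cell; ``unit="pair"`` keeps raw pairs.  Returns one row per cell with
    the mean, SD and n of the unit-level values; cells with no data are
    absent from the table rather than reported as zero.
    """
    if series.empty:
        return pd.DataFrame(columns=["light", "temperature", "mean_unrest_px", "sd", "n"])
    df = series.dropna(subset=["unrest_px"]).copy()
    df["light"] = [
        design.light_of(e, c) for e, c in zip(df["experiment_id"], df["compartment"])
    ]
    df["temperature"] = [design.thermal_of(e) for e in df["experiment_id"]]
    if unit == "window":
        unit_keys = ["light", "temperature", "experiment_id", "replicate", "day", "compartment"]
        if "window" in df.columns:
            unit_keys.append("window")
        elif "session" in df.columns:
            unit_keys.append("session")
        units = df.groupby(unit_keys, dropna=False)["unrest_px"].mean().reset_index()
    elif unit == "pair":
        units = df.rename(columns={"pair_index": "unit"})
    else:
        raise ValueError("unit must be 'window' or 'pair'")
    agg = (
        units.groupby(["light", "temperature"])["unrest_px"]
        .agg(mean_unrest_px="mean", sd="std", n="count")
        .reset_index()
    )
    return agg


def window_unrest_means(series: pd.DataFrame, design: ExperimentDesign) -> pd.DataFrame:
    """Window-level mean unrest with treatment labels (the ANOVA unit)."""
    df = series.dropna(subset=["unrest_px"]).copy()
    if df.empty:
        return pd.DataFrame(columns=["light", "temperature", "unrest_px"])
    df["light"] = [
        design.light_of(e, c) for e, c in zip(df["experiment_id"], df["compartment"])
    ]
    df["temperature"] = [design.thermal_of(e) for e in df["experiment_id"]]
    unit_keys = ["light", "temperature", "experiment_id", "replicate", "day", "compartment"]
    if "window" in df.columns:
        unit_keys.append("window")
    elif "session" in df.columns:
        unit_keys.append("session")
    return df.groupby(unit_keys, dropna=False)["unrest_px"].mean().reset_index()
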