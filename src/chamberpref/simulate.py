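"""Agent-based simulator of hens in the three-compartment preference chamber.

Each bird is an independent continuous-time Markov chain on the compartment
adjacency graph: from compartment ``c`` it jumps to an adjacent compartment
``d`` with rate proportional to ``d``'s preference weight.  Because the
jump rates satisfy detailed balance, the long-run occupancy of a fully
connected chamber is exactly proportional to the preference weights — which
is what makes simulated preference recoverable by the occupancy pipeline
and analytically checkable (:func:`stationary_occupancy`).

Within a compartment a bird's centroid follows a reflected Gaussian random
walk whose step scale carries the activity level (scaled per thermal
condition).  The observation model mimics a near-perfect detector: centroid
jitter, a small per-bird miss probability, and — the one systematic error
the detector makes — an occasional stale double-detection in the
just-vacated compartment when a bird crosses a doorway.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .occupancy import DEFAULT_DOOR_EDGES
from .streams import (
    COMPARTMENTS,
    DETECTION_COLUMNS,
    FRAME_HEIGHT,
    FRAME_WIDTH,
    LIGHTS,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate",
    "stationary_occupancy",
    "make_validation_fixture",
    "load_scenario",
]

_FULL_ADJACENCY = {"A": ["B", "C"], "B": ["A", "C"], "C": ["A", "B"]}

_SESSION_START_S = {"morning": 9.5 * 3600, "afternoon": 15.0 * 3600}


@dataclass
class SimConfig:
    """Parameters of one simulated monitoring session.

    Preference enters through per-light weights mapped onto compartments by
    ``light_map``; the stationary compartment occupancy is proportional to
    the mapped weights (fully connected chamber).  ``switch_rate`` is the
    expected number of compartment changes per bird-hour at stationarity —
    real hens' rates are unreported, so the default is an order-of-magnitude
    guess.  ``activity_scale`` multiplies the within-compartment step scale
    per thermal condition.
    """

    seed: int
    flock_size: int = 6
    light_weights: Mapping[str, float] = field(
        default_factory=lambda: {"white": 1.0, "green": 1.0, "red": 1.0}
    )
    light_map: Mapping[str, str] = field(
        default_factory=lambda: {"A": "white", "B": "green", "C": "red"}
    )
    thermal: str = "neutral"
    switch_rate: float = 12.0  # compartment changes per bird-hour
    within_step_px: float = 6.0  # per-frame step SD, pixels
    activity_scale: Mapping[str, float] = field(
        default_factory=lambda: {"hot": 1.0, "neutral": 1.0, "cold": 1.0}
    )
    miss_prob: float = 0.002
    double_prob: float = 0.5  # per doorway crossing
    double_duration_s: float = 0.5  # how long a stale double-detection persists
    jitter_px: float = 2.0
    fps: float = 15.0
    duration_s: float = 7200.0
    adjacency: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in _FULL_ADJACENCY.items()}
    )
    box_size: tuple[float, float] = (80.0, 60.0)
    frame_size: tuple[float, float] = (FRAME_WIDTH, FRAME_HEIGHT)
    start_compartments: Sequence[str] | None = None
    # stream metadata stamped on the emitted CSV rows
    experiment_id: int = 1
    replicate: int = 1
    day: int = 1
    session: str = "morning"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")
        if any(w <= 0 for w in self.light_weights.values()):
            raise ValueError("preference weights must be positive")
        for p, name in (
            (self.miss_prob, "miss_prob"),
            (self.double_prob, "double_prob"),
        ):
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not self.fps > 0:
            raise ValueError("fps must be positive")
        if self.switch_rate < 0:
            raise ValueError("switch_rate must be non-negative")
        _check_connected(self.adjacency)

    def compartment_weights(self) -> dict[str, float]:
        """Preference weight of each compartment under the light rotation."""
        return {c: float(self.light_weights[self.light_map[c]]) for c in self.adjacency}

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))


@dataclass
class GroundTruth:
    """What actually happened: positions, true counts, and the transition log."""

    positions: pd.DataFrame  # frame_index, bird_id, compartment, x, y
    counts: pd.DataFrame  # frame_index, compartment, count
    transitions: pd.DataFrame  # frame_index, bird_id, from, to, doubled


def _check_connected(adjacency: Mapping[str, Sequence[str]]) -> None:
    comps = list(adjacency)
    if not comps:
        raise ValueError("empty adjacency")
    seen = {comps[0]}
    stack = [comps[0]]
    while stack:
        for nb in adjacency[stack.pop()]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    if seen != set(comps):
        raise ValueError(f"adjacency graph is disconnected: reached {sorted(seen)}")


def _generator_matrix(config: SimConfig, rate_scale: float = 1.0) -> tuple[list[str], np.ndarray]:
    comps = sorted(config.adjacency)
    w = config.compartment_weights()
    n = len(comps)
    Q = np.zeros((n, n))
    for i, c in enumerate(comps):
        for d in config.adjacency[c]:
            Q[i, comps.index(d)] = rate_scale * w[d]
        Q[i, i] = -Q[i].sum()
    return comps, Q


def stationary_occupancy(config: SimConfig) -> dict[str, float]:
    """Exact long-run fraction of time a bird spends in each compartment.

    Solves the global balance equations pi Q = 0 of the configured chain;
    independent of the overall switch rate.  Raises for a disconnected
    (reducible) chain.
    """
    comps, Q = _generator_matrix(config)
    if config.switch_rate == 0:
        raise ValueError("chain with switch_rate=0 has no unique stationary law")
    # null space of Q^T: pi Q = 0, sum(pi) = 1
    A = np.vstack([Q.T, np.ones(len(comps))])
    b = np.zeros(len(comps) + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    if pi.min() < -1e-9:
        raise ValueError("chain appears reducible: no positive stationary law")
    pi = np.clip(pi, 0, None)
    pi = pi / pi.sum()
    return dict(zip(comps, pi))


def _rate_scale_per_second(config: SimConfig) -> float:
    """Scale jump rates so stationary-mean jumps per bird-hour = switch_rate."""
    if config.switch_rate == 0:
        return 0.0
    comps, Q = _generator_matrix(config)
    pi = stationary_occupancy(config)
    exit_rates = {c: -Q[i, i] for i, c in enumerate(comps)}  # at rate_scale=1
    mean_rate = sum(pi[c] * exit_rates[c] for c in comps)
    return (config.switch_rate / mean_rate) / 3600.0


def _door_edge(comp: str, other: str) -> str:
    return DEFAULT_DOOR_EDGES.get((comp, other), "right")


def _entry_point(
    comp: str, came_from: str, rng: np.random.Generator, frame_size, margin_x, margin_y
) -> np.ndarray:
    """A point just inside ``comp``'s door edge facing ``came_from``."""
    W, H = frame_size
    edge = _door_edge(comp, came_from)
    u = rng.uniform(0.35, 0.65)  # doors sit mid-edge
    if edge == "left":
        return np.array([margin_x, margin_y + u * (H - 2 * margin_y)])
    if edge == "right":
        return np.array([W - margin_x, margin_y + u * (H - 2 * margin_y)])
    if edge == "top":
        return np.array([margin_x + u * (W - 2 * margin_x), margin_y])
    return np.array([margin_x + u * (W - 2 * margin_x), H - margin_y])


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold a free walk into [lo, hi] by specular reflection."""
    L = hi - lo
    y = np.mod(x - lo, 2 * L)
    return lo + L - np.abs(y - L)


def simulate(config: SimConfig) -> tuple[GroundTruth, pd.DataFrame]:
    """Run one session; return the ground truth and the detection stream.

    The detection stream is a DataFrame in the canonical detection-CSV
    layout (one row per box, empty-frame rows preserved), bit-reproducible
    for a given config.
    """
    rng = np.random.default_rng(config.seed)
    comps = sorted(config.adjacency)
    n_frames = config.n_frames
    fps = config.fps
    W, H = config.frame_size
    bw, bh = config.box_size
    margin_x, margin_y = bw / 2, bh / 2
    step_sd = config.within_step_px * float(config.activity_scale.get(config.thermal, 1.0))
    rate_scale = _rate_scale_per_second(config)
    w = config.compartment_weights()

    if config.start_compartments is not None:
        if len(config.start_compartments) != config.flock_size:
            raise ValueError("start_compartments must list one compartment per bird")
        starts = list(config.start_compartments)
    elif config.switch_rate > 0:
        pi = stationary_occupancy(config)
        starts = list(rng.choice(comps, size=config.flock_size, p=[pi[c] for c in comps]))
    else:
        starts = list(rng.choice(comps, size=config.flock_size))

    duration = n_frames / fps
    frame_times = np.arange(n_frames) / fps

    pos = np.empty((config.flock_size, n_frames, 2))
    comp_idx = np.empty((config.flock_size, n_frames), dtype=int)
    transitions: list[dict] = []

    for bird in range(config.flock_size):
        # --- jump chain ---------------------------------------------------
        c = starts[bird]
        t = 0.0
        jump_times: list[float] = []
        jump_to: list[str] = []
        while rate_scale > 0:
            neighbors = list(config.adjacency[c])
            total = rate_scale * sum(w[d] for d in neighbors)
            t += rng.exponential(1.0 / total)
            if t >= duration:
                break
            probs = np.array([w[d] for d in neighbors])
            nxt = str(rng.choice(neighbors, p=probs / probs.sum()))
            jump_times.append(t)
            jump_to.append(nxt)
            c = nxt
        # compartment per frame instant
        seq = [starts[bird]] + jump_to
        which = np.searchsorted(np.array(jump_times), frame_times, side="right")
        comp_idx[bird] = [comps.index(seq[k]) for k in which]

        # --- positions: reflected walk per same-compartment run -----------
        boundaries = np.flatnonzero(np.diff(comp_idx[bird]) != 0) + 1
        run_starts = np.concatenate([[0], boundaries])
        run_ends = np.concatenate([boundaries, [n_frames]])
        for r, (s, e) in enumerate(zip(run_starts, run_ends)):
            cur = comps[comp_idx[bird][s]]
            if r == 0:
                entry = np.array(
                    [
                        rng.uniform(margin_x, W - margin_x),
                        rng.uniform(margin_y, H - margin_y),
                    ]
                )
            else:
                prev = comps[comp_idx[bird][s - 1]]
                entry = _entry_point(cur, prev, rng, (W, H), margin_x, margin_y)
                transitions.append(
                    {
                        "frame_index": int(s),
                        "bird_id": bird,
                        "from": prev,
                        "to": cur,
                        "doubled": False,  # filled below
                    }
                )
            steps = rng.normal(0.0, step_sd, size=(e - s, 2))
            steps[0] = 0.0
            free = entry + np.cumsum(steps, axis=0)
            pos[bird, s:e, 0] = _reflect(free[:, 0], margin_x, W - margin_x)
            pos[bird, s:e, 1] = _reflect(free[:, 1], margin_y, H - margin_y)

    # --- true counts -------------------------------------------------------
    counts_mat = np.zeros((n_frames, len(comps)), dtype=int)
    for bird in range(config.flock_size):
        np.add.at(counts_mat, (np.arange(n_frames), comp_idx[bird]), 1)

    # --- observation model -------------------------------------------------
    n_dup_frames = int(round(config.double_duration_s * fps))
    doubles: list[tuple[int, str, np.ndarray]] = []  # (frame, compartment, centroid)
    for tr in transitions:
        if config.double_prob > 0 and rng.random() < config.double_prob:
            tr["doubled"] = True
            ghost = _entry_point(
                tr["from"], tr["to"], rng, (W, H), margin_x, margin_y
            )
            for f in range(tr["frame_index"], min(tr["frame_index"] + max(n_dup_frames, 1), n_frames)):
                doubles.append((f, tr["from"], ghost))

    missed = (
        rng.random((config.flock_size, n_frames)) < config.miss_prob
        if config.miss_prob > 0
        else np.zeros((config.flock_size, n_frames), dtype=bool)
    )
    jitter = (
        rng.normal(0.0, config.jitter_px, size=(config.flock_size, n_frames, 2))
        if config.jitter_px > 0
        else np.zeros((config.flock_size, n_frames, 2))
    )

    det_frames: list[np.ndarray] = []
    det_comps: list[np.ndarray] = []
    det_cent: list[np.ndarray] = []
    for bird in range(config.flock_size):
        keep = ~missed[bird]
        det_frames.append(np.flatnonzero(keep))
        det_comps.append(comp_idx[bird][keep])
        det_cent.append(pos[bird][keep] + jitter[bird][keep])
    frames_arr = np.concatenate(det_frames)
    comps_arr = np.concatenate(det_comps)
    cents = np.concatenate(det_cent)
    if doubles:
        frames_arr = np.concatenate([frames_arr, [d[0] for d in doubles]])
        comps_arr = np.concatenate([comps_arr, [comps.index(d[1]) for d in doubles]])
        cents = np.concatenate([cents, np.array([d[2] for d in doubles])])

    cents[:, 0] = np.clip(cents[:, 0], margin_x, W - margin_x)
    cents[:, 1] = np.clip(cents[:, 1], margin_y, H - margin_y)

    t0 = _SESSION_START_S.get(config.session, 0.0)
    det = pd.DataFrame(
        {
            "experiment_id": config.experiment_id,
            "replicate": config.replicate,
            "day": config.day,
            "session": config.session,
            "compartment": np.array(comps, dtype=object)[comps_arr],
            "frame_index": frames_arr,
            "timestamp_s": t0 + frames_arr / fps,
            "x_min": cents[:, 0] - bw / 2,
            "y_min": cents[:, 1] - bh / 2,
            "x_max": cents[:, 0] + bw / 2,
            "y_max": cents[:, 1] + bh / 2,
        }
    )

    # explicit empty-frame records for (frame, compartment) with no detection
    present = np.zeros((n_frames, len(comps)), dtype=bool)
    present[frames_arr, comps_arr] = True
    empty_f, empty_c = np.nonzero(~present)
    if len(empty_f):
        det = pd.concat(
            [
                det,
                pd.DataFrame(
                    {
                        "experiment_id": config.experiment_id,
                        "replicate": config.replicate,
                        "day": config.day,
                        "session": config.session,
                        "compartment": np.array(comps, dtype=object)[empty_c],
                        "frame_index": empty_f,
                        "timestamp_s": t0 + empty_f / fps,
                        "x_min": np.nan,
                        "y_min": np.nan,
                        "x_max": np.nan,
                        "y_max": np.nan,
                    }
                ),
            ],
            ignore_index=True,
        )
    det = det.sort_values(["compartment", "frame_index", "x_min"], kind="stable")
    det = det[DETECTION_COLUMNS].reset_index(drop=True)
    det.attrs["fps"] = fps
    det.attrs["frame_step"] = 1

    positions = pd.DataFrame(
        {
            "frame_index": np.tile(np.arange(n_frames), config.flock_size),
            "bird_id": np.repeat(np.arange(config.flock_size), n_frames),
            "compartment": np.array(comps, dtype=object)[comp_idx.reshape(-1)],
            "x": pos[:, :, 0].reshape(-1),
            "y": pos[:, :, 1].reshape(-1),
        }
    )
    counts = pd.DataFrame(
        {
            "frame_index": np.repeat(np.arange(n_frames), len(comps)),
            "compartment": np.tile(np.array(comps, dtype=object), n_frames),
            "count": counts_mat.reshape(-1),
        }
    )
    trans = pd.DataFrame(
        transitions, columns=["frame_index", "bird_id", "from", "to", "doubled"]
    )
    return GroundTruth(positions=positions, counts=counts, transitions=trans), det


def make_validation_fixture(
    n_scenes: int,
    n_overcounts: int,
    seed: int,
    config: SimConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Aligned (true, predicted) per-frame count sequences for validation.

    True counts are drawn from the flock's stationary occupancy (each bird
    independently in a compartment, the validated frame showing one
    compartment chosen uniformly), so between zero and ``flock_size`` birds
    appear per frame.  Exactly ``n_overcounts`` frames, chosen at random,
    are over-counted by one; all other predictions are exact — the error
    structure of a detector whose only failure mode is an occasional
    doorway double-detection.
    """
    if n_overcounts > n_scenes:
        raise ValueError("more over-count errors than scenes")
    rng = np.random.default_rng(seed)
    config = config or SimConfig(seed=seed)
    pi = stationary_occupancy(config)
    comps = sorted(pi)
    probs = np.array([pi[c] for c in comps])
    # occupancy of one monitored compartment: Binomial(flock, p_comp)
    which = rng.integers(0, len(comps), size=n_scenes)
    true = rng.binomial(config.flock_size, probs[which])
    pred = true.copy()
    err_at = rng.choice(n_scenes, size=n_overcounts, replace=False)
    pred[err_at] += 1
    return true, pred


def load_scenario(name: str, seed: int, **overrides) -> SimConfig:
    """Load a named scenario preset (``thermoneutral``, ``cold``, ``hot``).

    Presets carry the light-preference weights and activity scaling of the
    three thermal conditions; any field can be overridden by keyword.
    """
    ref = resources.files("chamberpref") / "scenarios" / f"{name}.yaml"
    with ref.open() as fh:
        d = yaml.safe_load(fh)
    d.update(overrides)
    return SimConfig(seed=seed, **d)
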