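"""Adsorption-state segmentation of dye–nanoparticle time series.

A dye is *near the surface* while its COM-to-surface distance is at most the
adsorption threshold (default 5 Å).  Maximal near-surface runs, with brief
excursions shorter than a gap tolerance merged, form *episodes*; each episode
is labelled by duration and by how often the planar dye core sits parallel to
the local surface:

* ``A``  — stable adsorption: long enough (≥ ``min_A_duration``) and parallel
  in at least ``parallel_fraction_A`` of its frames;
* ``T``  — transient electrostatic trapping: the core essentially never turns
  parallel (parallel fraction below ``parallel_fraction_T_max``).  Such
  events are typically short (≲ 2 ns); a long never-parallel episode is still
  ``T`` but flagged;
* ``RA`` — reorientation/repositioning near the surface: everything between.

The dipole angle θ is reported per segment as a corroborating observable but
never used as a classification criterion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .trajio import register_schema

__all__ = [
    "ClassifierConfig",
    "StateSegment",
    "near_surface_episodes",
    "label_episode",
    "segment_states",
    "segments_from_metrics",
    "adsorbed_percentage",
    "average_over_repetitions",
    "round_half_up",
    "frame_labels",
]


@dataclass
class ClassifierConfig:
    """Thresholds of the episode classifier (lengths Å, durations ns)."""

    adsorption_threshold: float = 5.0
    parallel_tolerance: float = 30.0
    gap_tolerance: float = 0.2
    min_A_duration: float = 5.0
    max_T_duration: float = 2.0
    parallel_fraction_A: float = 0.8
    parallel_fraction_T_max: float = 0.2

    def __post_init__(self) -> None:
        if self.adsorption_threshold <= 0:
            raise ValueError("adsorption threshold must be > 0")
        for f in (self.parallel_fraction_A, self.parallel_fraction_T_max):
            if not 0 < f <= 1:
                raise ValueError("parallel fractions must be in (0, 1]")
        if self.min_A_duration <= self.max_T_duration:
            raise ValueError("min_A_duration must exceed max_T_duration")
        if self.gap_tolerance < 0:
            raise ValueError("gap tolerance must be >= 0")


@dataclass
class StateSegment:
    """One labelled near-surface episode of a dye–nanoparticle pair."""

    dye: str
    np: str
    label: str  # A | RA | T
    start: float  # ns, first frame time of the episode
    end: float  # ns, last frame time of the episode
    mean_surface_distance: float
    parallel_fraction: float
    mean_theta: float
    long_T: bool = False  # T episode exceeding max_T_duration, flagged

    @property
    def duration(self) -> float:
        return self.end - self.start


register_schema(
    "state_segments",
    [
        "dye",
        "np",
        "label",
        "start",
        "end",
        "mean_surface_distance",
        "parallel_fraction",
        "mean_theta",
        "long_T",
    ],
    formats={"start": "%.4f", "end": "%.4f"},
    record_type=StateSegment,
)


def near_surface_episodes(
    times: np.ndarray, distances: np.ndarray, config: ClassifierConfig
) -> list[tuple[int, int]]:
    """Maximal near-surface runs as inclusive frame-index intervals.

    Runs with ``distance <= adsorption_threshold`` separated by excursions
    shorter than ``gap_tolerance`` (in time) are merged.
    """
    times = np.asarray(times, dtype=float)
    distances = np.asarray(distances, dtype=float)
    if times.size == 0:
        raise ValueError("empty distance series")
    if times.shape != distances.shape:
        raise ValueError("times and distances are misaligned")
    near = distances <= config.adsorption_threshold
    if not near.any():
        return []
    d = np.diff(near.astype(int))
    starts = list(np.where(d == 1)[0] + 1)
    ends = list(np.where(d == -1)[0])
    if near[0]:
        starts.insert(0, 0)
    if near[-1]:
        ends.append(len(near) - 1)
    runs = list(zip(starts, ends))
    merged = [runs[0]]
    for s, e in runs[1:]:
        gap = times[s] - times[merged[-1][1]]
        if gap < config.gap_tolerance:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def label_episode(
    times: np.ndarray,
    episode: tuple[int, int],
    distances: np.ndarray,
    parallel_angles: np.ndarray,
    thetas: np.ndarray | None,
    config: ClassifierConfig,
    dye: str = "",
    np_label: str = "",
) -> StateSegment:
    """Label one episode as A, RA or T (see module docstring for the rules)."""
    times = np.asarray(times, dtype=float)
    if not (
        len(times) == len(distances) == len(parallel_angles)
        and (thetas is None or len(thetas) == len(times))
    ):
        raise ValueError("metric series are misaligned")
    i0, i1 = episode
    sl = slice(i0, i1 + 1)
    duration = times[i1] - times[i0]
    par = np.asarray(parallel_angles, dtype=float)[sl] <= config.parallel_tolerance
    frac = float(par.mean())
    if duration >= config.min_A_duration and frac >= config.parallel_fraction_A:
        label, long_t = "A", False
    elif frac < config.parallel_fraction_T_max:
        label, long_t = "T", duration > config.max_T_duration
    else:
        label, long_t = "RA", False
    theta_mean = (
        float(np.asarray(thetas, dtype=float)[sl].mean()) if thetas is not None
        else float("nan")
    )
    return StateSegment(
        dye=dye,
        np=np_label,
        label=label,
        start=float(times[i0]),
        end=float(times[i1]),
        mean_surface_distance=float(np.asarray(distances, dtype=float)[sl].mean()),
        parallel_fraction=frac,
        mean_theta=theta_mean,
        long_T=long_t,
    )


def segment_states(
    times: np.ndarray,
    distances: np.ndarray,
    parallel_angles: np.ndarray,
    thetas: np.ndarray | None,
    config: ClassifierConfig,
    dye: str = "",
    np_label: str = "",
) -> list[StateSegment]:
    """Segment one dye–nanoparticle metric series into labelled episodes."""
    episodes = near_surface_episodes(times, distances, config)
    return [
        label_episode(
            times, ep, distances, parallel_angles, thetas, config, dye, np_label
        )
        for ep in episodes
    ]


def segments_from_metrics(
    metrics: pd.DataFrame, config: ClassifierConfig
) -> list[StateSegment]:
    """Run the classifier on every (dye, np) series of a metrics table."""
    out: list[StateSegment] = []
    for (dye, np_label), sub in metrics.groupby(["dye", "np"], sort=True):
        sub = sub.sort_values("time_ns")
        out.extend(
            segment_states(
                sub["time_ns"].to_numpy(),
                sub["surface_dist_A"].to_numpy(),
                sub["parallel_angle_deg"].to_numpy(),
                sub["theta_deg"].to_numpy() if "theta_deg" in sub else None,
                config,
                dye=str(dye),
                np_label=str(np_label),
            )
        )
    return out


def _union_measure(intervals: Iterable[tuple[float, float]]) -> float:
    ivs = sorted(intervals)
    total, cur_s, cur_e = 0.0, None, None
    for s, e in ivs:
        if cur_s is None:
            cur_s, cur_e = s, e
        elif s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
    if cur_s is not None:
        total += cur_e - cur_s
    return total


def adsorbed_percentage(
    segments: Sequence[StateSegment],
    trajectory_length: float,
    count_states: frozenset[str] | set[str] = frozenset({"A", "RA"}),
) -> float:
    """Percentage of the run during which at least one dye is in a counted state.

    Overlapping segments of different dyes are counted once (union measure).
    ``count_states`` defaults to {A, RA}: both stable adsorption and
    near-surface reorientation keep a dye on the particle.
    """
    if trajectory_length <= 0:
        raise ValueError("trajectory length must be > 0")
    ivs = [(s.start, s.end) for s in segments if s.label in count_states]
    return 100.0 * _union_measure(ivs) / trajectory_length


def round_half_up(x: float) -> int:
    """Round to nearest integer with exact halves going up."""
    return int(math.floor(x + 0.5))


def average_over_repetitions(values: Sequence[float]) -> int:
    """Arithmetic mean of per-run percentages, rounded half-up to an integer."""
    if len(values) == 0:
        raise ValueError("need at least one repetition")
    return round_half_up(float(np.mean(values)))


def frame_labels(
    times: np.ndarray, segments: Sequence[StateSegment]
) -> np.ndarray:
    """Per-frame state labels implied by a segment list (``FREE`` elsewhere)."""
    times = np.asarray(times, dtype=float)
    out = np.array(["FREE"] * times.size, dtype=object)
    for s in segments:
        out[(times >= s.start) & (times <= s.end)] = s.label
    return out
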