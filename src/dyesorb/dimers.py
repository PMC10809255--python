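"""Stacking-dimer and transient-trimer detection and lifetime statistics.

Two dyes are in *stacking contact* while their planar-core COMs are within a
cutoff (default 6 Å) and their core-plane normals are parallel or
antiparallel within a tolerance (default 30°) — the geometry of face-to-face
π-stacked cores with the tails protruding.  A dye belongs to at most one
dimer at a time; simultaneous candidate contacts are resolved per frame in
favour of the smaller core distance.  Maximal exclusive-contact runs lasting
at least ``min_dimer_duration`` become :class:`DimerEvent`.

A third dye that satisfies the stacking contact with either member of a live
dimer marks a *transient trimer* interval; trimers are flagged, never
promoted to a stable species.

Events are classified by location (``matrix`` when the pair COM stays within
the matrix threshold of a particle surface, else ``solute``) and by end
reason (``dissociation`` — the contact breaks; ``desorption`` — the intact
pair leaves the surface; ``censored`` — the event reaches the final frame).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .states import StateSegment
from .trajio import register_schema

__all__ = [
    "DimerConfig",
    "DimerEvent",
    "TrimerInterval",
    "DimerStats",
    "stacking_contact",
    "detect_dimers",
    "detect_trimers",
    "classify_event",
    "classify_events",
    "dimer_statistics",
    "events_from_pair_metrics",
]


@dataclass
class DimerConfig:
    """Geometric and temporal thresholds of the dimer detector."""

    core_distance_cutoff: float = 6.0  # Å between core COMs
    stacking_tolerance: float = 30.0  # deg between core normals (folded)
    min_dimer_duration: float = 1.0  # ns
    matrix_threshold: float = 5.0  # Å pair-COM surface distance
    gap_tolerance: float = 0.2  # ns; contact flickers shorter than this merge

    def __post_init__(self) -> None:
        for name in ("core_distance_cutoff", "stacking_tolerance",
                     "min_dimer_duration", "matrix_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.gap_tolerance < 0:
            raise ValueError("gap_tolerance must be >= 0")


@dataclass
class DimerEvent:
    """One dimer episode of a dye pair."""

    pair: tuple[str, str]
    start: float  # ns, first frame time
    end: float  # ns, last frame time
    location: str | None = None  # solute | matrix
    end_reason: str | None = None  # dissociation | desorption | censored

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def pair_label(self) -> str:
        return f"{self.pair[0]}-{self.pair[1]}"


@dataclass
class TrimerInterval:
    """A transient third-dye contact with a live dimer."""

    members: tuple[str, str, str]  # (dimer i, dimer j, third dye)
    start: float
    end: float
    transient: bool = True


@dataclass
class DimerStats:
    """Per-system dimer statistics averaged over repetitions."""

    mean_dimer_count: float
    total_time: float  # mean over runs of summed event durations, ns
    mean_lifetime: float  # mean of pooled individual event durations, ns


register_schema(
    "dimer_events",
    ["pair", "start", "end", "location", "end_reason"],
    formats={"start": "%.4f", "end": "%.4f"},
)


def stacking_contact(
    core_dist: np.ndarray, stack_angle: np.ndarray, config: DimerConfig
) -> np.ndarray:
    """Per-frame stacking-contact indicator for one pair (or (F, P) arrays).

    ``stack_angle`` may be given in [0, 180]; it is folded so parallel and
    antiparallel normals both count as stacked.
    """
    ang = np.asarray(stack_angle, dtype=float)
    folded = np.minimum(ang, 180.0 - ang)
    return (np.asarray(core_dist, dtype=float) <= config.core_distance_cutoff) & (
        folded <= config.stacking_tolerance
    )


def _exclusive_contacts(
    pairs: Sequence[tuple[str, str]],
    core_dist: np.ndarray,
    contact: np.ndarray,
) -> np.ndarray:
    """Resolve per-frame exclusivity: greedy by ascending core distance."""
    f, p = contact.shape
    chosen = np.zeros_like(contact, dtype=bool)
    for fi in range(f):
        cand = np.where(contact[fi])[0]
        if cand.size == 0:
            continue
        used: set[str] = set()
        for pi in cand[np.argsort(core_dist[fi, cand], kind="stable")]:
            a, b = pairs[pi]
            if a in used or b in used:
                continue
            chosen[fi, pi] = True
            used.update((a, b))
    return chosen


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    if not mask.any():
        return []
    d = np.diff(mask.astype(int))
    starts = list(np.where(d == 1)[0] + 1)
    ends = list(np.where(d == -1)[0])
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask) - 1)
    return list(zip(starts, ends))


def detect_dimers(
    times: np.ndarray,
    pairs: Sequence[tuple[str, str]],
    core_dist: np.ndarray,
    stack_angle: np.ndarray,
    config: DimerConfig,
) -> list[DimerEvent]:
    """Detect dimer events from per-pair core distances and normal angles.

    ``core_dist`` and ``stack_angle`` have shape (frames, pairs), aligned with
    ``times``.  Exclusivity (a dye in at most one dimer per frame) is enforced
    before run extraction; runs shorter than ``min_dimer_duration`` are
    dropped.
    """
    times = np.asarray(times, dtype=float)
    contact = stacking_contact(core_dist, stack_angle, config)
    chosen = _exclusive_contacts(pairs, np.asarray(core_dist, float), contact)
    events: list[DimerEvent] = []
    for pi, pair in enumerate(pairs):
        runs = _runs(chosen[:, pi])
        if config.gap_tolerance > 0 and len(runs) > 1:
            merged = [runs[0]]
            for s, e in runs[1:]:
                if times[s] - times[merged[-1][1]] < config.gap_tolerance:
                    merged[-1] = (merged[-1][0], e)
                else:
                    merged.append((s, e))
            runs = merged
        for i0, i1 in runs:
            if times[i1] - times[i0] >= config.min_dimer_duration:
                events.append(
                    DimerEvent(pair=tuple(pair), start=float(times[i0]),
                               end=float(times[i1]))
                )
    events.sort(key=lambda e: (e.start, e.pair))
    return events


def detect_trimers(
    events: Sequence[DimerEvent],
    times: np.ndarray,
    pairs: Sequence[tuple[str, str]],
    core_dist: np.ndarray,
    stack_angle: np.ndarray,
    config: DimerConfig,
) -> list[TrimerInterval]:
    """Intervals where a third dye stacks on either member of a live dimer.

    Contacts are evaluated without exclusivity (the third dye is by
    definition in contact with an already-paired member).
    """
    times = np.asarray(times, dtype=float)
    contact = stacking_contact(core_dist, stack_angle, config)
    pair_index = {tuple(p): k for k, p in enumerate(pairs)}
    dyes = sorted({d for p in pairs for d in p})
    out: list[TrimerInterval] = []
    for ev in events:
        a, b = ev.pair
        in_event = (times >= ev.start) & (times <= ev.end)
        for third in dyes:
            if third in ev.pair:
                continue
            touch = np.zeros_like(in_event)
            for member in (a, b):
                key = tuple(sorted((member, third)))
                if key in pair_index:
                    touch |= contact[:, pair_index[key]]
            mask = in_event & touch
            for i0, i1 in _runs(mask):
                out.append(
                    TrimerInterval(
                        members=(a, b, third),
                        start=float(times[i0]),
                        end=float(times[i1]),
                    )
                )
    out.sort(key=lambda t: (t.start, t.members))
    return out


def classify_event(
    event: DimerEvent,
    times: np.ndarray,
    pair_surface_dist: np.ndarray,
    partner_segments: Sequence[StateSegment],
    config: DimerConfig,
    adsorption_window: float = 1.0,
) -> DimerEvent:
    """Fill ``location`` and ``end_reason`` of a detected event.

    * location: ``matrix`` if the median pair-COM surface distance during the
      event is within ``matrix_threshold``, else ``solute``;
    * censored: the event reaches the final frame;
    * desorption: the intact pair's surface distance rises from within the
      matrix threshold to beyond twice it before the contact breaks;
    * dissociation: the contact breaks; the canonical signature is a break
      within ``matrix_threshold + 5 Å`` of the surface with one partner
      entering A/RA within ``adsorption_window`` ns, but any remaining broken
      contact is also recorded as a dissociation.
    """
    times = np.asarray(times, dtype=float)
    d = np.asarray(pair_surface_dist, dtype=float)
    sl = (times >= event.start) & (times <= event.end)
    location = "matrix" if np.median(d[sl]) <= config.matrix_threshold else "solute"

    if event.end >= times[-1]:
        reason = "censored"
    else:
        reason = None
        de = d[sl]
        near = np.where(de <= config.matrix_threshold)[0]
        if near.size and np.any(de[near[0]:] > 2.0 * config.matrix_threshold):
            reason = "desorption"
        if reason is None:
            # dissociation: break near the surface followed by prompt adsorption
            d_end = d[sl][-1]
            if d_end <= config.matrix_threshold + 5.0:
                for seg in partner_segments:
                    if (
                        seg.dye in event.pair
                        and seg.label in ("A", "RA")
                        and seg.start <= event.end + adsorption_window
                        and seg.end >= event.end
                    ):
                        reason = "dissociation"
                        break
            if reason is None:
                reason = "dissociation"  # plain contact breakage
    return DimerEvent(
        pair=event.pair,
        start=event.start,
        end=event.end,
        location=location,
        end_reason=reason,
    )


def classify_events(
    events: Sequence[DimerEvent],
    times: np.ndarray,
    pairs: Sequence[tuple[str, str]],
    pair_surface_dist: np.ndarray,
    segments: Sequence[StateSegment],
    config: DimerConfig,
) -> list[DimerEvent]:
    """Classify every event; ``pair_surface_dist`` has shape (frames, pairs)."""
    pair_index = {tuple(p): k for k, p in enumerate(pairs)}
    out = []
    for ev in events:
        col = pair_index[tuple(ev.pair)]
        out.append(
            classify_event(
                ev, times, np.asarray(pair_surface_dist)[:, col], segments, config
            )
        )
    return out


def events_from_pair_metrics(
    pair_df: pd.DataFrame,
    config: DimerConfig,
    segments: Sequence[StateSegment] = (),
) -> tuple[list[DimerEvent], list[TrimerInterval]]:
    """Full detection + classification from a :func:`geometry.pair_metrics` table."""
    pairs = sorted(
        {(r.dye_i, r.dye_j) for r in pair_df[["dye_i", "dye_j"]].itertuples()}
    )
    times = np.sort(pair_df["time_ns"].unique())
    f, p = len(times), len(pairs)
    core = np.full((f, p), np.inf)
    ang = np.full((f, p), 90.0)
    surf = np.full((f, p), np.inf)
    t_index = {t: i for i, t in enumerate(times)}
    p_index = {pr: i for i, pr in enumerate(pairs)}
    for r in pair_df.itertuples():
        fi, pi = t_index[r.time_ns], p_index[(r.dye_i, r.dye_j)]
        core[fi, pi] = r.core_dist_A
        ang[fi, pi] = r.stack_angle_deg
        surf[fi, pi] = r.pair_surface_dist_A
    events = detect_dimers(times, pairs, core, ang, config)
    events = classify_events(events, times, pairs, surf, segments, config)
    trimers = detect_trimers(events, times, pairs, core, ang, config)
    return events, trimers


def dimer_statistics(
    events_by_run: Mapping[str, Sequence[DimerEvent]]
) -> DimerStats:
    """Mean dimer count, mean total dimer time and pooled mean lifetime.

    The pooled mean lifetime is the mean of all individual event durations
    across runs; note it generally differs from total_time / mean_count.
    """
    if len(events_by_run) == 0:
        raise ValueError("need at least one run")
    counts = [len(v) for v in events_by_run.values()]
    totals = [sum(e.duration for e in v) for v in events_by_run.values()]
    pooled = [e.duration for v in events_by_run.values() for e in v]
    return DimerStats(
        mean_dimer_count=float(np.mean(counts)),
        total_time=float(np.mean(totals)),
        mean_lifetime=float(np.mean(pooled)) if pooled else 0.0,
    )
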