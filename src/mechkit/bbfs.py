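"""Bond breaking/formation search over multi-frame trajectories.

The binary adjacency matrix is monitored frame by frame; a persistent flip
of an off-diagonal element is a bond event.  Short-lived flips that revert
within a debounce window are treated as vibrational chatter and discarded.
Events close in time are grouped into reaction windows, and one
transition-state candidate geometry (the temporal midpoint frame of the
window) is extracted per group, together with the adjacency matrices just
before and after the window so that downstream screening can identify the
reaction each candidate mediates.

The contract ends at candidate extraction: the ``active_atoms`` of each
candidate name the atoms an external saddle-point optimizer would relax
last, but no optimization is performed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .geometry import Geometry, Trajectory
from .molgraph import ConnectivityGraph, build_connectivity, DEFAULT_SCALE

__all__ = [
    "BondEvent",
    "TSCandidate",
    "detect_events",
    "group_events",
    "extract_candidates",
    "DEFAULT_DEBOUNCE",
    "DEFAULT_GAP",
]

DEFAULT_DEBOUNCE = 5
DEFAULT_GAP = 10


@dataclass(frozen=True)
class BondEvent:
    """A persistent adjacency flip: bond (i, j) formed or broken at ``frame``."""

    frame: int
    pair: tuple[int, int]
    kind: Literal["formed", "broken"]

    def __post_init__(self):
        i, j = self.pair
        if not i < j:
            raise ValueError(f"pair must be ordered i < j, got {self.pair}")


@dataclass
class TSCandidate:
    """One reaction window: its events, midpoint geometry and end-point graphs."""

    window: tuple[int, int]
    events: list[BondEvent]
    geometry: Geometry
    active_atoms: set[int]
    reactant_graph: ConnectivityGraph
    product_graph: ConnectivityGraph
    boundary_flag: bool = False
    source: str = ""


def _adjacency_series(traj: Trajectory, scale: float) -> np.ndarray:
    """Boolean array (n_frames, n, n) of per-frame bond matrices."""
    mats = [build_connectivity(f, scale).A.astype(bool) for f in traj.frames]
    return np.array(mats)


def _filtered_transitions(states: np.ndarray, debounce: int) -> list[int]:
    """Frames where a boolean series flips persistently.

    A run of the opposite state shorter than ``debounce`` frames is ignored
    (the state is considered unchanged) unless the run reaches the end of
    the trajectory, in which case it never reverted and counts.
    Returns the first frame of each accepted new state.
    """
    n = len(states)
    transitions: list[int] = []
    current = states[0]
    f = 1
    while f < n:
        if states[f] == current:
            f += 1
            continue
        # measure the run of the new state
        run_start = f
        new_state = states[f]
        while f < n and states[f] == new_state:
            f += 1
        run_len = f - run_start
        at_end = f == n
        if run_len >= debounce or at_end:
            transitions.append(run_start)
            current = new_state
        # else: chatter, state unchanged
    return transitions


def detect_events(
    traj: Trajectory,
    scale: float = DEFAULT_SCALE,
    debounce: int = DEFAULT_DEBOUNCE,
) -> list[BondEvent]:
    """Scan the adjacency series and return persistent bond events by frame."""
    adj = _adjacency_series(traj, scale)
    n = traj.n_atoms
    events: list[BondEvent] = []
    for i in range(n):
        for j in range(i + 1, n):
            series = adj[:, i, j]
            if series.min() == series.max():
                continue  # never flips
            for frame in _filtered_transitions(series, debounce):
                kind = "formed" if series[frame] else "broken"
                events.append(BondEvent(frame=frame, pair=(i, j), kind=kind))
    events.sort(key=lambda e: (e.frame, e.pair))
    return events


def group_events(events: list[BondEvent], gap: int = DEFAULT_GAP) -> list[list[BondEvent]]:
    """Partition frame-sorted events into groups separated by more than ``gap``."""
    groups: list[list[BondEvent]] = []
    for ev in sorted(events, key=lambda e: (e.frame, e.pair)):
        if groups and ev.frame - groups[-1][-1].frame <= gap:
            groups[-1].append(ev)
        else:
            groups.append([ev])
    return groups


def _apply_events(A: np.ndarray, events: list[BondEvent]) -> np.ndarray:
    out = A.copy()
    for ev in events:
        i, j = ev.pair
        val = 1.0 if ev.kind == "formed" else 0.0
        out[i, j] = out[j, i] = val
    return out


def extract_candidates(
    traj: Trajectory,
    groups: list[list[BondEvent]],
    scale: float = DEFAULT_SCALE,
    source: str = "",
) -> list[TSCandidate]:
    """One TS candidate per event group; null reactions are dropped.

    The candidate geometry is the frame at the temporal midpoint of the
    window.  The reactant graph is the debounce-filtered adjacency before
    the window (initial-frame adjacency with all earlier groups' events
    applied); the product graph applies the window's own events on top, so
    replaying the event list on the reactant graph reproduces the product
    graph by construction.  Groups whose flips cancel (reactant == product)
    are filtered out.  Windows touching a trajectory boundary are kept but
    flagged.
    """
    A0 = build_connectivity(traj.frames[0], scale).A
    r_ref = build_connectivity(traj.frames[0], scale).r_ref
    candidates: list[TSCandidate] = []
    current = A0
    for group in groups:
        first = group[0].frame
        last = group[-1].frame
        reactant = current
        product = _apply_events(reactant, group)
        current = product
        if np.array_equal(reactant, product):
            continue
        mid = (first + last) // 2
        candidates.append(
            TSCandidate(
                window=(first, last),
                events=list(group),
                geometry=traj.frames[mid],
                active_atoms={a for ev in group for a in ev.pair},
                reactant_graph=ConnectivityGraph(A=reactant.copy(), r_ref=r_ref),
                product_graph=ConnectivityGraph(A=product.copy(), r_ref=r_ref),
                boundary_flag=(first <= 0 or last >= traj.n_frames - 1),
                source=source,
            )
        )
    return candidates
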