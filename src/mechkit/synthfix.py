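"""Synthetic trajectories with scripted bond events and toy reaction networks.

This module stands in for the molecular-dynamics and electronic-structure
stages of a mechanism-discovery workflow: it manufactures inputs whose
ground truth is known analytically, so the event detector, the screening
filters, the statistical-rate machinery and the stochastic kinetics solver
can each be validated without any quantum-chemistry engine.

A scripted trajectory moves selected atom pairs along linear distance
ramps that cross the bond-detection threshold at an exactly computable
frame, while every other atom jitters with seeded uniform noise whose
amplitude stays below the threshold margin of the non-event bonds.  Toy
networks come in four flavours with closed-form kinetics: a two-channel
branching well, a sequential decay chain, a catalytic cycle with a
reversible inhibitor (known elementary orders, including a negative one),
and a three-transition-state / two-intermediate elimination chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bbfs import BondEvent
from .geometry import Atom, Geometry, Trajectory
from .molgraph import DEFAULT_SCALE
from .network import ReactionNetwork, network_from_dict

__all__ = [
    "EventScript",
    "ScriptedEvent",
    "make_trajectory",
    "make_toy_network",
]


@dataclass
class ScriptedEvent:
    """Linear ramp of the (i, j) distance from start_dist to end_dist."""

    pair: tuple[int, int]
    kind: str  # "broken" | "formed"
    start_frame: int
    end_frame: int
    start_dist: float
    end_dist: float


@dataclass
class EventScript:
    elements: list[str]
    base_coords: np.ndarray
    events: list[ScriptedEvent]
    n_frames: int
    vibration_amplitude: float = 0.01
    seed: int = 0
    scale: float = DEFAULT_SCALE

    def __post_init__(self):
        self.base_coords = np.asarray(self.base_coords, float)
        n = len(self.elements)
        used_atoms: set[int] = set()
        for ev in self.events:
            i, j = ev.pair
            if not (0 <= i < j < n):
                raise ValueError(f"event pair {ev.pair} out of range or unordered")
            if not (0 <= ev.start_frame < ev.end_frame < self.n_frames):
                raise ValueError(
                    f"event window ({ev.start_frame}, {ev.end_frame}) outside "
                    f"trajectory of {self.n_frames} frames"
                )
            thr = self._threshold(ev.pair)
            lo, hi = sorted((ev.start_dist, ev.end_dist))
            if not lo < thr < hi:
                raise ValueError(
                    f"event on pair {ev.pair}: distances ({ev.start_dist}, "
                    f"{ev.end_dist}) must straddle the threshold {thr:.4f}"
                )
            if ev.kind == "broken" and ev.end_dist <= ev.start_dist:
                raise ValueError("a breaking event must increase the distance")
            if ev.kind == "formed" and ev.end_dist >= ev.start_dist:
                raise ValueError("a forming event must decrease the distance")
            if used_atoms & {i, j}:
                raise ValueError("scripted events must involve disjoint atoms")
            used_atoms |= {i, j}

    def _threshold(self, pair: tuple[int, int]) -> float:
        i, j = pair
        ri = Atom.from_symbol(self.elements[i]).r_cov
        rj = Atom.from_symbol(self.elements[j]).r_cov
        return self.scale * (ri + rj)

    def scripted_distance(self, ev: ScriptedEvent, frame: int) -> float:
        if frame <= ev.start_frame:
            return ev.start_dist
        if frame >= ev.end_frame:
            return ev.end_dist
        frac = (frame - ev.start_frame) / (ev.end_frame - ev.start_frame)
        return ev.start_dist + frac * (ev.end_dist - ev.start_dist)

    def ground_truth(self) -> list[BondEvent]:
        """Exact threshold-crossing frame per event from the linear ramp.

        A bond exists while the distance is strictly below the threshold,
        so a breaking event fires at the first frame with d >= threshold
        and a forming event at the first frame with d < threshold.
        """
        out = []
        for ev in self.events:
            thr = self._threshold(ev.pair)
            for frame in range(ev.start_frame, ev.end_frame + 1):
                d = self.scripted_distance(ev, frame)
                crossed = d >= thr if ev.kind == "broken" else d < thr
                if crossed:
                    out.append(BondEvent(frame=frame, pair=ev.pair, kind=ev.kind))
                    break
        return sorted(out, key=lambda e: (e.frame, e.pair))


def make_trajectory(script: EventScript) -> tuple[Trajectory, list[BondEvent]]:
    """Render the script into frames and return it with its ground truth.

    Every atom gets seeded uniform jitter of the stated amplitude; the
    second atom of each scripted pair is then repositioned along the pair
    axis so the scripted distance holds exactly.
    """
    rng = np.random.default_rng(script.seed)
    frames = []
    for f in range(script.n_frames):
        coords = script.base_coords + rng.uniform(
            -script.vibration_amplitude,
            script.vibration_amplitude,
            size=script.base_coords.shape,
        )
        for ev in script.events:
            i, j = ev.pair
            d = script.scripted_distance(ev, f)
            axis = script.base_coords[j] - script.base_coords[i]
            norm = np.linalg.norm(axis)
            if norm == 0:
                raise ValueError(f"scripted pair {ev.pair} has coincident base atoms")
            coords[j] = coords[i] + axis / norm * d
        frames.append(
            Geometry.from_symbols(script.elements, coords, label=f"frame {f}")
        )
    return Trajectory(frames), script.ground_truth()


# ---------------------------------------------------------------------------
# Toy networks with known kinetics

_FREQS_SMALL = [500.0, 1000.0, 1500.0, 2000.0, 3000.0]
_FREQS_TS = [450.0, 900.0, 1400.0, 1900.0]


def make_toy_network(kind: str, **params) -> ReactionNetwork:
    """Build a schema-valid toy network with analytically known kinetics.

    kinds:
      ``two_channel``    A -> B (k1), A -> C (k2); branching k1/(k1+k2).
      ``sequential``     A -> B -> C; p_B(t) has the textbook closed form.
      ``catalytic_cycle`` mass-action cycle with reversible CO inhibition;
                         elementary orders known by construction, CO < 0.
      ``vcn_like``       a chain of three transition states and two
                         intermediates between the reactant well and a
                         product sink, with energies/frequencies suited to
                         microcanonical rate evaluation.
    """
    builders = {
        "two_channel": _two_channel,
        "sequential": _sequential,
        "catalytic_cycle": _catalytic_cycle,
        "vcn_like": _vcn_like,
    }
    if kind not in builders:
        raise ValueError(f"unknown toy network kind {kind!r}")
    return network_from_dict(builders[kind](**params))


def _well(label, energy, sink=False, freqs=None):
    return {
        "label": label,
        "energy_kcal": energy,
        "freqs_cm": list(freqs or _FREQS_SMALL),
        "m_opt": 1,
        "sink": sink,
    }


def _ts(label, energy, a, b, freqs=None, imag=None):
    d = {
        "label": label,
        "energy_kcal": energy,
        "freqs_cm": list(freqs or _FREQS_TS),
        "m_opt": 1,
        "connects": [a, b],
    }
    if imag:
        d["imag_freq_cm"] = imag
    return d


def _two_channel(k1: float = 2.0, k2: float = 1.0) -> dict:
    return {
        "schema_version": 1,
        "reference": "A",
        "wells": [
            _well("A", 0.0),
            _well("B", -20.0, sink=True),
            _well("C", -15.0, sink=True),
        ],
        "transition_states": [
            _ts("TS1", 30.0, "A", "B"),
            _ts("TS2", 32.0, "A", "C"),
        ],
        "rates": [
            {"from": "A", "ts": "TS1", "k_s": k1},
            {"from": "A", "ts": "TS2", "k_s": k2},
        ],
    }


def _sequential(k1: float = 1.0, k2: float = 1.0) -> dict:
    return {
        "schema_version": 1,
        "reference": "A",
        "wells": [
            _well("A", 0.0),
            _well("B", -10.0),
            _well("C", -30.0, sink=True),
        ],
        "transition_states": [
            _ts("TS1", 25.0, "A", "B"),
            _ts("TS2", 20.0, "B", "C"),
        ],
        "rates": [
            {"from": "A", "ts": "TS1", "k_s": k1},
            {"from": "B", "ts": "TS2", "k_s": k2},
        ],
    }


def _catalytic_cycle(
    k_bind: float = 1e4,
    k_unbind: float = 1e3,
    k_addition: float = 1.0,
    k_hydrogenolysis: float = 50.0,
) -> dict:
    """Catalytic cycle with a reversible off-cycle inhibitor.

    cat + CO <-> catCO sequesters the catalyst (fast pre-equilibrium), so
    the steady-state product rate falls with CO: the fitted CO order is
    negative.  Alkene addition is rate-determining (order ~1); H2 enters
    after it (small positive order); the catalyst order is ~1.
    """
    return {
        "schema_version": 1,
        "reference": "cat",
        "wells": [_well("cat", 0.0)],
        "transition_states": [],
        "reactions": [
            {"label": "bind", "reactants": ["cat", "CO"],
             "products": ["catCO"], "k": k_bind},
            {"label": "unbind", "reactants": ["catCO"],
             "products": ["cat", "CO"], "k": k_unbind},
            {"label": "addition", "reactants": ["cat", "alkene"],
             "products": ["acyl"], "k": k_addition},
            {"label": "hydrogenolysis", "reactants": ["acyl", "H2"],
             "products": ["cat", "P"], "k": k_hydrogenolysis},
        ],
    }


def _vcn_like(
    ts_energies: tuple = (95.0, 100.0, 90.0),
    well_energies: tuple = (0.0, 60.0, 55.0),
) -> dict:
    """Reactant -> I1 -> I2 -> product chain via three transition states."""
    e0, e1, e2 = well_energies
    t1, t2, t3 = ts_energies
    return {
        "schema_version": 1,
        "reference": "R",
        "wells": [
            _well("R", e0, freqs=[300, 600, 900, 1200, 1600, 2200, 3100]),
            _well("I1", e1, freqs=[250, 550, 850, 1150, 1550, 2100, 3000]),
            _well("I2", e2, freqs=[260, 560, 860, 1160, 1560, 2150, 3050]),
            _well("P", 20.0, sink=True,
                  freqs=[400, 800, 1300, 1900, 2600]),
        ],
        "transition_states": [
            _ts("TS1", t1, "R", "I1",
                freqs=[280, 580, 880, 1180, 1580, 2150], imag=1100.0),
            _ts("TS2", t2, "I1", "I2",
                freqs=[240, 540, 840, 1140, 1540, 2050], imag=1300.0),
            _ts("TS3", t3, "I2", "P",
                freqs=[260, 560, 880, 1200, 1600, 2100], imag=900.0),
        ],
    }
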