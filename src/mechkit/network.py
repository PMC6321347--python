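"""Reaction-network container and its JSON schema.

A network is a set of wells (potential-energy minima) joined by transition
states, with ZPE-inclusive energies in kcal/mol relative to a declared
reference species and harmonic frequencies in cm^-1.  The JSON layout::

    {
      "schema_version": 1,
      "reference": "W0",
      "wells": [
        {"label": "W0", "energy_kcal": 0.0, "freqs_cm": [...],
         "m_opt": 1, "sink": false}
      ],
      "transition_states": [
        {"label": "TS1", "energy_kcal": 30.0, "freqs_cm": [...],
         "m_opt": 1, "connects": ["W0", "W1"], "imag_freq_cm": 1200.0}
      ],
      "bimolecular": [{"ts": "TS1", "partner": "CO", "order": 1}],
      "rates": [{"from": "W0", "ts": "TS1", "k_s": 2.0}],
      "reactions": [
        {"label": "bind", "reactants": ["cat", "CO"],
         "products": ["catCO"], "k": 100.0}
      ]
    }

``rates`` (explicit first-order rate constants per directed edge) and
``reactions`` (a mass-action system for rate-law extraction) are optional
blocks; when present they take precedence over statistically computed
rates for the stochastic and deterministic solvers respectively.
Validation reports the offending entry by label and field.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "Well",
    "TransitionStateRecord",
    "Reaction",
    "ReactionNetwork",
    "NetworkValidationError",
    "load_network",
]

SCHEMA_VERSION = 1


class NetworkValidationError(ValueError):
    pass


@dataclass
class Well:
    label: str
    energy: float
    freqs: list[float]
    m_opt: int = 1
    is_product_sink: bool = False

    def __post_init__(self):
        if any(f <= 0 for f in self.freqs):
            raise NetworkValidationError(
                f"well {self.label!r}: all frequencies must be > 0"
            )
        if self.m_opt < 1:
            raise NetworkValidationError(
                f"well {self.label!r}: m_opt must be >= 1, got {self.m_opt}"
            )


@dataclass
class TransitionStateRecord:
    label: str
    energy: float
    freqs: list[float]
    connects: tuple[str, str]
    m_opt_ts: int = 1
    imag_freq: float | None = None
    dG_ddag: dict | None = None  # optional {direction: {T: value}} overrides

    def __post_init__(self):
        if any(f <= 0 for f in self.freqs):
            raise NetworkValidationError(
                f"transition state {self.label!r}: all real frequencies must "
                "be > 0 (the imaginary mode is excluded)"
            )
        if self.m_opt_ts < 1:
            raise NetworkValidationError(
                f"transition state {self.label!r}: m_opt must be >= 1"
            )


@dataclass
class Reaction:
    """Mass-action elementary step with rate constant ``k`` (units implied
    by the concentration scale and molecularity)."""

    reactants: list[str]
    products: list[str]
    k: float
    label: str = ""

    def __post_init__(self):
        if self.k < 0:
            raise NetworkValidationError(f"reaction {self.label!r}: k must be >= 0")
        if not self.reactants and not self.products:
            raise NetworkValidationError(f"reaction {self.label!r}: empty reaction")


@dataclass
class ReactionNetwork:
    reference: str
    wells: dict[str, Well]
    transition_states: dict[str, TransitionStateRecord]
    bimolecular: list[dict] = field(default_factory=list)
    explicit_rates: dict[tuple[str, str], float] = field(default_factory=dict)
    reactions: list[Reaction] = field(default_factory=list)

    def __post_init__(self):
        if self.reference not in self.wells and self.wells:
            raise NetworkValidationError(
                f"reference species {self.reference!r} is not a declared well"
            )
        for ts in self.transition_states.values():
            for w in ts.connects:
                if w not in self.wells:
                    raise NetworkValidationError(
                        f"transition state {ts.label!r} connects unknown well {w!r}"
                    )
        for (well, ts), k in self.explicit_rates.items():
            if ts not in self.transition_states:
                raise NetworkValidationError(
                    f"rates entry references unknown transition state {ts!r}"
                )
            if well not in self.transition_states[ts].connects:
                raise NetworkValidationError(
                    f"rates entry: well {well!r} is not an endpoint of {ts!r}"
                )
            if k < 0:
                raise NetworkValidationError(
                    f"rates entry ({well!r}, {ts!r}): k_s must be >= 0"
                )

    @property
    def species(self) -> list[str]:
        return list(self.wells)

    def other_end(self, ts_label: str, well_label: str) -> str:
        a, b = self.transition_states[ts_label].connects
        return b if well_label == a else a

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "reference": self.reference,
            "wells": [
                {
                    "label": w.label,
                    "energy_kcal": w.energy,
                    "freqs_cm": w.freqs,
                    "m_opt": w.m_opt,
                    "sink": w.is_product_sink,
                }
                for w in self.wells.values()
            ],
            "transition_states": [
                {
                    "label": t.label,
                    "energy_kcal": t.energy,
                    "freqs_cm": t.freqs,
                    "m_opt": t.m_opt_ts,
                    "connects": list(t.connects),
                    **({"imag_freq_cm": t.imag_freq} if t.imag_freq else {}),
                }
                for t in self.transition_states.values()
            ],
            "bimolecular": self.bimolecular,
            "rates": [
                {"from": well, "ts": ts, "k_s": k}
                for (well, ts), k in self.explicit_rates.items()
            ],
            "reactions": [
                {
                    "label": r.label,
                    "reactants": r.reactants,
                    "products": r.products,
                    "k": r.k,
                }
                for r in self.reactions
            ],
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _require(entry: dict, key: str, where: str):
    if key not in entry:
        raise NetworkValidationError(f"{where}: missing required field {key!r}")
    return entry[key]


def network_from_dict(data: dict) -> ReactionNetwork:
    if not isinstance(data, dict):
        raise NetworkValidationError("network document must be a JSON object")
    wells = {}
    for i, w in enumerate(data.get("wells", [])):
        where = f"wells[{i}]"
        label = _require(w, "label", where)
        wells[label] = Well(
            label=label,
            energy=float(_require(w, "energy_kcal", where)),
            freqs=list(_require(w, "freqs_cm", where)),
            m_opt=int(w.get("m_opt", 1)),
            is_product_sink=bool(w.get("sink", False)),
        )
    tss = {}
    for i, t in enumerate(data.get("transition_states", [])):
        where = f"transition_states[{i}]"
        label = _require(t, "label", where)
        connects = _require(t, "connects", where)
        if len(connects) != 2:
            raise NetworkValidationError(
                f"{where} ({label!r}): connects must name exactly two wells"
            )
        tss[label] = TransitionStateRecord(
            label=label,
            energy=float(_require(t, "energy_kcal", where)),
            freqs=list(_require(t, "freqs_cm", where)),
            connects=(connects[0], connects[1]),
            m_opt_ts=int(t.get("m_opt", 1)),
            imag_freq=t.get("imag_freq_cm"),
        )
    explicit = {}
    for i, r in enumerate(data.get("rates", [])):
        where = f"rates[{i}]"
        explicit[(_require(r, "from", where), _require(r, "ts", where))] = float(
            _require(r, "k_s", where)
        )
    reactions = [
        Reaction(
            reactants=list(_require(r, "reactants", f"reactions[{i}]")),
            products=list(_require(r, "products", f"reactions[{i}]")),
            k=float(_require(r, "k", f"reactions[{i}]")),
            label=r.get("label", f"r{i}"),
        )
        for i, r in enumerate(data.get("reactions", []))
    ]
    reference = data.get("reference", next(iter(wells), ""))
    return ReactionNetwork(
        reference=reference,
        wells=wells,
        transition_states=tss,
        bimolecular=list(data.get("bimolecular", [])),
        explicit_rates=explicit,
        reactions=reactions,
    )


def load_network(path) -> ReactionNetwork:
    """Load and validate a network JSON file."""
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise NetworkValidationError(f"{path}: invalid JSON ({exc})") from exc
    return network_from_dict(data)
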