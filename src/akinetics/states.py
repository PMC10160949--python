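"""Enumeration of the ten network species states.

The model tracks a single conformational coordinate — the ATP-binding LID
domain, open (O) or closed (C) — for five ligation species of adenylate
kinase: the apoenzyme E, the ATP-bound complex ET, the AMP-bound complex EM,
the productive ternary complex ETM (ATP bound first) and the unproductive
ternary complex ETMinh (AMP bound first).
"""

from __future__ import annotations

import enum


class Species(str, enum.Enum):
    """Ligation species, each carrying one opening/closing rate pair."""

    E = "E"
    ET = "ET"
    EM = "EM"
    ETM = "ETM"
    ETMinh = "ETMinh"


class SpeciesState(str, enum.Enum):
    """One of the ten nodes of the reaction network (species x conformation)."""

    E_O = "E_O"
    E_C = "E_C"
    ET_O = "ET_O"
    ET_C = "ET_C"
    EM_O = "EM_O"
    EM_C = "EM_C"
    ETM_O = "ETM_O"
    ETM_C = "ETM_C"
    ETMinh_O = "ETMinh_O"
    ETMinh_C = "ETMinh_C"

    @property
    def species(self) -> Species:
        return Species(self.value.rsplit("_", 1)[0])

    @property
    def is_open(self) -> bool:
        return self.value.endswith("_O")


#: Canonical state ordering used for every rate matrix and occupancy vector.
STATE_ORDER: tuple[SpeciesState, ...] = tuple(SpeciesState)

#: Index of each state in :data:`STATE_ORDER`.
STATE_INDEX: dict[SpeciesState, int] = {s: i for i, s in enumerate(STATE_ORDER)}

N_STATES = len(STATE_ORDER)
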