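"""Activator/repressor role (ARR) annotation of genecentric pathway members.

Each member is assigned a discrete weight in {-1, -0.5, 0, 0.5, 1} describing
whether it acts as a repressor, mainly a repressor, a neutral/ambiguous player,
predominantly an activator, or an activator of the pathway.  For a depth-1
genecentric pathway the evidence is the set of typed edges linking the member
to the central node: each interaction type carries a sign (+1 activating,
-1 inhibiting, 0 neutral) and the member's ARR is the consensus of the signed
evidence — unanimity gives ±1, a strict majority gives ±0.5, and a tie or
purely neutral evidence gives 0.  The central gene product is always an
activator (+1) of its own pathway.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

from .pathway_graph import GenecentricPathway, InteractionType

__all__ = ["DEFAULT_TYPE_SIGNS", "sign_of_type", "assign_arr", "load_type_signs"]

ARR_LEVELS = (-1.0, -0.5, 0.0, 0.5, 1.0)

# Conventional signaling semantics: covalent activating marks read as +1,
# inhibitory/removing marks as -1, physical-association types as neutral.
DEFAULT_TYPE_SIGNS: dict[InteractionType, int] = {
    InteractionType.ACTIVATION: +1,
    InteractionType.PHOSPHORYLATION: +1,
    InteractionType.INHIBITION: -1,
    InteractionType.REPRESSION: -1,
    InteractionType.DEPHOSPHORYLATION: -1,
    InteractionType.UBIQUITINATION: -1,
    InteractionType.COUPLING: 0,
    InteractionType.BINDING_ASSOCIATION: 0,
    InteractionType.DISSOCIATION: 0,
}


def sign_of_type(
    t: InteractionType, mapping: Mapping[InteractionType, int] | None = None
) -> int:
    """Signed role of one interaction type: +1 activating, -1 inhibiting, 0 neutral."""
    signs = DEFAULT_TYPE_SIGNS if mapping is None else mapping
    return signs[t]


def load_type_signs(path: str | Path) -> dict[InteractionType, int]:
    """Read an alternative type→sign convention from a two-column TSV
    (interaction_type, sign).  Types absent from the file keep the default."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, names=["interaction_type", "sign"])
    signs = dict(DEFAULT_TYPE_SIGNS)
    for _, row in df.iterrows():
        signs[InteractionType.parse(row["interaction_type"])] = int(row["sign"])
    return signs


def assign_arr(
    pathway: GenecentricPathway,
    type_signs: Mapping[InteractionType, int] | None = None,
    direction_mode: str = "ignore",
) -> dict[str, float]:
    """Assign an ARR value to every pathway member.

    Parameters
    ----------
    pathway
        A genecentric pathway with typed edges to/from the central node.
    type_signs
        Interaction-type → sign convention; defaults to
        :data:`DEFAULT_TYPE_SIGNS`.
    direction_mode
        ``"ignore"`` (default) counts edges in both directions as role
        evidence; ``"incoming_only"`` counts only edges pointing at the
        central node (upstream regulators).

    Returns
    -------
    dict mapping every member to one of the five ARR levels.  The central
    node gets +1; a member with no signed evidence gets 0.
    """
    if direction_mode not in ("ignore", "incoming_only"):
        raise ValueError(f"unknown direction_mode: {direction_mode!r}")
    signs = DEFAULT_TYPE_SIGNS if type_signs is None else type_signs

    arr: dict[str, float] = {pathway.central: 1.0}
    for member in pathway.members:
        if member == pathway.central:
            continue
        evidence: list[int] = []
        for e in pathway.edges_touching(member):
            if direction_mode == "incoming_only" and e.target != pathway.central:
                continue
            evidence.append(signs[e.type])
        pos = sum(1 for s in evidence if s > 0)
        neg = sum(1 for s in evidence if s < 0)
        if pos == 0 and neg == 0:
            arr[member] = 0.0
        elif neg == 0:
            arr[member] = 1.0
        elif pos == 0:
            arr[member] = -1.0
        elif pos > neg:
            arr[member] = 0.5
        elif neg > pos:
            arr[member] = -0.5
        else:
            arr[member] = 0.0
    return arr
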