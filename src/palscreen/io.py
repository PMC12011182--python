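"""Readers and writers for the interchange formats.

Pathway collections travel as TSV edge lists (``pathway_id, source, target,
interaction_type``), expression as a genes × samples TSV with a header row,
clinical follow-up as CSV (``sample_id, os_time, os_event, pfs_time,
pfs_event``) and therapy response as CSV (``sample_id, therapy, line,
recist``).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .pal_engine import ExpressionCohort
from .pathway_graph import PathwayCollection
from .survival_stats import SurvivalData

__all__ = [
    "write_pathway_collection",
    "write_expression",
    "read_expression",
    "write_clinical",
    "read_clinical",
    "write_ground_truth",
]


def write_pathway_collection(collection: PathwayCollection, path: str | Path) -> None:
    rows = [
        {"pathway_id": pid, "source": e.source, "target": e.target, "interaction_type": e.type.value}
        for pid, edges in collection.pathways.items()
        for e in edges
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


def read_expression(path: str | Path, scale: str = "raw_counts") -> ExpressionCohort:
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionCohort(matrix=matrix, scale=scale)


def write_clinical(clinical: dict[str, SurvivalData], path: str | Path) -> None:
    frame = pd.DataFrame(index=clinical[next(iter(clinical))].samples)
    for endpoint, surv in clinical.items():
        frame[f"{endpoint.lower()}_time"] = surv.time
        frame[f"{endpoint.lower()}_event"] = surv.event
    frame.to_csv(path, index_label="sample_id")


def read_clinical(path: str | Path) -> dict[str, SurvivalData]:
    frame = pd.read_csv(path, index_col="sample_id")
    clinical = {}
    for endpoint in ("OS", "PFS"):
        tcol, ecol = f"{endpoint.lower()}_time", f"{endpoint.lower()}_event"
        if tcol in frame.columns and ecol in frame.columns:
            clinical[endpoint] = SurvivalData(
                time=frame[tcol], event=frame[ecol].astype(int), endpoint=endpoint
            )
    if not clinical:
        raise ValueError(f"{path}: no recognised endpoint columns")
    return clinical


def write_ground_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
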