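"""End-to-end orchestration: build → extract → annotate → score → screen.

:func:`analyze` runs the whole analysis on in-memory objects and returns a
:class:`RunResult`; :func:`run_full` wraps it with file input/output and a
machine-readable JSON summary.  Per-stage failures (an undefined PAL, an
inadmissible cutpoint) are recorded in the affected output cell and the run
continues; only configuration errors abort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as _io
from .arr_annotator import assign_arr, load_type_signs
from .pal_engine import ExpressionCohort, PALResult, normalize_counts, score_cohort
from .pathway_graph import (
    GenecentricPathway,
    PathwayCollection,
    extract_genecentric,
    load_pathway_collection,
    merge_to_interactome,
)
from .response_stats import filter_response_cohort, response_effect_screen
from .survival_stats import SurvivalData, biomarker_screen, cluster_hr_profiles

__all__ = ["RunConfig", "RunResult", "analyze", "run_full"]


@dataclass
class RunConfig:
    """Paths and parameters of one full analysis run."""

    pathway_collection: str | Path
    expression: str | Path
    clinical: str | Path
    output_dir: str | Path
    response: str | Path | None = None
    central_genes: list[str] = field(default_factory=list)
    expression_scale: str = "raw_counts"
    pseudocount: float = 1.0
    minprop: float = 0.1
    arr_mapping: str | Path | None = None
    direction_mode: str = "ignore"
    linkage: str = "complete"
    min_therapy_group: int = 20
    seed: int = 0
    make_figures: bool = True

    def validate(self) -> None:
        for p in (self.pathway_collection, self.expression, self.clinical, self.response, self.arr_mapping):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class RunResult:
    pathways: dict[str, GenecentricPathway]
    arr_maps: dict[str, dict[str, float]]
    pal: PALResult
    verdicts: pd.DataFrame
    cluster: tuple | None
    response_report: pd.DataFrame | None
    log: list[str] = field(default_factory=list)

    def flagged_biomarkers(self) -> dict[str, str]:
        """Biomarkers with a consistent, significant survival direction on
        every endpoint, judged on the selection-corrected cutpoint p."""
        summ = self.verdicts[self.verdicts["endpoint"] == "OS+PFS_mean"]
        if "flagged" not in summ.columns:
            return {}
        flagged = summ[summ["flagged"].infer_objects(copy=False).astype(bool)]
        return dict(zip(flagged["biomarker"], flagged["direction"]))

    def summary(self) -> dict:
        """JSON-serialisable run summary: every verdict and every log entry."""
        def _clean(v):
            if isinstance(v, float) and (np.isnan(v) or np.isinf(v)):
                return None if np.isnan(v) else ("inf" if v > 0 else "-inf")
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            return v

        verdicts = [
            {k: _clean(v) for k, v in row.items()}
            for row in self.verdicts.to_dict(orient="records")
        ]
        out = {
            "pathways": {
                name: {"central": p.central, "n_members": len(p.members)}
                for name, p in self.pathways.items()
            },
            "pal_used_genes": self.pal.used_genes,
            "pal_undefined": self.pal.undefined,
            "verdicts": verdicts,
            "flagged_biomarkers": self.flagged_biomarkers(),
            "log": self.log,
        }
        if self.cluster is not None:
            order, labels, _ = self.cluster
            out["cluster"] = {"leaf_order": list(order), "labels": {k: int(v) for k, v in labels.items()}}
        if self.response_report is not None:
            out["response"] = [
                {k: _clean(v) for k, v in row.items()}
                for row in self.response_report.to_dict(orient="records")
            ]
        return out


def analyze(
    collection: PathwayCollection,
    cohort: ExpressionCohort,
    clinical: Mapping[str, SurvivalData],
    response: pd.DataFrame | None = None,
    central_genes: list[str] | None = None,
    pseudocount: float = 1.0,
    minprop: float = 0.1,
    type_signs=None,
    direction_mode: str = "ignore",
    min_therapy_group: int = 20,
    cohort_name: str = "cohort",
) -> RunResult:
    """Run the full analysis on in-memory inputs.

    ``central_genes`` defaults to every node that has first-order neighbors
    in more than one pathway file — in practice the caller names them.
    """
    log: list[str] = []
    interactome = merge_to_interactome(collection)
    log.append(
        f"interactome: {len(interactome.nodes)} nodes, {len(interactome.edges)} edges, "
        f"{interactome.connectivity.n_components} weak component(s), "
        f"largest {interactome.connectivity.largest_component_size}"
    )
    centrals = central_genes or []
    pathways: dict[str, GenecentricPathway] = {}
    arr_maps: dict[str, dict[str, float]] = {}
    for gene in centrals:
        try:
            p = extract_genecentric(interactome, gene)
        except KeyError as exc:
            log.append(f"extract {gene}: {exc}")
            continue
        pathways[gene] = p
        arr_maps[gene] = assign_arr(p, type_signs=type_signs, direction_mode=direction_mode)
        log.append(f"pathway {gene}: {len(p.members)} members")

    if cohort.scale == "raw_counts":
        cohort = normalize_counts(cohort)
        log.append("counts normalized with median-of-ratios size factors")
    pal = score_cohort(
        cohort,
        [(name, pathways[name], arr_maps[name]) for name in pathways],
        pseudocount=pseudocount,
        central_genes=centrals,
    )
    for name in pal.undefined:
        log.append(f"PAL undefined for pathway {name}")

    biomarkers = pal.pal.copy()
    if pal.gene_log_cnr is not None:
        for g in pal.gene_log_cnr.columns:
            biomarkers[f"gene:{g}"] = pal.gene_log_cnr[g]
    verdicts = biomarker_screen(biomarkers, clinical, minprop=minprop, cohort=cohort_name)

    cluster = None
    per_endpoint = verdicts[verdicts["endpoint"].isin(clinical.keys())]
    hr_rows = per_endpoint.pivot_table(index="endpoint", columns="biomarker", values="hr", dropna=False)
    if hr_rows.shape[0] >= 2:
        cluster = cluster_hr_profiles(hr_rows)
        log.append(f"clustered {hr_rows.shape[0]} HR profiles into 2 groups")

    response_report = None
    if response is not None and len(response):
        groups = filter_response_cohort(response, min_therapy_group=min_therapy_group)
        for item, rule, detail in groups.exclusions:
            log.append(f"response filter [{rule}] {item}: {detail}")
        if groups.empty:
            log.append("response cohort empty after filtering; response screen skipped")
        else:
            response_report = response_effect_screen(pal.pal, groups)
    else:
        log.append("no response table; response screen skipped")

    return RunResult(
        pathways=pathways, arr_maps=arr_maps, pal=pal, verdicts=verdicts,
        cluster=cluster, response_report=response_report, log=log,
    )


def _write_figures(result: RunResult, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster import hierarchy

    per_endpoint = result.verdicts[result.verdicts["endpoint"] != "OS+PFS_mean"]
    hr = per_endpoint.pivot_table(index="endpoint", columns="biomarker", values="hr", dropna=False)
    if not hr.empty:
        fig, ax = plt.subplots(figsize=(2 + 0.6 * hr.shape[1], 2 + 0.5 * hr.shape[0]))
        im = ax.imshow(np.log2(hr.values.astype(float)), cmap="RdBu_r", vmin=-2, vmax=2)
        ax.set_xticks(range(hr.shape[1]), hr.columns, rotation=90)
        ax.set_yticks(range(hr.shape[0]), hr.index)
        stars_grid = per_endpoint.pivot_table(
            index="endpoint", columns="biomarker", values="stars", aggfunc="first"
        ).reindex_like(hr)
        for i in range(hr.shape[0]):
            for j in range(hr.shape[1]):
                s = stars_grid.iloc[i, j]
                if isinstance(s, str) and s not in ("", "ns"):
                    ax.text(j, i, s, ha="center", va="center")
        fig.colorbar(im, label="log2 HR (high vs low)")
        fig.tight_layout()
        fig.savefig(outdir / "hr_heatmap.png", dpi=120)
        plt.close(fig)
    if result.cluster is not None:
        _, _, z = result.cluster
        fig, ax = plt.subplots(figsize=(6, 4))
        hierarchy.dendrogram(z, ax=ax, labels=list(hr.index))
        ax.set_ylabel("distance")
        fig.tight_layout()
        fig.savefig(outdir / "hr_dendrogram.png", dpi=120)
        plt.close(fig)
    if result.response_report is not None:
        fig, ax = plt.subplots(figsize=(5, 4))
        result.pal.pal.boxplot(ax=ax, rot=90)
        ax.set_ylabel("PAL")
        fig.tight_layout()
        fig.savefig(outdir / "pal_boxplot.png", dpi=120)
        plt.close(fig)


def run_full(config: RunConfig) -> RunResult:
    """Execute the full pipeline from files and write every table, figure and
    a machine-readable JSON summary under ``config.output_dir``."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    collection, load_report = load_pathway_collection(config.pathway_collection)
    cohort = _io.read_expression(config.expression, scale=config.expression_scale)
    clinical = _io.read_clinical(config.clinical)
    response = None
    if config.response is not None:
        response = pd.read_csv(config.response)
    type_signs = load_type_signs(config.arr_mapping) if config.arr_mapping else None

    result = analyze(
        collection, cohort, clinical, response=response,
        central_genes=config.central_genes, pseudocount=config.pseudocount,
        minprop=config.minprop, type_signs=type_signs,
        direction_mode=config.direction_mode,
        min_therapy_group=config.min_therapy_group,
    )
    for idx, reason in load_report.rejected_rows:
        result.log.insert(0, f"pathway load: row {idx} rejected ({reason})")

    result.pal.pal.to_csv(outdir / "pal.tsv", sep="\t", index_label="sample_id")
    result.verdicts.to_csv(outdir / "verdicts.tsv", sep="\t", index=False)
    if result.response_report is not None:
        result.response_report.to_csv(outdir / "response_report.tsv", sep="\t", index=False)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(result.summary(), fh, indent=2, sort_keys=True)
    if config.make_figures:
        _write_figures(result, outdir)
    return result
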