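"""Pathway activation level (PAL) scoring from expression cohorts.

The PAL of pathway *p* in one sample is

    PAL_p = 100 * sum_n( ARR_{n,p} * lg(CNR_n) ) / sum_n |ARR_{n,p}|

where the sum runs over the measured gene-class members of the pathway,
CNR_n (case-to-normal ratio) is the ratio of the expression of gene *n* in
the tested sample to its level in the reference profile, ARR is the member's
activator/repressor role, and lg is log base 10.  The reference is an
artificial profile obtained by averaging the normalized expression of all
samples in the study cohort, so PAL measures each sample's pathway shift
relative to its own cohort.

Raw RNA-seq counts are first normalized with median-of-ratios size factors
(each sample is divided by the median, over genes with a positive geometric
mean across samples, of the count-to-geometric-mean ratio).  A pseudocount
(default 1 on the normalized scale) keeps every log-ratio finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pathway_graph import GenecentricPathway, NodeClass

__all__ = [
    "ExpressionCohort",
    "PALResult",
    "normalize_counts",
    "build_reference",
    "compute_cnr",
    "compute_pal",
    "score_cohort",
]


class DegenerateInputError(ValueError):
    pass


class UndefinedPALError(ValueError):
    """Raised when a pathway has no usable signed, measured gene member."""


@dataclass
class ExpressionCohort:
    """Genes × samples expression matrix with a scale flag.

    ``scale`` is ``"raw_counts"`` for unnormalized sequencing counts and
    ``"normalized"`` after size-factor normalization (or for platforms such
    as microarrays that arrive pre-normalized).
    """

    matrix: pd.DataFrame  # index: gene ids, columns: sample ids
    scale: str = "raw_counts"

    def __post_init__(self) -> None:
        if self.scale not in ("raw_counts", "normalized"):
            raise ValueError(f"unknown scale flag: {self.scale!r}")
        if (self.matrix.values < 0).any():
            raise ValueError("expression matrix contains negative entries")
        if self.matrix.index.has_duplicates:
            raise ValueError("gene ids are not unique")
        if self.matrix.columns.has_duplicates:
            raise ValueError("sample ids are not unique")
        if self.scale == "normalized":
            vals = self.matrix.values
            if vals.size and vals.max() > 1e5 and np.allclose(vals, np.round(vals)):
                warnings.warn(
                    "matrix flagged 'normalized' is integer-valued with large maxima; "
                    "it may be raw counts",
                    stacklevel=2,
                )

    @property
    def genes(self) -> pd.Index:
        return self.matrix.index

    @property
    def samples(self) -> pd.Index:
        return self.matrix.columns

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]


@dataclass
class PALResult:
    """Samples × pathways PAL matrix plus bookkeeping.

    ``used_genes`` counts, per pathway, the gene-class members with nonzero
    ARR that were actually measured in the cohort; pathways whose usable gene
    set is empty appear as NaN columns and are listed in ``undefined``.
    ``gene_log_cnr`` carries per-sample log10 CNR for designated single genes
    (the central genes), enabling gene-level vs pathway-level comparisons.
    """

    pal: pd.DataFrame  # samples × pathways
    used_genes: dict[str, int]
    undefined: list[str] = field(default_factory=list)
    dropped_genes: dict[str, list[str]] = field(default_factory=dict)
    gene_log_cnr: pd.DataFrame | None = None  # samples × genes


def _size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors; genes with any zero are excluded from
    the geometric-mean reference, as in the standard RNA-seq formulation."""
    logs = np.log(counts, where=counts > 0, out=np.full_like(counts, np.nan, dtype=float))
    logs[counts == 0] = np.nan
    usable = ~np.isnan(logs).any(axis=1)
    factors = np.ones(counts.shape[1])
    if not usable.any():
        warnings.warn("no gene has all-positive counts; size factors set to 1", stacklevel=3)
        return factors
    log_geo_mean = logs[usable].mean(axis=1)
    for j in range(counts.shape[1]):
        ratios = logs[usable, j] - log_geo_mean
        ratios = ratios[~np.isnan(ratios)]
        if ratios.size == 0:
            warnings.warn(f"sample column {j} has no usable ratios; size factor 1", stacklevel=3)
            continue
        factors[j] = np.exp(np.median(ratios))
    return factors


def normalize_counts(cohort: ExpressionCohort) -> ExpressionCohort:
    """Normalize raw counts with median-of-ratios size factors.

    Each sample column is divided by its size factor; the result carries the
    ``normalized`` scale flag.  Genes containing zeros are excluded from size
    factor estimation but retained in the output matrix.
    """
    if cohort.scale != "raw_counts":
        raise ValueError("normalize_counts expects a raw_counts cohort")
    if cohort.n_samples < 2:
        raise ValueError("size-factor normalization requires at least 2 samples")
    counts = cohort.matrix.values.astype(float)
    if not counts.any():
        raise DegenerateInputError("all-zero expression matrix")
    factors = _size_factors(counts)
    normalized = cohort.matrix.astype(float) / factors
    return ExpressionCohort(matrix=normalized, scale="normalized")


def build_reference(cohort: ExpressionCohort, pseudocount: float = 1.0, method: str = "arithmetic") -> pd.Series:
    """Cohort-average reference profile: per-gene mean of normalized values
    plus the pseudocount, so every reference entry is strictly positive.

    ``method`` is ``"arithmetic"`` (default) or ``"geometric"`` (geometric
    mean of value + pseudocount).
    """
    if cohort.scale != "normalized":
        raise ValueError("build_reference expects a normalized cohort")
    if cohort.n_samples == 0:
        raise ValueError("empty cohort")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if method == "arithmetic":
        ref = cohort.matrix.mean(axis=1) + pseudocount
    elif method == "geometric":
        ref = np.exp(np.log(cohort.matrix + pseudocount).mean(axis=1))
    else:
        raise ValueError(f"unknown reference method: {method!r}")
    return ref


def compute_cnr(sample: pd.Series, reference: pd.Series, pseudocount: float = 1.0) -> pd.Series:
    """Case-to-normal ratio: (expression + pseudocount) / reference, per gene."""
    if not sample.index.equals(reference.index):
        if set(sample.index) != set(reference.index):
            raise ValueError("sample and reference gene universes differ")
        reference = reference.reindex(sample.index)
    cnr = (sample + pseudocount) / reference
    return cnr


def compute_pal(
    cnr: Mapping[str, float] | pd.Series,
    arr: Mapping[str, float],
    gene_class: Mapping[str, NodeClass] | None = None,
) -> tuple[float, int]:
    """Evaluate the PAL formula for one sample and one pathway.

    The sum runs over genes that (a) are in the ARR domain, (b) are
    gene-class members (metabolites carry no expression), (c) were measured
    (present in the CNR vector), and (d) have nonzero ARR.  Returns the PAL
    value and the number of genes used.

    Raises :class:`UndefinedPALError` when no usable gene remains.
    """
    if isinstance(cnr, pd.Series):
        cnr = cnr.to_dict()
    num = 0.0
    denom = 0.0
    used = 0
    for gene, weight in arr.items():
        if weight == 0:
            continue
        if gene_class is not None and gene_class.get(gene, NodeClass.GENE) is not NodeClass.GENE:
            continue
        if gene not in cnr:
            continue
        num += weight * np.log10(cnr[gene])
        denom += abs(weight)
        used += 1
    if denom == 0:
        raise UndefinedPALError("no measured gene-class member with nonzero ARR")
    return 100.0 * num / denom, used


def score_cohort(
    cohort: ExpressionCohort,
    pathways: Sequence[tuple[str, GenecentricPathway, Mapping[str, float]]],
    pseudocount: float = 1.0,
    reference_method: str = "arithmetic",
    central_genes: Sequence[str] | None = None,
) -> PALResult:
    """Score every sample of a normalized cohort against a set of annotated
    genecentric pathways.

    Parameters
    ----------
    cohort
        Normalized expression cohort.
    pathways
        Sequence of (pathway name, pathway, ARR map) triples.
    central_genes
        Genes whose per-sample log10 CNR is reported alongside PAL, for the
        single-gene biomarker comparison.

    Notes
    -----
    The implementation is vectorised over samples: for each pathway the
    usable gene rows are selected once and the weighted log-ratio sum is a
    single matrix product.
    """
    if cohort.scale != "normalized":
        raise ValueError("score_cohort expects a normalized cohort")
    reference = build_reference(cohort, pseudocount=pseudocount, method=reference_method)
    log_cnr = np.log10((cohort.matrix.add(pseudocount, axis=0)).div(reference, axis=0))

    pal = pd.DataFrame(index=cohort.samples.copy(), dtype=float)
    used_genes: dict[str, int] = {}
    undefined: list[str] = []
    dropped: dict[str, list[str]] = {}
    for name, pathway, arr in pathways:
        usable = [
            g
            for g, w in arr.items()
            if w != 0 and pathway.node_class(g) is NodeClass.GENE and g in log_cnr.index
        ]
        dropped[name] = sorted(
            g
            for g, w in arr.items()
            if w != 0 and pathway.node_class(g) is NodeClass.GENE and g not in log_cnr.index
        )
        if not usable:
            pal[name] = np.nan
            used_genes[name] = 0
            undefined.append(name)
            continue
        weights = np.array([arr[g] for g in usable])
        pal[name] = 100.0 * (weights @ log_cnr.loc[usable].values) / np.abs(weights).sum()
        used_genes[name] = len(usable)

    gene_log_cnr = None
    if central_genes:
        present = [g for g in central_genes if g in log_cnr.index]
        gene_log_cnr = log_cnr.loc[present].T.copy()
    return PALResult(
        pal=pal,
        used_genes=used_genes,
        undefined=undefined,
        dropped_genes=dropped,
        gene_log_cnr=gene_log_cnr,
    )
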