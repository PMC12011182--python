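"""Therapy-response cohort filtering and the normality-driven group comparison.

Patients with RECIST best response Complete Response or Partial Response are
responders (R), Progressive Disease patients are non-responders (NR), and
Stable Disease (SD) patients form their own class.  Cohort inclusion rules:
only therapy groups with at least 20 patients, only therapy lines 1-3, the
best response per patient across retained lines (CR > PR > SD > PD), and only
response groups of at least 3 patients.

Group comparisons follow a decision tree: Shapiro-Wilk normality per group
and Levene's (Brown-Forsythe, median-centered) homogeneity across groups;
with two groups, Student's t-test if all groups are normal, else the Wilcoxon
rank-sum test; with more than two groups, ANOVA with pairwise-t post hoc and
Benjamini-Hochberg correction if normal and homoscedastic, else
Kruskal-Wallis with Dunn's post hoc and Holm correction.  Significance at
p < 0.05 throughout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RECIST_ORDER",
    "ResponseGroups",
    "ComparisonReport",
    "filter_response_cohort",
    "compare_groups",
    "dunn_posthoc",
    "response_effect_screen",
]

# best-response preference, most favorable first
RECIST_ORDER = ["Complete Response", "Partial Response", "Stable Disease", "Progressive Disease"]
_RECIST_RANK = {label: i for i, label in enumerate(RECIST_ORDER)}
_CLASS_OF = {
    "Complete Response": "R",
    "Partial Response": "R",
    "Stable Disease": "SD",
    "Progressive Disease": "NR",
}


class InsufficientGroupError(ValueError):
    pass


@dataclass
class ResponseGroups:
    """Per-sample responder class (R / NR / SD) after filtering, plus the
    exclusion log (sample or group, rule name, detail)."""

    classes: pd.Series  # sample id -> {"R", "NR", "SD"}
    exclusions: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return len(self.classes) == 0

    def counts(self) -> dict[str, int]:
        return self.classes.value_counts().to_dict()


def filter_response_cohort(
    records: pd.DataFrame,
    min_therapy_group: int = 20,
    max_line: int = 3,
    min_response_group: int = 3,
) -> ResponseGroups:
    """Apply the cohort inclusion rules to a response table.

    ``records`` needs columns ``sample_id, therapy, line, recist`` (one row
    per administered therapy line).  Rules, in order: drop lines > ``max_line``
    ("line-1-3"); drop therapy groups with fewer than ``min_therapy_group``
    distinct patients ("min-20"); collapse each patient's retained lines to
    the best response; drop response classes with fewer than
    ``min_response_group`` patients ("min-3").  Every exclusion is logged
    with its rule.  An empty result is signalled via ``ResponseGroups.empty``,
    not an exception.
    """
    required = {"sample_id", "therapy", "line", "recist"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"response table missing columns {sorted(missing)}")
    exclusions: list[tuple[str, str, str]] = []

    kept = records[records["line"].astype(int) <= max_line]
    for sid in sorted(set(records["sample_id"]) - set(kept["sample_id"])):
        exclusions.append((sid, "line-1-3", f"only therapy lines above {max_line}"))

    sizes = kept.groupby("therapy")["sample_id"].nunique()
    small = sizes[sizes < min_therapy_group].index
    for therapy in small:
        n = int(sizes[therapy])
        exclusions.append((therapy, "min-20", f"therapy group has {n} < {min_therapy_group} patients"))
    kept = kept[~kept["therapy"].isin(small)]

    best = (
        kept.assign(_rank=kept["recist"].map(_RECIST_RANK))
        .sort_values("_rank", kind="mergesort")
        .drop_duplicates("sample_id", keep="first")
        .set_index("sample_id")["recist"]
    )
    classes = best.map(_CLASS_OF)

    counts = classes.value_counts()
    for cls in counts[counts < min_response_group].index:
        exclusions.append((cls, "min-3", f"response group has {int(counts[cls])} < {min_response_group} patients"))
        classes = classes[classes != cls]

    return ResponseGroups(classes=classes.sort_index(), exclusions=exclusions)


@dataclass
class ComparisonReport:
    test: str  # branch taken
    statistic: float
    p: float
    normal: bool
    homoscedastic: bool | None
    posthoc: pd.DataFrame | None = None
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return not self.degenerate and self.p < 0.05


def dunn_posthoc(groups: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-based pairwise post hoc test after Kruskal-Wallis, with a
    tie correction and Holm-adjusted p-values."""
    names = list(groups)
    pooled = np.concatenate([np.asarray(groups[g], float) for g in names])
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    mean_ranks, sizes, idx = {}, {}, 0
    for g in names:
        k = len(groups[g])
        mean_ranks[g] = ranks[idx : idx + k].mean()
        sizes[g] = k
        idx += k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12 * (n_total - 1))
    rows = []
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt((n_total * (n_total + 1) / 12 - tie_term) * (1 / sizes[a] + 1 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        rows.append({"group_a": a, "group_b": b, "statistic": z, "p": 2 * stats.norm.sf(abs(z))})
    table = pd.DataFrame(rows)
    table["p_adj"] = multipletests(table["p"], method="holm")[1]
    return table


def _pairwise_t(groups: Mapping[str, np.ndarray]) -> pd.DataFrame:
    rows = []
    for a, b in itertools.combinations(groups, 2):
        t, p = stats.ttest_ind(groups[a], groups[b])
        rows.append({"group_a": a, "group_b": b, "statistic": t, "p": p})
    table = pd.DataFrame(rows)
    table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
    return table


def compare_groups(values: pd.Series, classes: pd.Series, alpha: float = 0.05) -> ComparisonReport:
    """Compare a continuous score between response classes via the
    normality-driven decision tree.  Requires >= 2 groups with >= 3 values
    each; constant (zero-variance) inputs are flagged degenerate and no test
    is run.
    """
    shared = values.index.intersection(classes.index)
    values, classes = values.loc[shared].dropna(), classes.loc[shared]
    classes = classes.loc[values.index]
    groups = {g: values[classes == g].values for g in sorted(classes.unique())}
    if len(groups) < 2:
        raise InsufficientGroupError("need at least 2 groups")
    for g, v in groups.items():
        if len(v) < 3:
            raise InsufficientGroupError(f"group {g!r} has {len(v)} < 3 values")
    if all(np.ptp(v) == 0 for v in groups.values()) and len({v[0] for v in groups.values()}) == 1:
        return ComparisonReport("degenerate", np.nan, np.nan, False, None, degenerate=True)
    # a single constant group breaks Shapiro-Wilk; treat as non-normal
    normal = True
    for v in groups.values():
        if np.ptp(v) == 0:
            normal = False
            break
        if stats.shapiro(v).pvalue < alpha:
            normal = False
            break
    levene_p = stats.levene(*groups.values(), center="median").pvalue
    homoscedastic = bool(levene_p >= alpha)
    arrays = list(groups.values())
    if len(groups) == 2:
        if normal:
            res = stats.ttest_ind(*arrays)
            return ComparisonReport("t-test", float(res.statistic), float(res.pvalue), normal, homoscedastic)
        res = stats.mannwhitneyu(*arrays, alternative="two-sided")
        return ComparisonReport("wilcoxon-rank-sum", float(res.statistic), float(res.pvalue), normal, homoscedastic)
    if normal and homoscedastic:
        res = stats.f_oneway(*arrays)
        return ComparisonReport(
            "anova", float(res.statistic), float(res.pvalue), normal, homoscedastic,
            posthoc=_pairwise_t(groups),
        )
    res = stats.kruskal(*arrays)
    return ComparisonReport(
        "kruskal-wallis", float(res.statistic), float(res.pvalue), normal, homoscedastic,
        posthoc=dunn_posthoc(groups),
    )


def response_effect_screen(
    pal: pd.DataFrame, groups: ResponseGroups, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-pathway comparison of PAL between response classes.

    Returns one row per pathway with group medians and quartiles, the chosen
    test branch, its p, and a direction label ("lower activation responds
    better" / "higher activation responds better") for significant pathways
    with both R and NR represented.
    """
    rows = []
    for name in pal.columns:
        vals = pal[name].dropna()
        cell: dict = {"pathway": name}
        cls = groups.classes.loc[groups.classes.index.intersection(vals.index)]
        for g in ("R", "NR", "SD"):
            v = vals.loc[cls[cls == g].index]
            cell[f"n_{g}"] = len(v)
            cell[f"median_{g}"] = v.median() if len(v) else np.nan
            cell[f"q1_{g}"] = v.quantile(0.25) if len(v) else np.nan
            cell[f"q3_{g}"] = v.quantile(0.75) if len(v) else np.nan
        try:
            report = compare_groups(vals, cls, alpha=alpha)
            cell.update(test=report.test, statistic=report.statistic, p=report.p)
            direction = ""
            if report.significant and cell["n_R"] >= 3 and cell["n_NR"] >= 3:
                if cell["median_R"] < cell["median_NR"]:
                    direction = "lower activation responds better"
                elif cell["median_R"] > cell["median_NR"]:
                    direction = "higher activation responds better"
            cell["direction"] = direction
        except InsufficientGroupError as exc:
            cell.update(test="not testable", statistic=np.nan, p=np.nan, direction="", error=str(exc))
        rows.append(cell)
    return pd.DataFrame(rows)
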