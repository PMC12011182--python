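"""Survival biomarker statistics: optimal log-rank cutpoint, Kaplan-Meier,
Cox hazard ratios, verdict classification, and HR-profile clustering.

A continuous biomarker (a pathway activation level or a single gene's
log-ratio) is dichotomized at the threshold minimizing the two-sided log-rank
p-value over all admissible high/low splits (the maximally selected rank
statistic, with a minimum group proportion constraint).  The high-vs-low
hazard ratio then comes from a univariate Cox model; HR > 1 with p < 0.05 and
a 95% CI excluding 1 reads "activation is a negative prognostic biomarker".

Note the minimum-p cutpoint selection is anti-conservative: the log-rank p at
the selected threshold is biased low and is reported uncorrected (a
Benjamini-Hochberg column across the screen is emitted separately for
transparency, not used for the verdicts).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SurvivalData",
    "CutpointResult",
    "BiomarkerVerdict",
    "logrank_test",
    "maxsel_adjusted_p",
    "find_optimal_cutpoint",
    "km_estimate",
    "cox_hr",
    "biomarker_screen",
    "cluster_hr_profiles",
    "stars",
]


class NoCutpointError(ValueError):
    pass


class UndefinedTestError(ValueError):
    pass


@dataclass
class SurvivalData:
    """Per-sample follow-up: non-negative time (days) and binary event
    indicator (1 = death/progression, 0 = censored at last follow-up)."""

    time: pd.Series
    event: pd.Series
    endpoint: str = "OS"

    def __post_init__(self) -> None:
        if (self.time < 0).any():
            raise ValueError("survival times must be non-negative")
        if not self.event.isin([0, 1]).all():
            raise ValueError("event indicator must be binary")
        if not self.time.index.equals(self.event.index):
            raise ValueError("time and event must share the sample index")

    @property
    def samples(self) -> pd.Index:
        return self.time.index

    def subset(self, ids) -> "SurvivalData":
        return SurvivalData(self.time.loc[ids], self.event.loc[ids], self.endpoint)


@dataclass
class CutpointResult:
    threshold: float
    p_logrank: float
    n_high: int
    n_low: int
    statistic: float = np.nan
    p_adjusted: float = np.nan  # selection-corrected minimum-p (Lausen-Schumacher)


def maxsel_adjusted_p(chi2_max: float, minprop: float, maxprop: float) -> float:
    """Selection-corrected p-value for a maximally selected log-rank statistic.

    The minimum log-rank p over all admissible splits is anti-conservative;
    the improved Bonferroni-type approximation of Miller & Siegmund /
    Lausen & Schumacher gives, for the observed maximum absolute standardized
    statistic b over split proportions in [minprop, maxprop],

        p ≈ phi(b) * (b - 1/b) * log(maxprop(1-minprop)/(minprop(1-maxprop)))
            + 4 * phi(b) / b

    capped at 1.  Valid for b > 1; smaller maxima are reported as p = 1.
    """
    b = float(np.sqrt(chi2_max))
    if b <= 1.0:
        return 1.0
    log_k = np.log((maxprop * (1 - minprop)) / (minprop * (1 - maxprop)))
    phi = stats.norm.pdf(b)
    return float(min(1.0, phi * (b - 1.0 / b) * log_k + 4.0 * phi / b))


@dataclass
class BiomarkerVerdict:
    """Outcome of one (biomarker, endpoint) survival screen cell."""

    hr: float
    ci_low: float
    ci_high: float
    p_cox: float
    p_logrank: float
    stars: str
    direction: str  # "negative" (HR > 1), "positive" (HR < 1), "none"
    cutpoint: float | None = None
    monotone_likelihood: bool = False

    @property
    def significant(self) -> bool:
        return self.direction != "none"


def stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _logrank_stat(time: np.ndarray, event: np.ndarray, in_a: np.ndarray) -> tuple[float, float]:
    """Two-group log-rank chi-square and two-sided p, standard tied-risk-set
    handling (hypergeometric variance at each distinct event time)."""
    order = np.argsort(time, kind="mergesort")
    t, e, a = time[order], event[order], in_a[order]
    n = len(t)
    # risk set sizes just before each distinct time
    uniq, start = np.unique(t, return_index=True)
    at_risk = n - start
    at_risk_a = a.sum() - np.concatenate(([0], np.cumsum(a)))[start]
    d = np.add.reduceat(e, start)
    d_a = np.add.reduceat(e & a.astype(bool), start)
    keep = d > 0
    n_i, n_ai, d_i, d_ai = at_risk[keep], at_risk_a[keep], d[keep], d_a[keep]
    if d_i.sum() == 0:
        raise UndefinedTestError("no events in either group")
    expected = d_i * n_ai / n_i
    with np.errstate(divide="ignore", invalid="ignore"):
        var = d_i * (n_ai / n_i) * (1 - n_ai / n_i) * (n_i - d_i) / np.where(n_i > 1, n_i - 1, 1)
    o_minus_e = (d_ai - expected).sum()
    v = var.sum()
    if v == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / v
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def logrank_test(group_a: SurvivalData, group_b: SurvivalData) -> tuple[float, float]:
    """Standard two-group log-rank test; returns (chi-square, two-sided p)."""
    if len(group_a.time) == 0 or len(group_b.time) == 0:
        raise ValueError("both groups must be non-empty")
    time = np.concatenate([group_a.time.values, group_b.time.values]).astype(float)
    event = np.concatenate([group_a.event.values, group_b.event.values]).astype(int)
    in_a = np.concatenate([np.ones(len(group_a.time), bool), np.zeros(len(group_b.time), bool)])
    return _logrank_stat(time, event, in_a)


def find_optimal_cutpoint(
    values: pd.Series, survival: SurvivalData, minprop: float = 0.1
) -> CutpointResult:
    """Threshold among midpoints of consecutive sorted distinct values that
    minimizes the two-sided log-rank p over splits where both groups hold at
    least ``minprop`` of the samples.  Ties in p break toward the smaller
    threshold.
    """
    values = values.loc[survival.samples]
    distinct = np.sort(values.unique())
    if len(distinct) < 2:
        raise NoCutpointError("all biomarker values identical")
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    n = len(values)
    time = survival.time.values.astype(float)
    event = survival.event.values.astype(int)
    vals = values.values.astype(float)

    best: CutpointResult | None = None
    for thr in candidates:
        high = vals > thr
        n_high = int(high.sum())
        n_low = n - n_high
        if min(n_high, n_low) < minprop * n:
            continue
        try:
            chi2, p = _logrank_stat(time, event, high)
        except UndefinedTestError:
            continue
        if best is None or p < best.p_logrank - 1e-15:
            best = CutpointResult(
                threshold=float(thr), p_logrank=p, n_high=n_high, n_low=n_low, statistic=chi2
            )
    if best is None:
        raise NoCutpointError("no admissible split satisfies the minprop constraint")
    best.p_adjusted = maxsel_adjusted_p(best.statistic, minprop, 1.0 - minprop)
    return best


def km_estimate(survival: SurvivalData) -> pd.Series:
    """Kaplan-Meier product-limit survival curve (probability indexed by time)."""
    if len(survival.time) == 0:
        raise ValueError("empty survival data")
    kmf = KaplanMeierFitter()
    kmf.fit(survival.time, survival.event)
    return kmf.survival_function_["KM_estimate"]


def cox_hr(high: pd.Series, survival: SurvivalData) -> BiomarkerVerdict:
    """Univariate Cox model of a binary high/low biomarker group.

    Uses Efron tie handling, Wald 95% CI and p.  When one group has no
    events the partial likelihood is monotone; the verdict is flagged with
    an infinite-CI marker and excluded from HR clustering downstream.
    """
    high = high.loc[survival.samples].astype(int)
    if high.nunique() < 2:
        raise ValueError("both groups must be represented")
    if survival.event.sum() == 0:
        raise UndefinedTestError("no events")
    _, p_lr = _logrank_stat(
        survival.time.values.astype(float),
        survival.event.values.astype(int),
        high.values.astype(bool),
    )
    events_by_group = survival.event.groupby(high).sum()
    if (events_by_group == 0).any():
        hr = np.inf if events_by_group.get(1, 0) > 0 else 0.0
        return BiomarkerVerdict(
            hr=hr, ci_low=0.0, ci_high=np.inf, p_cox=np.nan, p_logrank=p_lr,
            stars="ns", direction="none", monotone_likelihood=True,
        )
    df = pd.DataFrame({"time": survival.time, "event": survival.event, "high": high})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    hr = float(np.exp(cph.params_["high"]))
    ci_low, ci_high = np.exp(cph.confidence_intervals_.loc["high"]).tolist()
    p_cox = float(cph.summary.loc["high", "p"])
    direction = "none"
    if p_cox < 0.05 and not (ci_low <= 1.0 <= ci_high):
        direction = "negative" if hr > 1 else "positive"
    return BiomarkerVerdict(
        hr=hr, ci_low=float(ci_low), ci_high=float(ci_high),
        p_cox=p_cox, p_logrank=p_lr, stars=stars(p_cox), direction=direction,
    )


def biomarker_screen(
    biomarkers: pd.DataFrame,
    clinical: Mapping[str, SurvivalData],
    minprop: float = 0.1,
    cohort: str = "cohort",
) -> pd.DataFrame:
    """Run cutpoint → log-rank → Cox for every (biomarker, endpoint) pair.

    ``biomarkers`` is samples × biomarkers (PAL columns and/or single-gene
    log-ratios); ``clinical`` maps endpoint names ("OS", "PFS") to follow-up
    data on the same samples.  Returns a tidy verdict table with one row per
    cell, a BH-adjusted Cox p column across the screen, and one summary row
    per biomarker with the OS/PFS-averaged HR carrying the lower significance
    level of the two endpoints.
    """
    rows = []
    for endpoint, surv in clinical.items():
        shared = biomarkers.index.intersection(surv.samples)
        surv_e = surv.subset(shared)
        for name in biomarkers.columns:
            vals = biomarkers.loc[shared, name].dropna()
            cell = {"cohort": cohort, "biomarker": name, "endpoint": endpoint}
            try:
                sub = surv_e.subset(vals.index)
                cut = find_optimal_cutpoint(vals, sub, minprop=minprop)
                verdict = cox_hr(vals > cut.threshold, sub)
                cell.update(
                    cutpoint=cut.threshold, hr=verdict.hr, ci_low=verdict.ci_low,
                    ci_high=verdict.ci_high, p_cox=verdict.p_cox,
                    p_logrank=cut.p_logrank, p_logrank_adj=cut.p_adjusted,
                    stars=verdict.stars, direction=verdict.direction, error="",
                    monotone=verdict.monotone_likelihood,
                )
            except (NoCutpointError, UndefinedTestError, ValueError) as exc:
                cell.update(
                    cutpoint=np.nan, hr=np.nan, ci_low=np.nan, ci_high=np.nan,
                    p_cox=np.nan, p_logrank=np.nan, p_logrank_adj=np.nan,
                    stars="", direction="undefined",
                    error=str(exc), monotone=False,
                )
            rows.append(cell)
    table = pd.DataFrame(rows)
    mask = table["p_cox"].notna()
    table["p_cox_bh"] = np.nan
    if mask.any():
        table.loc[mask, "p_cox_bh"] = multipletests(table.loc[mask, "p_cox"], method="fdr_bh")[1]

    _star_rank = {"***": 3, "**": 2, "*": 1, "ns": 0, "": 0}
    summaries = []
    for name, grp in table.groupby("biomarker", sort=False):
        ok = grp[grp["hr"].notna() & ~grp["monotone"]]
        if ok.empty:
            continue
        lower = min(ok["stars"], key=lambda s: _star_rank[s])
        direction = ok["direction"].iloc[0] if ok["direction"].nunique() == 1 else "mixed"
        # biomarker-level flag: consistent, significant direction on every
        # endpoint, judged on the selection-corrected cutpoint p
        flagged = bool(
            direction in ("negative", "positive")
            and (ok["p_logrank_adj"] < 0.05).all()
        )
        summaries.append(
            {
                "cohort": cohort, "biomarker": name, "endpoint": "OS+PFS_mean",
                "cutpoint": np.nan, "hr": ok["hr"].mean(), "ci_low": np.nan,
                "ci_high": np.nan, "p_cox": np.nan, "p_logrank": np.nan,
                "p_logrank_adj": np.nan, "stars": lower, "direction": direction,
                "flagged": flagged, "error": "", "monotone": False, "p_cox_bh": np.nan,
            }
        )
    if summaries:
        table = pd.concat([table, pd.DataFrame(summaries)], ignore_index=True)
    return table


def cluster_hr_profiles(
    hr_table: pd.DataFrame, n_clusters: int = 2, linkage: str = "complete"
) -> tuple[list[str], pd.Series, np.ndarray]:
    """Hierarchically cluster cohorts by their HR profiles across biomarkers.

    Undefined cells are imputed with HR = 1 (no effect) and flagged via the
    returned imputation mask attached as ``.attrs['imputed']``.  Euclidean
    distance, complete linkage, 2-cluster cut by default.

    Returns (leaf order of cohorts, flat cluster labels per cohort, linkage
    matrix).
    """
    if hr_table.shape[0] < 2:
        raise ValueError("clustering requires at least 2 cohorts")
    imputed = hr_table.isna()
    filled = hr_table.fillna(1.0)
    z = hierarchy.linkage(filled.values, method=linkage, metric="euclidean")
    order = [filled.index[i] for i in hierarchy.leaves_list(z)]
    labels = pd.Series(hierarchy.fcluster(z, t=n_clusters, criterion="maxclust"), index=filled.index)
    labels.attrs["imputed"] = imputed
    return order, labels, z
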