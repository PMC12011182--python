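"""Log-rank, optimal cutpoint, Kaplan-Meier, Cox HR, screening, clustering."""

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test as ll_logrank
from scipy import stats as sps

from palscreen.survival_stats import (
    NoCutpointError,
    SurvivalData,
    UndefinedTestError,
    biomarker_screen,
    cluster_hr_profiles,
    cox_hr,
    find_optimal_cutpoint,
    km_estimate,
    logrank_test,
    maxsel_adjusted_p,
    stars,
)


def _surv(times, events, ids=None, endpoint="OS"):
    idx = pd.Index(ids if ids is not None else [f"p{i}" for i in range(len(times))])
    return SurvivalData(
        time=pd.Series(np.asarray(times, float), index=idx),
        event=pd.Series(np.asarray(events, int), index=idx),
        endpoint=endpoint,
    )


class TestLogrank:
    def test_identical_groups(self):
        g = _surv([1, 2, 3], [1, 1, 0])
        h = _surv([1, 2, 3], [1, 1, 0], ids=["q0", "q1", "q2"])
        chi2, p = logrank_test(g, h)
        assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_six_patient_example_matches_risk_table_oracle(self):
        # group A: events at 1, 3; censored 5.  group B: events at 2, 4, 6.
        a = _surv([1, 3, 5], [1, 1, 0])
        b = _surv([2, 4, 6], [1, 1, 1], ids=["q0", "q1", "q2"])
        chi2, p = logrank_test(a, b)
        # independent oracle: explicit risk-table walk
        records = sorted(
            [(1, 1, "A"), (3, 1, "A"), (5, 0, "A"), (2, 1, "B"), (4, 1, "B"), (6, 1, "B")]
        )
        o_minus_e, var = 0.0, 0.0
        for t, _, _ in [r for r in records if r[1] == 1]:
            at_risk = [r for r in records if r[0] >= t]
            n, na = len(at_risk), sum(1 for r in at_risk if r[2] == "A")
            d = sum(1 for r in records if r[0] == t and r[1] == 1)
            da = sum(1 for r in records if r[0] == t and r[1] == 1 and r[2] == "A")
            o_minus_e += da - d * na / n
            if n > 1:
                var += d * (na / n) * (1 - na / n) * (n - d) / (n - 1)
        assert chi2 == pytest.approx(o_minus_e**2 / var)

    def test_label_exchange_symmetry(self):
        a = _surv([1, 4, 7], [1, 0, 1])
        b = _surv([2, 3, 9], [1, 1, 1], ids=["q0", "q1", "q2"])
        assert logrank_test(a, b)[1] == pytest.approx(logrank_test(b, a)[1])

    def test_no_events_is_undefined(self):
        with pytest.raises(UndefinedTestError):
            logrank_test(_surv([1, 2], [0, 0]), _surv([3], [0], ids=["q"]))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_lifelines(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        t = rng.exponential(10, n)
        e = rng.integers(0, 2, n)
        if e.sum() == 0:
            e[0] = 1
        split = n // 2
        a = _surv(t[:split], e[:split])
        b = _surv(t[split:], e[split:], ids=[f"q{i}" for i in range(n - split)])
        chi2, p = logrank_test(a, b)
        ref = ll_logrank(t[:split], t[split:], e[:split], e[split:])
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-8)
        assert p == pytest.approx(ref.p_value, rel=1e-8)


class TestCutpoint:
    def test_four_patient_brute_force(self):
        """Biomarker perfectly anti-ordered with survival: the chosen split is
        the brute-force minimum over the three admissible splits."""
        vals = pd.Series([1.0, 2.0, 3.0, 4.0], index=[f"p{i}" for i in range(4)])
        surv = _surv([10, 9, 2, 1], [1, 1, 1, 1])
        cut = find_optimal_cutpoint(vals, surv, minprop=0.25)
        best_p, best_thr = np.inf, None
        for thr in (1.5, 2.5, 3.5):
            high = vals.values > thr
            res = ll_logrank(
                surv.time.values[high], surv.time.values[~high],
                surv.event.values[high], surv.event.values[~high],
            )
            if res.p_value < best_p:
                best_p, best_thr = res.p_value, thr
        assert cut.threshold == pytest.approx(best_thr)
        assert cut.p_logrank == pytest.approx(best_p, rel=1e-8)
        # the high group contains the shortest survivors
        assert surv.time[vals > cut.threshold].max() < surv.time[vals <= cut.threshold].min()

    def test_identical_values_error(self):
        vals = pd.Series([5.0] * 4, index=[f"p{i}" for i in range(4)])
        with pytest.raises(NoCutpointError):
            find_optimal_cutpoint(vals, _surv([1, 2, 3, 4], [1, 1, 1, 1]))

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_brute_force_minimum(self, seed):
        """The returned split is exactly the admissible minimum-p split found
        by brute-force enumeration with lifelines as the log-rank oracle."""
        rng = np.random.default_rng(200 + seed)
        n = int(rng.integers(15, 60))
        vals = pd.Series(rng.normal(size=n), index=[f"p{i}" for i in range(n)])
        surv = _surv(rng.exponential(10, n), rng.integers(0, 2, n))
        if surv.event.sum() == 0:
            surv.event.iloc[0] = 1
        minprop = 0.1
        cut = find_optimal_cutpoint(vals, surv, minprop=minprop)
        distinct = np.sort(vals.unique())
        best_p, best_thr = np.inf, None
        for thr in (distinct[:-1] + distinct[1:]) / 2:
            high = vals.values > thr
            if min(high.sum(), n - high.sum()) < minprop * n:
                continue
            res = ll_logrank(
                surv.time.values[high], surv.time.values[~high],
                surv.event.values[high], surv.event.values[~high],
            )
            if res.p_value < best_p - 1e-15:
                best_p, best_thr = res.p_value, thr
        assert cut.threshold == pytest.approx(best_thr)
        assert cut.p_logrank == pytest.approx(best_p, rel=1e-8)

    def test_adjusted_p_exceeds_naive_p(self):
        # the selection-corrected p exceeds the naive chi-square p and
        # saturates at 1 for weak maxima
        for chi2 in (2.0, 4.0, 9.0):
            assert 1.0 >= maxsel_adjusted_p(chi2, 0.1, 0.9) > sps.chi2.sf(chi2, 1)
        assert maxsel_adjusted_p(0.5, 0.1, 0.9) == 1.0
        assert maxsel_adjusted_p(30.0, 0.1, 0.9) < 1e-4


class TestKaplanMeier:
    def test_no_censoring_is_empirical_survival(self):
        s = km_estimate(_surv([1, 2, 3, 4], [1, 1, 1, 1]))
        np.testing.assert_allclose(s.loc[[1.0, 2.0, 3.0, 4.0]], [0.75, 0.5, 0.25, 0.0])

    def test_all_censored_stays_at_one(self):
        s = km_estimate(_surv([1, 2, 3], [0, 0, 0]))
        np.testing.assert_allclose(s, 1.0)

    def test_five_patient_product_limit_table(self):
        s = km_estimate(_surv([1, 2, 3, 4, 5], [1, 1, 0, 1, 1]))
        np.testing.assert_allclose(s.loc[[1.0, 2.0, 3.0, 4.0, 5.0]], [0.8, 0.6, 0.6, 0.3, 0.0])

    def test_monotone_and_starts_at_one(self):
        rng = np.random.default_rng(2)
        s = km_estimate(_surv(rng.exponential(5, 30), rng.integers(0, 2, 30)))
        assert s.iloc[0] <= 1.0 and s.loc[0.0] == 1.0
        assert (np.diff(s.values) <= 1e-12).all()


def _efron_free_cox_beta(time, event, x):
    """Independent Newton-Raphson maximizer of the no-ties Cox partial
    likelihood for one binary covariate (oracle; distinct times only)."""
    order = np.argsort(time)
    t, e, z = time[order], event[order], x[order]
    beta = 0.0
    for _ in range(50):
        u, i_info = 0.0, 0.0
        for k in range(len(t)):
            if not e[k]:
                continue
            risk = z[k:]
            w = np.exp(beta * risk)
            zbar = (risk * w).sum() / w.sum()
            u += z[k] - zbar
            i_info += (risk**2 * w).sum() / w.sum() - zbar**2
        step = u / i_info
        beta += step
        if abs(step) < 1e-12:
            break
    return beta


class TestCox:
    def test_identical_groups_hr_near_one(self):
        t = np.array([1, 2, 3, 4, 5, 6, 7, 8], float)
        e = np.ones(8, int)
        surv = _surv(np.concatenate([t, t]), np.concatenate([e, e]))
        high = pd.Series([True] * 8 + [False] * 8, index=surv.samples)
        v = cox_hr(high, surv)
        assert v.hr == pytest.approx(1.0, abs=1e-6)
        assert v.ci_low < 1.0 < v.ci_high and v.direction == "none"

    def test_eight_patient_coefficient_matches_newton_raphson_oracle(self):
        time = np.array([3.0, 5.0, 7.0, 11.0, 13.0, 17.0, 19.0, 23.0])
        event = np.array([1, 1, 0, 1, 1, 0, 1, 1])
        x = np.array([1, 0, 1, 0, 1, 0, 0, 1])
        surv = _surv(time, event)
        v = cox_hr(pd.Series(x.astype(bool), index=surv.samples), surv)
        beta_oracle = _efron_free_cox_beta(time, event, x.astype(float))
        assert np.log(v.hr) == pytest.approx(beta_oracle, abs=1e-6)

    def test_swapping_group_labels_inverts_hr(self):
        rng = np.random.default_rng(4)
        n = 60
        high = pd.Series(rng.random(n) < 0.5, index=[f"p{i}" for i in range(n)])
        surv = _surv(rng.exponential(10 - 5 * high.values), np.ones(n, int), ids=high.index)
        v1, v2 = cox_hr(high, surv), cox_hr(~high, surv)
        assert v1.hr == pytest.approx(1 / v2.hr, rel=1e-6)
        assert v1.ci_low == pytest.approx(1 / v2.ci_high, rel=1e-6)

    def test_monotone_likelihood_flagged(self):
        surv = _surv([1, 2, 3, 4], [1, 1, 0, 0])
        high = pd.Series([False, False, True, True], index=surv.samples)
        v = cox_hr(high, surv)
        assert v.monotone_likelihood and v.direction == "none"

    @pytest.mark.parametrize("seed", range(3))
    def test_recovers_generative_rate_ratio(self, seed):
        rng = np.random.default_rng(seed)
        n = 400
        high = pd.Series(np.arange(n) < n // 2, index=[f"p{i}" for i in range(n)])
        lam = 0.01 * np.where(high.values, 2.0, 1.0)
        surv = _surv(rng.exponential(1 / lam), np.ones(n, int), ids=high.index)
        v = cox_hr(high, surv)
        assert 1.6 < v.hr < 2.5 and v.direction == "negative"


class TestScreen:
    def _screen_inputs(self, seed=0, n=120, beta=np.log(2)):
        rng = np.random.default_rng(seed)
        ids = [f"p{i}" for i in range(n)]
        pal = pd.Series(rng.normal(size=n), index=ids)
        lam = 0.01 * np.exp(beta * (pal.values > 0))
        clinical = {}
        for endpoint in ("OS", "PFS"):
            t = rng.exponential(1 / lam)
            c = rng.exponential(200, n)
            clinical[endpoint] = _surv(np.minimum(t, c), (t <= c).astype(int), ids, endpoint)
        return pd.DataFrame({"PAL": pal}), clinical

    def test_high_hazard_pal_reads_negative(self):
        biomarkers, clinical = self._screen_inputs()
        table = biomarker_screen(biomarkers, clinical)
        cells = table[table["endpoint"].isin(["OS", "PFS"])]
        assert (cells["direction"] == "negative").all()

    def test_mean_hr_row_is_arithmetic_mean_with_lower_stars(self):
        biomarkers, clinical = self._screen_inputs(seed=1)
        table = biomarker_screen(biomarkers, clinical)
        cells = table[table["endpoint"].isin(["OS", "PFS"])]
        mean_row = table[table["endpoint"] == "OS+PFS_mean"].iloc[0]
        assert mean_row["hr"] == pytest.approx(cells["hr"].mean())
        order = {"ns": 0, "*": 1, "**": 2, "***": 3}
        assert order[mean_row["stars"]] == min(order[s] for s in cells["stars"])

    def test_all_censored_endpoint_marked_undefined(self):
        biomarkers, clinical = self._screen_inputs()
        dead = clinical["OS"]
        clinical["OS"] = SurvivalData(dead.time, dead.event * 0, "OS")
        table = biomarker_screen(biomarkers, clinical)
        os_row = table[(table["endpoint"] == "OS")].iloc[0]
        assert os_row["direction"] == "undefined" and os_row["error"]


class TestClusterHr:
    def test_two_blocks_recovered(self):
        rng = np.random.default_rng(9)
        block1 = 2.0 + rng.normal(0, 0.05, size=(5, 4))
        block2 = 0.5 + rng.normal(0, 0.05, size=(4, 4))
        hr = pd.DataFrame(
            np.vstack([block1, block2]), index=[f"c{i}" for i in range(9)]
        )
        _, labels, _ = cluster_hr_profiles(hr)
        assert labels.iloc[:5].nunique() == 1 and labels.iloc[5:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_identical_rows_merge_at_zero_height(self):
        hr = pd.DataFrame([[1.0, 2.0]] * 3, index=["a", "b", "c"])
        _, labels, z = cluster_hr_profiles(hr)
        assert z[:, 2].max() == 0.0

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(12)
        hr = pd.DataFrame(rng.uniform(0.5, 2, size=(6, 3)), index=[f"c{i}" for i in range(6)])
        _, labels1, _ = cluster_hr_profiles(hr)
        perm = hr.sample(frac=1, random_state=1)
        _, labels2, _ = cluster_hr_profiles(perm)
        parts1 = {tuple(sorted(labels1[labels1 == k].index)) for k in labels1.unique()}
        parts2 = {tuple(sorted(labels2[labels2 == k].index)) for k in labels2.unique()}
        assert parts1 == parts2

    def test_single_row_errors(self):
        with pytest.raises(ValueError):
            cluster_hr_profiles(pd.DataFrame([[1.0]], index=["a"]))


def test_star_thresholds():
    assert stars(0.0005) == "***" and stars(0.005) == "**" and stars(0.02) == "*" and stars(0.2) == "ns"
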