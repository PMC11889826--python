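"""Clinical statistics contracts: response dichotomy, log-rank vs a
hand-built risk table, Cox recovery/coverage, rank tests, correlations."""

import numpy as np
import pandas as pd
import pytest

from cfmon.errors import CfmonError, ConfigurationError
from cfmon.outcomes import (correlation_matrix, cox_fit,
                            dichotomize_response, group_compare, km_logrank)


def test_response_dichotomy():
    assert dichotomize_response(6.8, True) == "SCR"
    assert dichotomize_response(15.6, True) == "DCR"
    assert dichotomize_response(12.0, True) == "SCR"       # boundary <= 12
    assert dichotomize_response(13.0, False) == "DCR"      # censored past cut
    assert dichotomize_response(9.0, False) == "not_evaluable"


def test_logrank_identical_groups_is_null():
    times = [1.0, 2.0, 3.0, 4.0]
    events = [True, True, False, True]
    res = km_logrank(times + times, events + events, [0] * 4 + [1] * 4)
    assert res["statistic"] == pytest.approx(0.0, abs=1e-12)
    assert res["p"] == pytest.approx(1.0)


def _brute_force_logrank(times, events, groups):
    """Textbook risk-table computation of the two-group log-rank statistic."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    groups = np.asarray(groups)
    obs1 = exp1 = var = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == 1)).sum()
        d = (events & (times == t)).sum()
        d1 = (events & (times == t) & (groups == 1)).sum()
        obs1 += d1
        exp1 += d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (obs1 - exp1) ** 2 / var


def test_logrank_matches_hand_risk_table():
    times = [1.0, 2.0, 3.0, 4.0]
    events = [True] * 4
    groups = [0, 0, 1, 1]
    res = km_logrank(times, events, groups)
    assert res["statistic"] == pytest.approx(
        _brute_force_logrank(times, events, groups))


def test_logrank_requires_two_groups_and_events():
    with pytest.raises(ConfigurationError):
        km_logrank([1, 2], [True, True], [0, 0])
    with pytest.raises(ConfigurationError):
        km_logrank([1, 2], [False, False], [0, 1])


def test_logrank_power_under_hr_four():
    """HR = 4, n = 50/arm exponential survival: p < 0.01 in >= 90% of
    replicates."""
    rng = np.random.default_rng(0)
    hits = 0
    reps = 100
    for _ in range(reps):
        t0 = rng.exponential(1.0, size=50)
        t1 = rng.exponential(1.0 / 4.0, size=50)
        res = km_logrank(np.r_[t0, t1], np.ones(100, bool),
                         np.r_[np.zeros(50), np.ones(50)])
        hits += res["p"] < 0.01
    assert hits >= 90


def test_cox_null_covariate_hr_near_one():
    times = np.r_[np.arange(1, 21), np.arange(1, 21)]
    events = np.ones(40, bool)
    cov = pd.DataFrame({"arm": np.r_[np.zeros(20), np.ones(20)]})
    fit = cox_fit(times, events, cov)
    assert fit.ci95[0] <= 1.0 <= fit.ci95[1]


def test_cox_ci_coverage_of_true_hr():
    """95% CI covers the true HR=4 in about 95% of replicates (n=100)."""
    rng = np.random.default_rng(1)
    covered = 0
    reps = 60
    for _ in range(reps):
        arm = rng.random(100) < 0.5
        t = rng.exponential(1.0 / np.where(arm, 4.0, 1.0))
        fit = cox_fit(t, np.ones(100, bool),
                      pd.DataFrame({"arm": arm.astype(int)}))
        covered += fit.ci95[0] <= 4.0 <= fit.ci95[1]
    assert covered / reps >= 0.85


def test_cox_univariate_close_to_multivariable_with_noise_covariate():
    rng = np.random.default_rng(2)
    n = 500
    arm = (rng.random(n) < 0.5).astype(int)
    t = rng.exponential(1.0 / np.exp(np.log(3) * arm))
    noise = rng.normal(size=n)
    uni = cox_fit(t, np.ones(n, bool), pd.DataFrame({"arm": arm}))
    mva = cox_fit(t, np.ones(n, bool),
                  pd.DataFrame({"arm": arm, "noise": noise}))
    assert abs(np.log(uni.hazard_ratio) - np.log(mva.hazard_ratio)) < 0.2


def test_cox_needs_events():
    with pytest.raises(CfmonError, match="events"):
        cox_fit([1.0, 2.0], [False, False], pd.DataFrame({"x": [0, 1]}))


def test_mannwhitney_exact_enumeration():
    """{1,2,3} vs {10,11,12}: U = 0, exact two-sided p = 2/20 = 0.1."""
    res = group_compare([1, 2, 3], [10, 11, 12])
    assert res["p"] == pytest.approx(0.1)


def test_group_compare_degenerate_inputs():
    res = group_compare([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
    assert res["p"] == 1.0 and res["degenerate"]
    paired = group_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=True)
    assert paired["p"] == 1.0 and paired["degenerate"]


def test_paired_test_uses_wilcoxon():
    a = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
    b = [2.0, 3.0, 4.0, 5.0, 6.0, 7.0]
    res = group_compare(a, b, paired=True)
    from scipy.stats import wilcoxon
    assert res["p"] == pytest.approx(wilcoxon(a, b).pvalue)


def test_spearman_hand_case_and_banding():
    x = pd.DataFrame({"x": [1, 2, 3, 4, 5]})
    y = pd.DataFrame({"y": [1, 2, 3, 5, 4]})
    mat = correlation_matrix(x, y)
    assert mat["rho"].iloc[0] == pytest.approx(0.9)
    self_mat = correlation_matrix(pd.DataFrame({"a": [1., 2, 3, 4, 5],
                                                "b": [-1., -2, -3, -4, -5]}))
    rho_ab = self_mat.query("x=='a' and y=='b'")["rho"].iloc[0]
    assert rho_ab == pytest.approx(-1.0)
    assert self_mat.query("x=='a' and y=='a'")["band"].iloc[0] == "strong"


def test_correlation_insufficient_pairs_flagged():
    x = pd.DataFrame({"x": [1.0, np.nan, np.nan, np.nan, np.nan]})
    y = pd.DataFrame({"y": [1.0, 2.0, 3.0, 4.0, 5.0]})
    mat = correlation_matrix(x, y)
    assert mat["band"].iloc[0] == "not_evaluable"
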