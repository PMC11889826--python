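"""Threshold calibration, per-sample calls, combination rules, and
longitudinal classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cfmon.detection import (DEFAULT_DIRECTIONS, MARKERS, assign_group_ab,
                             call_sample, classify_longitudinal,
                             fit_thresholds, quantile_splits)
from cfmon.errors import CalibrationError, ConfigurationError


def _fit(values, spec=0.95, direction="high", marker="m"):
    table = pd.DataFrame({marker: values})
    return fit_thresholds(table, specificity=spec,
                          directions={marker: direction},
                          min_healthy=min(10, len(values)))


def test_threshold_order_statistic_rule():
    """Healthy values 1..20 at 95% specificity -> threshold 19 (only the
    value 20 exceeds; achieved specificity 95%)."""
    fitted = _fit(np.arange(1, 21))
    assert fitted.thresholds["m"] == 19
    assert fitted.achieved_specificity["m"] == pytest.approx(0.95)


def test_threshold_brute_force_agreement():
    """The fitted threshold equals the smallest healthy value whose strict
    exceedance share is within budget, for arbitrary value sets."""
    rng = np.random.default_rng(3)
    for _ in range(20):
        vals = np.round(rng.normal(size=rng.integers(10, 40)), 2)
        fitted = _fit(vals)
        thr = fitted.thresholds["m"]
        candidates = [t for t in np.sort(vals)
                      if np.mean(vals > t) <= 0.05]
        assert thr == min(candidates)


def test_threshold_all_equal_values():
    fitted = _fit(np.full(12, 3.3))
    assert fitted.thresholds["m"] == pytest.approx(3.3)


def test_threshold_full_specificity_is_max():
    fitted = _fit(np.arange(1, 21), spec=1.0)
    assert fitted.thresholds["m"] == 20


def test_threshold_low_direction():
    fitted = _fit(np.arange(1, 21), direction="low")
    assert fitted.thresholds["m"] == 2  # only the value 1 falls below


def test_threshold_needs_enough_healthy():
    with pytest.raises(CalibrationError):
        fit_thresholds(pd.DataFrame({"m": [1.0, 2.0]}))
    with pytest.raises(ConfigurationError):
        fit_thresholds(pd.DataFrame({"m": np.arange(20.0)}), specificity=0.4)


@settings(max_examples=40, deadline=None)
@given(st.lists(st.floats(-100, 100, allow_nan=False), min_size=10,
                max_size=60))
def test_calibration_specificity_guarantee(values):
    """By construction, at most 5% of calibration samples exceed the fitted
    threshold (strict comparison; ties call negative)."""
    fitted = _fit(np.asarray(values))
    thr = fitted.thresholds["m"]
    assert np.mean(np.asarray(values) > thr) <= 0.05


def _thr(**kw):
    markers = dict.fromkeys(MARKERS, 1.0)
    markers.update(kw)
    return fit_thresholds(
        pd.DataFrame({m: np.full(10, v) for m, v in markers.items()}),
        min_healthy=10)


def test_all_markers_at_healthy_level_negative():
    thr = _thr()
    call = call_sample({m: 1.0 for m in MARKERS}, thr)
    assert not call.ctdna_any and not call.cnv_detect \
        and not call.residual_ctdna


def test_ctcpa_alone_drives_cnv_and_residual():
    thr = _thr()
    mv = {m: 1.0 for m in MARKERS}
    mv["ctcpa"] = 2.0
    call = call_sample(mv, thr)
    assert call.cnv_detect and call.residual_ctdna and call.ctdna_any
    assert not call.marker_positive["cpa"]


def test_mds_alone_is_any_but_not_residual():
    thr = _thr()
    mv = {m: 1.0 for m in MARKERS}
    mv["mds"] = 2.0
    call = call_sample(mv, thr)
    assert call.ctdna_any and not call.cnv_detect and not call.residual_ctdna


def test_undefined_marker_is_negative_with_flag():
    thr = _thr()
    mv = {m: 1.0 for m in MARKERS}
    mv["ctcpa"] = float("nan")
    call = call_sample(mv, thr)
    assert "ctcpa" in call.not_evaluable
    assert not call.marker_positive["ctcpa"]


def test_union_dominates_every_single_marker():
    """sensitivity(any marker) >= max per-marker sensitivity: set inclusion
    on random call matrices."""
    rng = np.random.default_rng(9)
    for _ in range(20):
        calls = rng.random((30, len(MARKERS))) < 0.3
        union_sens = np.mean(calls.any(axis=1))
        assert union_sens >= calls.mean(axis=0).max()


def test_longitudinal_truth_table():
    assert classify_longitudinal(True, False) == "clearance"
    assert classify_longitudinal(False, False) == "double_negative"
    assert classify_longitudinal(False, True) == "residual_positive"
    assert classify_longitudinal(True, True) == "residual_positive"
    assert classify_longitudinal(None, True) == "not_evaluable"
    assert classify_longitudinal(True, None) == "not_evaluable"


def test_group_ab_truth_table():
    assert assign_group_ab(50.0, False, False) == "A"
    assert assign_group_ab(0.0, False, False) == "B"
    assert assign_group_ab(50.0, True, False) == "B"
    assert assign_group_ab(50.0, False, True) == "B"
    assert assign_group_ab(1.0, False, False) == "A"  # TPS >= 1 boundary
    assert assign_group_ab(None, False, False) == "not_evaluable"
    assert assign_group_ab(float("nan"), False, False) == "not_evaluable"


def test_quantile_splits_median_of_one_to_eight():
    splits = quantile_splits(np.arange(1, 9))
    assert splits["q50"].sum() == 4  # cut at 4.5 -> values 5..8 above
    assert list(np.arange(1, 9)[splits["q50"]]) == [5, 6, 7, 8]


def test_quantile_splits_q90_of_ten_values():
    splits = quantile_splits(np.arange(1, 11))
    assert splits["q90"].sum() == 1


def test_quantile_splits_identical_values():
    splits = quantile_splits(np.full(10, 2.5))
    assert not splits.to_numpy().any()
    with pytest.raises(CalibrationError):
        quantile_splits([1, 2, 3])
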