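"""Specificity-calibrated ctDNA detection and longitudinal classification.

Per-marker thresholds are order statistics of the healthy cohort chosen so
that at most a ``1 - specificity`` share of healthy calibration samples
falls beyond them; a sample calls positive only when it is STRICTLY beyond
the threshold in the marker's direction (ties call negative, preserving the
specificity guarantee).

Combination rules:

* ``cnv_detect``     = CPA+ or ctCPA+
* ``ctdna_any``      = any marker positive
* ``residual_ctdna`` = cnv_detect or iwFAF+  (the post-cycle-4 construct)

Markers that cannot be evaluated for a sample (e.g. ctCPA without an
informative segment set) count as negative and are flagged not-evaluable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CalibrationError, ConfigurationError

MARKERS = ["cpa", "ctcpa", "p126_135", "d126_135", "mds", "alu", "iwfaf"]

# all markers call positive when HIGH by default; P126-135 moves both ways,
# which is exactly why D126-135 exists, but both stay in the marker list.
DEFAULT_DIRECTIONS = {m: "high" for m in MARKERS}


@dataclass
class DetectionThresholds:
    thresholds: dict                 # marker -> float
    directions: dict                 # marker -> "high" | "low"
    specificity: float
    n_healthy: dict                  # marker -> int
    achieved_specificity: dict       # marker -> float on calibration cohort
    provenance: dict = field(default_factory=dict)


@dataclass
class DetectionCall:
    sample_id: str
    marker_positive: dict            # marker -> bool
    not_evaluable: set
    cnv_detect: bool
    ctdna_any: bool
    residual_ctdna: bool


def _one_threshold(values: np.ndarray, specificity: float, direction: str
                   ) -> tuple[float, float]:
    """Smallest (largest for direction=low) healthy value t such that the
    share of healthy values strictly beyond t is <= 1 - specificity."""
    v = np.asarray(values, dtype=float)
    if direction == "low":
        v = -v
    v = np.sort(v)
    allowed = 1.0 - specificity
    # candidates in increasing order; exceedance share is non-increasing
    for t in v:
        if np.mean(v > t) <= allowed:
            thr = t
            break
    achieved = 1.0 - float(np.mean(v > thr))
    return (float(-thr) if direction == "low" else float(thr)), achieved


def fit_thresholds(healthy_marker_table: pd.DataFrame,
                   specificity: float = 0.95,
                   directions: dict | None = None,
                   min_healthy: int = 10) -> DetectionThresholds:
    """Per-marker detection thresholds from healthy-cohort marker scores.

    ``healthy_marker_table`` has one row per healthy sample and one column
    per marker; NaNs (not-evaluable) are ignored per marker.
    """
    if not 0.5 < specificity <= 1.0:
        raise ConfigurationError("specificity must lie in (0.5, 1]")
    directions = {**DEFAULT_DIRECTIONS, **(directions or {})}
    thresholds, n_used, achieved = {}, {}, {}
    for marker in healthy_marker_table.columns:
        vals = healthy_marker_table[marker].dropna().to_numpy(dtype=float)
        if len(vals) < min_healthy:
            raise CalibrationError(
                f"marker {marker}: {len(vals)} healthy values "
                f"< required {min_healthy}")
        direction = directions.get(marker, "high")
        thr, ach = _one_threshold(vals, specificity, direction)
        thresholds[marker] = thr
        n_used[marker] = len(vals)
        achieved[marker] = ach
    return DetectionThresholds(thresholds, directions, specificity,
                               n_used, achieved)


def _beyond(value: float, threshold: float, direction: str) -> bool:
    return value > threshold if direction == "high" else value < threshold


def call_sample(marker_vector, thresholds: DetectionThresholds
                ) -> DetectionCall:
    """Apply fitted thresholds to one sample's marker scores.

    ``marker_vector`` is a mapping/Series of marker -> score; missing or NaN
    markers are negative-with-flag.
    """
    mv = dict(marker_vector)
    sample_id = str(mv.pop("sample_id", ""))
    positive, not_evaluable = {}, set()
    for marker, thr in thresholds.thresholds.items():
        value = mv.get(marker, np.nan)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            positive[marker] = False
            not_evaluable.add(marker)
        else:
            positive[marker] = _beyond(float(value), thr,
                                       thresholds.directions[marker])
    cnv = positive.get("cpa", False) or positive.get("ctcpa", False)
    any_pos = any(positive.values())
    residual = cnv or positive.get("iwfaf", False)
    return DetectionCall(sample_id, positive, not_evaluable, cnv, any_pos,
                         residual)


def classify_longitudinal(baseline_positive, cycle4_positive) -> str:
    """Two-timepoint category: double_negative / clearance / residual_positive.

    Any positive cycle-4 sample is residual_positive regardless of baseline;
    a missing timepoint makes the pair not evaluable.
    """
    if baseline_positive is None or cycle4_positive is None:
        return "not_evaluable"
    if cycle4_positive:
        return "residual_positive"
    return "clearance" if baseline_positive else "double_negative"


def assign_group_ab(tps_percent, baseline_d126_positive,
                    cycle4_residual_positive) -> str:
    """Integrated risk group.

    Group A: PD-L1 TPS >= 1%, undetectable baseline D126-135 AND no residual
    ctDNA after 4 cycles; Group B: any of those biomarkers positive or
    TPS < 1%. Missing inputs make the subject not evaluable.
    """
    if tps_percent is None or baseline_d126_positive is None \
            or cycle4_residual_positive is None:
        return "not_evaluable"
    if isinstance(tps_percent, float) and math.isnan(tps_percent):
        return "not_evaluable"
    if (tps_percent >= 1.0 and not baseline_d126_positive
            and not cycle4_residual_positive):
        return "A"
    return "B"


def quantile_splits(cohort_baseline_values,
                    quantiles=(0.25, 0.5, 0.75, 0.9)) -> pd.DataFrame:
    """Dichotomize a cohort at increasing quantiles of its baseline values.

    Returns a boolean DataFrame (one column per quantile, True = strictly
    above the empirical quantile cut, linear interpolation).
    """
    values = np.asarray(list(cohort_baseline_values), dtype=float)
    if len(values) < 8:
        raise CalibrationError(
            f"need >= 8 baseline values for quantile splits, got {len(values)}")
    out = {}
    for q in quantiles:
        cut = float(np.quantile(values, q))
        out[f"q{int(round(q * 100))}"] = values > cut
    return pd.DataFrame(out)
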