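"""End-to-end orchestration: simulate -> extract -> profile -> score ->
calibrate -> detect -> classify -> outcomes.

The cohort-level entry point is :func:`run_pipeline`; the pieces
(:func:`calibrate`, :func:`marker_vector`, :func:`run_cohort`) are reusable
by scripts and tests. All marker computations flow through the same code
paths for healthy calibration samples and patient samples.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cnv, detection, fragmentomics as fm, outcomes, scores
from .errors import CfmonError, InsufficientDataError
from .fragments import SampleFragmentSet, filter_fragments, \
    filter_mononucleosomal
from .simulate import SimulationConfig, SyntheticCohort, \
    alu_intervals_frame, config_to_dict, simulate_cohort, simulation_context

log = logging.getLogger("cfmon")

MIN_FRAGMENT_LENGTH = 50


@dataclass
class Calibration:
    """Everything derived from the healthy cohort that downstream calls need."""

    bins: cnv.GenomeBins
    panel: cnv.PanelOfNormals
    alu_intervals: pd.DataFrame | None
    end_reference: fm.EndPositionReference
    healthy_profiles: list                  # normalized BinProfile per healthy
    healthy_p126: np.ndarray
    healthy_table: pd.DataFrame             # marker scores per healthy sample
    thresholds: detection.DetectionThresholds
    specificity: float
    warnings: list = field(default_factory=list)


def _mono(fragset: SampleFragmentSet) -> SampleFragmentSet:
    """The fragmentomic-marker view of a sample: quality + length filtered,
    then restricted to the mononucleosomal peak. CNV profiling keeps all
    lengths."""
    fs = filter_fragments(fragset, min_length=MIN_FRAGMENT_LENGTH,
                          drop_duplicates=True)
    return filter_mononucleosomal(fs)


def _fragment_markers(fragset: SampleFragmentSet,
                      alu_intervals: pd.DataFrame | None,
                      end_reference: fm.EndPositionReference | None,
                      healthy_p126: np.ndarray | None) -> dict:
    mono = _mono(fragset)
    out = {"p126_135": np.nan, "d126_135": np.nan, "mds": np.nan,
           "alu": np.nan, "iwfaf": np.nan}
    try:
        out["p126_135"] = fm.p126_135(mono)
    except InsufficientDataError:
        return out
    if healthy_p126 is not None and len(healthy_p126) >= 3:
        out["d126_135"] = fm.d126_135(out["p126_135"], healthy_p126)
    try:
        out["mds"] = fm.mds(fm.end_motif_counts(mono))
    except InsufficientDataError:
        pass
    if alu_intervals is not None:
        try:
            out["alu"] = fm.alu_cgn_ncg_ratio(mono, alu_intervals)
        except InsufficientDataError:
            pass
    if end_reference is not None:
        out["iwfaf"] = fm.iwfaf(mono, end_reference)
    return out


def sample_cnv(fragset: SampleFragmentSet, calib: "Calibration"
               ) -> tuple[cnv.BinProfile, cnv.SegmentProfile, float]:
    """Normalized profile, segmentation, and CPA score for one sample."""
    prof = cnv.bin_counts(fragset, calib.bins)
    norm = cnv.normalize(prof, calib.bins, calib.panel)
    seg = cnv.segment(norm)
    return norm, seg, scores.cpa_score(seg)


def calibrate(healthy_fragsets, bins: cnv.GenomeBins,
              alu_intervals: pd.DataFrame | None = None,
              specificity: float = 0.95) -> Calibration:
    """Build the panel of normals, the healthy end-position reference, the
    healthy marker distributions, and the 95%-specificity thresholds."""
    healthy_fragsets = list(healthy_fragsets)
    panel = cnv.build_panel(healthy_fragsets, bins)
    monos = [_mono(fs) for fs in healthy_fragsets]
    end_ref = fm.build_end_position_reference(monos)
    healthy_p126 = np.array([fm.p126_135(m) for m in monos])

    rows, profiles = [], []
    for fs, mono in zip(healthy_fragsets, monos):
        prof = cnv.normalize(cnv.bin_counts(fs, bins), bins, panel)
        profiles.append(prof)
        seg = cnv.segment(prof)
        row = {"sample_id": fs.sample_id,
               "cpa": scores.cpa_score(seg)}
        row.update(_fragment_markers(fs, alu_intervals, end_ref,
                                     healthy_p126))
        rows.append(row)
    table = pd.DataFrame(rows).set_index("sample_id")
    warnings = []
    if alu_intervals is None:
        table = table.drop(columns=["alu"])
        warnings.append("no Alu intervals supplied; ALU marker skipped")
    thresholds = detection.fit_thresholds(
        table, specificity=specificity,
        min_healthy=min(10, len(healthy_fragsets)))
    return Calibration(bins, panel, alu_intervals, end_ref, profiles,
                       healthy_p126, table, thresholds, specificity,
                       warnings)


def ctcpa_healthy_values(calib: Calibration,
                         informative: scores.InformativeSegmentSet
                         ) -> np.ndarray:
    """Project every healthy panel profile through an informative segment
    set: the null distribution for that patient's ctCPA threshold."""
    return np.array([scores.ctcpa_score(p, informative)
                     for p in calib.healthy_profiles])


def ctcpa_threshold(calib: Calibration,
                    informative: scores.InformativeSegmentSet) -> float:
    vals = ctcpa_healthy_values(calib, informative)
    table = pd.DataFrame({"ctcpa": vals})
    fitted = detection.fit_thresholds(
        table, specificity=calib.specificity,
        min_healthy=min(10, len(vals)))
    return fitted.thresholds["ctcpa"]


def marker_vector(fragset: SampleFragmentSet, calib: Calibration,
                  informative: scores.InformativeSegmentSet | None = None
                  ) -> dict:
    """All seven marker scores for one sample (ctCPA NaN without an
    informative segment set)."""
    norm, seg, cpa = sample_cnv(fragset, calib)
    out = {"sample_id": fragset.sample_id, "cpa": cpa, "ctcpa": np.nan}
    if informative is not None and informative.n > 0:
        out["ctcpa"] = scores.ctcpa_score(norm, informative)
    out.update(_fragment_markers(fragset, calib.alu_intervals,
                                 calib.end_reference, calib.healthy_p126))
    return out


@dataclass
class CohortResults:
    scores: pd.DataFrame
    calls: pd.DataFrame
    thresholds: detection.DetectionThresholds
    ctcpa_thresholds: dict
    longitudinal: pd.DataFrame
    survival: pd.DataFrame
    calibration: Calibration
    km: dict = field(default_factory=dict)


def _call_row(row: pd.Series, calib: Calibration,
              ctcpa_thr: dict) -> detection.DetectionCall:
    thr = detection.DetectionThresholds(
        dict(calib.thresholds.thresholds),
        dict(calib.thresholds.directions),
        calib.thresholds.specificity,
        dict(calib.thresholds.n_healthy),
        dict(calib.thresholds.achieved_specificity))
    subject = row.get("subject_id", "")
    if subject in ctcpa_thr:
        thr.thresholds["ctcpa"] = ctcpa_thr[subject]
        thr.directions["ctcpa"] = "high"
    else:
        thr.thresholds.pop("ctcpa", None)
    return detection.call_sample(
        {m: row[m] for m in detection.MARKERS if m in row.index},
        thr)


def run_cohort(cohort: SyntheticCohort, specificity: float = 0.95
               ) -> CohortResults:
    """Score, call, classify, and analyze a full synthetic cohort."""
    config = cohort.config
    ctx = simulation_context(config)
    alu = alu_intervals_frame(config)
    calib = calibrate(cohort.healthy, ctx.bins, alu, specificity)

    # per-subject informative sets from CNV-detectable baselines
    informative, ctcpa_thr = {}, {}
    seg_cache = {}
    for subject, samples in cohort.patient_samples.items():
        base = samples.get("baseline")
        if base is None:
            continue
        norm, seg, cpa = sample_cnv(base, calib)
        seg_cache[base.sample_id] = (norm, seg, cpa)
        if cpa > calib.thresholds.thresholds["cpa"]:
            inf = scores.select_informative_segments(seg, subject_id=subject)
            if inf.n > 0:
                informative[subject] = inf
                ctcpa_thr[subject] = ctcpa_threshold(calib, inf)

    rows = []
    for fs in cohort.all_patient_fragsets():
        inf = informative.get(fs.subject_id)
        mv = marker_vector(fs, calib, inf)
        mv.update(subject_id=fs.subject_id, timepoint=fs.timepoint)
        rows.append(mv)
    score_table = pd.DataFrame(rows)

    call_rows = []
    for _, row in score_table.iterrows():
        call = _call_row(row, calib, ctcpa_thr)
        call_rows.append({
            "sample_id": row["sample_id"],
            "subject_id": row["subject_id"],
            "timepoint": row["timepoint"],
            **{f"{m}_pos": call.marker_positive.get(m, False)
               for m in detection.MARKERS},
            "not_evaluable": ";".join(sorted(call.not_evaluable)),
            "cnv_detect": call.cnv_detect,
            "ctdna_any": call.ctdna_any,
            "residual_ctdna": call.residual_ctdna,
        })
    calls = pd.DataFrame(call_rows)

    # longitudinal classification on the residual-ctDNA basis
    long_rows = []
    for subject in sorted(cohort.patient_samples):
        sub = calls[calls["subject_id"] == subject]
        base = sub[sub["timepoint"] == "baseline"]
        c4 = sub[sub["timepoint"] == "cycle4"]
        b = bool(base["residual_ctdna"].iloc[0]) if len(base) else None
        c = bool(c4["residual_ctdna"].iloc[0]) if len(c4) else None
        category = detection.classify_longitudinal(b, c)
        d126_b = bool(base["d126_135_pos"].iloc[0]) if len(base) else None
        clin = cohort.clinical[cohort.clinical["subject_id"] == subject]
        tps = float(clin["pd_l1_tps"].iloc[0]) if len(clin) else None
        group = detection.assign_group_ab(tps, d126_b, c)
        long_rows.append({"subject_id": subject,
                          "baseline_residual": b, "cycle4_residual": c,
                          "baseline_d126_pos": d126_b,
                          "category": category, "group_ab": group})
    longitudinal = pd.DataFrame(long_rows)

    survival, km = _survival_fits(cohort.clinical, longitudinal)
    return CohortResults(score_table, calls, calib.thresholds, ctcpa_thr,
                         longitudinal, survival, calib, km)


def _survival_fits(clinical: pd.DataFrame, longitudinal: pd.DataFrame
                   ) -> tuple[pd.DataFrame, dict]:
    df = clinical.merge(longitudinal, on="subject_id")
    fits, km = [], {}

    def _one(label, flag_col, endpoint):
        time_col = "pfs_months" if endpoint == "PFS" else "os_months"
        event_col = "pfs_event" if endpoint == "PFS" else "os_event"
        sub = df[df[flag_col].notna()].copy()
        sub["_flag"] = sub[flag_col].astype(int)
        if sub["_flag"].nunique() < 2:
            return
        try:
            fit = outcomes.cox_fit(sub[time_col], sub[event_col],
                                   sub[["_flag"]], endpoint=endpoint,
                                   grouping=label)
            lr = outcomes.km_logrank(sub[time_col], sub[event_col],
                                     sub["_flag"])
            km[f"{label}:{endpoint}"] = lr["curves"]
            fits.append({"grouping": label, "endpoint": endpoint,
                         "hr": fit.hazard_ratio, "ci_low": fit.ci95[0],
                         "ci_high": fit.ci95[1], "cox_p": fit.p_value,
                         "logrank_p": lr["p"],
                         "n_neg": int((sub["_flag"] == 0).sum()),
                         "n_pos": int((sub["_flag"] == 1).sum())})
        except CfmonError as exc:
            log.warning("survival fit %s/%s skipped: %s", label, endpoint, exc)

    _one("baseline_d126", "baseline_d126_pos", "PFS")
    _one("residual_ctdna_cycle4", "cycle4_residual", "PFS")
    _one("residual_ctdna_cycle4", "cycle4_residual", "OS")
    dfb = df.assign(group_b=lambda d: d["group_ab"].map(
        {"A": False, "B": True, "not_evaluable": np.nan}))
    df["group_b"] = dfb["group_b"]
    _one("group_b", "group_b", "PFS")
    _one("group_b", "group_b", "OS")
    return pd.DataFrame(fits), km


def config_hash(config: SimulationConfig) -> str:
    blob = json.dumps(config_to_dict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_pipeline(config: SimulationConfig, outdir,
                 specificity: float = 0.95,
                 cohort: SyntheticCohort | None = None) -> CohortResults:
    """Simulate (unless a cohort is supplied), run the full analysis, and
    write the report bundle under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cohort is None:
        cohort = simulate_cohort(config)
    results = run_cohort(cohort, specificity)
    h = config_hash(config)

    def _write(df: pd.DataFrame, name: str):
        path = outdir / name
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")

    _write(results.scores.assign(config_hash=h), "scores.tsv")
    _write(results.calls.assign(config_hash=h), "calls.tsv")
    _write(results.longitudinal.assign(config_hash=h), "longitudinal.tsv")
    _write(results.survival.assign(config_hash=h)
           if len(results.survival) else results.survival, "survival.tsv")
    onco = results.calls.set_index("sample_id")[
        [f"{m}_pos" for m in detection.MARKERS]]
    onco.to_csv(outdir / "oncoprint.tsv", sep="\t")

    import yaml
    thr = results.thresholds
    with open(outdir / "thresholds.yaml", "w") as fh:
        yaml.safe_dump({
            "specificity": thr.specificity,
            "thresholds": {k: float(v) for k, v in thr.thresholds.items()},
            "directions": thr.directions,
            "achieved_specificity": {k: float(v) for k, v
                                     in thr.achieved_specificity.items()},
            "ctcpa_per_subject": {k: float(v) for k, v
                                  in results.ctcpa_thresholds.items()},
            "config_hash": h,
        }, fh, sort_keys=False)
    manifest = {
        "config_hash": h,
        "seed": config.seed,
        "n_healthy": config.n_healthy,
        "n_subjects": config.n_subjects,
        "warnings": results.calibration.warnings,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return results
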