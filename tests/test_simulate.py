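"""Synthetic cohort generator: determinism, conservation, analytic window
mass, degenerate limits, and cohort-level structure."""

import dataclasses

import numpy as np
import pytest

from cfmon.errors import ConfigurationError
from cfmon.fragments import filter_mononucleosomal
from cfmon.fragmentomics import p126_135
from cfmon.outcomes import km_logrank
from cfmon.simulate import (LengthModel, OutcomeModel, default_config,
                            expected_window_mass, simulate_cohort,
                            simulate_healthy_sample, simulate_tumor_sample,
                            simulation_context)


def test_fragment_count_and_length_bounds(cfg):
    fs = simulate_healthy_sample(cfg, seed=1)
    assert fs.n == cfg.n_fragments_per_sample
    assert (fs.fragments["length"] >= cfg.length_model.min_length).all()
    assert (fs.fragments["length"] <= cfg.length_model.max_length).all()
    assert (fs.fragments["end"] - fs.fragments["start"]
            == fs.fragments["length"]).all()
    chrom_len = dict(cfg.genome_spec)
    for chrom, grp in fs.fragments.groupby("chrom"):
        assert (grp["start"] >= 0).all()
        assert (grp["end"] <= chrom_len[chrom]).all()


def test_same_config_and_seed_is_byte_identical(cfg):
    a = simulate_healthy_sample(cfg, seed=7)
    b = simulate_healthy_sample(cfg, seed=7)
    assert a.fragments.to_csv() == b.fragments.to_csv()
    c = simulate_healthy_sample(cfg, seed=8)
    assert not a.fragments.equals(c.fragments)


def test_healthy_window_mass_matches_analytic_mixture(cfg):
    """Empirical P126-135 sits within 3 SE of the integral of the configured
    length mixture over the window."""
    fs = filter_mononucleosomal(simulate_healthy_sample(cfg, seed=11))
    p_hat = p126_135(fs)
    p_true = expected_window_mass(cfg, tf=0.0)
    se = np.sqrt(p_true * (1 - p_true) / fs.n)
    assert abs(p_hat - p_true) <= 3 * se


def test_tf_zero_reduces_to_healthy_sampler(cfg):
    tumor = simulate_tumor_sample(cfg, tf=0.0, seed=5)
    healthy = simulate_healthy_sample(cfg, seed=5)
    assert tumor.fragments.equals(healthy.fragments)


def test_homozygous_deletion_excludes_tumor_fragments():
    """At tf=1 a CN=0 segment receives zero sampling weight; with end-site
    snapping disabled no fragment can start inside it."""
    from cfmon.simulate import EndPositionModel
    cfg = default_config(
        cnv_segments=(("chr1", 10_000_000, 20_000_000, 0),),
        end_position_model=EndPositionModel(p_adhere=0.0))
    fs = simulate_tumor_sample(cfg, tf=1.0, seed=3)
    df = fs.fragments
    mid = (df["start"] + df["end"]) // 2
    inside = (df["chrom"] == "chr1") & (mid >= 10_000_000) & (mid < 20_000_000)
    assert inside.sum() == 0


def test_window_mass_monotone_in_tumor_fraction(cfg):
    """Mean P126-135 strictly increases along a tf dilution series."""
    means = []
    for tf in (0.0, 0.05, 0.1, 0.2):
        vals = [p126_135(filter_mononucleosomal(
            simulate_tumor_sample(cfg, tf, seed=500 + rep)))
            for rep in range(8)]
        means.append(np.mean(vals))
    assert np.all(np.diff(means) > 0)


def test_tumor_fraction_out_of_range_raises(cfg):
    with pytest.raises(ConfigurationError):
        simulate_tumor_sample(cfg, tf=1.5, seed=0)


@pytest.mark.parametrize("bad, match", [
    (dict(tumor_fraction=2.0), "tumor_fraction"),
    (dict(bin_width=0), "bin_width"),
    (dict(cnv_segments=(("chr1", 0, 10, 2), ("chr1", 5, 20, 3))),
     "overlap"),
    (dict(cnv_segments=(("chr9", 0, 10, 2),)), "chromosome"),
    (dict(cnv_segments=(("chr1", 0, 10, 7),)), "copy number"),
    (dict(length_model=LengthModel(min_length=300, max_length=200)),
     "length"),
    (dict(baseline_tf_range=(0.5, 0.1)), "baseline_tf_range"),
])
def test_invalid_config_names_offending_field(bad, match):
    with pytest.raises(ConfigurationError, match=match):
        default_config(**bad)


@pytest.fixture(scope="module")
def small_cohort():
    cfg = default_config(n_healthy=6, n_subjects=8,
                         n_fragments_per_sample=2_000, seed=5)
    return cfg, simulate_cohort(cfg)


def test_cohort_structure_invariants(small_cohort):
    cfg, cohort = small_cohort
    assert len(cohort.healthy) == cfg.n_healthy
    subjects = list(cohort.patient_samples)
    assert len(subjects) == len(set(subjects)) == cfg.n_subjects
    clin_ids = set(cohort.clinical["subject_id"])
    truth = cohort.truth.set_index("subject_id")
    for subject, samples in cohort.patient_samples.items():
        assert subject in clin_ids
        assert {"baseline", "cycle4"} <= set(samples)
        assert not np.isnan(truth.loc[subject, "baseline_tf"])
    assert (cohort.clinical["os_months"]
            >= cohort.clinical["pfs_months"] - 1e-12).all()
    assert (cohort.clinical["pfs_months"] >= 0).all()


def test_responders_clear_tumor_fraction_at_cycle4(small_cohort):
    _, cohort = small_cohort
    truth = cohort.truth
    responders = truth[~truth["residual_truth"]]
    assert len(responders) > 0
    assert (responders["cycle4_tf"] == 0).all()
    nonresp = truth[truth["residual_truth"]]
    assert (nonresp["cycle4_tf"] <= nonresp["baseline_tf"] + 1e-12).all()


def test_null_outcome_model_breaks_survival_association():
    """With log-HR 0 the truth flag carries no hazard signal, so log-rank
    should not be systematically significant."""
    pvals = []
    for rep in range(5):
        cfg = default_config(
            n_healthy=2, n_subjects=30, n_fragments_per_sample=1_000,
            outcome_model=OutcomeModel(loghr_residual=0.0), seed=900 + rep)
        cohort = simulate_cohort(cfg)
        df = cohort.clinical.merge(cohort.truth, on="subject_id")
        res = km_logrank(df["pfs_months"], df["pfs_event"],
                         df["residual_truth"])
        pvals.append(res["p"])
    assert max(pvals) > 0.05  # all-significant would be ~impossible under null


def test_bin_level_gc_bias_is_deterministic_per_config(cfg):
    ctx = simulation_context(cfg)
    assert ctx.bins.n == sum(l // cfg.bin_width for _, l in cfg.genome_spec)
    assert np.all(ctx.gc_factor > 0)
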