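"""The five fragmentation markers: hand-computable cases, conservation,
pattern logic, reference construction, and sampling consistency."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cfmon.errors import CalibrationError, InsufficientDataError
from cfmon.fragments import filter_mononucleosomal
from cfmon.fragmentomics import (EndPositionReference, alu_cgn_ncg_ratio,
                                 build_end_position_reference, d126_135,
                                 end_motif_counts, iwfaf, mds, p126_135)
from cfmon.simulate import MOTIFS, AluModel, default_config, \
    simulate_healthy_sample, simulation_context

from conftest import make_fragset


# ------------------------------ P126-135 / D126-135 -----------------------

def test_p126_all_in_window():
    fs = make_fragset([("chr1", 0, 130)] * 1000)
    assert p126_135(fs) == 1.0


def test_p126_inclusive_boundaries():
    fs = make_fragset([("chr1", 0, 126), ("chr1", 0, 135),
                       ("chr1", 0, 136), ("chr1", 0, 200)])
    assert p126_135(fs, min_fragments=4) == pytest.approx(0.5)


def test_p126_empty_window_mass():
    fs = make_fragset([("chr1", 0, 200)] * 1000)
    assert p126_135(fs) == 0.0


def test_p126_insufficient_fragments_raises():
    fs = make_fragset([("chr1", 0, 130)] * 10)
    with pytest.raises(InsufficientDataError):
        p126_135(fs)


def test_d126_is_absolute_deviation_from_healthy_median():
    healthy = [0.05, 0.07, 0.09]
    assert d126_135(0.07, healthy) == 0.0
    assert d126_135(0.10, healthy) == pytest.approx(0.03)
    assert d126_135(0.04, healthy) == pytest.approx(0.03)  # two-sided
    with pytest.raises(CalibrationError):
        d126_135(0.1, [0.07, 0.08])


# ------------------------------ motif counts / MDS -------------------------

def test_motif_counts_pool_both_ends():
    fs = make_fragset([("chr1", 0, 100, "AAA", "CCC")])
    counts = end_motif_counts(fs)
    assert counts["AAA"] == 1 and counts["CCC"] == 1
    assert counts.sum() == 2


def test_motif_counts_exclude_n_and_conserve_total():
    fs = make_fragset([("chr1", 0, 100, "AAA", "NNN"),
                       ("chr1", 0, 120, "ACG", "TTT")])
    counts = end_motif_counts(fs)
    assert counts.sum() == 3
    all_n = make_fragset([("chr1", 0, 100, "NNN", "NNN")])
    with pytest.raises(InsufficientDataError):
        end_motif_counts(all_n)


def test_mds_uniform_single_and_hand_case():
    assert mds(np.ones(64)) == pytest.approx(1.0)
    single = np.zeros(64)
    single[5] = 10
    assert mds(single) == 0.0
    counts = np.zeros(64)
    counts[0], counts[21], counts[42] = 2, 1, 1  # AAA:2, CCC:1, GGG:1
    assert mds(counts) == pytest.approx(0.25)


@settings(max_examples=30, deadline=None)
@given(st.lists(st.integers(0, 50), min_size=64, max_size=64),
       st.randoms(use_true_random=False))
def test_mds_invariant_to_motif_relabeling(counts, rand):
    counts = np.asarray(counts)
    if counts.sum() == 0:
        return
    perm = list(range(64))
    rand.shuffle(perm)
    assert mds(counts) == pytest.approx(mds(counts[perm]))


def test_simulated_motif_frequencies_match_simplex():
    """Empirical end-motif frequencies agree with the configured simplex
    within multinomial noise (Alu intervals made negligible)."""
    cfg = default_config(alu_model=AluModel(period=40_000_000,
                                            interval_length=300))
    ctx = simulation_context(cfg)
    fs = simulate_healthy_sample(cfg, seed=4)
    counts = end_motif_counts(fs).to_numpy().astype(float)
    total = counts.sum()
    f = counts / total
    se = np.sqrt(ctx.healthy_simplex * (1 - ctx.healthy_simplex) / total)
    assert np.all(np.abs(f - ctx.healthy_simplex) <= 4 * se + 1e-4)


# ------------------------------ Alu CGN/NCG ratio ---------------------------

ALU = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1_000]})


def _alu_fragset(left_motifs):
    """Fragments whose left end is inside the Alu interval and whose right
    end (motif TTT) is far outside it."""
    rows = [("chr1", 10 + i, 5_000 + i, m, "TTT")
            for i, m in enumerate(left_motifs)]
    return make_fragset(rows)


def test_alu_ratio_with_pseudocounts():
    fs = _alu_fragset(["CGA"] * 30 + ["ACG"] * 15)
    ratio = alu_cgn_ncg_ratio(fs, ALU, min_alu_ends=40)
    assert ratio == pytest.approx(30.5 / 15.5)


def test_alu_ratio_equal_counts_is_one():
    fs = _alu_fragset(["CGT"] * 20 + ["TCG"] * 20)
    assert alu_cgn_ncg_ratio(fs, ALU, min_alu_ends=20) == pytest.approx(1.0)


def test_alu_pattern_logic():
    """CGG counts as CGN only; GCG and CCG as NCG only; disjoint patterns."""
    fs = _alu_fragset(["CGG"] * 10 + ["GCG"] * 5 + ["CCG"] * 5)
    ratio = alu_cgn_ncg_ratio(fs, ALU, min_alu_ends=10)
    assert ratio == pytest.approx((10 + 0.5) / (10 + 0.5))


def test_alu_ratio_needs_enough_alu_ends():
    fs = _alu_fragset(["CGA"] * 10)
    with pytest.raises(InsufficientDataError):
        alu_cgn_ncg_ratio(fs, ALU, min_alu_ends=200)


# ------------------------------ end positions / iwFAF -----------------------

def _healthy_sets(n_samples, shared_positions, private_offset=10_000):
    """Each sample uses every shared position once plus one private end."""
    sets = []
    for s in range(n_samples):
        rows = [("chr1", p, p + 160) for p in shared_positions]
        rows.append(("chr1", private_offset + 100 * s,
                     private_offset + 100 * s + 161))
        sets.append(make_fragset(rows, sample_id=f"H{s}"))
    return sets


def test_reference_includes_universal_positions():
    sets = _healthy_sets(20, [1_000, 2_000])
    ref = build_end_position_reference(sets)
    assert ref.k == 5
    assert 1_000 in ref.positions["chr1"]
    assert 2_000 in ref.positions["chr1"]


def test_reference_excludes_rare_positions():
    sets = _healthy_sets(20, [1_000])
    ref = build_end_position_reference(sets, k=5)
    # each private position was used by exactly one sample
    assert 10_000 not in ref.positions["chr1"]


def test_raising_k_shrinks_reference_monotonically():
    sets = _healthy_sets(8, [1_000, 2_000])
    sizes = [build_end_position_reference(sets, k=k).n_positions
             for k in (1, 4, 8)]
    assert sizes == sorted(sizes, reverse=True)


def test_reference_requires_five_samples():
    with pytest.raises(CalibrationError):
        build_end_position_reference(_healthy_sets(4, [1_000]))


def _uniform_reference(positions, per_pos_freq, pseudocount):
    pos = np.array(sorted(positions))
    total = int(round(pseudocount / per_pos_freq - pseudocount))
    return EndPositionReference(
        positions={"chr1": pos},
        freqs={"chr1": np.full(len(pos), per_pos_freq)},
        total_ends=total, k=1, window=0, pseudocount=pseudocount, n_healthy=5)


def test_iwfaf_extremes():
    ref = _uniform_reference([100, 500], 0.25, 0.5)
    on_ref = make_fragset([("chr1", 100, 500)] * 4)
    assert iwfaf(on_ref, ref) == 0.0
    off_ref = make_fragset([("chr1", 7_000, 7_160)] * 4)
    assert iwfaf(off_ref, ref) == 1.0


def test_iwfaf_equal_weights_half_aberrant():
    """With the floor frequency equal to the reference frequency all weights
    coincide, so 2 aberrant of 4 fragments -> 0.5."""
    ref = _uniform_reference([100, 500], 0.1, 1.0)  # floor = 1/10 = 0.1
    assert ref.floor_frequency() == pytest.approx(0.1)
    fs = make_fragset([("chr1", 100, 500), ("chr1", 100, 500),
                       ("chr1", 7_000, 7_160), ("chr1", 8_000, 8_160)])
    assert iwfaf(fs, ref) == pytest.approx(0.5)


def test_iwfaf_window_tolerance():
    ref = _uniform_reference([100], 0.25, 0.5)
    near = make_fragset([("chr1", 102, 400)])
    assert iwfaf(near, ref) == 1.0
    ref_w = dataclasses.replace(ref, window=3) if dataclasses.is_dataclass(ref) \
        else ref
    ref_w = EndPositionReference(ref.positions, ref.freqs, ref.total_ends,
                                 ref.k, 3, ref.pseudocount, ref.n_healthy)
    assert iwfaf(near, ref_w) == 0.0
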