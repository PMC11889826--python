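"""The five cfDNA fragmentation markers.

All markers operate on a mononucleosome-filtered fragment set (length
<= 250 bp):

* ``p126_135`` — proportion of fragments 126-135 bp (inclusive) among all
  fragments in the filtered set;
* ``d126_135`` — absolute deviation of that proportion from the healthy
  cohort median (captures shifts in either direction);
* ``mds`` — motif diversity score: Shannon entropy of the 64 fragment-end
  trinucleotide frequencies, normalized by log(64) to [0, 1];
* ``alu_cgn_ncg_ratio`` — ratio of CG-leading to CG-trailing end motifs
  among ends inside Alu intervals (fragmentomic proxy for Alu
  hypomethylation; both counts receive a 0.5 pseudocount);
* ``iwfaf`` — information-weighted fraction of aberrant fragments: share of
  self-information-weighted fragments with NEITHER end at a recurrent
  healthy end position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CalibrationError, InsufficientDataError
from .fragments import SampleFragmentSet

_N64 = 64
MIN_FRAGMENTS = 1_000
MIN_ALU_ENDS = 200


def p126_135(fragset_mono: SampleFragmentSet, window=(126, 135),
             min_fragments: int = MIN_FRAGMENTS) -> float:
    """Fraction of fragments with length inside ``window`` (both ends
    inclusive) among all fragments of the filtered set."""
    lengths = fragset_mono.fragments["length"].to_numpy()
    if len(lengths) < min_fragments:
        raise InsufficientDataError(
            f"{fragset_mono.sample_id}: {len(lengths)} fragments "
            f"< min_fragments={min_fragments}")
    lo, hi = window
    return float(np.mean((lengths >= lo) & (lengths <= hi)))


def d126_135(p_sample: float, healthy_p_values) -> float:
    """|P126-135 of the sample - median P126-135 of the healthy cohort|."""
    healthy = np.asarray(list(healthy_p_values), dtype=float)
    if len(healthy) < 3:
        raise CalibrationError(
            f"need >= 3 healthy P126-135 values, got {len(healthy)}")
    return float(abs(p_sample - np.median(healthy)))


def end_motif_counts(fragset_mono: SampleFragmentSet) -> pd.Series:
    """Counts over the 64 trinucleotides, pooling both fragment ends.

    The right-end motif is already reverse-complemented at read time, so both
    ends are counted on the same (5'->3' of the cut) strand. ``NNN`` motifs
    are excluded.
    """
    from .simulate import MOTIFS

    df = fragset_mono.fragments
    motifs = pd.concat([df["motif5_left"], df["motif5_right"]],
                       ignore_index=True)
    motifs = motifs[motifs != "NNN"]
    if len(motifs) == 0:
        raise InsufficientDataError(
            f"{fragset_mono.sample_id}: no informative end motifs")
    counts = motifs.value_counts()
    return counts.reindex(MOTIFS, fill_value=0).astype(np.int64)


def mds(motif_counts) -> float:
    """Normalized Shannon entropy of the 64-motif frequency vector."""
    counts = np.asarray(motif_counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise InsufficientDataError("zero total motif count")
    f = counts / total
    nz = f > 0
    return float(-(f[nz] * np.log(f[nz])).sum() / np.log(_N64))


def alu_cgn_ncg_ratio(fragset_mono: SampleFragmentSet, alu_intervals,
                      min_alu_ends: int = MIN_ALU_ENDS,
                      pseudocount: float = 0.5) -> float:
    """CGN/NCG end-motif ratio among fragment ends inside Alu intervals.

    CGN = motif starting with CG; NCG = motif ending with CG (a 3-mer can
    never match both). ``alu_intervals`` is a DataFrame with chrom/start/end
    in 0-based half-open coordinates.
    """
    df = fragset_mono.fragments
    alu = alu_intervals if isinstance(alu_intervals, pd.DataFrame) \
        else pd.DataFrame(alu_intervals, columns=["chrom", "start", "end"])
    ends = pd.DataFrame({
        "chrom": pd.concat([df["chrom"], df["chrom"]], ignore_index=True),
        # right end is exclusive: its last covered base is end - 1
        "pos": pd.concat([df["start"], df["end"] - 1], ignore_index=True),
        "motif": pd.concat([df["motif5_left"], df["motif5_right"]],
                           ignore_index=True),
    })
    inside = np.zeros(len(ends), dtype=bool)
    for chrom, grp in alu.groupby("chrom", sort=False):
        sel = (ends["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        starts = grp["start"].to_numpy()
        stops = grp["end"].to_numpy()
        order = np.argsort(starts)
        starts, stops = starts[order], stops[order]
        pos = ends.loc[sel, "pos"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = idx >= 0
        hit = np.zeros(len(pos), dtype=bool)
        hit[ok] = pos[ok] < stops[idx[ok]]
        inside[sel] = hit
    alu_motifs = ends.loc[inside, "motif"]
    alu_motifs = alu_motifs[alu_motifs != "NNN"]
    if len(alu_motifs) < min_alu_ends:
        raise InsufficientDataError(
            f"{fragset_mono.sample_id}: {len(alu_motifs)} Alu ends "
            f"< min_alu_ends={min_alu_ends}")
    cgn = int(alu_motifs.str.startswith("CG").sum())
    ncg = int(alu_motifs.str.endswith("CG").sum())
    return float((cgn + pseudocount) / (ncg + pseudocount))


@dataclass
class EndPositionReference:
    """Recurrent healthy fragment end positions with pooled usage frequencies.

    Built only from healthy samples. ``positions`` maps chrom -> sorted int
    array; ``freqs`` holds the pooled usage frequency of each position in the
    same order. ``window`` is the match tolerance in bp.
    """

    positions: dict
    freqs: dict
    total_ends: int
    k: int
    window: int
    pseudocount: float
    n_healthy: int

    @property
    def n_positions(self) -> int:
        return sum(len(v) for v in self.positions.values())

    def floor_frequency(self) -> float:
        return self.pseudocount / (self.total_ends + self.pseudocount)

    def lookup(self, chrom_arr: np.ndarray, pos_arr: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray]:
        """Per end: (matched flag, usage frequency; floor when unmatched)."""
        matched = np.zeros(len(pos_arr), dtype=bool)
        freq = np.full(len(pos_arr), self.floor_frequency())
        for chrom, sites in self.positions.items():
            sel = chrom_arr == chrom
            if not sel.any() or len(sites) == 0:
                continue
            pos = pos_arr[sel]
            right = np.searchsorted(sites, pos)
            right = np.clip(right, 0, len(sites) - 1)
            left = np.clip(right - 1, 0, len(sites) - 1)
            d_right = np.abs(sites[right] - pos)
            d_left = np.abs(sites[left] - pos)
            nearest = np.where(d_right <= d_left, right, left)
            dist = np.minimum(d_right, d_left)
            hit = dist <= self.window
            f = freq[sel]
            f[hit] = self.freqs[chrom][nearest[hit]]
            freq[sel] = f
            m = matched[sel]
            m[hit] = True
            matched[sel] = m
        return matched, freq


def _sample_end_frame(fragset: SampleFragmentSet) -> pd.DataFrame:
    df = fragset.fragments
    return pd.DataFrame({
        "chrom": pd.concat([df["chrom"], df["chrom"]], ignore_index=True),
        "pos": pd.concat([df["start"], df["end"]], ignore_index=True),
    })


def build_end_position_reference(healthy_fragsets, k: int | None = None,
                                 window: int = 0, pseudocount: float = 0.5
                                 ) -> EndPositionReference:
    """Positions used as a fragment end (either end) by at least ``k``
    distinct healthy samples, with pooled usage frequencies.

    ``k`` defaults to ceil(n_healthy / 4).
    """
    healthy_fragsets = list(healthy_fragsets)
    n = len(healthy_fragsets)
    if n < 5:
        raise CalibrationError(
            f"need >= 5 healthy samples to build an end-position reference, "
            f"got {n}")
    if k is None:
        k = int(np.ceil(n / 4))
    frames = []
    for i, fs in enumerate(healthy_fragsets):
        f = _sample_end_frame(fs)
        f["sample"] = i
        frames.append(f)
    pooled = pd.concat(frames, ignore_index=True)
    total_ends = len(pooled)
    grp = pooled.groupby(["chrom", "pos"]).agg(
        n_samples=("sample", "nunique"), n_ends=("sample", "size"))
    recurrent = grp[grp["n_samples"] >= k].reset_index()
    positions, freqs = {}, {}
    for chrom, sub in recurrent.groupby("chrom", sort=False):
        order = np.argsort(sub["pos"].to_numpy())
        positions[chrom] = sub["pos"].to_numpy()[order]
        freqs[chrom] = (sub["n_ends"].to_numpy()[order] / total_ends)
    return EndPositionReference(positions, freqs, total_ends, k, window,
                                pseudocount, n)


def iwfaf(fragset_mono: SampleFragmentSet,
          reference: EndPositionReference) -> float:
    """Information-weighted fraction of aberrant fragments.

    A fragment is aberrant iff NEITHER end lies within ``reference.window``
    bp of a recurrent healthy end position. Each fragment carries the
    self-information -log(p) of its less frequent end under the pooled
    healthy end-usage distribution (floored by the pseudocount frequency for
    unmatched ends); the score is the weighted share of aberrant fragments.
    """
    if reference.n_positions == 0:
        raise CalibrationError("end-position reference is empty")
    df = fragset_mono.fragments
    if len(df) == 0:
        raise InsufficientDataError(
            f"{fragset_mono.sample_id}: no fragments for iwFAF")
    chrom = df["chrom"].to_numpy()
    left_hit, left_f = reference.lookup(chrom, df["start"].to_numpy())
    right_hit, right_f = reference.lookup(chrom, df["end"].to_numpy())
    aberrant = ~(left_hit | right_hit)
    weight = -np.log(np.minimum(left_f, right_f))
    return float(weight[aberrant].sum() / weight.sum())
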