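"""Copy-number instability scores.

* ``cpa_score`` — genome-wide chromosomal instability: the length-weighted
  mean absolute segment log2 copy ratio.
* ``ctcpa_score`` — tumor-informed refinement: the signed, length-weighted
  projection of a follow-up sample's bin ratios onto the patient-specific
  CNV segments (and their directions) identified in a prior CNV-positive
  plasma sample of the same subject. Positive values mean the follow-up
  deviates from copy-number neutrality in the baseline's direction; a
  copy-neutral plasma projects to ~0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cnv import BinProfile, SegmentProfile
from .errors import ConfigurationError, InsufficientDataError


@dataclass
class InformativeSegmentSet:
    """Patient-specific CNV segments carried over from a prior sample.

    ``segments`` columns: chrom, start, end, sign, abs_log2, length.
    """

    subject_id: str
    source_sample_id: str
    segments: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.segments)


def cpa_score(segprofile: SegmentProfile) -> float:
    """Length-weighted mean |segment log2 ratio| over the usable genome."""
    seg = segprofile.segments
    if seg is None or len(seg) == 0:
        raise InsufficientDataError("empty segment profile")
    w = seg["length"].to_numpy(dtype=float)
    r = seg["mean_log2"].to_numpy(dtype=float)
    return float(np.sum(w * np.abs(r)) / np.sum(w))


def select_informative_segments(baseline_segprofile: SegmentProfile,
                                z_min: float = 3.0,
                                min_len_bins: int = 3,
                                subject_id: str = ""
                                ) -> InformativeSegmentSet:
    """Segments of a CNV-detectable baseline that qualify as patient-specific
    CNVs: z-score of the segment mean (mean bin z * sqrt(n_bins)) at least
    ``z_min`` in magnitude and at least ``min_len_bins`` bins long.

    May legitimately return an empty set (baselines marginally above the CPA
    threshold without clear CNVs); callers then fall back to CPA only.
    """
    seg = baseline_segprofile.segments
    stat = seg["mean_z"].to_numpy() * np.sqrt(seg["n_bins"].to_numpy())
    keep = (np.abs(stat) >= z_min) & (seg["n_bins"].to_numpy() >= min_len_bins)
    chosen = seg[keep]
    out = pd.DataFrame({
        "chrom": chosen["chrom"].to_numpy(),
        "start": chosen["start"].to_numpy(),
        "end": chosen["end"].to_numpy(),
        "sign": np.sign(chosen["mean_log2"].to_numpy()),
        "abs_log2": np.abs(chosen["mean_log2"].to_numpy()),
        "length": chosen["length"].to_numpy(),
    })
    return InformativeSegmentSet(subject_id, baseline_segprofile.sample_id,
                                 out.reset_index(drop=True))


def ctcpa_score(followup_profile: BinProfile,
                informative: InformativeSegmentSet) -> float:
    """Signed length-weighted mean follow-up bin ratio inside the informative
    segments, oriented by each segment's baseline direction."""
    if informative.n == 0:
        raise InsufficientDataError(
            "informative segment set is empty; ctCPA undefined")
    if followup_profile.log2_ratio is None:
        raise ConfigurationError("follow-up profile must be normalized")
    bins = followup_profile.bins
    chrom = bins.table["chrom"].to_numpy()
    mid = (bins.table["start"].to_numpy() + bins.table["end"].to_numpy()) // 2
    usable = bins.usable
    ratio = followup_profile.log2_ratio
    num = 0.0
    den = 0.0
    for row in informative.segments.itertuples(index=False):
        sel = usable & (chrom == row.chrom) & (mid >= row.start) \
            & (mid < row.end)
        if not sel.any():
            raise ConfigurationError(
                f"informative segment {row.chrom}:{row.start}-{row.end} has "
                "no usable bins in the follow-up profile (bin set mismatch?)")
        num += row.length * row.sign * float(np.nanmean(ratio[sel]))
        den += row.length
    return float(num / den)
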