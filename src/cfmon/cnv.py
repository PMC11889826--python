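"""Read-depth copy-number profiling against a healthy panel of normals.

The stage is a transparent replacement for black-box lcWGS CNV callers:
fragment midpoints are counted in fixed-width bins, counts are library-size
scaled and GC-corrected by median ratio per GC decile, divided by the
panel-of-normals expectation, and segmented per chromosome with an
optimal-partitioning changepoint fit (L2 cost, BIC-style penalty).
CNV profiling deliberately uses ALL fragment lengths; the mononucleosomal
filter applies to fragmentomic markers only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InsufficientDataError
from .fragments import SampleFragmentSet

# floor for normalized counts so log2 ratios stay finite on empty bins
_NORM_FLOOR = 1e-3


def default_gc(n_bins: int) -> np.ndarray:
    """Synthetic per-bin GC fractions: a slow sinusoid around 0.45.

    The period (17.3 bins) is incommensurate with typical CNV segment
    boundaries so every GC decile samples all copy-number states.
    """
    i = np.arange(n_bins)
    return 0.45 + 0.08 * np.sin(2 * np.pi * i / 17.3)


@dataclass
class GenomeBins:
    """Fixed-width, genome-ordered bins with GC content and usability mask."""

    table: pd.DataFrame  # chrom, start, end, gc, usable
    bin_width: int

    @classmethod
    def from_genome_spec(cls, genome_spec, bin_width: int,
                         gc: np.ndarray | None = None) -> "GenomeBins":
        rows = []
        for chrom, length in genome_spec:
            starts = np.arange(0, length, bin_width, dtype=np.int64)
            ends = np.minimum(starts + bin_width, length)
            rows.append(pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends}))
        table = pd.concat(rows, ignore_index=True)
        table["gc"] = default_gc(len(table)) if gc is None else np.asarray(gc)
        if not ((table["gc"] >= 0) & (table["gc"] <= 1)).all():
            raise ConfigurationError("gc fractions must lie in [0, 1]")
        table["usable"] = True
        return cls(table, bin_width)

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def usable(self) -> np.ndarray:
        return self.table["usable"].to_numpy()

    def chrom_slices(self) -> dict[str, slice]:
        out, start = {}, 0
        for chrom, grp in self.table.groupby("chrom", sort=False):
            out[chrom] = slice(start, start + len(grp))
            start += len(grp)
        return out

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


@dataclass
class BinProfile:
    """Per-bin raw counts and (after :func:`normalize`) log2 ratios and z."""

    sample_id: str
    bins: GenomeBins
    raw_count: np.ndarray
    log2_ratio: np.ndarray | None = None
    z: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = self.bins.to_frame()
        df["raw_count"] = self.raw_count
        if self.log2_ratio is not None:
            df["log2_ratio"] = self.log2_ratio
            df["z"] = self.z
        return df


@dataclass
class SegmentProfile:
    """Changepoint segmentation of a normalized profile.

    ``segments`` columns: chrom, start, end, mean_log2, mean_z, n_bins,
    length (bp). Segments partition the usable bins of each chromosome.
    """

    sample_id: str
    segments: pd.DataFrame


@dataclass
class PanelOfNormals:
    """Per-bin expectation and spread of GC-corrected normalized healthy counts."""

    bins: GenomeBins
    mean: np.ndarray
    sd_log2: np.ndarray
    n_healthy: int
    sample_ids: list = field(default_factory=list)


def bin_counts(fragset: SampleFragmentSet, bins: GenomeBins) -> BinProfile:
    """Count fragment midpoints per bin (half-open bins; midpoint rounded down)."""
    counts = np.zeros(bins.n, dtype=np.int64)
    slices = bins.chrom_slices()
    df = fragset.fragments
    covered = df["chrom"].isin(slices.keys())
    df = df[covered]
    for chrom, grp in df.groupby("chrom", sort=False):
        sl = slices[chrom]
        mid = ((grp["start"].to_numpy() + grp["end"].to_numpy()) // 2)
        idx = mid // bins.bin_width
        idx = idx[(idx >= 0) & (idx < sl.stop - sl.start)]
        np.add.at(counts, sl.start + idx, 1)
    return BinProfile(fragset.sample_id, bins, counts)


def _gc_corrected(counts: np.ndarray, bins: GenomeBins,
                  n_deciles: int = 10) -> np.ndarray:
    """Library-size scale to mean 1 over usable bins, then median-ratio
    correction per GC decile."""
    usable = bins.usable
    x = counts.astype(float)
    total = x[usable].sum()
    if total <= 0:
        raise InsufficientDataError("no fragments in usable bins")
    x = x / total * usable.sum()
    gc = bins.table["gc"].to_numpy()
    # decile membership by GC rank among usable bins
    order = np.argsort(gc[usable], kind="mergesort")
    decile = np.empty(usable.sum(), dtype=int)
    decile[order] = (np.arange(usable.sum()) * n_deciles) // usable.sum()
    xu = x[usable]
    global_med = np.median(xu)
    corr = np.ones_like(xu)
    for d in range(n_deciles):
        sel = decile == d
        med = np.median(xu[sel])
        if med > 0 and global_med > 0:
            corr[sel] = med / global_med
    out = x.copy()
    out[usable] = xu / corr
    return out


def build_panel(healthy_fragsets, bins: GenomeBins) -> PanelOfNormals:
    """Panel of normals from healthy samples only."""
    mats, ids = [], []
    for fs in healthy_fragsets:
        if fs.timepoint != "healthy":
            raise ConfigurationError(
                f"panel sample {fs.sample_id} has timepoint {fs.timepoint!r};"
                " panels are built from healthy samples only")
        prof = bin_counts(fs, bins)
        mats.append(_gc_corrected(prof.raw_count, bins))
        ids.append(fs.sample_id)
    if len(mats) < 2:
        raise ConfigurationError("panel of normals needs >= 2 healthy samples")
    mat = np.vstack(mats)
    mean = mat.mean(axis=0)
    usable = bins.usable & (mean > _NORM_FLOOR)
    bins.table["usable"] = usable
    ratios = np.log2(np.maximum(mat, _NORM_FLOOR)
                     / np.maximum(mean, _NORM_FLOOR))
    sd = ratios.std(axis=0, ddof=1)
    sd = np.maximum(sd, 1e-6)
    return PanelOfNormals(bins, mean, sd, len(mats), ids)


def normalize(profile: BinProfile, bins: GenomeBins,
              panel: PanelOfNormals) -> BinProfile:
    """Scale, GC-correct, and express counts as log2 ratio vs panel mean."""
    if panel.bins.n != bins.n or not panel.bins.table["start"].equals(
            bins.table["start"]):
        raise ConfigurationError(
            "panel was built on a different bin set than the sample profile")
    x = _gc_corrected(profile.raw_count, bins)
    ratio = np.full(bins.n, np.nan)
    z = np.full(bins.n, np.nan)
    usable = bins.usable
    ratio[usable] = np.log2(np.maximum(x[usable], _NORM_FLOOR)
                            / np.maximum(panel.mean[usable], _NORM_FLOOR))
    z[usable] = ratio[usable] / panel.sd_log2[usable]
    return BinProfile(profile.sample_id, bins, profile.raw_count, ratio, z)


def _dp_changepoints(y: np.ndarray, penalty: float) -> list[int]:
    """Optimal partitioning with per-segment L2 cost and linear penalty.

    Returns sorted interior changepoint indices (segment starts).
    """
    n = len(y)
    s1 = np.concatenate([[0.0], np.cumsum(y)])
    s2 = np.concatenate([[0.0], np.cumsum(y * y)])

    def cost(i, j):  # cost of segment y[i:j]
        m = j - i
        return s2[j] - s2[i] - (s1[j] - s1[i]) ** 2 / m

    best = np.zeros(n + 1)
    last = np.zeros(n + 1, dtype=int)
    for j in range(1, n + 1):
        cands = [(best[i] + cost(i, j) + (penalty if i > 0 else 0.0), i)
                 for i in range(j)]
        best[j], last[j] = min(cands)
    cps = []
    j = n
    while j > 0:
        i = last[j]
        if i > 0:
            cps.append(i)
        j = i
    return sorted(cps)


def segment(profile: BinProfile, penalty_mult: float = 3.0,
            penalty: float | None = None) -> SegmentProfile:
    """Segment the normalized profile per chromosome.

    The default penalty is ``penalty_mult * sigma^2 * log(n)`` where
    ``sigma`` is a robust (MAD of first differences) per-bin noise estimate.
    """
    if profile.log2_ratio is None:
        raise ConfigurationError("profile must be normalized before segment()")
    bins = profile.bins
    usable = bins.usable
    rows = []
    slices = bins.chrom_slices()
    for chrom, sl in slices.items():
        mask = usable[sl]
        y = profile.log2_ratio[sl][mask]
        zc = profile.z[sl][mask]
        starts = bins.table["start"].to_numpy()[sl][mask]
        ends = bins.table["end"].to_numpy()[sl][mask]
        if len(y) == 0:
            continue
        if len(y) < 2:
            cps = []
        else:
            if penalty is None:
                d = np.diff(y)
                sigma = np.median(np.abs(d - np.median(d))) * 1.4826 / np.sqrt(2)
                sigma = max(sigma, 1e-8)
                pen = penalty_mult * sigma ** 2 * np.log(len(y))
            else:
                pen = penalty
            cps = _dp_changepoints(y, pen)
        bounds = [0] + cps + [len(y)]
        for a, b in zip(bounds[:-1], bounds[1:]):
            rows.append({
                "chrom": chrom,
                "start": int(starts[a]),
                "end": int(ends[b - 1]),
                "mean_log2": float(np.mean(y[a:b])),
                "mean_z": float(np.mean(zc[a:b])),
                "n_bins": b - a,
                "length": int(ends[b - 1] - starts[a]),
            })
    if not rows:
        raise InsufficientDataError("no usable bins to segment")
    return SegmentProfile(profile.sample_id, pd.DataFrame(rows))
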