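"""Canonical cfDNA fragment model and readers/writers.

A *fragment* is the outer span of a properly paired read pair, kept in
0-based half-open coordinates throughout the package (BED convention).
``motif5_left`` is the reference-strand trinucleotide at the left 5' end;
``motif5_right`` is the reverse complement of the reference at the right
end, i.e. the 5' trinucleotide of the bottom-strand read. ``NNN`` is the
sentinel for an unknown motif.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataFormatError

FRAGMENT_COLUMNS = [
    "chrom",
    "start",
    "end",
    "length",
    "motif5_left",
    "motif5_right",
    "mapq",
    "is_duplicate",
]

TABLE_COLUMNS = ["sample_id", "chrom", "start", "end", "length",
                 "motif5_left", "motif5_right"]

_MOTIF_RE = re.compile(r"^[ACGT]{3}$|^NNN$")
_AUTOSOME_RE = re.compile(r"^(chr)?\d+$")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SampleFragmentSet:
    """All retained fragments of one plasma sample.

    ``fragments`` is a DataFrame with :data:`FRAGMENT_COLUMNS`. ``timepoint``
    is one of ``healthy``, ``baseline``, ``cycle4``, ``progression``.
    """

    sample_id: str
    subject_id: str = ""
    timepoint: str = "healthy"
    fragments: pd.DataFrame = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.sample_id:
            raise ConfigurationError("sample_id must be non-empty")
        if self.fragments is None:
            self.fragments = empty_fragment_frame()

    @property
    def n(self) -> int:
        return len(self.fragments)

    def with_fragments(self, df: pd.DataFrame, note: str | None = None
                       ) -> "SampleFragmentSet":
        prov = dict(self.provenance)
        if note:
            prov.setdefault("filters", []).append(note)
        return SampleFragmentSet(self.sample_id, self.subject_id,
                                 self.timepoint, df.reset_index(drop=True),
                                 prov)


def empty_fragment_frame() -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": pd.Series(dtype=str),
        "start": pd.Series(dtype=np.int64),
        "end": pd.Series(dtype=np.int64),
        "length": pd.Series(dtype=np.int64),
        "motif5_left": pd.Series(dtype=str),
        "motif5_right": pd.Series(dtype=str),
        "mapq": pd.Series(dtype=np.int64),
        "is_duplicate": pd.Series(dtype=bool),
    })


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop rows violating fragment invariants; return (kept, n_dropped)."""
    ok = (
        (df["end"] > df["start"])
        & (df["start"] >= 0)
        & (df["length"] == df["end"] - df["start"])
        & df["motif5_left"].astype(str).str.match(_MOTIF_RE)
        & df["motif5_right"].astype(str).str.match(_MOTIF_RE)
    )
    return df[ok], int((~ok).sum())


def read_fragment_table(path, sample_meta: dict | None = None
                        ) -> SampleFragmentSet:
    """Read a plain fragment TSV (simulator output format) into a sample set.

    Rows violating the fragment invariants are dropped; the drop count is
    recorded in ``provenance['rows_dropped']``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    if len(df.columns) and df.empty:
        pass
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(
            f"{path}: missing required columns {missing}")
    meta = dict(sample_meta or {})
    sample_id = meta.pop("sample_id", None)
    if sample_id is None:
        ids = df["sample_id"].unique()
        sample_id = str(ids[0]) if len(ids) else path.stem
    df = df[df["sample_id"].astype(str) == str(sample_id)] if len(df) else df
    if "mapq" not in df.columns:
        df = df.assign(mapq=60)
    if "is_duplicate" not in df.columns:
        df = df.assign(is_duplicate=False)
    df = df[FRAGMENT_COLUMNS].copy()
    if df.empty:
        fs = SampleFragmentSet(str(sample_id), fragments=empty_fragment_frame(),
                               **meta)
        fs.provenance.update(source=str(path), rows_dropped=0, empty=True)
        return fs
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["length"] = df["length"].astype(np.int64)
    kept, dropped = _validate_rows(df)
    fs = SampleFragmentSet(str(sample_id), fragments=kept.reset_index(drop=True),
                           **meta)
    fs.provenance.update(source=str(path), rows_dropped=dropped)
    return fs


def write_fragment_table(fragset: SampleFragmentSet, path) -> None:
    df = fragset.fragments.copy()
    df.insert(0, "sample_id", fragset.sample_id)
    df[TABLE_COLUMNS + ["mapq", "is_duplicate"]].to_csv(
        path, sep="\t", index=False)


def read_alignments(path, min_mapq: int = 30, drop_duplicates: bool = True,
                    autosomes_only: bool = True, reference_fasta=None,
                    sample_meta: dict | None = None) -> SampleFragmentSet:
    """Extract fragments from a coordinate-sorted, indexed paired-end BAM.

    One fragment per proper pair, spanning the leftmost start to the
    rightmost end (TLEN-equivalent). End motifs are looked up from
    ``reference_fasta`` when provided, else set to ``NNN``.
    """
    import pysam

    path = Path(path)
    meta = dict(sample_meta or {})
    sample_id = meta.pop("sample_id", path.stem)
    fasta = None
    if reference_fasta is not None:
        from pyfaidx import Fasta
        try:
            fasta = Fasta(str(reference_fasta))
        except Exception as exc:  # missing file or .fai failure
            raise ConfigurationError(
                f"cannot open reference FASTA {reference_fasta}: {exc}")
    try:
        bam = pysam.AlignmentFile(str(path), "rb")
    except (OSError, ValueError) as exc:
        raise DataFormatError(f"cannot open BAM {path}: {exc}")
    if not bam.has_index():
        raise DataFormatError(f"{path} has no index (.bai); sort and index it")

    rows = {"chrom": [], "start": [], "end": [], "mapq": [], "dup": []}
    for read in bam.fetch():
        if (not read.is_proper_pair or read.is_secondary
                or read.is_supplementary or read.is_unmapped):
            continue
        # keep the forward-oriented mate once per pair
        if read.template_length <= 0:
            continue
        if read.mapping_quality < min_mapq:
            continue
        if read.is_duplicate and drop_duplicates:
            continue
        chrom = read.reference_name
        if autosomes_only and not _AUTOSOME_RE.match(chrom):
            continue
        rows["chrom"].append(chrom)
        rows["start"].append(read.reference_start)
        rows["end"].append(read.reference_start + read.template_length)
        rows["mapq"].append(read.mapping_quality)
        rows["dup"].append(read.is_duplicate)
    bam.close()

    df = pd.DataFrame({
        "chrom": pd.Series(rows["chrom"], dtype=str),
        "start": pd.Series(rows["start"], dtype=np.int64),
        "end": pd.Series(rows["end"], dtype=np.int64),
    })
    df["length"] = df["end"] - df["start"]
    if fasta is not None and len(df):
        left, right = [], []
        for chrom, s, e in zip(df["chrom"], df["start"], df["end"]):
            seq = fasta[chrom]
            left.append(str(seq[s:s + 3]).upper())
            right.append(revcomp(str(seq[e - 3:e]).upper()))
        df["motif5_left"] = [m if _MOTIF_RE.match(m) else "NNN" for m in left]
        df["motif5_right"] = [m if _MOTIF_RE.match(m) else "NNN" for m in right]
    else:
        df["motif5_left"] = "NNN"
        df["motif5_right"] = "NNN"
    df["mapq"] = pd.Series(rows["mapq"], dtype=np.int64)
    df["is_duplicate"] = pd.Series(rows["dup"], dtype=bool)
    df = df[FRAGMENT_COLUMNS]

    fs = SampleFragmentSet(str(sample_id), fragments=df.reset_index(drop=True),
                           **meta)
    fs.provenance.update(source=str(path), min_mapq=min_mapq,
                         drop_duplicates=drop_duplicates,
                         autosomes_only=autosomes_only)
    return fs


def write_alignments(fragset: SampleFragmentSet, path, genome_spec,
                     read_length: int = 50) -> None:
    """Write fragments as a coordinate-sorted, indexed paired-end BAM.

    Used to exercise :func:`read_alignments` against simulator output; reads
    carry placeholder sequence and are flagged as proper pairs.
    """
    import pysam

    path = Path(path)
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": name, "LN": int(length)}
                     for name, length in genome_spec]}
    tid = {name: i for i, (name, _) in enumerate(genome_spec)}
    frags = fragset.fragments.sort_values(
        ["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)

    unsorted = path.with_suffix(".unsorted.bam")
    with pysam.AlignmentFile(str(unsorted), "wb", header=header) as out:
        for i, row in enumerate(frags.itertuples(index=False)):
            rl = min(read_length, int(row.length))
            for mate in (1, 2):
                a = pysam.AlignedSegment()
                a.query_name = f"{fragset.sample_id}:frag{i}"
                a.reference_id = tid[row.chrom]
                a.mapping_quality = int(row.mapq)
                a.query_sequence = "A" * rl
                a.query_qualities = pysam.qualitystring_to_array("I" * rl)
                a.cigarstring = f"{rl}M"
                a.is_paired = True
                a.is_proper_pair = True
                a.is_duplicate = bool(row.is_duplicate)
                if mate == 1:
                    a.is_read1 = True
                    a.is_reverse = False
                    a.mate_is_reverse = True
                    a.reference_start = int(row.start)
                    a.next_reference_id = tid[row.chrom]
                    a.next_reference_start = int(row.end) - rl
                    a.template_length = int(row.length)
                else:
                    a.is_read2 = True
                    a.is_reverse = True
                    a.mate_is_reverse = False
                    a.reference_start = int(row.end) - rl
                    a.next_reference_id = tid[row.chrom]
                    a.next_reference_start = int(row.start)
                    a.template_length = -int(row.length)
                out.write(a)
    pysam.sort("-o", str(path), str(unsorted))
    unsorted.unlink()
    pysam.index(str(path))


def filter_fragments(fragset: SampleFragmentSet, min_mapq: int | None = None,
                     min_length: int | None = None,
                     drop_duplicates: bool = False) -> SampleFragmentSet:
    """Apply quality filters; idempotent and order-independent."""
    df = fragset.fragments
    mask = pd.Series(True, index=df.index)
    notes = []
    if min_mapq is not None:
        mask &= df["mapq"] >= min_mapq
        notes.append(f"mapq>={min_mapq}")
    if min_length is not None:
        mask &= df["length"] >= min_length
        notes.append(f"length>={min_length}")
    if drop_duplicates:
        mask &= ~df["is_duplicate"]
        notes.append("no_duplicates")
    return fragset.with_fragments(df[mask], ";".join(notes) or None)


def filter_mononucleosomal(fragset: SampleFragmentSet,
                           max_length: int = 250) -> SampleFragmentSet:
    """Restrict to the mononucleosomal peak (length <= ``max_length``, inclusive).

    Applied before every fragmentomic marker but never before CNV binning.
    """
    df = fragset.fragments
    kept = df[df["length"] <= max_length]
    return fragset.with_fragments(kept, f"length<={max_length}")
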