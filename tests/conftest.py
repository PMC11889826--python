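"""Shared fixtures: one default simulation config, a 40-donor healthy
calibration, and a tumor-informed segment set, reused across test modules to
keep the suite fast."""

import numpy as np
import pandas as pd
import pytest

from cfmon.fragments import SampleFragmentSet
from cfmon.pipeline import calibrate, sample_cnv
from cfmon.scores import select_informative_segments
from cfmon.simulate import (alu_intervals_frame, default_config,
                            simulate_healthy_sample, simulate_tumor_sample,
                            simulation_context)


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def calib40(cfg):
    healthy = [simulate_healthy_sample(cfg, seed=i) for i in range(40)]
    ctx = simulation_context(cfg)
    return calibrate(healthy, ctx.bins, alu_intervals_frame(cfg))


@pytest.fixture(scope="session")
def informative(cfg, calib40):
    baseline = simulate_tumor_sample(cfg, 0.2, seed=90_000)
    _, seg, _ = sample_cnv(baseline, calib40)
    inf = select_informative_segments(seg)
    assert inf.n > 0
    return inf


def make_fragset(rows, sample_id="S1", **kwargs) -> SampleFragmentSet:
    """Hand-built fragment set from (chrom, start, end[, left, right]) rows."""
    recs = []
    for row in rows:
        chrom, start, end = row[:3]
        left = row[3] if len(row) > 3 else "AAA"
        right = row[4] if len(row) > 4 else "AAA"
        recs.append({"chrom": chrom, "start": start, "end": end,
                     "length": end - start, "motif5_left": left,
                     "motif5_right": right, "mapq": 60,
                     "is_duplicate": False})
    df = pd.DataFrame(recs)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["length"] = df["length"].astype(np.int64)
    return SampleFragmentSet(sample_id, fragments=df, **kwargs)
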