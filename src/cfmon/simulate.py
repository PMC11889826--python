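"""Synthetic cfDNA cohort generator.

Generates healthy-donor and NSCLC-like plasma fragment sets with the
statistical structure every downstream marker assumes, plus clinical
outcomes whose hazard depends on true residual-disease status:

* mononucleosomal fragment lengths (modal ~166 bp) with a 10-bp sawtooth
  below 160 bp, a minor dinucleosomal tail, and a tumor-specific short mode
  that enriches the 126-135 bp window in proportion to tumor fraction;
* 64-state fragment-end trinucleotide composition, flattened (more diverse)
  for tumor-derived fragments;
* recurrent, cohort-shared preferred end sites with tumor-dependent
  off-site (aberrant) ends;
* elevated CG-leading end motifs inside Alu intervals for tumor fragments
  (the fragmentomic readout of Alu hypomethylation);
* bin-level copy-number signal mixing a diploid background with an
  aneuploid tumor clone, with a mild shared GC bias;
* exponential progression-free survival with a multiplicative hazard for
  subjects carrying residual tumor fraction at therapy cycle 4, and
  administrative censoring.

Everything is deterministic given ``(config, seed)``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict, replace
from functools import lru_cache

import numpy as np
import pandas as pd

from .cnv import GenomeBins
from .errors import ConfigurationError
from .fragments import SampleFragmentSet

MOTIFS = np.array(["".join(m) for m in itertools.product("ACGT", repeat=3)])
_CGN = np.array([m.startswith("CG") for m in MOTIFS])
_NCG = np.array([m.endswith("CG") for m in MOTIFS])


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LengthModel:
    """Discrete fragment-length mixture (bp).

    Healthy: Gaussian core at ``healthy_mode`` plus geometrically decaying
    sawtooth sub-peaks every ``sawtooth_period`` bp below it and a small
    dinucleosomal tail. Tumor-derived fragments replace ``tumor_short_weight``
    of that mixture with a short mode at ``tumor_short_mode``.
    """

    min_length: int = 50
    max_length: int = 400
    healthy_mode: float = 166.0
    healthy_sd: float = 9.0
    sawtooth_period: int = 10
    n_sawtooth: int = 8
    sawtooth_weight: float = 0.12
    sawtooth_decay: float = 0.75
    sawtooth_sd: float = 2.5
    dinucleosome_mode: float = 310.0
    dinucleosome_sd: float = 25.0
    dinucleosome_weight: float = 0.04
    tumor_short_mode: float = 143.0
    tumor_short_sd: float = 9.0
    tumor_short_weight: float = 0.7


@dataclass(frozen=True)
class MotifModel:
    """Fragment-end trinucleotide model.

    Healthy ends follow a product-of-positions composition sharpened by a
    single dominant motif; tumor ends use the same simplex raised to
    ``tumor_flatten`` < 1 (renormalized), i.e. a flatter, more diverse motif
    usage as observed for ctDNA.
    """

    base_weights: tuple = (
        (0.34, 0.22, 0.16, 0.28),  # position 1: A C G T
        (0.28, 0.30, 0.20, 0.22),
        (0.30, 0.26, 0.18, 0.26),
    )
    spike_motif: str = "CCA"
    spike_weight: float = 0.12
    tumor_flatten: float = 0.55


@dataclass(frozen=True)
class EndPositionModel:
    """Nucleosome-phased preferred end sites, shared across the cohort.

    ``sites_per_mb`` is scaled to the desk-scale fragment count so each site
    collects a few healthy ends per sample; healthy left ends snap to the
    nearest site with probability ``p_adhere`` while tumor-derived fragments
    lose a further ``tumor_offsite`` share of that adherence.
    """

    sites_per_mb: float = 30.0
    p_adhere: float = 0.85
    tumor_offsite: float = 0.75


@dataclass(frozen=True)
class AluModel:
    """Regularly spaced Alu-like intervals and CG-end emission inside them."""

    interval_length: int = 300
    period: int = 1500
    offset: int = 600
    healthy_cgn: float = 0.04
    healthy_ncg: float = 0.10
    tumor_cgn: float = 0.30
    tumor_ncg: float = 0.10


@dataclass(frozen=True)
class OutcomeModel:
    """Exponential PFS with multiplicative hazard for residual disease."""

    base_hazard_per_month: float = 0.076  # median PFS ~9 months when negative
    loghr_residual: float = float(np.log(4.0))
    censoring_horizon_months: float = 60.0
    os_extra_hazard: float = 0.05


@dataclass(frozen=True)
class SimulationConfig:
    genome_spec: tuple = (("chr1", 50_000_000), ("chr2", 50_000_000))
    bin_width: int = 500_000
    n_fragments_per_sample: int = 10_000
    tumor_fraction: float = 0.1
    # (chrom, start, end, tumor copy number); diploid elsewhere.
    cnv_segments: tuple = (
        ("chr1", 0, 30_000_000, 3),
        ("chr1", 30_000_000, 50_000_000, 4),
        ("chr2", 0, 30_000_000, 1),
        ("chr2", 40_000_000, 50_000_000, 1),
    )
    gc_bias: float = 1.0
    duplicate_rate: float = 0.0
    length_model: LengthModel = field(default_factory=LengthModel)
    motif_model: MotifModel = field(default_factory=MotifModel)
    end_position_model: EndPositionModel = field(default_factory=EndPositionModel)
    alu_model: AluModel = field(default_factory=AluModel)
    outcome_model: OutcomeModel = field(default_factory=OutcomeModel)
    # cohort design
    n_healthy: int = 57
    n_subjects: int = 49
    baseline_tf_range: tuple = (0.01, 0.30)
    nonresponder_fraction: float = 0.5
    nonresponder_cycle4_factor_range: tuple = (0.7, 1.0)
    responder_cycle4_factor: float = 0.0
    progression_fraction: float = 0.5
    progression_tf_multiplier_range: tuple = (1.0, 2.0)
    seed: int = 0

    def validate(self) -> None:
        if not self.genome_spec or any(l <= 0 for _, l in self.genome_spec):
            raise ConfigurationError("genome_spec: chromosome lengths must be > 0")
        if self.bin_width <= 0:
            raise ConfigurationError("bin_width must be > 0")
        if self.n_fragments_per_sample <= 0:
            raise ConfigurationError("n_fragments_per_sample must be > 0")
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ConfigurationError("tumor_fraction must lie in [0, 1]")
        if not 0.0 <= self.duplicate_rate < 1.0:
            raise ConfigurationError("duplicate_rate must lie in [0, 1)")
        lm = self.length_model
        if lm.min_length <= 0 or lm.max_length <= lm.min_length:
            raise ConfigurationError(
                "length_model: need 0 < min_length < max_length")
        for w in (lm.sawtooth_weight, lm.dinucleosome_weight,
                  lm.tumor_short_weight):
            if not 0.0 <= w <= 1.0:
                raise ConfigurationError("length_model: weights must lie in [0,1]")
        mm = self.motif_model
        for row in mm.base_weights:
            if abs(sum(row) - 1.0) > 1e-9 or any(p < 0 for p in row):
                raise ConfigurationError(
                    "motif_model.base_weights rows must be simplexes")
        if not 0.0 <= mm.spike_weight < 1.0 or not 0.0 < mm.tumor_flatten <= 1.0:
            raise ConfigurationError("motif_model: spike_weight/tumor_flatten "
                                     "out of range")
        ep = self.end_position_model
        if not 0.0 <= ep.p_adhere <= 1.0 or not 0.0 <= ep.tumor_offsite <= 1.0:
            raise ConfigurationError(
                "end_position_model: probabilities must lie in [0, 1]")
        am = self.alu_model
        for p in (am.healthy_cgn, am.healthy_ncg, am.tumor_cgn, am.tumor_ncg):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("alu_model: emission probabilities "
                                         "must lie in [0, 1]")
        if am.healthy_cgn + am.healthy_ncg > 1 or am.tumor_cgn + am.tumor_ncg > 1:
            raise ConfigurationError("alu_model: CGN + NCG mass exceeds 1")
        if am.period <= 0 or am.interval_length <= 0 \
                or am.interval_length > am.period:
            raise ConfigurationError("alu_model: need 0 < interval_length <= period")
        chrom_len = dict(self.genome_spec)
        seen = {c: [] for c in chrom_len}
        for chrom, s, e, cn in self.cnv_segments:
            if chrom not in chrom_len:
                raise ConfigurationError(
                    f"cnv_segments: unknown chromosome {chrom!r}")
            if not (0 <= s < e <= chrom_len[chrom]):
                raise ConfigurationError(
                    f"cnv_segments: segment {chrom}:{s}-{e} outside genome")
            if cn not in (0, 1, 2, 3, 4):
                raise ConfigurationError(
                    f"cnv_segments: tumor copy number {cn} not in 0..4")
            for s0, e0 in seen[chrom]:
                if s < e0 and s0 < e:
                    raise ConfigurationError(
                        f"cnv_segments: overlapping segments on {chrom}")
            seen[chrom].append((s, e))
        if not 0.0 <= self.nonresponder_fraction <= 1.0 \
                or not 0.0 <= self.progression_fraction <= 1.0:
            raise ConfigurationError("cohort fractions must lie in [0, 1]")
        lo, hi = self.baseline_tf_range
        if not 0.0 < lo <= hi <= 1.0:
            raise ConfigurationError("baseline_tf_range must satisfy "
                                     "0 < lo <= hi <= 1")
        om = self.outcome_model
        if om.base_hazard_per_month <= 0 or om.censoring_horizon_months <= 0:
            raise ConfigurationError("outcome_model: hazards and horizon "
                                     "must be > 0")


def default_config(**overrides) -> SimulationConfig:
    cfg = SimulationConfig(**overrides)
    cfg.validate()
    return cfg


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)

    def _tup(x):
        return tuple(tuple(i) if isinstance(i, (list, tuple)) else i for i in x)

    for key in ("genome_spec", "cnv_segments"):
        if key in d:
            d[key] = _tup(d[key])
    for key in ("baseline_tf_range", "nonresponder_cycle4_factor_range",
                "progression_tf_multiplier_range"):
        if key in d:
            d[key] = tuple(d[key])
    for key, cls in (("length_model", LengthModel), ("motif_model", MotifModel),
                     ("end_position_model", EndPositionModel),
                     ("alu_model", AluModel), ("outcome_model", OutcomeModel)):
        if key in d and isinstance(d[key], dict):
            sub = d[key]
            if key == "motif_model" and "base_weights" in sub:
                sub["base_weights"] = _tup(sub["base_weights"])
            d[key] = cls(**sub)
    cfg = SimulationConfig(**d)
    cfg.validate()
    return cfg


# --------------------------------------------------------------------------
# deterministic per-config context
# --------------------------------------------------------------------------

def _discrete_normal(grid: np.ndarray, mu: float, sd: float) -> np.ndarray:
    w = np.exp(-0.5 * ((grid - mu) / sd) ** 2)
    return w / w.sum()


def _length_pmfs(lm: LengthModel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    grid = np.arange(lm.min_length, lm.max_length + 1)
    core = _discrete_normal(grid, lm.healthy_mode, lm.healthy_sd)
    saw = np.zeros_like(core)
    weights = lm.sawtooth_decay ** np.arange(lm.n_sawtooth)
    weights /= weights.sum()
    for k, w in enumerate(weights, start=1):
        mu = lm.healthy_mode - k * lm.sawtooth_period
        saw += weights[k - 1] * _discrete_normal(grid, mu, lm.sawtooth_sd)
    dinuc = _discrete_normal(grid, lm.dinucleosome_mode, lm.dinucleosome_sd)
    core_w = 1.0 - lm.sawtooth_weight - lm.dinucleosome_weight
    healthy = core_w * core + lm.sawtooth_weight * saw \
        + lm.dinucleosome_weight * dinuc
    healthy /= healthy.sum()
    short = _discrete_normal(grid, lm.tumor_short_mode, lm.tumor_short_sd)
    tumor = (1.0 - lm.tumor_short_weight) * healthy \
        + lm.tumor_short_weight * short
    tumor /= tumor.sum()
    return grid, healthy, tumor


def _motif_simplexes(mm: MotifModel) -> tuple[np.ndarray, np.ndarray]:
    w = np.ones(64)
    for pos in range(3):
        base_idx = np.array([("ACGT".index(m[pos])) for m in MOTIFS])
        w *= np.asarray(mm.base_weights[pos])[base_idx]
    w /= w.sum()
    spike = np.zeros(64)
    spike[np.where(MOTIFS == mm.spike_motif)[0][0]] = 1.0
    healthy = (1.0 - mm.spike_weight) * w + mm.spike_weight * spike
    tumor = healthy ** mm.tumor_flatten
    tumor /= tumor.sum()
    return healthy, tumor


def _alu_simplex(base: np.ndarray, cgn_mass: float, ncg_mass: float
                 ) -> np.ndarray:
    out = np.zeros_like(base)
    rest = ~(_CGN | _NCG)
    out[_CGN] = cgn_mass * base[_CGN] / base[_CGN].sum()
    out[_NCG] = ncg_mass * base[_NCG] / base[_NCG].sum()
    out[rest] = (1.0 - cgn_mass - ncg_mass) * base[rest] / base[rest].sum()
    return out


class _SimContext:
    """Cohort-level deterministic structures derived from the config."""

    def __init__(self, config: SimulationConfig):
        config.validate()
        self.config = config
        lm = config.length_model
        self.length_grid, self.healthy_len_pmf, self.tumor_len_pmf = \
            _length_pmfs(lm)
        self.healthy_simplex, self.tumor_simplex = \
            _motif_simplexes(config.motif_model)
        am = config.alu_model
        self.alu_healthy_simplex = _alu_simplex(
            self.healthy_simplex, am.healthy_cgn, am.healthy_ncg)
        self.alu_tumor_simplex = _alu_simplex(
            self.tumor_simplex, am.tumor_cgn, am.tumor_ncg)

        self.bins = GenomeBins.from_genome_spec(
            config.genome_spec, config.bin_width)
        tab = self.bins.table
        self.bin_chrom = tab["chrom"].to_numpy()
        self.bin_start = tab["start"].to_numpy()
        self.bin_end = tab["end"].to_numpy()
        mid = (self.bin_start + self.bin_end) // 2
        cn = np.full(self.bins.n, 2, dtype=float)
        for chrom, s, e, c in config.cnv_segments:
            cn[(self.bin_chrom == chrom) & (mid >= s) & (mid < e)] = c
        self.bin_cn = cn
        gc = tab["gc"].to_numpy()
        self.gc_factor = 1.0 + config.gc_bias * (gc - gc.mean())
        self.gc_factor = np.maximum(self.gc_factor, 0.05)
        widths = (self.bin_end - self.bin_start).astype(float)
        self.healthy_bin_w = 2.0 * self.gc_factor * widths
        self.tumor_bin_w = cn * self.gc_factor * widths
        self.mean_cn = float((cn * widths).sum() / widths.sum())

        self.chrom_lengths = dict(config.genome_spec)
        rng_sites = np.random.default_rng([config.seed, 777])
        self.sites = {}
        for chrom, length in config.genome_spec:
            k = max(1, int(round(config.end_position_model.sites_per_mb
                                 * length / 1e6)))
            pos = np.sort(rng_sites.integers(0, length, size=k))
            self.sites[chrom] = np.unique(pos)
        self.alu = {}
        for chrom, length in config.genome_spec:
            starts = np.arange(am.offset, length - am.interval_length,
                               am.period, dtype=np.int64)
            self.alu[chrom] = (starts, starts + am.interval_length)

    def in_alu(self, chrom_arr: np.ndarray, pos_arr: np.ndarray) -> np.ndarray:
        out = np.zeros(len(pos_arr), dtype=bool)
        for chrom, (starts, ends) in self.alu.items():
            sel = chrom_arr == chrom
            if not sel.any():
                continue
            idx = np.searchsorted(starts, pos_arr[sel], side="right") - 1
            ok = idx >= 0
            inside = np.zeros(sel.sum(), dtype=bool)
            inside[ok] = pos_arr[sel][ok] < ends[idx[ok]]
            out[sel] = inside
        return out


@lru_cache(maxsize=16)
def _context(config: SimulationConfig) -> _SimContext:
    return _SimContext(config)


def simulation_context(config: SimulationConfig) -> _SimContext:
    """Public access to the cached cohort-level context (bins, sites, Alu)."""
    return _context(config)


def alu_intervals_frame(config: SimulationConfig) -> pd.DataFrame:
    ctx = _context(config)
    rows = []
    for chrom, (starts, ends) in ctx.alu.items():
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


def expected_window_mass(config: SimulationConfig, tf: float,
                         window=(126, 135), max_length: int = 250) -> float:
    """Analytic P(window | length <= max_length) under the configured mixture.

    This is the population value the empirical P126-135 marker estimates.
    """
    ctx = _context(config)
    p_t = _tumor_dna_fraction(ctx, tf)
    pmf = (1.0 - p_t) * ctx.healthy_len_pmf + p_t * ctx.tumor_len_pmf
    grid = ctx.length_grid
    win = (grid >= window[0]) & (grid <= window[1])
    mono = grid <= max_length
    return float(pmf[win].sum() / pmf[mono].sum())


# --------------------------------------------------------------------------
# sampling
# --------------------------------------------------------------------------

def _tumor_dna_fraction(ctx: _SimContext, tf: float) -> float:
    """DNA-mass fraction contributed by tumor cells at cell fraction tf."""
    if tf <= 0:
        return 0.0
    return tf * ctx.mean_cn / ((1.0 - tf) * 2.0 + tf * ctx.mean_cn)


def _draw_from_pmf(rng, cum: np.ndarray, size: int) -> np.ndarray:
    return np.searchsorted(cum, rng.random(size), side="right")


def _simulate(config: SimulationConfig, tf: float, seed: int,
              sample_id: str, subject_id: str, timepoint: str
              ) -> SampleFragmentSet:
    if not 0.0 <= tf <= 1.0:
        raise ConfigurationError(f"tumor fraction {tf} outside [0, 1]")
    ctx = _context(config)
    rng = np.random.default_rng([config.seed, int(seed)])
    n = config.n_fragments_per_sample

    p_t = _tumor_dna_fraction(ctx, tf)
    is_tumor = rng.random(n) < p_t
    n_t = int(is_tumor.sum())
    n_h = n - n_t

    # bin-weighted positions: healthy copy 2 everywhere, tumor weighted by CN
    cum_h = np.cumsum(ctx.healthy_bin_w)
    cum_h /= cum_h[-1]
    bin_idx = np.empty(n, dtype=np.int64)
    bin_idx[~is_tumor] = _draw_from_pmf(rng, cum_h, n_h)
    if n_t:
        cum_t = np.cumsum(ctx.tumor_bin_w)
        cum_t /= cum_t[-1]
        bin_idx[is_tumor] = _draw_from_pmf(rng, cum_t, n_t)

    lengths = np.empty(n, dtype=np.int64)
    cum_len_h = np.cumsum(ctx.healthy_len_pmf)
    lengths[~is_tumor] = ctx.length_grid[
        _draw_from_pmf(rng, cum_len_h, n_h)]
    if n_t:
        cum_len_t = np.cumsum(ctx.tumor_len_pmf)
        lengths[is_tumor] = ctx.length_grid[
            _draw_from_pmf(rng, cum_len_t, n_t)]

    bs = ctx.bin_start[bin_idx]
    be = ctx.bin_end[bin_idx]
    start = bs + np.floor(rng.random(n) * (be - bs)).astype(np.int64)
    chrom = ctx.bin_chrom[bin_idx]

    # snap adhering left ends to the nearest preferred site
    ep = config.end_position_model
    adhere_p = np.where(is_tumor, ep.p_adhere * (1.0 - ep.tumor_offsite),
                        ep.p_adhere)
    adhere = rng.random(n) < adhere_p
    for c, sites in ctx.sites.items():
        sel = adhere & (chrom == c)
        if not sel.any() or len(sites) == 0:
            continue
        pos = start[sel]
        right = np.searchsorted(sites, pos)
        right = np.clip(right, 0, len(sites) - 1)
        left = np.clip(right - 1, 0, len(sites) - 1)
        pick = np.where(np.abs(sites[right] - pos) <= np.abs(sites[left] - pos),
                        right, left)
        start[sel] = sites[pick]

    # keep fragments inside chromosome bounds
    for c, length in ctx.chrom_lengths.items():
        sel = chrom == c
        start[sel] = np.clip(start[sel], 0, length - lengths[sel])
    end = start + lengths

    # end motifs: simplex depends on (tumor origin, Alu membership of the end)
    left_alu = ctx.in_alu(chrom, start)
    right_alu = ctx.in_alu(chrom, end - 1)
    simplex_cums = [np.cumsum(s) for s in (
        ctx.healthy_simplex, ctx.alu_healthy_simplex,
        ctx.tumor_simplex, ctx.alu_tumor_simplex)]

    def _motifs(in_alu_flags: np.ndarray) -> np.ndarray:
        cat = is_tumor.astype(int) * 2 + in_alu_flags.astype(int)
        u = rng.random(n)
        idx = np.empty(n, dtype=np.int64)
        for c in range(4):
            sel = cat == c
            if sel.any():
                idx[sel] = np.searchsorted(simplex_cums[c], u[sel],
                                           side="right")
        return MOTIFS[np.clip(idx, 0, 63)]

    motif_left = _motifs(left_alu)
    motif_right = _motifs(right_alu)

    dup = np.zeros(n, dtype=bool)
    if config.duplicate_rate > 0:
        dup = rng.random(n) < config.duplicate_rate

    df = pd.DataFrame({
        "chrom": chrom,
        "start": start,
        "end": end,
        "length": lengths,
        "motif5_left": motif_left,
        "motif5_right": motif_right,
        "mapq": np.full(n, 60, dtype=np.int64),
        "is_duplicate": dup,
    }).sort_values(["chrom", "start", "end"], kind="mergesort"
                   ).reset_index(drop=True)

    fs = SampleFragmentSet(sample_id, subject_id, timepoint, df)
    fs.provenance.update(tumor_fraction=tf, seed=int(seed),
                         config_seed=config.seed)
    return fs


def simulate_healthy_sample(config: SimulationConfig, seed: int,
                            sample_id: str | None = None) -> SampleFragmentSet:
    """One healthy-donor plasma sample; deterministic given (config, seed)."""
    return _simulate(config, 0.0, seed, sample_id or f"HD{seed:04d}",
                     subject_id="", timepoint="healthy")


def simulate_tumor_sample(config: SimulationConfig, tf: float, seed: int,
                          sample_id: str | None = None,
                          subject_id: str = "",
                          timepoint: str = "baseline") -> SampleFragmentSet:
    """One patient plasma sample at tumor fraction ``tf``.

    ``tf = 0`` reduces exactly to :func:`simulate_healthy_sample` (same code
    path, same RNG stream).
    """
    return _simulate(config, tf, seed, sample_id or f"TU{seed:04d}",
                     subject_id=subject_id, timepoint=timepoint)


# --------------------------------------------------------------------------
# cohort
# --------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    config: SimulationConfig
    healthy: list
    patient_samples: dict            # subject_id -> {timepoint: SampleFragmentSet}
    clinical: pd.DataFrame
    truth: pd.DataFrame

    def all_patient_fragsets(self):
        for subject in sorted(self.patient_samples):
            for tp, fs in self.patient_samples[subject].items():
                yield fs


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Healthy cohort plus per-subject baseline / cycle-4 (/progression)
    samples with linked exponential survival outcomes."""
    config.validate()
    rng = np.random.default_rng([config.seed, 424_242])
    healthy = [simulate_healthy_sample(config, seed=i)
               for i in range(config.n_healthy)]

    lo, hi = config.baseline_tf_range
    om = config.outcome_model
    patient_samples: dict = {}
    clin_rows, truth_rows = [], []
    for j in range(config.n_subjects):
        subject = f"P{j:03d}"
        baseline_tf = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        nonresponder = bool(rng.random() < config.nonresponder_fraction)
        if nonresponder:
            f_lo, f_hi = config.nonresponder_cycle4_factor_range
            factor = float(rng.uniform(f_lo, f_hi))
        else:
            factor = float(config.responder_cycle4_factor)
        cycle4_tf = baseline_tf * factor
        residual_truth = cycle4_tf > 0.0

        samples = {
            "baseline": simulate_tumor_sample(
                config, baseline_tf, seed=1000 + j,
                sample_id=f"{subject}_baseline", subject_id=subject,
                timepoint="baseline"),
            "cycle4": simulate_tumor_sample(
                config, cycle4_tf, seed=2000 + j,
                sample_id=f"{subject}_cycle4", subject_id=subject,
                timepoint="cycle4"),
        }
        has_prog = bool(rng.random() < config.progression_fraction)
        prog_tf = np.nan
        if has_prog:
            m_lo, m_hi = config.progression_tf_multiplier_range
            prog_tf = baseline_tf * float(rng.uniform(m_lo, m_hi))
            samples["progression"] = simulate_tumor_sample(
                config, min(prog_tf, 1.0), seed=3000 + j,
                sample_id=f"{subject}_progression", subject_id=subject,
                timepoint="progression")
        patient_samples[subject] = samples

        hazard = om.base_hazard_per_month * np.exp(
            om.loghr_residual * residual_truth)
        t_pfs = float(rng.exponential(1.0 / hazard))
        horizon = om.censoring_horizon_months
        pfs_months = min(t_pfs, horizon)
        pfs_event = t_pfs <= horizon
        t_os = t_pfs + float(rng.exponential(1.0 / om.os_extra_hazard))
        os_months = min(t_os, horizon)
        os_event = t_os <= horizon

        tps_cat = rng.random()
        if tps_cat < 0.143:
            tps = 0.0
        elif tps_cat < 0.51:
            tps = float(rng.integers(1, 50))
        else:
            tps = float(rng.integers(50, 101))
        clin_rows.append({
            "subject_id": subject,
            "age": int(np.clip(round(rng.normal(66, 8)), 40, 90)),
            "sex": "male" if rng.random() < 0.71 else "female",
            "histology": ("adeno" if (h := rng.random()) < 0.755
                          else "squamous" if h < 0.975 else "NOS"),
            "stage": "III" if rng.random() < 0.08 else "IV",
            "therapy": "mono" if rng.random() < 0.53 else "combo",
            "pd_l1_tps": tps,
            "tp53_status": ("mutated" if (t := rng.random()) < 0.35
                            else "wildtype" if t < 0.78 else "unknown"),
            "ldh": float(np.exp(rng.normal(np.log(220), 0.3))),
            "crp": float(np.exp(rng.normal(np.log(5), 0.8))),
            "hemoglobin": float(rng.normal(13.5, 1.5)),
            "creatinine": float(rng.normal(0.9, 0.15)),
            "nlr": float(np.exp(rng.normal(np.log(3.5), 0.4))),
            "platelets": float(rng.normal(260, 60)),
            "pfs_months": pfs_months,
            "pfs_event": bool(pfs_event),
            "os_months": os_months,
            "os_event": bool(os_event),
        })
        truth_rows.append({
            "subject_id": subject,
            "baseline_tf": baseline_tf,
            "cycle4_tf": cycle4_tf,
            "progression_tf": prog_tf,
            "residual_truth": residual_truth,
        })

    return SyntheticCohort(config, healthy, patient_samples,
                           pd.DataFrame(clin_rows), pd.DataFrame(truth_rows))


# --------------------------------------------------------------------------
# writers
# --------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Persist a cohort as plain-text tables (fragments, clinical, truth,
    Alu BED, bins, config)."""
    import yaml
    from pathlib import Path
    from .fragments import write_fragment_table

    outdir = Path(outdir)
    (outdir / "fragments").mkdir(parents=True, exist_ok=True)
    manifest = []
    for fs in list(cohort.healthy) + list(cohort.all_patient_fragsets()):
        path = outdir / "fragments" / f"{fs.sample_id}.tsv"
        write_fragment_table(fs, path)
        manifest.append({"sample_id": fs.sample_id,
                         "subject_id": fs.subject_id,
                         "timepoint": fs.timepoint,
                         "path": str(path.relative_to(outdir))})
    pd.DataFrame(manifest).to_csv(outdir / "samples.tsv", sep="\t", index=False)
    cohort.clinical.to_csv(outdir / "clinical.csv", index=False)
    cohort.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    alu_intervals_frame(cohort.config).to_csv(
        outdir / "alu.bed", sep="\t", index=False, header=False)
    ctx = _context(cohort.config)
    ctx.bins.to_frame().to_csv(outdir / "bins.tsv", sep="\t", index=False)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config_to_dict(cohort.config), fh, sort_keys=False)
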