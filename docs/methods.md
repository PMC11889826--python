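# Methods

`cfmon` re-implements, as a tested pipeline over a synthetic cohort
generator, a tumor-agnostic strategy for quantifying and monitoring
circulating tumor DNA (ctDNA) from low-coverage whole-genome sequencing
(lcWGS) of plasma cell-free DNA (cfDNA): genome-wide copy-number
instability scoring, a patient-informed refinement of it, five fragmentomic
markers, healthy-cohort specificity calibration, marker combination, and
longitudinal response stratification with survival analysis.

## The marker panel

All coordinates are 0-based half-open; a *fragment* is the outer span of a
properly paired read pair. Fragmentomic markers are computed on the
mononucleosomal peak (fragments ≤ 250 bp, after a minimum-length filter of
50 bp and duplicate removal); CNV profiling deliberately uses all fragment
lengths.

**CPA (copy-number abnormality).** Bin counts (fragment midpoints, 500 kb
bins on the toy genome) are library-size scaled, GC-corrected by median
ratio per GC decile, and divided by a panel-of-normals expectation built
from healthy donors only; log2 ratios are segmented per chromosome by
optimal partitioning (L2 cost, penalty `3·σ̂²·log n` with σ̂ a robust MAD
estimate from first differences). CPA is the length-weighted mean absolute
segment log2 ratio, Σ L_s·|r̄_s| / Σ L_s. The score is used only relative
to its own healthy-derived threshold, so any strictly monotone variant of
the published scaling is equivalent for detection.

**ctCPA (tumor-informed CPA).** For a subject whose baseline is
CNV-detectable (CPA above threshold), segments qualify as *informative*
when the z-score of the segment mean — mean bin z times √n_bins — is at
least 3 in magnitude and the segment spans ≥ 3 bins. We use the z of the
mean rather than the mean bin z because whole-chromosome CNVs at modest
tumor fraction produce per-bin z well below any useful cut while the
segment-level evidence is overwhelming; a per-bin rule would make exactly
the baselines the method targets unusable. A follow-up sample's ctCPA is
the signed, length-weighted mean of its bin log2 ratios inside the
informative segments, oriented by the baseline segment signs: positive when
the follow-up deviates in the baseline's direction, ≈ 0 for copy-neutral
plasma, negative for inverted deviation. The ctCPA null distribution is
patient-specific: every healthy panel profile is projected through the same
informative set and thresholded like any other marker. When no segment
qualifies, ctCPA is undefined and callers fall back to CPA.

**P126-135 / D126-135.** The fraction of mononucleosomal fragments with
length in [126, 135] bp (both boundaries inclusive; denominator = all
fragments surviving the filters), and its absolute deviation from the
healthy-cohort median. The absolute deviation exists because tumor burden
can shift the short-fragment fraction in either direction; D126-135 is
one-sided-high by construction.

**MDS (motif diversity score).** Shannon entropy of the 64 fragment-end
trinucleotide frequencies, pooled over both ends (the right-end motif is
reverse-complemented at read time so both ends are read 5'→3' off the cut),
normalized by log 64 into [0, 1]. The log base cancels.

**Alu CGN/NCG ratio.** Among end motifs of ends falling inside Alu
intervals, the ratio of CG-leading (CG·) to CG-trailing (·CG) motifs, each
count + 0.5 pseudocount. A 3-mer can never match both patterns. Elevated
CG-leading ends inside Alu elements are the fragmentomic signature of Alu
hypomethylation and are treated as tumor-like (direction high;
configurable).

**iwFAF (information-weighted fraction of aberrant fragments).** A
reference of recurrent healthy end positions is built from ≥ 5 healthy
samples: positions used as a fragment end (either end) by at least
k = ⌈n_healthy/4⌉ distinct donors, with pooled usage frequencies. A
fragment is aberrant iff neither end lies within `window` bp (default 0) of
a reference position. Each fragment is weighted by the self-information
−log p̂ of its less frequent end (pseudocount-floored for unmatched ends);
iwFAF is the weighted share of aberrant fragments. The exact published
weighting is not restated in the primary description; this self-information
weighting is our declared reconstruction preserving the name's semantics.

## Detection and combination

Per-marker thresholds are order statistics of the healthy cohort: the
smallest healthy value t such that the share of healthy values strictly
above t is ≤ 1 − specificity (default specificity 0.95; symmetric for
direction-low markers). Ties at the threshold call negative, so the
calibration-cohort specificity guarantee is exact. There is no
interpolation: the rule is conservative, exact, and reproducible. On truly
held-out healthy samples the expected exceedance of such a threshold is
(k+1)/(n+1) where k = ⌊n(1−spec)⌋ — about 7.3% at n = 40, 5.2% at n = 57 —
which is why the held-out false-positive rate sits slightly above the
nominal 5% at small calibration cohorts.

Combination rules: `cnv_detect` = CPA⁺ ∨ ctCPA⁺; `ctdna_any` = any marker⁺;
`residual_ctdna` = cnv_detect ∨ iwFAF⁺ (the post-cycle-4 construct).
Markers that cannot be evaluated (e.g. ctCPA without informative segments)
count as negative and carry a not-evaluable flag. Longitudinal categories
on the residual basis: (−,−) double-negative, (+,−) clearance, (·,+)
residual-positive. The integrated risk group A requires PD-L1 TPS ≥ 1%,
undetectable baseline D126-135, and no residual ctDNA after 4 cycles;
anything else (or TPS < 1%) is group B. Cohort quantile splits use the
linear-interpolation empirical quantile.

## Outcomes

Durable vs short clinical response is dichotomized at 12 months PFS
(SCR iff PFS ≤ 12 with an event; subjects censored before 12 months are not
evaluable — the boundary case is unexercised in the emulated cohort design,
so we refuse to guess). Censoring is administrative: event = 0 at the
horizon. Kaplan-Meier/log-rank and Cox proportional-hazards machinery is
delegated to lifelines, rank tests and Spearman correlation to scipy; the
package tests their contracts against hand-built risk tables, exhaustive
permutation p-values, and coverage simulations rather than re-deriving
them. Correlations are banded at |ρ| ≥ 0.25 (moderate) and ≥ 0.7 (strong)
with p < 0.05. P-values are reported unadjusted.

## The synthetic cohort generator

The generator is first-class, tested code: it defines the statistical
structure every marker assumes, at desk scale.

* **Genome.** Two 50 Mb chromosomes, 500 kb bins. Tumor copy numbers
  default to a grossly aneuploid clone typical of advanced disease: chr1
  entirely gained (CN 3 over 0–30 Mb, CN 4 over 30–50 Mb), chr2 mostly lost
  (CN 1 over 0–30 Mb and 40–50 Mb). Mean tumor ploidy 2.3. Per-bin GC runs
  a slow sinusoid (period 8.65 Mb, incommensurate with segment boundaries)
  and multiplies sampling weights by 1 + gc_bias·(gc − ḡ), so GC deciles
  sample all copy-number states and the decile-median correction removes GC
  without absorbing CNV signal.
* **Mixture sampling.** A fragment is tumor-derived with the DNA-mass
  probability tf·CN̄/((1−tf)·2 + tf·CN̄); tumor positions are CN-weighted,
  so expected bin counts follow (1−tf)·2 + tf·CN(x) and a tf = 0 sample is
  the healthy sampler on the identical RNG stream.
* **Lengths (bp).** Healthy: Gaussian core at 166 (sd 9), a 10-bp sawtooth
  of sub-peaks below 160 (total weight 0.12, geometric decay), and a small
  dinucleosomal tail at 310 (weight 0.04). Tumor-derived fragments replace
  70% of that mixture with a short mode at 143 (sd 9), which raises the
  [126, 135] window mass from ≈ 0.017 (healthy) to ≈ 0.13 (pure tumor).
  The analytic window mass of the configured mixture is exposed for tests.
* **End motifs.** Healthy ends follow a product-of-positions composition
  sharpened by a 12% spike on one dominant motif (MDS ≈ 0.94); tumor ends
  use the same simplex flattened (raised to 0.55 and renormalized), i.e.
  more diverse ends. Inside Alu intervals (regular 300 bp intervals every
  1.5 kb, ≈ 20% of the genome, written as BED) the CG-leading/CG-trailing
  block masses are 0.04/0.10 for healthy and 0.30/0.10 for tumor ends.
* **End positions.** ≈ 30 preferred sites per Mb are drawn once per cohort
  and shared by all samples; healthy left ends snap to the nearest site
  with probability 0.85, tumor fragments lose 75% of that adherence. The
  site density is deliberately matched to the desk-scale fragment count
  (10⁴ per sample) so each site collects ~3 healthy ends per sample and the
  recurrence rule k = ⌈n/4⌉ yields a dense reference; at realistic
  nucleosome spacing the same rule would select nothing at this depth.
* **Outcomes.** Exponential PFS with base hazard 0.076/month (median ≈ 9
  months) multiplied by e^{log 4} for subjects with residual tumor fraction
  at cycle 4; OS adds an independent exponential tail; administrative
  censoring at a configurable horizon (60 months default; 12 months in the
  hazard-recovery experiment, giving ≈ 20% censoring). Baseline tumor
  fractions are log-uniform on [0.01, 0.30] (≈ 60% CNV-detectable
  baselines, mirroring a mixed-burden population); responders clear to
  tf = 0 at cycle 4, non-responders retain 70–100% of baseline.

Effect sizes (short-fragment weight, motif flattening, Alu emission,
adherence loss, CNV architecture) were fixed once by power analysis so that
every marker's expected value is monotone in tumor fraction and resolvable
at 10⁴ fragments per sample; a dilution-series pilot confirmed Spearman
ρ > 0.9 for all markers before the tests were frozen.

What the generator does **not** emulate: sequencing error, mappability and
real GC structure, chromatin-state-dependent fragmentation, inter-donor
biological variation in motif usage or nucleosome spacing, non-exponential
hazards, or informative censoring. Passing tests therefore demonstrate the
correctness and statistical behavior of the pipeline under its stated
assumptions, not clinical performance on real plasma.

## Problem sizes and numerics

Per-sample fragment counts default to 10⁴ (the low-tumor-fraction
sensitivity experiment uses the same), healthy cohorts to 40–57 samples,
and recovery experiments to 20 replicates — sizes chosen so the full
analysis runs on a laptop-class single core in minutes while every
monotonicity and calibration property remains resolvable. Normalized
counts are floored at 10⁻³ before logs so empty bins stay finite;
segmentation falls back to a single segment for < 2 usable bins; Cox fits
refuse configurations with fewer events than covariates and report
separation diagnostics instead of diverging.

## Known limitations

* The CPA/ctCPA formulas are reconstructions (length-weighted mean
  |segment ratio|; signed projection): the primary description cites but
  does not restate its exact scaling, and only threshold-relative behavior
  is exercised here.
* Whether ctCPA should use bin- or segment-level follow-up ratios, and
  whether the published MDS/Alu metrics use one or both fragment ends, is
  unstated in the primary description; this package uses bin-level ratios
  and both ends, declared in the docstrings.
* At a 40-donor calibration cohort the order-statistic threshold's held-out
  false-positive rate is ≈ 7.3% in expectation with wide sampling spread
  (Beta(3, 38)); specificity-critical deployments need larger healthy
  cohorts, which is why the cohort default is 57.
* No tumor-fraction point estimation, allele-specific copy number, or
  genome-wide fragmentation profiles; no multiple-testing correction.
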