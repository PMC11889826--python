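# cfmon — tumor-agnostic ctDNA quantification and monitoring from lcWGS

`cfmon` implements a tumor-agnostic pipeline for quantifying and tracking
circulating tumor DNA (ctDNA) in plasma from low-coverage whole-genome
sequencing (lcWGS) of cell-free DNA (cfDNA), aimed at response monitoring
in advanced cancer under immune checkpoint blockade. It is written for
computational biologists who want the complete chain — from aligned
fragments to survival stratification — as a tested, reusable library,
exercised end-to-end on a built-in synthetic cfDNA cohort generator (no
controlled-access patient data required).

## What it computes

From each plasma sample's fragments (BAM or plain fragment table), seven
markers:

* **CPA** — chromosomal instability as the length-weighted mean absolute
  segment log2 copy ratio, Σ L_s·|r̄_s| / Σ L_s, from panel-of-normals
  normalized 500 kb bin counts;
* **ctCPA** — tumor-informed refinement: the signed projection
  Σ L_s·sign(r̄_s^base)·r̄_s^follow-up / Σ L_s over patient-specific CNV
  segments found in a prior CNV⁺ sample of the same subject;
* **P126-135** — proportion of mononucleosomal (≤ 250 bp) fragments of
  126–135 bp, and **D126-135**, its absolute deviation from the healthy
  cohort median;
* **MDS** — fragment-end trinucleotide diversity,
  −Σ f_m log f_m / log 64 ∈ [0, 1];
* **Alu CGN/NCG** — ratio of CG-leading to CG-trailing end motifs inside
  Alu intervals (fragmentomic proxy for Alu hypomethylation);
* **iwFAF** — information-weighted fraction of fragments with neither end
  at a recurrent healthy end position.

Per-marker detection thresholds are order statistics of a healthy cohort at
95% specificity; samples call positive only strictly beyond a threshold.
Combination rules (`cnv_detect` = CPA⁺ ∨ ctCPA⁺; `residual_ctdna` =
cnv_detect ∨ iwFAF⁺), longitudinal categories (double-negative /
clearance / residual-positive), the integrated PD-L1 TPS + D126-135 +
residual-ctDNA risk groups, and Kaplan-Meier/log-rank/Cox survival
analysis complete the pipeline. See `docs/methods.md` for definitions,
assumptions, and design choices.

## Worked example

The numbered drivers under `analysis/` run the whole study on a synthetic
cohort (57 healthy donors, 49 subjects with baseline and cycle-4 plasma):

```bash
python analysis/01_simulate_cohort.py 1     # writes scratch/cohort/
python analysis/02_score_and_call.py        # writes results/pipeline/
python analysis/03_detection_summary.py
python analysis/04_survival_stratification.py
python analysis/05_benchmark_experiments.py
```

With seed 1 this prints, among others:

```
scored 121 patient samples
  ctDNA+ by any marker: 103 (85.1%)
  CNV-detectable (CPA or ctCPA): 67 (55.4%)

timepoint   n  cnv_detect  ctdna_any  gain_over_cnv_pct
      all 121          67        103               29.8
 baseline  49          31         49               36.7
   cycle4  49          20         31               22.4

             grouping endpoint       hr   ci_low  ci_high  logrank_p  median_pfs_neg  median_pfs_pos
residual_ctdna_cycle4      PFS 3.803756 1.905880 7.591536   0.000066       12.463106        1.402784
```

Reading: 55% of patient samples carry detectable copy-number signal, and
adding the five fragmentomic markers lifts detection by ~30 percentage
points — the markers are complementary, not redundant. Patients with
residual ctDNA after four therapy cycles progress about four times faster
(the cohort was generated with a true hazard ratio of 4; the pipeline
recovers HR ≈ 3.8, 95% CI 1.9–7.6) and their median progression-free
survival drops from ~12.5 to ~1.4 months.

The same machinery is scriptable as a CLI
(`cfmon simulate|extract|cnv|markers|calibrate|detect|outcomes|run`) or as
a library:

```python
from cfmon import (default_config, simulate_cohort, run_cohort)

cohort = simulate_cohort(default_config(seed=7))
results = run_cohort(cohort)          # scores, calls, survival fits
print(results.survival)
```

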