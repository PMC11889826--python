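"""Generate the study cohort: 57 healthy donors and 49 NSCLC-like subjects
with baseline / cycle-4 (/progression) plasma samples and linked outcomes.

Writes fragment tables, the clinical table, per-sample truth, Alu intervals
and the genome bins under scratch/cohort/ (raw per-sample data is bulky and
regenerable; only summary tables live under results/).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from cfmon.simulate import default_config, simulate_cohort, write_cohort

OUT = Path(__file__).resolve().parents[1] / "scratch" / "cohort"


def main(seed: int = 1) -> None:
    cfg = default_config(seed=seed)
    cohort = simulate_cohort(cfg)
    write_cohort(cohort, OUT)
    n_samples = sum(len(s) for s in cohort.patient_samples.values())
    print(f"cohort: {cfg.n_healthy} healthy donors, {cfg.n_subjects} "
          f"subjects, {n_samples} patient samples -> {OUT}")
    print(f"residual-positive truth: "
          f"{int(cohort.truth['residual_truth'].sum())}/{cfg.n_subjects}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
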